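"""Segmentation evaluation suite.

Overlap and confusion metrics (Dice, IoU, accuracy, precision, recall,
specificity, F1), boundary distances (95th-percentile Hausdorff, average
symmetric surface distance, median surface distance) and the structural
similarity index.

Conventions for degenerate inputs: two empty masks agree perfectly (Dice =
IoU = 1), an empty against a nonempty mask scores 0, and zero-denominator
confusion ratios return 0 rather than NaN.  Surface distances require both
masks to be nonempty and raise otherwise.  Boundaries are extracted as the
4-connectivity erosion difference and distances are in pixel units.
"""

from __future__ import annotations

from dataclasses import dataclass, asdict

import numpy as np
from scipy import ndimage as ndi
from scipy.spatial import cKDTree
from skimage.metrics import structural_similarity

__all__ = [
    "ConfusionCounts",
    "MetricReport",
    "confusion_counts",
    "dice",
    "iou",
    "basic_rates",
    "surface_distances",
    "ssim",
    "metric_report",
    "mean_report",
]

_CROSS = np.array([[0, 1, 0], [1, 1, 1], [0, 1, 0]], dtype=bool)


@dataclass(frozen=True)
class ConfusionCounts:
    tp: int
    tn: int
    fp: int
    fn: int

    @property
    def total(self) -> int:
        return self.tp + self.tn + self.fp + self.fn


@dataclass
class MetricReport:
    dice: float
    iou: float
    accuracy: float
    precision: float
    recall: float
    specificity: float
    f1: float
    hd95: float = np.nan
    assd: float = np.nan
    msd: float = np.nan
    ssim: float = np.nan

    def as_dict(self) -> dict:
        return asdict(self)


def _as_binary(mask) -> np.ndarray:
    arr = np.asarray(getattr(mask, "pixels", mask))
    uniq = np.unique(arr)
    if not np.all(np.isin(uniq, (0, 1))):
        raise ValueError("mask must be binary with values in {0, 1}")
    return arr.astype(bool)


def confusion_counts(pred, truth) -> ConfusionCounts:
    p, g = _as_binary(pred), _as_binary(truth)
    if p.shape != g.shape:
        raise ValueError("prediction and truth shapes differ")
    return ConfusionCounts(
        tp=int(np.sum(p & g)),
        tn=int(np.sum(~p & ~g)),
        fp=int(np.sum(p & ~g)),
        fn=int(np.sum(~p & g)),
    )


def dice(pred, truth) -> float:
    p, g = _as_binary(pred), _as_binary(truth)
    sp, sg = int(p.sum()), int(g.sum())
    if sp == 0 and sg == 0:
        return 1.0
    return 2.0 * np.sum(p & g) / (sp + sg)


def iou(pred, truth) -> float:
    p, g = _as_binary(pred), _as_binary(truth)
    union = np.sum(p | g)
    if union == 0:
        return 1.0
    return float(np.sum(p & g) / union)


def _safe_ratio(num: int, den: int) -> float:
    return num / den if den else 0.0


def basic_rates(c: ConfusionCounts) -> tuple[float, float, float, float, float]:
    """(accuracy, precision, recall, specificity, F1); zero denominators
    yield 0."""
    accuracy = _safe_ratio(c.tp + c.tn, c.total)
    precision = _safe_ratio(c.tp, c.tp + c.fp)
    recall = _safe_ratio(c.tp, c.tp + c.fn)
    specificity = _safe_ratio(c.tn, c.tn + c.fp)
    f1 = _safe_ratio(2 * c.tp, 2 * c.tp + c.fp + c.fn)
    return accuracy, precision, recall, specificity, f1


def _boundary(mask: np.ndarray) -> np.ndarray:
    """4-connectivity boundary: mask minus its erosion."""
    eroded = ndi.binary_erosion(mask, structure=_CROSS, border_value=0)
    return mask & ~eroded


def surface_distances(pred, truth) -> tuple[float, float, float]:
    """(HD95, ASSD, MSD) between the mask boundaries, in pixels.

    HD95 takes the max of the two directed 95th-percentile distances; ASSD is
    the mean and MSD the median of the distances pooled over both directions
    (so all three are symmetric in their arguments).
    """
    p, g = _as_binary(pred), _as_binary(truth)
    if not p.any():
        raise ValueError("surface distances undefined: prediction mask is empty")
    if not g.any():
        raise ValueError("surface distances undefined: truth mask is empty")
    bp = np.argwhere(_boundary(p))
    bg = np.argwhere(_boundary(g))
    d_pg = cKDTree(bg).query(bp)[0]
    d_gp = cKDTree(bp).query(bg)[0]
    hd95 = max(np.percentile(d_pg, 95), np.percentile(d_gp, 95))
    pooled = np.concatenate([d_pg, d_gp])
    return float(hd95), float(pooled.mean()), float(np.median(pooled))


def ssim(pred_soft, truth) -> float:
    """Structural similarity with a 7x7 Gaussian window, k1=0.01, k2=0.03,
    data range 1."""
    a = np.asarray(getattr(pred_soft, "pixels", pred_soft), dtype=np.float64)
    b = np.asarray(getattr(truth, "pixels", truth), dtype=np.float64)
    if a.shape != b.shape:
        raise ValueError("ssim inputs must share a shape")
    return float(structural_similarity(
        a, b, win_size=7, gaussian_weights=True, sigma=1.5,
        K1=0.01, K2=0.03, data_range=1.0))


def metric_report(pred, truth, pred_soft=None) -> MetricReport:
    """All metrics for one prediction/truth pair.

    Surface distances are reported as NaN when either mask is empty; SSIM is
    computed from ``pred_soft`` when given, else from the binary prediction.
    """
    c = confusion_counts(pred, truth)
    accuracy, precision, recall, specificity, f1 = basic_rates(c)
    report = MetricReport(
        dice=dice(pred, truth), iou=iou(pred, truth), accuracy=accuracy,
        precision=precision, recall=recall, specificity=specificity, f1=f1,
    )
    try:
        report.hd95, report.assd, report.msd = surface_distances(pred, truth)
    except ValueError:
        pass
    soft = pred_soft if pred_soft is not None else _as_binary(pred).astype(np.float64)
    report.ssim = ssim(soft, _as_binary(truth).astype(np.float64))
    return report


def mean_report(reports: list[MetricReport]) -> MetricReport:
    """Field-wise arithmetic mean over per-pair reports (NaN-aware for the
    surface distances)."""
    if not reports:
        raise ValueError("no reports to average")
    fields = reports[0].as_dict().keys()
    vals = {}
    for f in fields:
        col = np.array([r.as_dict()[f] for r in reports])
        finite = col[np.isfinite(col)]
        vals[f] = float(finite.mean()) if finite.size else float("nan")
    return MetricReport(**vals)
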