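"""Tumor-likelihood prior channel.

The fourth network input is a per-pixel tumor-likelihood map built without
any learned weights: estimate the brain region (automatic threshold, largest
connected component, holes filled), z-score intensities within it, cluster
the within-brain intensities with K-means (k = 3), keep the cluster with the
highest mean intensity as the tumor candidate, clean it morphologically
(3 x 3 closing then 3 x 3 median filter), soften the binary candidate by
distance-to-boundary, and min-max scale the result to [0, 1].

Because z-scoring absorbs any positive affine intensity change, the whole
pipeline is invariant to ``a * I + b`` (a > 0) rescalings of the input.
"""

from __future__ import annotations

import warnings

import numpy as np
from scipy import ndimage as ndi
from skimage import filters, measure, morphology
from sklearn.cluster import KMeans

from .types import BinaryMask, ImageVolume

__all__ = [
    "brain_mask_estimate",
    "zscore",
    "kmeans_intensity",
    "select_tumor_candidate",
    "refine_mask",
    "build_prior",
    "assemble_four_channel",
]

_SQUARE3 = np.ones((3, 3), dtype=bool)


def _gray(image: ImageVolume | np.ndarray) -> np.ndarray:
    px = image.pixels if isinstance(image, ImageVolume) else np.asarray(image, dtype=np.float64)
    if px.ndim == 3:
        px = px.mean(axis=2)
    return px


def brain_mask_estimate(image: ImageVolume | np.ndarray) -> BinaryMask:
    """Foreground (brain) mask: Otsu threshold on the channel-mean image,
    largest connected component, holes filled.

    An all-zero (or constant) image yields an empty mask and a warning.
    """
    gray = _gray(image)
    if np.ptp(gray) == 0:
        warnings.warn("constant image: returning an empty brain mask", stacklevel=2)
        return BinaryMask(np.zeros(gray.shape, dtype=np.uint8))
    thr = filters.threshold_otsu(gray)
    fg = gray > thr
    if not fg.any():
        warnings.warn("no foreground above threshold: empty brain mask", stacklevel=2)
        return BinaryMask(np.zeros(gray.shape, dtype=np.uint8))
    labels = measure.label(fg, connectivity=1)
    largest = labels == np.argmax(np.bincount(labels.ravel())[1:]) + 1
    filled = ndi.binary_fill_holes(largest)
    return BinaryMask(filled.astype(np.uint8))


def zscore(image: ImageVolume | np.ndarray, brain_mask: BinaryMask) -> ImageVolume:
    """Z-score intensities within the brain mask; outside pixels are 0.

    A constant within-mask region maps to all zeros.
    """
    gray = _gray(image)
    m = brain_mask.pixels.astype(bool)
    if not m.any():
        raise ValueError("brain mask is empty")
    vals = gray[m]
    sd = vals.std()
    out = np.zeros_like(gray)
    if sd > 0:
        out[m] = (vals - vals.mean()) / sd
    return ImageVolume(out[:, :, None], channel_names=("zscore",))


def kmeans_intensity(image: ImageVolume | np.ndarray, brain_mask: BinaryMask,
                     k: int = 3, seed: int = 0) -> np.ndarray:
    """K-means (k-means++ seeding, Lloyd iterations to 1e-6 or 100 iters) on
    the 1-D within-mask intensities.  Returns an H x W label image with -1
    outside the mask and cluster ids inside; deterministic for a fixed seed.
    """
    gray = _gray(image)
    m = brain_mask.pixels.astype(bool)
    vals = gray[m].reshape(-1, 1)
    if len(np.unique(vals)) < k:
        raise ValueError(f"need at least {k} distinct masked intensities")
    km = KMeans(n_clusters=k, init="k-means++", n_init=10, max_iter=100, tol=1e-6,
                random_state=seed)
    labels = km.fit_predict(vals)
    out = np.full(gray.shape, -1, dtype=np.int32)
    out[m] = labels
    return out


def select_tumor_candidate(labels: np.ndarray, image: ImageVolume | np.ndarray
                           ) -> BinaryMask:
    """Binary mask of the cluster with the highest mean intensity (ties break
    toward the lowest cluster index)."""
    gray = _gray(image)
    ids = np.unique(labels[labels >= 0])
    means = np.array([gray[labels == i].mean() for i in ids])
    best = ids[int(np.argmax(means))]  # argmax returns the first maximum
    return BinaryMask((labels == best).astype(np.uint8))


def refine_mask(mask: BinaryMask) -> BinaryMask:
    """Morphological closing (3 x 3) followed by a 3 x 3 median filter."""
    m = mask.pixels.astype(bool)
    closed = morphology.closing(m, footprint=_SQUARE3)
    med = ndi.median_filter(closed.astype(np.uint8), size=3)
    return BinaryMask(med.astype(np.uint8))


def _soften(candidate: np.ndarray) -> np.ndarray:
    """Turn a binary candidate into a graded likelihood: 0 outside, and
    0.5 + 0.5 * (normalized distance to boundary) inside, so that candidate
    pixels always score above background while the blob core scores highest."""
    if not candidate.any():
        return np.zeros(candidate.shape, dtype=np.float64)
    dist = ndi.distance_transform_edt(candidate)
    return np.where(candidate, 0.5 + 0.5 * dist / dist.max(), 0.0)


def build_prior(image: ImageVolume | np.ndarray, seed: int = 0) -> ImageVolume:
    """Full prior pipeline; returns an H x W x 1 map in [0, 1].

    Degenerate inputs (empty brain mask, constant within-mask intensities,
    or fewer than three distinct values) fall back to an all-zero prior.
    """
    gray = _gray(image)
    brain = brain_mask_estimate(image)
    if not brain.pixels.any():
        return ImageVolume(np.zeros(gray.shape + (1,)), channel_names=("prior",))
    z = zscore(image, brain)
    try:
        labels = kmeans_intensity(z, brain, k=3, seed=seed)
    except ValueError:
        return ImageVolume(np.zeros(gray.shape + (1,)), channel_names=("prior",))
    candidate = select_tumor_candidate(labels, z)
    refined = refine_mask(candidate)
    soft = _soften(refined.pixels.astype(bool))
    lo, hi = soft.min(), soft.max()
    prior = (soft - lo) / (hi - lo) if hi > lo else np.zeros_like(soft)
    return ImageVolume(prior[:, :, None], channel_names=("prior",))


def assemble_four_channel(image: ImageVolume, prior: ImageVolume | np.ndarray
                          ) -> np.ndarray:
    """Stack three MRI-like channels and the prior into a channel-first
    ``4 x H x W`` network input."""
    px = image.pixels
    if px.shape[2] != 3:
        raise ValueError(f"expected a 3-channel image, got {px.shape[2]} channels")
    pr = prior.pixels if isinstance(prior, ImageVolume) else np.asarray(prior, dtype=np.float64)
    if pr.ndim == 3:
        pr = pr[:, :, 0]
    if pr.shape != px.shape[:2]:
        raise ValueError("prior and image spatial shapes disagree")
    if not (np.all(np.isfinite(px)) and np.all(np.isfinite(pr))):
        raise ValueError("non-finite values in four-channel input")
    return np.concatenate([np.moveaxis(px, 2, 0), pr[None]], axis=0)
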