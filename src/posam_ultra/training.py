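"""Training loop with deep supervision, early stopping and checkpointing;
prediction and test-set evaluation.

Data flows as plain arrays: inputs ``(N, 4, H, W)`` (three image channels
plus the prior) and targets ``(N, H, W)`` in {0, 1}.  Each optimization step
computes the composite loss (BCE + Dice + focal) on the main output and both
auxiliary outputs and combines them as
``L_main + lambda1 * L_aux1 + lambda2 * L_aux2``.  Validation Dice is
computed in inference mode (auxiliary heads off, running batch-norm
statistics) at threshold 0.5; the checkpoint is overwritten whenever it
improves, and training stops early after ``patience`` non-improving epochs.
Runs are fully seeded and deterministic on CPU.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import metrics as M
from .losses import composite_loss, total_loss
from .network import PoSamUltraNet
from .optim import build_optimizer
from .phantom import apply_augmentation, sample_augmentation
from .prior import build_prior
from .types import (
    AugmentationConfig,
    BinaryMask,
    ImageVolume,
    LossWeights,
    NetworkConfig,
    TrainConfig,
)

__all__ = [
    "TrainRecord",
    "train",
    "save_checkpoint",
    "load_checkpoint",
    "predict",
    "evaluate",
    "prepare_inputs",
]


@dataclass
class TrainRecord:
    train_loss: list[float] = field(default_factory=list)
    val_dice: list[float] = field(default_factory=list)
    val_iou: list[float] = field(default_factory=list)
    best_epoch: int = -1
    best_val_dice: float = -1.0
    checkpoint_path: str | None = None
    stopped_early: bool = False


def prepare_inputs(images: list[ImageVolume], masks: list[BinaryMask],
                   seed: int = 0) -> tuple[np.ndarray, np.ndarray]:
    """Stack phantoms into network arrays, building the prior channel for
    each slice."""
    xs, ys = [], []
    for i, (img, msk) in enumerate(zip(images, masks)):
        prior = build_prior(img, seed=(seed + i) % (2**31))
        x = np.concatenate([np.moveaxis(img.pixels, 2, 0), prior.pixels[None, :, :, 0]],
                           axis=0)
        xs.append(x)
        ys.append(msk.pixels.astype(np.float64))
    return np.stack(xs), np.stack(ys)


def _augment_batch(xb: np.ndarray, yb: np.ndarray, aug: AugmentationConfig,
                   rng: np.random.Generator) -> tuple[np.ndarray, np.ndarray]:
    """On-the-fly augmentation of a channel-first batch.  Geometric draws hit
    all four channels and the mask; intensity draws hit the image channels
    only (the prior is a likelihood, not an intensity)."""
    xo = np.empty_like(xb)
    yo = np.empty_like(yb)
    for i in range(len(xb)):
        draw = sample_augmentation(aug, rng)
        img = ImageVolume(np.moveaxis(xb[i, :3], 0, 2))
        msk = BinaryMask((yb[i] > 0.5).astype(np.uint8))
        a_img, a_msk = apply_augmentation(img, msk, draw)
        geo = {**draw, "brightness": 0.0, "contrast": 0.0}
        a_prior, _ = apply_augmentation(
            ImageVolume(xb[i, 3][:, :, None]), msk, geo)
        xo[i, :3] = np.moveaxis(a_img.pixels, 2, 0)
        xo[i, 3] = a_prior.pixels[:, :, 0]
        yo[i] = a_msk.pixels
    return xo, yo


def _validation_dice(net: PoSamUltraNet, x: np.ndarray, y: np.ndarray,
                     batch_size: int, threshold: float = 0.5
                     ) -> tuple[float, float]:
    dices, ious = [], []
    for a in range(0, len(x), batch_size):
        probs = net.predict_proba(x[a : a + batch_size])
        for p, g in zip(probs[:, 0], y[a : a + batch_size]):
            pm = (p >= threshold).astype(np.uint8)
            gm = (g > 0.5).astype(np.uint8)
            dices.append(M.dice(pm, gm))
            ious.append(M.iou(pm, gm))
    return float(np.mean(dices)), float(np.mean(ious))


def train(model_cfg: NetworkConfig, train_cfg: TrainConfig,
          loss_weights: LossWeights, data: dict,
          checkpoint_path: str | Path = "checkpoint.npz",
          augmentation: AugmentationConfig | None = None,
          log=None) -> TrainRecord:
    """Train a network; ``data`` holds ``train=(X, Y)`` and ``val=(X, Y)``.

    Raises ``RuntimeError`` with diagnostics on a non-finite loss.
    """
    x_tr, y_tr = data["train"]
    x_va, y_va = data["val"]
    if len(x_tr) == 0 or len(x_va) == 0:
        raise ValueError("train and val sets must be nonempty")
    aug = augmentation if augmentation is not None else (
        AugmentationConfig() if train_cfg.augment else None)

    net = PoSamUltraNet(model_cfg)
    opt = build_optimizer(train_cfg.optimizer_name, net.parameters(),
                          train_cfg.learning_rate,
                          weight_decay=train_cfg.weight_decay,
                          momentum=train_cfg.momentum)
    rng = np.random.default_rng(train_cfg.seed)
    record = TrainRecord(checkpoint_path=str(checkpoint_path))
    lr0 = train_cfg.learning_rate
    since_best = 0

    for epoch in range(train_cfg.epochs):
        opt.lr = lr0 * 0.5 ** (epoch // train_cfg.lr_decay_step)
        net.train()
        order = rng.permutation(len(x_tr))
        losses = []
        for a in range(0, len(order), train_cfg.batch_size):
            idx = order[a : a + train_cfg.batch_size]
            xb, yb = x_tr[idx], y_tr[idx]
            if aug is not None:
                xb, yb = _augment_batch(xb, yb, aug, rng)
            out = net.forward(xb, mode="train")
            g = yb[:, None]
            loss = total_loss(
                composite_loss(out.main, g, loss_weights),
                composite_loss(out.aux1, g, loss_weights),
                composite_loss(out.aux2, g, loss_weights),
                loss_weights.lambda1, loss_weights.lambda2)
            value = float(loss)
            if not np.isfinite(value):
                raise RuntimeError(
                    f"non-finite training loss at epoch {epoch} (lr={opt.lr:g})")
            opt.zero_grad()
            loss.backward()
            opt.step()
            losses.append(value)
        vd, vi = _validation_dice(net, x_va, y_va, train_cfg.batch_size)
        record.train_loss.append(float(np.mean(losses)))
        record.val_dice.append(vd)
        record.val_iou.append(vi)
        if log:
            log(f"epoch {epoch}: loss={record.train_loss[-1]:.4f} val_dice={vd:.4f}")
        if vd > record.best_val_dice:
            record.best_val_dice = vd
            record.best_epoch = epoch
            since_best = 0
            save_checkpoint(net, checkpoint_path, extra={"val_dice": vd})
        else:
            since_best += 1
            if since_best >= train_cfg.patience:
                record.stopped_early = True
                break
    return record


# -- checkpointing ---------------------------------------------------------

def save_checkpoint(net: PoSamUltraNet, path: str | Path, extra: dict | None = None
                    ) -> Path:
    """Serialize weights, running statistics and the network config."""
    path = Path(path)
    meta = {"config": vars(net.cfg), "extra": extra or {}}
    state = {f"state/{k}": v for k, v in net.state_dict().items()}
    np.savez(path, __meta__=np.frombuffer(
        yaml.safe_dump(meta).encode(), dtype=np.uint8), **state)
    return path


def load_checkpoint(path: str | Path) -> tuple[PoSamUltraNet, dict]:
    with np.load(Path(path)) as npz:
        meta = yaml.safe_load(bytes(npz["__meta__"]).decode())
        state = {k[len("state/"):]: npz[k] for k in npz.files if k.startswith("state/")}
    net = PoSamUltraNet(NetworkConfig(**meta["config"]))
    net.load_state_dict(state)
    net.eval()
    return net, meta


# -- inference -------------------------------------------------------------

def _pad_to_multiple(x: np.ndarray, factor: int) -> tuple[np.ndarray, tuple]:
    h, w = x.shape[-2:]
    side = max(h, w)
    target = int(np.ceil(side / factor)) * factor
    ph, pw = target - h, target - w
    if ph == 0 and pw == 0:
        return x, (0, 0, h, w)
    pad = [(0, 0)] * (x.ndim - 2) + [(0, ph), (0, pw)]
    return np.pad(x, pad, mode="reflect"), (0, 0, h, w)


def predict(checkpoint: str | Path | PoSamUltraNet, images, threshold: float = 0.5,
            prior_seed: int = 0) -> list[np.ndarray]:
    """Binary masks for a list of 3-channel ``ImageVolume``s (or ready-made
    ``4 x H x W`` arrays).  Non-divisible resolutions are reflect-padded and
    cropped back."""
    net = checkpoint if hasattr(checkpoint, "predict_proba") else \
        load_checkpoint(checkpoint)[0]
    factor = 2 ** (net.cfg.n_stages + 1)
    out = []
    for i, item in enumerate(images):
        if isinstance(item, ImageVolume):
            prior = build_prior(item, seed=(prior_seed + i) % (2**31))
            x = np.concatenate(
                [np.moveaxis(item.pixels, 2, 0), prior.pixels[None, :, :, 0]], axis=0)
        else:
            x = np.asarray(item, dtype=np.float64)
        xp, (_, _, h, w) = _pad_to_multiple(x, factor)
        probs = net.predict_proba(xp[None])[0, 0, :h, :w]
        out.append((probs >= threshold).astype(np.uint8))
    return out


def evaluate(checkpoint: str | Path | PoSamUltraNet, x: np.ndarray, y: np.ndarray,
             batch_size: int = 8, threshold: float = 0.5,
             csv_path: str | Path | None = None
             ) -> tuple[list[M.MetricReport], M.MetricReport]:
    """Per-pair metric reports plus their mean on a test set of prepared
    arrays; optionally writes a CSV with one row per pair and a mean row."""
    if len(x) == 0:
        raise ValueError("test set is empty")
    net = checkpoint if hasattr(checkpoint, "predict_proba") else \
        load_checkpoint(checkpoint)[0]
    reports = []
    for a in range(0, len(x), batch_size):
        probs = net.predict_proba(x[a : a + batch_size])
        for p, g in zip(probs[:, 0], y[a : a + batch_size]):
            pm = (p >= threshold).astype(np.uint8)
            gm = (g > 0.5).astype(np.uint8)
            reports.append(M.metric_report(pm, gm))
    mean = M.mean_report(reports)
    if csv_path is not None:
        rows = [r.as_dict() for r in reports] + [{"pair": "mean", **mean.as_dict()}]
        pd.DataFrame(rows).to_csv(csv_path, index=False)
    return reports, mean
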