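"""Desk-scale reproducibility benchmarks.

Two seeded, CPU-sized experiments exercise the full pipeline end to end:

* :func:`overfit_benchmark` — a memorization smoke test: the tiny network
  (8 base filters, 3 stages, no dropout) is trained for 200 steps on a single
  phantom with Adam at lr 2e-3 and must reproduce that phantom's mask.
* :func:`desk_scale_benchmark` — the small-data study: train the tiny network
  on 200 synthetic phantoms (20 for validation) for up to 15 epochs with the
  default training settings, then evaluate on 50 held-out phantoms.
"""

from __future__ import annotations

import tempfile
from pathlib import Path

import numpy as np

from . import metrics as M
from .losses import composite_loss, total_loss
from .network import PoSamUltraNet
from .optim import Adam
from .phantom import generate_dataset, generate_phantom
from .training import evaluate, prepare_inputs, train
from .types import LossWeights, NetworkConfig, PhantomSpec, TrainConfig

__all__ = ["overfit_benchmark", "desk_scale_benchmark"]


def _tiny(seed: int, dropout: float) -> NetworkConfig:
    return NetworkConfig(base_filters=8, n_stages=3, cbam_reduction=4,
                         dropout=dropout, seed=seed)


def overfit_benchmark(seed: int = 0, steps: int = 200) -> float:
    """Train-Dice after memorizing a single phantom for ``steps`` steps."""
    img, msk = generate_phantom(PhantomSpec(seed=(seed + 7) % (2**31)))
    x, y = prepare_inputs([img], [msk], seed=seed)
    net = PoSamUltraNet(_tiny(seed, dropout=0.0))
    opt = Adam(net.parameters(), 2e-3)
    lw = LossWeights()
    for _ in range(steps):
        out = net.forward(x)
        loss = total_loss(composite_loss(out.main, y[:, None], lw),
                          composite_loss(out.aux1, y[:, None], lw),
                          composite_loss(out.aux2, y[:, None], lw),
                          lw.lambda1, lw.lambda2)
        opt.zero_grad()
        loss.backward()
        opt.step()
    pred = (net.predict_proba(x)[0, 0] >= 0.5).astype(np.uint8)
    return M.dice(pred, msk.pixels)


def desk_scale_benchmark(seed: int = 0, n_train: int = 200, n_val: int = 20,
                         n_test: int = 50, epochs: int = 15,
                         checkpoint_dir: str | Path | None = None) -> dict:
    """Train on seeded phantoms and report validation/test performance."""
    spec = PhantomSpec()
    tr = generate_dataset(n_train, spec, seed=(seed * 3 + 11) % (2**31))
    va = generate_dataset(n_val, spec, seed=(seed * 3 + 12) % (2**31))
    te = generate_dataset(n_test, spec, seed=(seed * 3 + 13) % (2**31))
    x_tr, y_tr = prepare_inputs(*tr, seed=seed)
    x_va, y_va = prepare_inputs(*va, seed=seed + 1)
    x_te, y_te = prepare_inputs(*te, seed=seed + 2)

    ckdir = Path(checkpoint_dir) if checkpoint_dir else Path(tempfile.mkdtemp())
    ckpt = ckdir / "desk_scale.npz"
    record = train(
        _tiny(seed, dropout=0.1),
        TrainConfig(epochs=epochs, batch_size=8, learning_rate=1e-3,
                    patience=epochs, seed=seed),
        LossWeights(),
        {"train": (x_tr, y_tr), "val": (x_va, y_va)},
        checkpoint_path=ckpt,
    )
    _, mean = evaluate(ckpt, x_te, y_te)
    return {
        "best_val_dice": record.best_val_dice,
        "best_epoch": record.best_epoch,
        "test": mean,
        "record": record,
    }
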