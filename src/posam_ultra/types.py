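"""Core value types shared across the package.

Images are ``H x W x C`` float arrays; masks are ``H x W`` arrays with values
in {0, 1}.  Network inputs are channel-first ``4 x H x W`` stacks of the three
MRI-like channels plus the tumor-likelihood prior.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "ImageVolume",
    "BinaryMask",
    "PhantomSpec",
    "AugmentationConfig",
    "SplitIndices",
    "NetworkConfig",
    "LossWeights",
    "TrainConfig",
    "PlacementError",
]


class PlacementError(RuntimeError):
    """Raised when a requested tumor cannot be placed inside the brain region."""


@dataclass
class ImageVolume:
    """A single multi-channel slice; pixel values nominally in [0, 1] after
    normalization."""

    pixels: np.ndarray
    channel_names: tuple[str, ...] = ()

    def __post_init__(self):
        self.pixels = np.asarray(self.pixels, dtype=np.float64)
        if self.pixels.ndim == 2:
            self.pixels = self.pixels[:, :, None]
        if self.pixels.ndim != 3:
            raise ValueError("ImageVolume expects an H x W x C array")
        h, w, c = self.pixels.shape
        if h < 8 or w < 8:
            raise ValueError("ImageVolume requires H >= 8 and W >= 8")
        if c not in (1, 3, 4):
            raise ValueError(f"ImageVolume supports 1, 3 or 4 channels, got {c}")
        if not self.channel_names:
            self.channel_names = tuple(f"ch{i}" for i in range(c))

    @property
    def shape(self):
        return self.pixels.shape


@dataclass
class BinaryMask:
    """An H x W mask with values in {0, 1}."""

    pixels: np.ndarray

    def __post_init__(self):
        arr = np.asarray(self.pixels)
        uniq = np.unique(arr)
        if not np.all(np.isin(uniq, (0, 1))):
            raise ValueError("BinaryMask values must lie in {0, 1}")
        self.pixels = arr.astype(np.uint8)

    @property
    def shape(self):
        return self.pixels.shape


@dataclass
class PhantomSpec:
    """Parameters of one synthetic brain slice.

    The defaults describe the desk-scale study conditions: a 64 x 64 slice, a
    single tumor occupying 5% of the frame, moderate acquisition noise and a
    tumor about 0.45 intensity units brighter than surrounding tissue.
    """

    height: int = 64
    width: int = 64
    tumor_area_fraction: float = 0.05
    n_tumors: int = 1
    noise_sd: float = 0.03
    tumor_contrast: float = 0.45
    seed: int = 0

    def __post_init__(self):
        if self.height < 8 or self.width < 8:
            raise ValueError("phantom must be at least 8 x 8")
        if not 0.0 <= self.tumor_area_fraction <= 0.3:
            raise ValueError("tumor_area_fraction must lie in [0, 0.3]")
        if self.n_tumors < 0:
            raise ValueError("n_tumors must be >= 0")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")
        if self.tumor_contrast <= 0:
            raise ValueError("tumor_contrast must be > 0")


@dataclass
class AugmentationConfig:
    """On-the-fly training augmentation: rotations up to +/-20 degrees,
    random flips, mild rescaling, and brightness/contrast jitter."""

    max_rotation_deg: float = 20.0
    h_flip_prob: float = 0.5
    v_flip_prob: float = 0.5
    scale_range: tuple[float, float] = (0.9, 1.1)
    brightness_delta: float = 0.1
    contrast_delta: float = 0.1

    def __post_init__(self):
        lo, hi = self.scale_range
        if not (lo <= 1.0 <= hi) or lo <= 0:
            raise ValueError("scale_range must bracket 1.0 with positive bounds")
        for p in (self.h_flip_prob, self.v_flip_prob):
            if not 0.0 <= p <= 1.0:
                raise ValueError("flip probabilities must lie in [0, 1]")
        if self.max_rotation_deg < 0:
            raise ValueError("max_rotation_deg must be >= 0")

    @classmethod
    def identity(cls) -> "AugmentationConfig":
        return cls(max_rotation_deg=0.0, h_flip_prob=0.0, v_flip_prob=0.0,
                   scale_range=(1.0, 1.0), brightness_delta=0.0, contrast_delta=0.0)


@dataclass
class SplitIndices:
    train: np.ndarray
    val: np.ndarray
    test: np.ndarray

    def __post_init__(self):
        self.train = np.asarray(self.train, dtype=np.int64)
        self.val = np.asarray(self.val, dtype=np.int64)
        self.test = np.asarray(self.test, dtype=np.int64)

    def sizes(self) -> tuple[int, int, int]:
        return len(self.train), len(self.val), len(self.test)


@dataclass
class NetworkConfig:
    """Architecture knobs.

    ``base_filters`` is the channel width of the first encoder stage (the
    hyperparameter search offers 32/64/128/256; 8 is the desk-scale "tiny"
    setting).  ``lambda1``/``lambda2`` weight the two auxiliary
    deep-supervision losses.
    """

    base_filters: int = 32
    n_stages: int = 4
    cbam_reduction: int = 16
    dropout: float = 0.1
    lambda1: float = 0.4
    lambda2: float = 0.2
    seed: int = 0

    def __post_init__(self):
        if self.base_filters < 4:
            raise ValueError("base_filters must be >= 4")
        if self.n_stages not in (2, 3, 4):
            raise ValueError("n_stages must lie in [2, 4]")
        if not 0.0 <= self.dropout <= 0.9:
            raise ValueError("dropout must lie in [0, 0.9]")
        if not (np.isfinite(self.lambda1) and np.isfinite(self.lambda2)):
            raise ValueError("deep-supervision weights must be finite")

    @classmethod
    def tiny(cls, seed: int = 0) -> "NetworkConfig":
        return cls(base_filters=8, n_stages=3, cbam_reduction=4, dropout=0.1, seed=seed)


@dataclass
class LossWeights:
    """Composite segmentation loss weights (BCE + soft Dice + focal) plus the
    deep-supervision lambdas."""

    w_bce: float = 0.4
    w_dice: float = 0.4
    w_focal: float = 0.2
    lambda1: float = 0.4
    lambda2: float = 0.2
    focal_gamma: float = 2.0
    focal_alpha: float = 0.25

    def __post_init__(self):
        vals = (self.w_bce, self.w_dice, self.w_focal, self.lambda1, self.lambda2)
        if not all(np.isfinite(v) and v >= 0 for v in vals):
            raise ValueError("loss weights must be finite and nonnegative")


@dataclass
class TrainConfig:
    epochs: int = 50
    batch_size: int = 8
    learning_rate: float = 1e-3
    optimizer_name: str = "adam"
    weight_decay: float = 0.0
    momentum: float = 0.9
    lr_decay_step: int = 10
    patience: int = 10
    seed: int = 0
    augment: bool = False

    def __post_init__(self):
        if self.epochs < 1:
            raise ValueError("epochs must be >= 1")
        if self.optimizer_name not in ("adam", "sgd", "rmsprop"):
            raise ValueError("optimizer_name must be adam, sgd or rmsprop")
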