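"""Synthetic glioma phantoms and the slice-level preprocessing pipeline.

The generator emulates the appearance of FLAIR-like lower-grade glioma
slices: a dark background, a bright elliptical "brain" with smooth intensity
variation, and one or more hyperintense tumor blobs fully contained in the
brain, with a matching binary ground-truth mask.  The preprocessing mirrors
the training pipeline of the segmentation tool: bilinear resize to a common
resolution (masks nearest-neighbor), global min-max normalization to [0, 1],
randomized geometric/intensity augmentation, and a seeded 80/10/10
train/validation/test split.
"""

from __future__ import annotations

import math
from pathlib import Path

import numpy as np
import pandas as pd
from PIL import Image
from scipy import ndimage as ndi
from skimage import transform as sktf
import tifffile

from .types import (
    AugmentationConfig,
    BinaryMask,
    ImageVolume,
    PhantomSpec,
    PlacementError,
    SplitIndices,
)

__all__ = [
    "generate_phantom",
    "generate_dataset",
    "resize_pair",
    "minmax_normalize",
    "sample_augmentation",
    "apply_augmentation",
    "augment_pair",
    "split_dataset",
    "save_pair",
    "load_pair",
    "mask_sibling_path",
    "write_manifest",
]

_BACKGROUND = 0.05
_BRAIN_LEVEL = 0.35


def _ellipse_mask(h: int, w: int, cy: float, cx: float, ry: float, rx: float,
                  theta: float = 0.0) -> np.ndarray:
    yy, xx = np.mgrid[0:h, 0:w].astype(np.float64)
    y, x = yy - cy, xx - cx
    ct, st = math.cos(theta), math.sin(theta)
    u = ct * x + st * y
    v = -st * x + ct * y
    return (u / rx) ** 2 + (v / ry) ** 2 <= 1.0


def generate_phantom(spec: PhantomSpec) -> tuple[ImageVolume, BinaryMask]:
    """Generate one synthetic slice and its ground-truth tumor mask.

    Deterministic for a fixed ``spec.seed``.  Raises :class:`PlacementError`
    when the requested tumor area cannot fit inside the brain ellipse.
    """
    rng = np.random.default_rng(spec.seed)
    h, w = spec.height, spec.width

    # brain: centered ellipse with mild jitter and smooth intensity texture
    cy = h / 2 + rng.uniform(-0.03, 0.03) * h
    cx = w / 2 + rng.uniform(-0.03, 0.03) * w
    ry = 0.38 * h * rng.uniform(0.95, 1.05)
    rx = 0.32 * w * rng.uniform(0.95, 1.05)
    brain = _ellipse_mask(h, w, cy, cx, ry, rx)

    texture = ndi.gaussian_filter(rng.normal(size=(h, w)), sigma=max(h, w) / 16)
    tmax = np.abs(texture).max()
    if tmax > 0:
        texture = texture / tmax * 0.06
    base = np.full((h, w), _BACKGROUND)
    base[brain] = _BRAIN_LEVEL + texture[brain]

    # tumors: equal-area ellipses placed fully inside the brain
    mask = np.zeros((h, w), dtype=bool)
    if spec.n_tumors > 0 and spec.tumor_area_fraction > 0:
        area_each = spec.tumor_area_fraction * h * w / spec.n_tumors
        interior = ndi.distance_transform_edt(brain)
        for _ in range(spec.n_tumors):
            placed = False
            for _attempt in range(200):
                aspect = rng.uniform(0.6, 1.0)
                r_b = math.sqrt(area_each / (math.pi * aspect))
                r_a = aspect * r_b
                r_max = max(r_a, r_b)
                candidates = np.argwhere(interior >= r_max + 1)
                if len(candidates) == 0:
                    break
                ty, tx = candidates[rng.integers(len(candidates))]
                blob = _ellipse_mask(h, w, ty, tx, r_a, r_b,
                                     theta=rng.uniform(0, math.pi))
                if blob.sum() > 0 and np.all(brain[blob]):
                    mask |= blob
                    base[blob] = _BRAIN_LEVEL + spec.tumor_contrast + texture[blob]
                    placed = True
                    break
            if not placed:
                raise PlacementError(
                    f"cannot place a tumor of area fraction "
                    f"{spec.tumor_area_fraction / spec.n_tumors:.3f} inside the brain"
                )

    # three correlated channels with per-channel gain and independent noise
    gains = (1.0, 0.92, 1.08)
    channels = []
    for g in gains:
        ch = base * g + rng.normal(scale=spec.noise_sd, size=(h, w))
        channels.append(np.clip(ch, 0.0, 1.0))
    pixels = np.stack(channels, axis=-1)
    return (
        ImageVolume(pixels, channel_names=("mod1", "mod2", "mod3")),
        BinaryMask(mask.astype(np.uint8)),
    )


def generate_dataset(n: int, spec: PhantomSpec | None = None, seed: int = 0):
    """Generate ``n`` phantoms with per-item seeds derived from ``seed``."""
    spec = spec or PhantomSpec()
    images, masks = [], []
    for i in range(n):
        s = PhantomSpec(**{**vars(spec), "seed": (seed * 100_003 + i) % (2**31)})
        img, msk = generate_phantom(s)
        images.append(img)
        masks.append(msk)
    return images, masks


# -- preprocessing ---------------------------------------------------------

def resize_pair(image: ImageVolume, mask: BinaryMask, size: int = 256
                ) -> tuple[ImageVolume, BinaryMask]:
    """Resize image (bilinear) and mask (nearest-neighbor) to ``size x size``."""
    if image.pixels.shape[:2] != mask.pixels.shape:
        raise ValueError("image and mask must share H x W")
    if image.pixels.shape[:2] == (size, size):
        return ImageVolume(image.pixels.copy(), image.channel_names), BinaryMask(mask.pixels.copy())
    img = sktf.resize(image.pixels, (size, size), order=1, mode="edge",
                      anti_aliasing=False, preserve_range=True)
    msk = sktf.resize(mask.pixels, (size, size), order=0, mode="edge",
                      anti_aliasing=False, preserve_range=True)
    return ImageVolume(img, image.channel_names), BinaryMask(msk.astype(np.uint8))


def minmax_normalize(image: ImageVolume) -> ImageVolume:
    """Scale pixel values to [0, 1]; a constant image maps to all zeros."""
    px = image.pixels
    if not np.all(np.isfinite(px)):
        raise ValueError("image contains non-finite values")
    lo, hi = px.min(), px.max()
    if hi == lo:
        out = np.zeros_like(px)
    else:
        out = (px - lo) / (hi - lo)
    return ImageVolume(out, image.channel_names)


# -- augmentation ----------------------------------------------------------

def sample_augmentation(config: AugmentationConfig, rng: np.random.Generator) -> dict:
    """Draw one set of augmentation parameters."""
    return {
        "angle": float(rng.uniform(-config.max_rotation_deg, config.max_rotation_deg))
        if config.max_rotation_deg > 0 else 0.0,
        "h_flip": bool(rng.random() < config.h_flip_prob),
        "v_flip": bool(rng.random() < config.v_flip_prob),
        "scale": float(rng.uniform(*config.scale_range))
        if config.scale_range != (1.0, 1.0) else 1.0,
        "brightness": float(rng.uniform(-config.brightness_delta, config.brightness_delta))
        if config.brightness_delta > 0 else 0.0,
        "contrast": float(rng.uniform(-config.contrast_delta, config.contrast_delta))
        if config.contrast_delta > 0 else 0.0,
    }


def _warp_about_center(arr: np.ndarray, angle_deg: float, scale: float, order: int
                       ) -> np.ndarray:
    h, w = arr.shape[:2]
    center = np.array([(w - 1) / 2.0, (h - 1) / 2.0])
    t1 = sktf.AffineTransform(translation=-center)
    t2 = sktf.AffineTransform(rotation=np.deg2rad(angle_deg), scale=(scale, scale))
    t3 = sktf.AffineTransform(translation=center)
    tform = t1 + t2 + t3
    return sktf.warp(arr, tform.inverse, order=order, mode="edge", preserve_range=True)


def apply_augmentation(image: ImageVolume, mask: BinaryMask, draw: dict
                       ) -> tuple[ImageVolume, BinaryMask]:
    """Apply a sampled draw; geometric ops hit image and mask identically,
    intensity ops hit the image only."""
    img = image.pixels.copy()
    msk = mask.pixels.copy()
    if draw["h_flip"]:
        img = img[:, ::-1]
        msk = msk[:, ::-1]
    if draw["v_flip"]:
        img = img[::-1]
        msk = msk[::-1]
    if draw["angle"] != 0.0 or draw["scale"] != 1.0:
        img = _warp_about_center(img, draw["angle"], draw["scale"], order=1)
        msk = _warp_about_center(msk.astype(np.float64), draw["angle"], draw["scale"],
                                 order=0).astype(np.uint8)
    if draw["contrast"] != 0.0:
        mean = img.mean()
        img = mean + (1.0 + draw["contrast"]) * (img - mean)
    if draw["brightness"] != 0.0:
        img = img + draw["brightness"]
    img = np.clip(img, 0.0, 1.0)
    return ImageVolume(np.ascontiguousarray(img), image.channel_names), BinaryMask(
        np.ascontiguousarray(msk))


def augment_pair(image: ImageVolume, mask: BinaryMask, config: AugmentationConfig,
                 rng: np.random.Generator) -> tuple[ImageVolume, BinaryMask]:
    if image.pixels.shape[:2] != mask.pixels.shape:
        raise ValueError("image and mask must share H x W")
    return apply_augmentation(image, mask, sample_augmentation(config, rng))


# -- splitting -------------------------------------------------------------

def split_dataset(n_items: int, ratios: tuple[float, float, float] = (0.8, 0.1, 0.1),
                  seed: int = 0) -> SplitIndices:
    """Shuffled train/val/test partition.

    ``|train| = floor(r_train * n)``; the remainder is divided between
    validation and test in proportion to the remaining ratios, validation
    taking the extra item when the remainder is odd.
    """
    if n_items < 3:
        raise ValueError("need at least 3 items to split")
    r0, r1, r2 = ratios
    if not math.isclose(r0 + r1 + r2, 1.0, abs_tol=1e-9):
        raise ValueError("ratios must sum to 1")
    perm = np.random.default_rng(seed).permutation(n_items)
    n_train = int(math.floor(r0 * n_items))
    rem = n_items - n_train
    n_val = int(math.ceil(rem * r1 / (r1 + r2)))
    return SplitIndices(
        train=perm[:n_train],
        val=perm[n_train : n_train + n_val],
        test=perm[n_train + n_val :],
    )


# -- file I/O --------------------------------------------------------------

def mask_sibling_path(image_path: str | Path) -> Path:
    p = Path(image_path)
    return p.with_name(f"{p.stem}_mask{p.suffix}")


def save_pair(image: ImageVolume, mask: BinaryMask, image_path: str | Path) -> Path:
    """Write an image and its ``<stem>_mask`` sibling.

    TIFF images are stored as float32 (lossless round trip); PNG images as
    8-bit.  Masks are stored as 8-bit {0, 255}.
    """
    p = Path(image_path)
    mp = mask_sibling_path(p)
    ext = p.suffix.lower()
    if ext in (".tif", ".tiff"):
        photometric = "rgb" if image.pixels.shape[2] == 3 else "minisblack"
        tifffile.imwrite(p, image.pixels.astype(np.float32), photometric=photometric)
        tifffile.imwrite(mp, (mask.pixels * 255).astype(np.uint8))
    elif ext == ".png":
        arr = np.clip(np.round(image.pixels * 255), 0, 255).astype(np.uint8)
        Image.fromarray(arr.squeeze()).save(p)
        Image.fromarray((mask.pixels * 255).astype(np.uint8)).save(mp)
    else:
        raise ValueError(f"unsupported extension {ext}; use .tif/.tiff/.png")
    return mp


def load_pair(image_path: str | Path) -> tuple[ImageVolume, BinaryMask]:
    """Load an image and its mask sibling; 8-bit data comes back in [0, 1]
    and masks are binarized at >127."""
    p = Path(image_path)
    mp = mask_sibling_path(p)
    if not p.exists():
        raise FileNotFoundError(str(p))
    if not mp.exists():
        raise FileNotFoundError(f"missing mask sibling: expected {mp}")
    ext = p.suffix.lower()
    if ext in (".tif", ".tiff"):
        img = np.asarray(tifffile.imread(p))
        msk = np.asarray(tifffile.imread(mp))
    elif ext == ".png":
        img = np.asarray(Image.open(p))
        msk = np.asarray(Image.open(mp))
    else:
        raise ValueError(f"unsupported extension {ext}")
    if img.dtype == np.uint8:
        img = img.astype(np.float64) / 255.0
    else:
        img = img.astype(np.float64)
    mask = (msk.astype(np.float64) > 127).astype(np.uint8) if msk.dtype == np.uint8 \
        else (msk.astype(np.float64) > 0.5).astype(np.uint8)
    return ImageVolume(img), BinaryMask(mask)


def write_manifest(directory: str | Path, image_paths: list, split: SplitIndices
                   ) -> Path:
    """Write a CSV manifest (image_path, mask_path, split) next to the data."""
    directory = Path(directory)
    labels = np.empty(len(image_paths), dtype=object)
    labels[split.train] = "train"
    labels[split.val] = "val"
    labels[split.test] = "test"
    df = pd.DataFrame({
        "image_path": [str(p) for p in image_paths],
        "mask_path": [str(mask_sibling_path(p)) for p in image_paths],
        "split": labels,
    })
    out = directory / "manifest.csv"
    df.to_csv(out, index=False)
    return out
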