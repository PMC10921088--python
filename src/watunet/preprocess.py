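"""Image enhancement and stochastic augmentation applied identically to image and mask.

CLAHE (contrast-limited adaptive histogram equalisation) is applied to the
8-bit image at native resolution, before any resizing, because the tile
histograms are better defined there.  The clip limit follows the 8-bit
convention (multiples of the uniform histogram level, default 2.0) and is
mapped internally to the normalised fraction scikit-image expects.

Augmentation draws one affine transform per call — rotation, zoom,
horizontal flip, width/height shifts, shear — and applies it to image
(bilinear) and mask (nearest) alike, with out-of-frame pixels filled with
black to match the dark sector background of ultrasound frames.  A
brightness factor additionally scales the image only.  Magnitudes default
to conservative ranges, since aggressive photometric or zoom distortion
can destroy diagnostically relevant detail in ultrasound.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from skimage import exposure, transform

__all__ = [
    "ClaheParams",
    "AugmentParams",
    "clahe_enhance",
    "resize_normalize",
    "augment_pair",
    "balance_classes",
]


@dataclass
class ClaheParams:
    clip_limit: float = 2.0  # 8-bit convention: multiple of the uniform bin level
    tile_grid: tuple[int, int] = (8, 8)

    def __post_init__(self):
        if self.clip_limit <= 0:
            raise ValueError("clip_limit must be positive")
        if min(self.tile_grid) < 1:
            raise ValueError("tile_grid dims must be >= 1")


@dataclass
class AugmentParams:
    rotation_range: float = 15.0  # degrees, symmetric
    zoom_range: tuple[float, float] = (0.9, 1.1)
    horizontal_flip: bool = True
    width_shift: float = 0.1  # fraction of width, symmetric
    height_shift: float = 0.1
    shear: float = 0.1  # radians, symmetric
    brightness_range: tuple[float, float] = (0.8, 1.2)  # image only
    seed: int | None = None

    def __post_init__(self):
        if self.zoom_range[0] > self.zoom_range[1] or self.zoom_range[0] <= 0:
            raise ValueError("zoom_range must be a nonempty positive interval")
        if self.brightness_range[0] > self.brightness_range[1]:
            raise ValueError("brightness_range must be nonempty")


def clahe_enhance(image: np.ndarray, params: ClaheParams | None = None) -> np.ndarray:
    """CLAHE on an 8-bit grayscale image; returns uint8 of the same shape."""
    params = params or ClaheParams()
    image = np.asarray(image)
    if image.ndim != 2:
        raise ValueError(f"expected a 2-D grayscale image, got shape {image.shape}")
    if image.min() < 0 or image.max() > 255:
        raise ValueError("expected intensities in [0, 255]")
    rows, cols = params.tile_grid
    kernel = (
        max(1, int(math.ceil(image.shape[0] / rows))),
        max(1, int(math.ceil(image.shape[1] / cols))),
    )
    out = exposure.equalize_adapthist(
        image.astype(np.uint8), kernel_size=kernel, clip_limit=params.clip_limit / 256.0
    )
    return np.round(out * 255.0).astype(np.uint8)


def resize_normalize(
    image: np.ndarray, mask: np.ndarray, target: tuple[int, int] = (128, 128)
) -> tuple[np.ndarray, np.ndarray]:
    """Resize to ``target`` and rescale: image bilinear to [0,1], mask nearest {0,1}."""
    if image.shape != mask.shape:
        raise ValueError(f"image {image.shape} and mask {mask.shape} shapes differ")
    if min(target) < 1:
        raise ValueError(f"target size must be positive, got {target}")
    img = transform.resize(
        np.asarray(image, dtype=float), target, order=1, preserve_range=True, anti_aliasing=True
    )
    msk = transform.resize(
        np.asarray(mask, dtype=float), target, order=0, preserve_range=True, anti_aliasing=False
    )
    return (img / 255.0).astype(np.float32), (msk > 0.5).astype(np.uint8)


def _draw_transform(shape, params: AugmentParams, rng: np.random.Generator):
    h, w = shape
    angle = math.radians(rng.uniform(-params.rotation_range, params.rotation_range))
    zoom = rng.uniform(*params.zoom_range)
    shear = rng.uniform(-params.shear, params.shear)
    tx = rng.uniform(-params.width_shift, params.width_shift) * w
    ty = rng.uniform(-params.height_shift, params.height_shift) * h
    flip = bool(params.horizontal_flip and rng.random() < 0.5)
    # pixel centres sit on integer coordinates, so the grid centre is (n-1)/2
    center = np.array([(w - 1) / 2.0, (h - 1) / 2.0])
    tf = (
        transform.AffineTransform(translation=-center)
        + transform.AffineTransform(scale=(-zoom if flip else zoom, zoom), rotation=angle, shear=shear)
        + transform.AffineTransform(translation=center + np.array([tx, ty]))
    )
    return tf


def _warp_pair(image, mask, tf):
    img = transform.warp(
        np.asarray(image, dtype=float), tf.inverse, order=1, cval=0.0, preserve_range=True
    )
    msk = transform.warp(
        np.asarray(mask, dtype=float), tf.inverse, order=0, cval=0.0, preserve_range=True
    )
    return img, (msk > 0.5).astype(np.uint8)


def augment_pair(
    image: np.ndarray,
    mask: np.ndarray,
    params: AugmentParams,
    rng: np.random.Generator,
    return_transform: bool = False,
):
    """One stochastic augmentation of an aligned (image, mask) pair.

    The same geometric transform is applied to both; a brightness factor
    scales the image only; the warped mask is re-binarized at 0.5.
    Returns uint8 image (clipped to [0,255]) and {0,1} mask.
    """
    if image.shape != mask.shape:
        raise ValueError(f"image {image.shape} and mask {mask.shape} shapes differ")
    tf = _draw_transform(image.shape, params, rng)
    img, msk = _warp_pair(image, mask, tf)
    img = img * rng.uniform(*params.brightness_range)
    img = np.clip(img, 0, 255).astype(np.uint8)
    if return_transform:
        return img, msk, tf
    return img, msk


def balance_classes(
    samples,
    target_count: int,
    params: AugmentParams,
    rng: np.random.Generator,
):
    """Augment each class up to exactly ``target_count`` members.

    ``samples`` is a list of objects with image/mask/label attributes
    (phantom samples or equivalents).  Classes larger than the target are
    subsampled deterministically (first ``target_count``); smaller classes
    are topped up with fresh augmentation draws of randomly chosen
    originals.  Returns a list of (image, mask, label) triples.
    """
    from collections import defaultdict

    by_class = defaultdict(list)
    for s in samples:
        by_class[s.label].append(s)
    out = []
    for label in sorted(by_class):
        pool = by_class[label]
        chosen = pool[:target_count]
        out.extend((s.image, s.mask, label) for s in chosen)
        need = target_count - len(chosen)
        for _ in range(need):
            src = pool[rng.integers(len(pool))]
            img, msk = augment_pair(src.image, src.mask, params, rng)
            out.append((img, msk, label))
    return out
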