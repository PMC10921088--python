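"""Seeded generator of synthetic B-mode-like speckle phantoms with lesion masks.

Real breast ultrasound cannot be redistributed here, so every stage of
the toolchain is exercised on phantoms that reproduce the features the
segmentation task actually depends on: multiplicative speckle texture,
and darker (hypoechoic) lesion regions whose outline statistics differ
by class — smooth ellipses for benign lesions, harmonically perturbed
and spiculated outlines for malignant ones, and empty masks for frames
with no mass.  The default class mix follows the 2048 : 820 : 950
(no mass : benign : malignant) frame proportions of the clinical sweep
dataset the tool targets.

Speckle is modelled as the squared envelope of two independent smoothed
Gaussian fields (a Rayleigh-amplitude analogue), normalised to unit mean
and applied multiplicatively — visually and statistically close to
B-mode texture without simulating wave physics.

Everything is driven by ``numpy.random.Generator`` seeds: the same
config and seed reproduce a dataset bit for bit.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from PIL import Image
from scipy import ndimage

__all__ = [
    "LABELS",
    "PhantomSample",
    "PhantomConfig",
    "apportion",
    "generate_sample",
    "generate_dataset",
    "load_dataset",
]

LABELS = ("no_mass", "benign", "malignant")

# VSI-like frame proportions: 2048 no-mass, 820 benign, 950 malignant of 3818.
DEFAULT_PROPORTIONS = (2048 / 3818, 820 / 3818, 950 / 3818)


@dataclass
class PhantomSample:
    image: np.ndarray  # uint8 grayscale, H x W
    mask: np.ndarray  # uint8 in {0,1}, H x W
    label: str

    def __post_init__(self):
        if self.image.shape != self.mask.shape:
            raise ValueError("image and mask shapes differ")
        if self.label not in LABELS:
            raise ValueError(f"unknown label {self.label!r}")


@dataclass
class PhantomConfig:
    n_samples: int = 200
    class_proportions: tuple[float, float, float] = DEFAULT_PROPORTIONS
    image_size: tuple[int, int] = (128, 128)
    lesion_area_range: tuple[float, float] = (0.03, 0.15)
    speckle_smoothing: float = 1.5
    lesion_contrast: float = 0.45
    seed: int = 0

    def __post_init__(self):
        if self.n_samples < 1:
            raise ValueError("n_samples must be >= 1")
        props = np.asarray(self.class_proportions, dtype=float)
        if props.size != 3 or np.any(props < 0) or abs(props.sum() - 1.0) > 1e-9:
            raise ValueError("class_proportions must be 3 nonnegative fractions summing to 1")
        lo, hi = self.lesion_area_range
        if not (0.0 < lo <= hi < 0.5):
            raise ValueError("lesion_area_range must be an interval inside (0, 0.5)")
        if not 0.0 < self.lesion_contrast < 1.0:
            raise ValueError("lesion_contrast must lie in (0,1)")


def apportion(n: int, proportions) -> list[int]:
    """Largest-remainder apportionment of n items over the given fractions."""
    props = np.asarray(proportions, dtype=float)
    raw = props * n
    counts = np.floor(raw).astype(int)
    remainder = n - counts.sum()
    # distribute leftovers to the largest fractional parts; ties to lower index
    order = np.argsort(-(raw - counts), kind="stable")
    for i in order[:remainder]:
        counts[i] += 1
    return counts.tolist()


def _speckle(shape, smoothing: float, rng: np.random.Generator) -> np.ndarray:
    """Unit-mean multiplicative speckle field (squared smoothed-Gaussian envelope)."""
    g1 = ndimage.gaussian_filter(rng.standard_normal(shape), smoothing)
    g2 = ndimage.gaussian_filter(rng.standard_normal(shape), smoothing)
    intensity = g1**2 + g2**2
    return intensity / intensity.mean()


def _ellipse_mask(shape, center, a, b, angle) -> np.ndarray:
    h, w = shape
    yy, xx = np.mgrid[0:h, 0:w]
    dy, dx = yy - center[0], xx - center[1]
    ca, sa = np.cos(angle), np.sin(angle)
    u = ca * dx + sa * dy
    v = -sa * dx + ca * dy
    return ((u / a) ** 2 + (v / b) ** 2 <= 1.0).astype(np.uint8)


def _irregular_mask(shape, center, r_theta, thetas) -> np.ndarray:
    """Star-convex region with radius profile r(theta) interpolated from samples."""
    h, w = shape
    yy, xx = np.mgrid[0:h, 0:w]
    dy, dx = yy - center[0], xx - center[1]
    angle = np.arctan2(dy, dx)
    radius = np.hypot(dy, dx)
    r_at = np.interp(angle, thetas, r_theta, period=2 * np.pi)
    return (radius <= r_at).astype(np.uint8)


def _malignant_radius(r0: float, rng: np.random.Generator, n_theta: int = 720):
    """Radius profile with low-order angular harmonics plus Gaussian spicule bumps."""
    thetas = np.linspace(-np.pi, np.pi, n_theta, endpoint=False)
    r = np.full(n_theta, 1.0)
    for order in range(3, 9):
        amp = rng.uniform(0.0, 0.05)
        r += amp * np.cos(order * thetas + rng.uniform(0, 2 * np.pi))
    for _ in range(rng.integers(2, 6)):
        center = rng.uniform(-np.pi, np.pi)
        width = rng.uniform(0.15, 0.30)  # radians
        amp = rng.uniform(0.10, 0.30)
        d = np.angle(np.exp(1j * (thetas - center)))
        r += amp * np.exp(-0.5 * (d / width) ** 2)
    return thetas, np.clip(r, 0.4, 1.8) * r0


def _lesion_mask(config: PhantomConfig, label: str, rng: np.random.Generator) -> np.ndarray:
    h, w = config.image_size
    lo, hi = config.lesion_area_range
    for _ in range(30):
        target = rng.uniform(lo, hi)
        if label == "benign":
            q = rng.uniform(0.55, 0.95)  # axis ratio
            a = np.sqrt(target * h * w / (np.pi * q))
            b = q * a
            rmax = max(a, b)
            if 2 * rmax + 4 >= min(h, w):
                continue
            cy = rng.uniform(rmax + 2, h - rmax - 2)
            cx = rng.uniform(rmax + 2, w - rmax - 2)
            mask = _ellipse_mask((h, w), (cy, cx), a, b, rng.uniform(0, np.pi))
        else:
            r0 = np.sqrt(target * h * w / np.pi)
            thetas, r_prof = _malignant_radius(r0, rng)
            # one fixed-point correction so the discretised area lands on target
            rmax = r_prof.max()
            if 2 * rmax + 4 >= min(h, w):
                continue
            cy = rng.uniform(rmax + 2, h - rmax - 2)
            cx = rng.uniform(rmax + 2, w - rmax - 2)
            mask = _irregular_mask((h, w), (cy, cx), r_prof, thetas)
            actual = mask.sum() / (h * w)
            if actual > 0:
                r_prof = r_prof * np.sqrt(target / actual)
                if 2 * r_prof.max() + 4 >= min(h, w):
                    continue
                mask = _irregular_mask((h, w), (cy, cx), r_prof, thetas)
        frac = mask.sum() / (h * w)
        if lo <= frac <= hi and ndimage.label(mask)[1] == 1:
            return mask
    raise ValueError(
        f"could not fit a lesion with area fraction in [{lo}, {hi}] "
        f"into a {h}x{w} frame; the configuration is degenerate"
    )


def generate_sample(config: PhantomConfig, label: str, rng: np.random.Generator) -> PhantomSample:
    """One speckle frame plus mask for the requested class."""
    if label not in LABELS:
        raise ValueError(f"unknown label {label!r}; expected one of {LABELS}")
    h, w = config.image_size
    base = 115.0 * _speckle((h, w), config.speckle_smoothing, rng)
    if label == "no_mass":
        mask = np.zeros((h, w), dtype=np.uint8)
    else:
        mask = _lesion_mask(config, label, rng)
        # soften the lesion edge by a pixel so the boundary is not a hard step
        soft = ndimage.gaussian_filter(mask.astype(float), 1.0)
        base = base * (1.0 - (1.0 - config.lesion_contrast) * soft)
    image = np.clip(base, 0, 255).astype(np.uint8)
    return PhantomSample(image=image, mask=mask, label=label)


def generate_dataset(
    config: PhantomConfig, out_dir: str | os.PathLike | None = None
) -> tuple[list[PhantomSample], pd.DataFrame]:
    """Generate the full dataset and its manifest; optionally write PNG pairs.

    Class counts follow largest-remainder apportionment of ``n_samples`` by
    ``class_proportions``.  When ``out_dir`` is given, each sample is written
    as an 8-bit grayscale PNG with its mask beside it (``*_mask.png``,
    lesion pixels stored as 255), plus a ``manifest.csv``.
    """
    counts = apportion(config.n_samples, config.class_proportions)
    ss = np.random.SeedSequence(config.seed)
    labels = [lab for lab, k in zip(LABELS, counts) for _ in range(k)]
    samples = []
    rows = []
    for idx, (label, child) in enumerate(zip(labels, ss.spawn(len(labels)))):
        sample = generate_sample(config, label, np.random.default_rng(child))
        samples.append(sample)
        img_name = f"{label}_{idx:05d}.png"
        mask_name = f"{label}_{idx:05d}_mask.png"
        rows.append({"image_path": img_name, "mask_path": mask_name, "label": label})
        if out_dir is not None:
            os.makedirs(out_dir, exist_ok=True)
            Image.fromarray(sample.image, mode="L").save(os.path.join(out_dir, img_name))
            Image.fromarray(sample.mask * 255, mode="L").save(os.path.join(out_dir, mask_name))
    manifest = pd.DataFrame(rows)
    if out_dir is not None:
        manifest.to_csv(os.path.join(out_dir, "manifest.csv"), index=False)
    return samples, manifest


def load_dataset(manifest_path: str | os.PathLike) -> tuple[list[PhantomSample], pd.DataFrame]:
    """Read back a dataset written by :func:`generate_dataset`."""
    manifest = pd.read_csv(manifest_path)
    root = os.path.dirname(os.fspath(manifest_path))
    samples = []
    for _, row in manifest.iterrows():
        image = np.asarray(Image.open(os.path.join(root, row["image_path"])).convert("L"))
        mask = np.asarray(Image.open(os.path.join(root, row["mask_path"])).convert("L"))
        samples.append(
            PhantomSample(image=image, mask=(mask > 127).astype(np.uint8), label=row["label"])
        )
    return samples, manifest
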