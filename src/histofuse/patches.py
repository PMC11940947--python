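"""Bifocal patch extraction, stain preprocessing and augmentation.

A *bifocal patch* is a pair of crops around one annotated coordinate: a
32x32 inner crop carrying cell-level detail and a 64x64 outer crop carrying
tissue context.  The inner crop is always exactly the central 32x32 region of
the outer crop; operations that transform a patch act on the outer crop and
re-derive the inner one, so the nesting identity can never be violated.

The 64x64 window spans [x-32, x+32) x [y-32, y+32): the annotated pixel sits
at index (32, 32) of the outer crop.  Crops that reach past the slide border
are reflection-padded.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy import ndimage
from skimage.color import lab2rgb, rgb2lab

OUTER = 64
INNER = 32
HALF = OUTER // 2
INSET = (OUTER - INNER) // 2  # 16


@dataclass
class BifocalPatch:
    inner: np.ndarray  # 32 x 32 x 3 uint8
    outer: np.ndarray  # 64 x 64 x 3 uint8
    center: tuple[int, int]
    label: str | None = None
    slide_id: str = ""
    marker: str = ""

    def with_outer(self, outer: np.ndarray) -> "BifocalPatch":
        """New patch with a transformed outer crop; inner re-sliced from it."""
        return BifocalPatch(
            inner=outer[INSET:INSET + INNER, INSET:INSET + INNER],
            outer=outer,
            center=self.center,
            label=self.label,
            slide_id=self.slide_id,
            marker=self.marker,
        )


@dataclass
class ReferenceStats:
    """Per-channel mean/std of a reference image in CIELAB."""

    mean: np.ndarray
    std: np.ndarray

    @classmethod
    def from_image(cls, image: np.ndarray) -> "ReferenceStats":
        lab = rgb2lab(image)
        return cls(mean=lab.mean(axis=(0, 1)), std=lab.std(axis=(0, 1)))


@dataclass
class PreprocessConfig:
    reference_stats: ReferenceStats | None = None
    background_sigma: float = 24.0
    edge_amount: float = 0.6
    enabled_steps: tuple[str, ...] = ("normalize", "background_subtract", "edge_enhance")
    contrast_range: tuple[float, float] = (0.8, 1.2)
    sharpness_range: tuple[float, float] = (0.5, 1.5)

    def __post_init__(self) -> None:
        if self.background_sigma <= 0:
            raise ValueError("background_sigma must be positive")
        if self.edge_amount < 0:
            raise ValueError("edge_amount must be >= 0")
        known = {"normalize", "background_subtract", "edge_enhance"}
        if not set(self.enabled_steps) <= known:
            raise ValueError(f"enabled_steps must be a subset of {sorted(known)}")


def extract_bifocal(
    image: np.ndarray,
    center: tuple[int, int],
    label: str | None = None,
    slide_id: str = "",
    marker: str = "",
) -> BifocalPatch:
    """Extract the 64/32 crop pair centered on (x, y), reflect-padded at
    borders."""
    h, w = image.shape[:2]
    if h < OUTER or w < OUTER:
        raise ValueError(f"image must be at least {OUTER}x{OUTER}, got {w}x{h}")
    x, y = center
    padded = np.pad(image, ((HALF, HALF), (HALF, HALF), (0, 0)), mode="reflect")
    outer = padded[y:y + OUTER, x:x + OUTER]
    patch = BifocalPatch(
        inner=np.empty(0), outer=np.ascontiguousarray(outer),
        center=(x, y), label=label, slide_id=slide_id, marker=marker,
    )
    return patch.with_outer(patch.outer)


def normalize_color(image: np.ndarray, reference_stats: ReferenceStats) -> np.ndarray:
    """Reinhard-style statistics transfer: match per-channel mean and std in
    CIELAB to a reference slide, then clip back to 8-bit RGB.

    Zero-variance channels fall back to a pure mean shift with a warning.
    """
    lab = rgb2lab(image)
    mean = lab.mean(axis=(0, 1))
    std = lab.std(axis=(0, 1))
    scale = np.ones(3)
    nonzero = std > 1e-8
    if not nonzero.all():
        warnings.warn("zero-variance channel: applying mean shift only",
                      stacklevel=2)
    scale[nonzero] = reference_stats.std[nonzero] / std[nonzero]
    out = (lab - mean) * scale + reference_stats.mean
    rgb = lab2rgb(out)
    return (np.clip(rgb, 0, 1) * 255).round().astype(np.uint8)


def subtract_background(image: np.ndarray, background_sigma: float) -> np.ndarray:
    """Remove the low-frequency background (large-sigma Gaussian estimate),
    re-centering at the image's global mean so the result stays in range."""
    if background_sigma <= 0:
        raise ValueError("background_sigma must be positive")
    img = image.astype(np.float64)
    sigma = (background_sigma, background_sigma, 0) if img.ndim == 3 else background_sigma
    background = ndimage.gaussian_filter(img, sigma=sigma, mode="reflect")
    out = img - background + img.mean(axis=(0, 1), keepdims=True)
    return np.clip(out, 0, 255).round().astype(np.uint8)


def enhance_edges(image: np.ndarray, edge_amount: float, sigma: float = 1.0) -> np.ndarray:
    """Unsharp-mask sharpening: img + amount * (img - blur).  amount 0 is the
    identity."""
    if edge_amount < 0:
        raise ValueError("edge_amount must be >= 0")
    if edge_amount == 0:
        return image.copy()
    img = image.astype(np.float64)
    s = (sigma, sigma, 0) if img.ndim == 3 else sigma
    blur = ndimage.gaussian_filter(img, sigma=s, mode="reflect")
    out = img + edge_amount * (img - blur)
    return np.clip(out, 0, 255).round().astype(np.uint8)


def preprocess_image(image: np.ndarray, config: PreprocessConfig) -> np.ndarray:
    """Apply the enabled preprocessing steps to a whole slide, in order."""
    out = image
    for step in config.enabled_steps:
        if step == "normalize":
            if config.reference_stats is None:
                raise ValueError("normalize enabled but reference_stats missing")
            out = normalize_color(out, config.reference_stats)
        elif step == "background_subtract":
            out = subtract_background(out, config.background_sigma)
        elif step == "edge_enhance":
            out = enhance_edges(out, config.edge_amount)
    return out


def _adjust_contrast(img: np.ndarray, factor: float) -> np.ndarray:
    f = img.astype(np.float64)
    mean = f.mean()
    return np.clip((f - mean) * factor + mean, 0, 255).round().astype(np.uint8)


def _adjust_sharpness(img: np.ndarray, factor: float) -> np.ndarray:
    # factor 1 = identity, > 1 sharpens, < 1 blends toward a slight blur
    f = img.astype(np.float64)
    blur = ndimage.gaussian_filter(f, sigma=(1, 1, 0), mode="reflect")
    out = blur + factor * (f - blur)
    return np.clip(out, 0, 255).round().astype(np.uint8)


def augment(patch: BifocalPatch, seed: int,
            config: PreprocessConfig | None = None) -> BifocalPatch:
    """Seeded training-time augmentation: rotation by a random multiple of
    90 degrees plus contrast and sharpness jitter.  The outer crop is
    transformed and the inner crop re-sliced, keeping the pair consistent;
    the label is untouched."""
    config = config or PreprocessConfig()
    rng = np.random.default_rng(seed)
    k = int(rng.integers(0, 4))
    contrast = float(rng.uniform(*config.contrast_range))
    sharpness = float(rng.uniform(*config.sharpness_range))
    outer = np.rot90(patch.outer, k=k)
    outer = _adjust_contrast(outer, contrast)
    outer = _adjust_sharpness(outer, sharpness)
    return patch.with_outer(np.ascontiguousarray(outer))


def rotate90(patch: BifocalPatch, k: int) -> BifocalPatch:
    """Deterministic 90-degree rotation helper (k quarter turns)."""
    return patch.with_outer(np.ascontiguousarray(np.rot90(patch.outer, k=k)))


def extract_dataset(
    image: np.ndarray,
    annotations: Sequence,
    preprocess: PreprocessConfig | None = None,
) -> list[BifocalPatch]:
    """Preprocess a slide once, then extract one bifocal patch per dot."""
    if preprocess is not None:
        image = preprocess_image(image, preprocess)
    return [
        extract_bifocal(image, (a.x, a.y), label=a.label,
                        slide_id=a.slide_id, marker=a.marker)
        for a in annotations
    ]
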