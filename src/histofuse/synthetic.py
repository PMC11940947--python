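"""Synthetic IHC-like slide generator with known single-cell ground truth.

Renders brown (DAB-like) immunopositive cells — round macrophage-like discs
and ramified cells with thin radiating processes — together with faintly
counterstained negative cells on a pale hematoxylin-like background.  Serial
"sections" for different markers can be generated with a controllable
cross-marker co-localization fraction and a known rigid offset, so that every
downstream stage (detection, registration, fusion, morphometry) can be tested
against exact ground truth.

Coordinates are 0-based pixel indices, x = column, y = row, origin top-left.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import imageio.v3 as iio
import numpy as np
import pandas as pd
from skimage.draw import disk, line_aa

PHENOTYPES = ("round_positive", "ramified_positive", "negative")

# DAB reaction product: high red+green, low blue. Hematoxylin counterstain:
# pale blue-gray. Values are the mean 8-bit colors before texture noise.
DAB_BROWN = np.array([145.0, 95.0, 40.0])
FAINT_BLUE = np.array([170.0, 180.0, 220.0])
BACKGROUND = np.array([226.0, 230.0, 242.0])


class PlacementError(RuntimeError):
    """Raised when cells cannot be placed without overlap."""

    def __init__(self, requested: int, achieved: int):
        super().__init__(
            f"could only place {achieved} of {requested} requested cells "
            f"without overlap (1000 attempts per cell)"
        )
        self.requested = requested
        self.achieved = achieved


@dataclass(frozen=True)
class CellGroundTruth:
    """One rendered cell: center, phenotype and rendering parameters."""

    x: int
    y: int
    phenotype: str
    radius_px: float
    n_processes: int
    stain_intensity: float

    def __post_init__(self) -> None:
        if self.phenotype not in PHENOTYPES:
            raise ValueError(f"unknown phenotype {self.phenotype!r}")
        if self.phenotype == "round_positive" and self.n_processes != 0:
            raise ValueError("round_positive cells have no processes")
        if self.phenotype == "ramified_positive" and self.n_processes < 2:
            raise ValueError("ramified_positive cells need >= 2 processes")
        if self.radius_px < 2:
            raise ValueError("radius_px must be >= 2")


@dataclass
class SyntheticSlide:
    """Rendered RGB image plus the exact cell ground truth."""

    image: np.ndarray  # H x W x 3 uint8
    cells: list[CellGroundTruth]
    marker: str
    seed: int
    slide_id: str = "synthetic"
    offset_from_base: tuple[float, float] = (0.0, 0.0)

    @property
    def shape(self) -> tuple[int, int]:
        return self.image.shape[:2]


@dataclass
class StainParams:
    """Rendering knobs: radii are min/max in px, noise is multiplicative."""

    radius_range: tuple[float, float] = (5.0, 9.0)
    intensity_range: tuple[float, float] = (0.75, 1.0)
    process_count_range: tuple[int, int] = (2, 5)
    process_length_factor: tuple[float, float] = (2.0, 4.0)
    texture_noise_sd: float = 0.06
    background_noise_sd: float = 2.5
    min_separation: float = 4.0  # gap between cell discs, px


@dataclass
class SerialPanelConfig:
    """Configuration of an adjacent-serial-section panel.

    ``coloc_fraction`` is the probability that a positive cell on the base
    (first) marker's section has a positive partner within ``coloc_radius``
    pixels on each other marker's section; the remaining cells are placed
    uniformly at random.
    """

    markers: Sequence[str] = ("CD276", "Iba1", "CD163")
    image_size: tuple[int, int] = (512, 512)  # (H, W)
    n_round: int = 40
    n_ramified: int = 15
    n_negative: int = 30
    coloc_fraction: float = 0.5
    coloc_radius: float = 12.0
    section_offsets: dict[str, tuple[float, float]] = field(default_factory=dict)
    stain: StainParams = field(default_factory=StainParams)

    def __post_init__(self) -> None:
        if len(self.markers) < 2:
            raise ValueError("a serial panel needs at least 2 markers")
        if not 0.0 <= self.coloc_fraction <= 1.0:
            raise ValueError("coloc_fraction must lie in [0, 1]")
        h, w = self.image_size
        if self.coloc_radius >= min(h, w):
            raise ValueError("coloc_radius larger than the image")
        for m, (dx, dy) in self.section_offsets.items():
            if abs(dx) >= w or abs(dy) >= h:
                raise ValueError(f"section offset for {m} exceeds image size")


def _render(
    width: int,
    height: int,
    cells: Sequence[CellGroundTruth],
    rng: np.random.Generator,
    stain: StainParams,
) -> np.ndarray:
    img = np.ones((height, width, 3), dtype=np.float64) * BACKGROUND
    img += rng.normal(0.0, stain.background_noise_sd, size=img.shape)
    for cell in cells:
        if cell.phenotype == "negative":
            color = FAINT_BLUE + (BACKGROUND - FAINT_BLUE) * (1 - cell.stain_intensity)
        else:
            color = DAB_BROWN + (255.0 - DAB_BROWN) * (1.0 - cell.stain_intensity)
        rr, cc = disk((cell.y, cell.x), cell.radius_px, shape=(height, width))
        texture = 1.0 + rng.normal(0.0, stain.texture_noise_sd, size=rr.shape)
        img[rr, cc] = color[None, :] * texture[:, None]
        if cell.phenotype == "ramified_positive":
            angles = rng.uniform(0.0, 2 * np.pi, size=cell.n_processes)
            lengths = rng.uniform(*stain.process_length_factor, size=cell.n_processes)
            for ang, lf in zip(angles, lengths):
                ex = int(round(cell.x + np.cos(ang) * lf * cell.radius_px))
                ey = int(round(cell.y + np.sin(ang) * lf * cell.radius_px))
                ex = int(np.clip(ex, 0, width - 1))
                ey = int(np.clip(ey, 0, height - 1))
                rr, cc, val = line_aa(int(cell.y), int(cell.x), ey, ex)
                keep = (rr >= 0) & (rr < height) & (cc >= 0) & (cc < width)
                rr, cc, val = rr[keep], cc[keep], val[keep]
                img[rr, cc] = (1 - val[:, None]) * img[rr, cc] + val[:, None] * color
    return np.clip(img, 0, 255).astype(np.uint8)


def _place_cells(
    width: int,
    height: int,
    counts: dict[str, int],
    rng: np.random.Generator,
    stain: StainParams,
    fixed_positions: Sequence[tuple[float, float]] | None = None,
    fixed_phenotype: str = "round_positive",
) -> list[CellGroundTruth]:
    """Rejection-sample non-overlapping cells; 1000 attempts per cell.

    ``fixed_positions`` (used by the serial-panel generator) are placed first
    at exactly the given coordinates and count toward ``counts``.
    """
    total_requested = sum(counts.values()) + len(fixed_positions or [])
    placed: list[CellGroundTruth] = []
    occupied: list[tuple[float, float, float]] = []  # x, y, radius

    def overlaps(x: float, y: float, r: float) -> bool:
        for ox, oy, orad in occupied:
            if (x - ox) ** 2 + (y - oy) ** 2 < (r + orad + stain.min_separation) ** 2:
                return True
        return False

    def make(x: float, y: float, phenotype: str) -> CellGroundTruth:
        radius = rng.uniform(*stain.radius_range)
        intensity = rng.uniform(*stain.intensity_range)
        n_proc = 0
        if phenotype == "ramified_positive":
            n_proc = int(rng.integers(stain.process_count_range[0],
                                      stain.process_count_range[1] + 1))
        return CellGroundTruth(int(round(x)), int(round(y)), phenotype,
                               radius, n_proc, intensity)

    for (fx, fy) in fixed_positions or []:
        cell = make(fx, fy, fixed_phenotype)
        placed.append(cell)
        occupied.append((cell.x, cell.y, cell.radius_px))

    margin = stain.radius_range[1] + 1
    for phenotype in PHENOTYPES:
        for _ in range(counts.get(phenotype, 0)):
            for _attempt in range(1000):
                x = rng.uniform(margin, width - margin)
                y = rng.uniform(margin, height - margin)
                radius = stain.radius_range[1]
                if not overlaps(x, y, radius):
                    cell = make(x, y, phenotype)
                    placed.append(cell)
                    occupied.append((cell.x, cell.y, cell.radius_px))
                    break
            else:
                raise PlacementError(total_requested, len(placed))
    return placed


def generate_slide(
    width: int,
    height: int,
    counts: dict[str, int],
    marker: str,
    seed: int,
    stain: StainParams | None = None,
    slide_id: str | None = None,
) -> SyntheticSlide:
    """Render one synthetic slide with exactly the requested cells.

    Parameters
    ----------
    width, height : int
        Image size in pixels; both must be >= 128.
    counts : dict
        Requested number of cells per phenotype
        (``round_positive``, ``ramified_positive``, ``negative``).
    marker : str
        Marker name recorded in the ground truth (e.g. ``"Iba1"``).
    seed : int
        Seeds all randomness; same (arguments, seed) is bit-identical.
    """
    if width < 128 or height < 128:
        raise ValueError("slide must be at least 128x128 px")
    bad = set(counts) - set(PHENOTYPES)
    if bad:
        raise ValueError(f"unknown phenotypes {sorted(bad)}")
    if any(v < 0 for v in counts.values()):
        raise ValueError("cell counts must be non-negative")
    stain = stain or StainParams()
    rng = np.random.default_rng(seed)
    cells = _place_cells(width, height, counts, rng, stain)
    image = _render(width, height, cells, rng, stain)
    return SyntheticSlide(
        image=image,
        cells=cells,
        marker=marker,
        seed=seed,
        slide_id=slide_id or f"{marker}-s{seed}",
    )


def generate_serial_panel(
    config: SerialPanelConfig, seed: int
) -> tuple[list[SyntheticSlide], dict]:
    """Generate one slide per marker emulating adjacent serial sections.

    The first marker is the base section.  On every other marker's section, a
    fraction ``coloc_fraction`` of the positive (round) cells is planted
    within ``coloc_radius`` px of a base-section positive cell (before the
    rigid section offset is applied); the rest are uniform.  Each section's
    content is then shifted by its configured offset, emulating the physical
    misalignment of adjacent slices on the scanner stage.

    Returns the slides and a manifest recording per-marker offsets and the
    realized co-localization fraction (the fraction of base positives with a
    partner within ``coloc_radius``, measured from the planted coordinates).
    """
    rng = np.random.default_rng(seed)
    h, w = config.image_size
    stain = config.stain
    base_counts = {
        "round_positive": config.n_round,
        "ramified_positive": config.n_ramified,
        "negative": config.n_negative,
    }
    base_cells = _place_cells(w, h, base_counts, rng, stain)
    base_marker = config.markers[0]
    slides: list[SyntheticSlide] = []
    manifest: dict = {"seed": seed, "markers": {}, "coloc_radius": config.coloc_radius}

    base_pos = np.array(
        [(c.x, c.y) for c in base_cells if c.phenotype != "negative"], dtype=float
    )

    for mi, marker in enumerate(config.markers):
        offset = tuple(config.section_offsets.get(marker, (0.0, 0.0)))
        if mi == 0:
            cells = base_cells
        else:
            # partner positions near base positives, in base coordinates
            partners: list[tuple[float, float]] = []
            n_coloc = 0
            for (bx, by) in base_pos:
                if rng.uniform() < config.coloc_fraction:
                    r = config.coloc_radius * np.sqrt(rng.uniform())
                    ang = rng.uniform(0, 2 * np.pi)
                    px = float(np.clip(bx + r * np.cos(ang), 8, w - 9))
                    py = float(np.clip(by + r * np.sin(ang), 8, h - 9))
                    partners.append((px, py))
                    n_coloc += 1
            n_uniform_round = max(0, config.n_round - len(partners))
            counts = {
                "round_positive": n_uniform_round,
                "ramified_positive": config.n_ramified,
                "negative": config.n_negative,
            }
            cells = _place_cells(w, h, counts, rng, stain,
                                 fixed_positions=partners)
        # apply the rigid section offset to all cell coordinates
        dx, dy = offset
        shifted = []
        for c in cells:
            sx = int(np.clip(c.x + dx, 0, w - 1))
            sy = int(np.clip(c.y + dy, 0, h - 1))
            shifted.append(CellGroundTruth(sx, sy, c.phenotype, c.radius_px,
                                           c.n_processes, c.stain_intensity))
        image = _render(w, h, shifted, rng, stain)
        slide = SyntheticSlide(
            image=image,
            cells=shifted,
            marker=marker,
            seed=seed,
            slide_id=f"{marker}-panel-s{seed}",
            offset_from_base=offset,
        )
        slides.append(slide)
        entry: dict = {"offset": list(offset)}
        if mi > 0:
            entry["realized_coloc_fraction"] = realized_coloc_fraction(
                slides[0], slide, config.coloc_radius
            )
        manifest["markers"][marker] = entry
    return slides, manifest


def realized_coloc_fraction(
    base: SyntheticSlide, other: SyntheticSlide, radius: float
) -> float:
    """Fraction of base-section positives with an ``other``-section positive
    within ``radius`` px, after undoing both sections' rigid offsets."""
    from scipy.spatial import cKDTree

    def positives(slide: SyntheticSlide) -> np.ndarray:
        dx, dy = slide.offset_from_base
        return np.array(
            [(c.x - dx, c.y - dy) for c in slide.cells if c.phenotype != "negative"],
            dtype=float,
        )

    a, b = positives(base), positives(other)
    if len(a) == 0 or len(b) == 0:
        return 0.0
    tree = cKDTree(b)
    dist, _ = tree.query(a, k=1)
    return float(np.mean(dist <= radius))


def ground_truth_heatmap(slide: SyntheticSlide, stride: int = 10,
                         radius: float | None = None):
    """Idealized detection heatmap straight from the planted ground truth.

    A grid cell scores 1.0 when a positive (non-``negative``) cell center
    lies within ``radius`` px (default: the largest rendered cell radius) of
    its window center, else 0.0.  This is what a perfect detector would
    produce, and it lets registration and fusion be exercised independently
    of any trained model.
    """
    from scipy.spatial import cKDTree

    from .heatmap import Heatmap, grid_shape

    h, w = slide.image.shape[:2]
    gh, gw = grid_shape(h, w, stride)
    pos = np.array([(c.x, c.y) for c in slide.cells if c.phenotype != "negative"],
                   dtype=float)
    grid = np.zeros((gh, gw))
    if len(pos):
        if radius is None:
            radius = max(c.radius_px for c in slide.cells)
        gy, gx = np.mgrid[0:gh, 0:gw]
        centers = np.stack([gx.ravel() * stride, gy.ravel() * stride], axis=1)
        dist, _ = cKDTree(pos).query(centers, k=1)
        grid = (dist <= radius).astype(float).reshape(gh, gw)
    return Heatmap(grid=grid, stride=stride, slide_id=slide.slide_id,
                   marker=slide.marker, threshold=0.5)


# ---------------------------------------------------------------------------
# serialization

def write_slide(slide: SyntheticSlide, directory: str | Path) -> dict[str, Path]:
    """Write the raster (PNG), ground truth (CSV + JSON) for one slide."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    png = directory / f"{slide.slide_id}.png"
    iio.imwrite(png, slide.image)
    rows = [
        {
            "slide_id": slide.slide_id,
            "marker": slide.marker,
            "x": c.x,
            "y": c.y,
            "phenotype": c.phenotype,
            "radius_px": c.radius_px,
            "stain_intensity": c.stain_intensity,
        }
        for c in slide.cells
    ]
    csv = directory / f"{slide.slide_id}.cells.csv"
    pd.DataFrame(
        rows,
        columns=["slide_id", "marker", "x", "y", "phenotype",
                 "radius_px", "stain_intensity"],
    ).to_csv(csv, index=False)
    meta = directory / f"{slide.slide_id}.json"
    meta.write_text(
        json.dumps(
            {
                "slide_id": slide.slide_id,
                "marker": slide.marker,
                "seed": slide.seed,
                "offset_from_base": list(slide.offset_from_base),
                "height": slide.image.shape[0],
                "width": slide.image.shape[1],
                "n_cells": len(slide.cells),
            },
            indent=2,
        )
    )
    return {"image": png, "cells": csv, "meta": meta}


def write_panel_manifest(manifest: dict, path: str | Path) -> None:
    Path(path).write_text(json.dumps(manifest, indent=2))
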