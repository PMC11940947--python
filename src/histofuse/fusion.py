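"""Registration of adjacent-section heatmaps and categorical fusion.

Adjacent serial sections are stained for different markers, so their
detection heatmaps are only comparable after spatial registration.  A rigid
integer-grid translation is found by exhaustively evaluating the distance
matrix E — the mean squared difference between the two binarized grids over
their overlap at every candidate shift — and taking its minimum.  The fusion
function then assigns each grid cell of the registered overlap one of three
categories: *both* markers' cells present (rendered red), exactly *one*
present (white), or *neither* (turquoise).

A quantitative co-localization summary (counts, co-localization index and an
optional toroidal-permutation null) is layered on top of the categorical map
without altering it.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import imageio.v3 as iio
import numpy as np

from .heatmap import Heatmap, binarize

PALETTE = {
    "neither": np.array([64, 224, 208], dtype=np.uint8),   # turquoise
    "one": np.array([255, 255, 255], dtype=np.uint8),      # white
    "both": np.array([255, 0, 0], dtype=np.uint8),         # red
}
CATEGORY_CODES = {"neither": 0, "one": 1, "both": 2}


class RegistrationError(RuntimeError):
    pass


@dataclass(frozen=True)
class RigidTransform:
    """Integer-grid translation of section B relative to section A, in px
    (always a multiple of the heatmap stride), with the cost at optimum."""

    dx: float
    dy: float
    score: float


@dataclass
class FusionMap:
    categories: np.ndarray  # (h, w) uint8 codes 0/1/2 over the overlap
    counts: dict
    pair: tuple[str, str]
    transform: RigidTransform
    source_thresholds: dict
    stride: int
    a_mask: np.ndarray = field(repr=False, default=None)
    b_mask: np.ndarray = field(repr=False, default=None)


@dataclass
class ColocalizationSummary:
    n_both: int
    n_one: int
    n_neither: int
    coloc_index: float | None
    permutation_p: float | None = None


def _overlap_slices(shape_a, shape_b, sx: int, sy: int):
    """Index slices of A and B for shift (sx, sy) cells, where B's content is
    A's shifted by (sx, sy): b[y + sy, x + sx] ~ a[y, x]."""
    ha, wa = shape_a
    hb, wb = shape_b
    ya0, ya1 = max(0, -sy), min(ha, hb - sy)
    xa0, xa1 = max(0, -sx), min(wa, wb - sx)
    if ya1 <= ya0 or xa1 <= xa0:
        return None
    return ((slice(ya0, ya1), slice(xa0, xa1)),
            (slice(ya0 + sy, ya1 + sy), slice(xa0 + sx, xa1 + sx)))


def distance_matrix(a: np.ndarray, b: np.ndarray, radius_cells: int) -> np.ndarray:
    """The registration cost E(dy, dx) on binarized grids: MSE over the
    overlap for every shift in [-radius, radius]^2 (NaN where empty)."""
    size = 2 * radius_cells + 1
    e = np.full((size, size), np.nan)
    af = a.astype(np.float64)
    bf = b.astype(np.float64)
    for iy, sy in enumerate(range(-radius_cells, radius_cells + 1)):
        for ix, sx in enumerate(range(-radius_cells, radius_cells + 1)):
            sl = _overlap_slices(a.shape, b.shape, sx, sy)
            if sl is None:
                continue
            (sa, sb) = sl
            e[iy, ix] = float(((af[sa] - bf[sb]) ** 2).mean())
    return e


def register(hm_a: Heatmap, hm_b: Heatmap, search_radius: int = 50) -> RigidTransform:
    """Find the translation of B relative to A minimizing the distance
    matrix E, exhaustively over +-search_radius px (rounded up to whole grid
    cells).  Ties break toward the smallest |dx| + |dy|, then
    lexicographically on (dx, dy)."""
    if hm_a.stride != hm_b.stride:
        raise ValueError("heatmaps must share the same stride")
    stride = hm_a.stride
    radius_cells = max(1, int(np.ceil(search_radius / stride)))
    a = binarize(hm_a)
    b = binarize(hm_b)
    e = distance_matrix(a, b, radius_cells)
    if np.isnan(e).all():
        raise RegistrationError("no overlap at any candidate offset")
    best = None
    for iy in range(e.shape[0]):
        for ix in range(e.shape[1]):
            if np.isnan(e[iy, ix]):
                continue
            sx, sy = ix - radius_cells, iy - radius_cells
            key = (e[iy, ix], abs(sx) + abs(sy), sx, sy)
            if best is None or key < best[0]:
                best = (key, sx, sy)
    (cost, _, _, _), sx, sy = best
    return RigidTransform(dx=float(sx * stride), dy=float(sy * stride),
                          score=float(cost))


def fuse(
    hm_a: Heatmap,
    hm_b: Heatmap,
    transform: RigidTransform,
    thresholds: dict | None = None,
) -> FusionMap:
    """Combine two registered heatmaps into the categorical fusion map.

    Per registered-overlap grid cell: both detections -> ``both`` (red),
    exactly one -> ``one`` (white), none -> ``neither`` (turquoise).
    """
    if hm_a.stride != hm_b.stride:
        raise ValueError("stride mismatch between heatmaps")
    stride = hm_a.stride
    thresholds = thresholds or {}
    ta = thresholds.get(hm_a.marker, hm_a.threshold)
    tb = thresholds.get(hm_b.marker, hm_b.threshold)
    a = binarize(hm_a, ta)
    b = binarize(hm_b, tb)
    sx = int(round(transform.dx / stride))
    sy = int(round(transform.dy / stride))
    sl = _overlap_slices(a.shape, b.shape, sx, sy)
    if sl is None:
        raise RegistrationError("transform leaves no overlap")
    sa, sb = sl
    am, bm = a[sa], b[sb]
    categories = np.zeros(am.shape, dtype=np.uint8)
    categories[am ^ bm] = CATEGORY_CODES["one"]
    categories[am & bm] = CATEGORY_CODES["both"]
    counts = {
        "both": int((am & bm).sum()),
        "one": int((am ^ bm).sum()),
        "neither": int((~am & ~bm).sum()),
        "a_only": int((am & ~bm).sum()),
        "b_only": int((~am & bm).sum()),
    }
    return FusionMap(
        categories=categories, counts=counts,
        pair=(hm_a.marker, hm_b.marker), transform=transform,
        source_thresholds={hm_a.marker: ta, hm_b.marker: tb},
        stride=stride, a_mask=am, b_mask=bm,
    )


def render_fusion(fm: FusionMap) -> np.ndarray:
    """Red = both markers, white = exactly one, turquoise = neither;
    nearest-neighbor upsampling to slide scale."""
    lut = np.stack([PALETTE["neither"], PALETTE["one"], PALETTE["both"]])
    rgb = lut[fm.categories]
    return np.repeat(np.repeat(rgb, fm.stride, axis=0), fm.stride, axis=1)


def decode_fusion(rendered: np.ndarray, stride: int) -> np.ndarray:
    """Recover the category grid from a rendered fusion image."""
    sub = rendered[::stride, ::stride]
    lut = np.stack([PALETTE["neither"], PALETTE["one"], PALETTE["both"]])
    codes = np.zeros(sub.shape[:2], dtype=np.uint8)
    for code, color in enumerate(lut):
        codes[(sub == color).all(axis=-1)] = code
    return codes


def _coloc_index(am: np.ndarray, bm: np.ndarray) -> float | None:
    n_both = int((am & bm).sum())
    n_one = int((am ^ bm).sum())
    if n_both + n_one == 0:
        return None
    return n_both / (n_both + n_one)


def summarize(fm: FusionMap, n_permutations: int = 0, seed: int = 0) -> ColocalizationSummary:
    """Counts, co-localization index = n_both / (n_both + n_one), and an
    optional one-sided permutation p-value.

    The null is built by toroidally shifting the B mask by uniform random
    offsets, which preserves both markers' detection densities and spatial
    autocorrelation while destroying their cross-alignment; the p-value uses
    the standard +1 rank correction.
    """
    if n_permutations < 0:
        raise ValueError("n_permutations must be >= 0")
    counts = fm.counts
    observed = _coloc_index(fm.a_mask, fm.b_mask)
    p = None
    if n_permutations > 0 and observed is not None:
        rng = np.random.default_rng(seed)
        h, w = fm.b_mask.shape
        hits = 0
        for _ in range(n_permutations):
            oy = int(rng.integers(0, h))
            ox = int(rng.integers(0, w))
            rolled = np.roll(np.roll(fm.b_mask, oy, axis=0), ox, axis=1)
            ci = _coloc_index(fm.a_mask, rolled)
            if ci is not None and ci >= observed:
                hits += 1
        p = (1 + hits) / (n_permutations + 1)
    return ColocalizationSummary(
        n_both=counts["both"], n_one=counts["one"], n_neither=counts["neither"],
        coloc_index=observed, permutation_p=p,
    )


def save_fusion(fm: FusionMap, stem: str | Path) -> dict[str, Path]:
    """Persist category grid (npz), metadata (JSON) and rendered PNG."""
    stem = Path(stem)
    grid_path = stem.with_suffix(".npz")
    np.savez(grid_path, categories=fm.categories,
             a_mask=fm.a_mask, b_mask=fm.b_mask)
    meta_path = stem.with_suffix(".json")
    meta_path.write_text(json.dumps({
        "pair": list(fm.pair),
        "transform": {"dx": fm.transform.dx, "dy": fm.transform.dy,
                      "score": fm.transform.score},
        "counts": fm.counts,
        "source_thresholds": fm.source_thresholds,
        "stride": fm.stride,
    }, indent=2))
    png_path = stem.with_suffix(".png")
    iio.imwrite(png_path, render_fusion(fm))
    return {"grid": grid_path, "meta": meta_path, "png": png_path}
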