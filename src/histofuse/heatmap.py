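"""Sliding-window whole-slide inference into per-marker probability heatmaps.

The slide is scanned on a regular grid of window centers starting at pixel 0
with a fixed stride (default 10 px, the evaluation stride used throughout).
Every center gets a bifocal patch (reflection-padded at slide borders, so the
full slide is covered) and the classifier's positive-class probability; the
result is a stride-spaced probability grid plus the threshold T used by the
downstream categorical stages.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view

from .patches import HALF, INNER, INSET, OUTER, PreprocessConfig, preprocess_image

TURQUOISE = np.array([64, 224, 208], dtype=np.float64)
RED = np.array([255, 0, 0], dtype=np.float64)


@dataclass
class Heatmap:
    grid: np.ndarray  # (gh, gw) floats in [0, 1]
    stride: int
    origin: tuple[int, int] = (0, 0)
    slide_id: str = ""
    marker: str = ""
    threshold: float = 0.5

    def __post_init__(self) -> None:
        g = np.asarray(self.grid, dtype=np.float64)
        if g.ndim != 2:
            raise ValueError("heatmap grid must be 2-D")
        if g.size and (g.min() < 0 or g.max() > 1):
            raise ValueError("heatmap values must lie in [0, 1]")
        self.grid = g


def grid_shape(height: int, width: int, stride: int) -> tuple[int, int]:
    """Number of window centers per axis: centers 0, stride, ... <= dim-1."""
    return ((height - 1) // stride + 1, (width - 1) // stride + 1)


def scan(
    image: np.ndarray,
    model,
    stride: int = 10,
    preprocess: PreprocessConfig | None = None,
    slide_id: str = "",
    marker: str = "",
    batch_rows: int = 8,
) -> Heatmap:
    """Scan a slide into a probability heatmap.

    ``model`` is anything with ``predict_proba_arrays(inner, outer)`` taking
    NCHW float32 batches (the trained bifocal classifier, or a stub in
    tests).  The scan is chunked ``batch_rows`` grid rows at a time so memory
    stays bounded regardless of slide size; chunking is invisible in the
    output.
    """
    if stride < 1:
        raise ValueError("stride must be >= 1")
    h, w = image.shape[:2]
    if h < OUTER or w < OUTER:
        raise ValueError(f"image must be at least {OUTER}x{OUTER}")
    if preprocess is not None:
        image = preprocess_image(image, preprocess)
    padded = np.pad(image, ((HALF, HALF), (HALF, HALF), (0, 0)), mode="reflect")
    windows = sliding_window_view(padded, (OUTER, OUTER), axis=(0, 1))
    # windows[y, x] is the 64x64 window centered on slide pixel (x, y)
    grid_view = windows[0:h:stride, 0:w:stride]  # (gh, gw, 3, 64, 64)
    gh, gw = grid_view.shape[:2]
    grid = np.empty((gh, gw), dtype=np.float64)
    for r0 in range(0, gh, batch_rows):
        r1 = min(r0 + batch_rows, gh)
        outer = np.ascontiguousarray(grid_view[r0:r1]).reshape(-1, 3, OUTER, OUTER)
        outer = outer.astype(np.float32) / 255.0 - 0.5
        inner = outer[:, :, INSET:INSET + INNER, INSET:INSET + INNER]
        proba = model.predict_proba_arrays(np.ascontiguousarray(inner), outer)
        grid[r0:r1] = proba.reshape(r1 - r0, gw)
    threshold = getattr(getattr(model, "config", None), "threshold", 0.5)
    return Heatmap(grid=np.clip(grid, 0.0, 1.0), stride=stride,
                   slide_id=slide_id, marker=marker, threshold=threshold)


def binarize(hm: Heatmap, threshold: float | None = None) -> np.ndarray:
    """Boolean detection grid: cell positive iff its probability >= T."""
    t = hm.threshold if threshold is None else threshold
    if not 0.0 < t <= 1.0:
        raise ValueError("threshold must lie in (0, 1]")
    return hm.grid >= t


def render_heatmap(hm: Heatmap) -> np.ndarray:
    """Render detections in red on a turquoise background, upsampled to
    slide scale by nearest neighbor.

    The color ramp is monotone in the probability: 0 maps to turquoise, the
    threshold to the ramp midpoint and 1 to pure red, so sub-threshold cells
    stay turquoise-ish and confident detections saturate to red.
    """
    t = np.empty_like(hm.grid)
    thr = hm.threshold
    below = hm.grid < thr
    t[below] = 0.5 * hm.grid[below] / max(thr, 1e-12)
    t[~below] = 0.5 + 0.5 * (hm.grid[~below] - thr) / max(1.0 - thr, 1e-12)
    rgb = (1 - t[..., None]) * TURQUOISE + t[..., None] * RED
    rgb = np.clip(rgb, 0, 255).round().astype(np.uint8)
    return np.repeat(np.repeat(rgb, hm.stride, axis=0), hm.stride, axis=1)


def detect_cells(hm: Heatmap, threshold: float | None = None) -> np.ndarray:
    """Detected cell centers as (x, y) slide pixels.

    The thresholded grid is segmented into connected components (one blob of
    supra-threshold probability per detected cell) and each component
    contributes one detection at its probability-weighted centroid.  Working
    per component rather than per raw local maximum makes the detector
    immune to plateau ties, which saturated probabilities produce routinely.
    """
    from scipy import ndimage

    t = hm.threshold if threshold is None else threshold
    mask = hm.grid >= t
    if not mask.any():
        return np.empty((0, 2), dtype=int)
    labeled, n = ndimage.label(mask, structure=np.ones((3, 3), dtype=int))
    out = []
    for idx in range(1, n + 1):
        ys, xs = np.nonzero(labeled == idx)
        v = hm.grid[ys, xs]
        out.append((
            int(round((xs * v).sum() / v.sum() * hm.stride)) + hm.origin[0],
            int(round((ys * v).sum() / v.sum() * hm.stride)) + hm.origin[1],
        ))
    return np.array(out, dtype=int)


def calibrate_threshold(
    hm: Heatmap,
    true_centers: np.ndarray,
    match_radius: float | None = None,
    candidates: np.ndarray | None = None,
) -> float:
    """Pick the detection threshold maximizing F1 against known centers.

    Used on a validation slide with ground truth (synthetic, or a
    hand-annotated tile): every candidate threshold is applied with
    :func:`detect_cells`, detections are matched to true centers within
    ``match_radius`` px (default: one stride), and the threshold with the
    best F1 is returned.  Ties prefer the larger threshold (sharper maps).
    """
    from scipy.spatial import cKDTree

    true_centers = np.asarray(true_centers, dtype=float)
    if match_radius is None:
        match_radius = float(hm.stride)
    if candidates is None:
        candidates = np.arange(0.30, 0.95, 0.05)
    best_t, best_f1 = 0.5, -1.0
    for t in candidates:
        det = detect_cells(hm, threshold=float(t))
        if len(det) == 0 or len(true_centers) == 0:
            continue
        d_gt, _ = cKDTree(det).query(true_centers)
        d_det, _ = cKDTree(true_centers).query(det)
        recall = float((d_gt <= match_radius).mean())
        precision = float((d_det <= match_radius).mean())
        if precision + recall == 0:
            continue
        f1 = 2 * precision * recall / (precision + recall)
        if f1 >= best_f1:
            best_f1, best_t = f1, float(t)
    return best_t


def save_heatmap(hm: Heatmap, path: str | Path) -> None:
    path = Path(path)
    meta = json.dumps({
        "stride": hm.stride, "origin": list(hm.origin),
        "slide_id": hm.slide_id, "marker": hm.marker,
        "threshold": hm.threshold,
    })
    np.savez(path, grid=hm.grid,
             __meta__=np.frombuffer(meta.encode(), dtype=np.uint8))


def load_heatmap(path: str | Path) -> Heatmap:
    data = np.load(path if str(path).endswith(".npz") else f"{path}.npz")
    meta = json.loads(bytes(data["__meta__"]).decode())
    return Heatmap(grid=data["grid"], stride=int(meta["stride"]),
                   origin=tuple(meta["origin"]), slide_id=meta["slide_id"],
                   marker=meta["marker"], threshold=float(meta["threshold"]))
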