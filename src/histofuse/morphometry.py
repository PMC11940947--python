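"""Post-detection cell segmentation and feature quantification.

After the classifier has located cells, each one is segmented from its
surroundings by automatic binary thresholding (Otsu), edge detection and
contour tracing, and quantified with four shape/intensity features: area
(px^2, shoelace formula on the traced polygon), perimeter (polygonal arc
length), compactness (the isoperimetric ratio 4*pi*A / P^2, 1 for a perfect
circle and smaller for elongated or ramified shapes) and minimum pixel
intensity inside the filled contour.  Per-slide means of these features
summarize each detected population.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import ndimage
from skimage import measure
from skimage.feature import canny
from skimage.filters import threshold_otsu


@dataclass
class CellContour:
    """Closed polygon traced around one segmented cell, (x, y) vertices."""

    vertices: np.ndarray  # (n, 2) float, columns x, y
    slide_id: str = ""
    marker: str = ""
    touches_border: bool = False
    has_holes: bool = False

    def __post_init__(self) -> None:
        v = np.asarray(self.vertices, dtype=np.float64)
        if v.ndim != 2 or v.shape[1] != 2 or v.shape[0] < 3:
            raise ValueError("a contour needs at least 3 (x, y) vertices")
        # drop a duplicated closing vertex; closure is implicit
        if np.allclose(v[0], v[-1]):
            v = v[:-1]
        if v.shape[0] < 3:
            raise ValueError("degenerate contour after closing")
        self.vertices = v


@dataclass
class CellFeatures:
    area: float
    perimeter: float
    compactness: float
    min_intensity: float


def to_grayscale(image: np.ndarray, invert: bool = True) -> np.ndarray:
    """Luminance channel; inverted by default so stained (dark) cells are
    bright, matching the white-cells-on-black convention."""
    if image.ndim == 3:
        gray = image @ np.array([0.299, 0.587, 0.114])
    else:
        gray = image.astype(np.float64)
    return 255.0 - gray if invert else gray


def threshold_binary(image: np.ndarray, cells_bright: bool = True) -> np.ndarray:
    """Otsu threshold to a binary mask (True = cell, False = background).

    A constant image yields an empty mask with a warning rather than an
    exception.  With ``cells_bright=False`` the polarity is flipped, so
    inverting both the image and the flag gives the same mask.
    """
    img = np.asarray(image, dtype=np.float64)
    if np.ptp(img) == 0:
        warnings.warn("constant image: returning empty mask", stacklevel=2)
        return np.zeros(img.shape, dtype=bool)
    t = threshold_otsu(img)
    return img > t if cells_bright else img < t


def detect_edges(image: np.ndarray, sigma: float = 1.5,
                 low: float = 0.1, high: float = 0.3) -> np.ndarray:
    """Canny edge map (gradient magnitude with hysteresis) marking sharp
    intensity changes, typically cell borders."""
    img = np.asarray(image, dtype=np.float64)
    if np.ptp(img) == 0:
        return np.zeros(img.shape, dtype=bool)
    img = (img - img.min()) / np.ptp(img)
    return canny(img, sigma=sigma, low_threshold=low, high_threshold=high)


def find_contours(mask: np.ndarray, min_area: float = 0.0,
                  slide_id: str = "", marker: str = "") -> list[CellContour]:
    """Trace one closed contour per connected foreground component with
    pixel area >= min_area.  Holes are filled before tracing (recorded per
    contour); components touching the border are kept and flagged."""
    labeled, n = ndimage.label(mask)
    out: list[CellContour] = []
    for idx in range(1, n + 1):
        component = labeled == idx
        if component.sum() < min_area:
            continue
        filled = ndimage.binary_fill_holes(component)
        has_holes = bool((filled & ~component).any())
        padded = np.pad(filled, 1).astype(np.float64)
        contours = measure.find_contours(padded, 0.5)
        if not contours:
            continue
        rc = max(contours, key=len) - 1.0  # undo padding; (row, col)
        vertices = rc[:, ::-1]  # -> (x, y)
        ys, xs = np.nonzero(component)
        touches = bool(
            xs.min() == 0 or ys.min() == 0
            or xs.max() == mask.shape[1] - 1 or ys.max() == mask.shape[0] - 1
        )
        out.append(CellContour(vertices=vertices, slide_id=slide_id,
                               marker=marker, touches_border=touches,
                               has_holes=has_holes))
    return out


def polygon_area(vertices: np.ndarray) -> float:
    """Shoelace formula (absolute value)."""
    x, y = vertices[:, 0], vertices[:, 1]
    return float(abs(np.dot(x, np.roll(y, -1)) - np.dot(y, np.roll(x, -1))) / 2)


def polygon_perimeter(vertices: np.ndarray) -> float:
    d = np.diff(np.vstack([vertices, vertices[:1]]), axis=0)
    return float(np.hypot(d[:, 0], d[:, 1]).sum())


def measure_contour(contour: CellContour, image: np.ndarray) -> CellFeatures:
    """Area, perimeter, compactness and minimum interior intensity of one
    cell.  Holes are filled for the interior minimum, so staining voids do
    not contribute."""
    from skimage.draw import polygon as draw_polygon

    v = contour.vertices
    area = polygon_area(v)
    perimeter = polygon_perimeter(v)
    if area <= 0 or perimeter <= 0:
        raise ValueError("degenerate contour: zero area or perimeter")
    compactness = 4 * np.pi * area / perimeter**2
    img = np.asarray(image, dtype=np.float64)
    if img.ndim == 3:
        img = to_grayscale(img, invert=False)
    rr, cc = draw_polygon(v[:, 1], v[:, 0], shape=img.shape)
    if rr.size == 0:  # sub-pixel contour: fall back to rounded vertices
        rr = np.clip(np.round(v[:, 1]).astype(int), 0, img.shape[0] - 1)
        cc = np.clip(np.round(v[:, 0]).astype(int), 0, img.shape[1] - 1)
    return CellFeatures(
        area=area, perimeter=perimeter, compactness=float(compactness),
        min_intensity=float(img[rr, cc].min()),
    )


def summarize_features(features: list[CellFeatures]) -> dict:
    """Arithmetic means of each feature plus n; no means when empty."""
    n = len(features)
    if n == 0:
        return {"n": 0}
    return {
        "n": n,
        "mean_area": float(np.mean([f.area for f in features])),
        "mean_perimeter": float(np.mean([f.perimeter for f in features])),
        "mean_compactness": float(np.mean([f.compactness for f in features])),
        "mean_min_intensity": float(np.mean([f.min_intensity for f in features])),
    }


def measure_detections(
    image: np.ndarray,
    detections: np.ndarray,
    window: int = 32,
    min_area: float = 9.0,
    slide_id: str = "",
    marker: str = "",
) -> pd.DataFrame:
    """Segment and measure a window around each accepted detection.

    For every detected center a ``window``-sized crop is thresholded
    (Otsu on inverted luminance, so stained cells are foreground) and the
    contour containing — or nearest to — the center is measured.  Returns
    the per-cell feature table.
    """
    rows = []
    gray = to_grayscale(image, invert=True)
    orig = to_grayscale(image, invert=False)
    h, w = gray.shape
    half = window // 2
    for cell_id, (x, y) in enumerate(np.asarray(detections, dtype=int)):
        x0, x1 = max(0, x - half), min(w, x + half)
        y0, y1 = max(0, y - half), min(h, y + half)
        crop = gray[y0:y1, x0:x1]
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            mask = threshold_binary(crop)
        contours = find_contours(mask, min_area=min_area,
                                 slide_id=slide_id, marker=marker)
        if not contours:
            continue
        cx, cy = x - x0, y - y0
        contour = min(
            contours,
            key=lambda c: np.hypot(c.vertices[:, 0].mean() - cx,
                                   c.vertices[:, 1].mean() - cy),
        )
        feats = measure_contour(contour, orig[y0:y1, x0:x1])
        rows.append({
            "slide_id": slide_id, "marker": marker, "cell_id": cell_id,
            "x": int(x), "y": int(y),
            "area_px2": feats.area, "perimeter_px": feats.perimeter,
            "compactness": feats.compactness,
            "min_intensity": feats.min_intensity,
        })
    return pd.DataFrame(
        rows, columns=["slide_id", "marker", "cell_id", "x", "y",
                       "area_px2", "perimeter_px", "compactness",
                       "min_intensity"],
    )
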