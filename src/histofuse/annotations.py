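"""Dot-annotation data model, tile partitioning and train/test splitting.

Experts mark cells of interest with "red dots" (positive) and confounding
unlabeled cells or tissue with "blue dots" (negative).  Slides are divided
into four non-overlapping tiles and the split into training and test sets is
made at tile level, so patches from nearly the same location can never land
on both sides.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

LABELS = ("positive", "negative")


@dataclass(frozen=True)
class DotAnnotation:
    slide_id: str
    marker: str
    x: int
    y: int
    label: str

    def __post_init__(self) -> None:
        if self.label not in LABELS:
            raise ValueError(f"label must be one of {LABELS}, got {self.label!r}")


@dataclass(frozen=True)
class TilePartition:
    """Four half-open rectangles (x0, y0, x1, y1) covering a slide exactly."""

    slide_id: str
    tiles: tuple[tuple[int, int, int, int], ...]

    def tile_of(self, x: int, y: int) -> int:
        for i, (x0, y0, x1, y1) in enumerate(self.tiles):
            if x0 <= x < x1 and y0 <= y < y1:
                return i
        raise ValueError(f"point ({x}, {y}) outside all tiles of {self.slide_id}")


class AnnotationParseError(ValueError):
    def __init__(self, line: int, message: str):
        super().__init__(f"line {line}: {message}")
        self.line = line


def partition_slide(width: int, height: int, slide_id: str = "") -> TilePartition:
    """2x2 partition at floor midpoints; tiles half-open, so every pixel
    belongs to exactly one tile."""
    if width < 2 or height < 2:
        raise ValueError("slide must be at least 2x2 to partition")
    mx, my = width // 2, height // 2
    tiles = (
        (0, 0, mx, my),
        (mx, 0, width, my),
        (0, my, mx, height),
        (mx, my, width, height),
    )
    return TilePartition(slide_id=slide_id, tiles=tiles)


def split_annotations(
    annotations: Sequence[DotAnnotation],
    partition: TilePartition,
    test_tiles: Iterable[int],
) -> tuple[list[DotAnnotation], list[DotAnnotation]]:
    """Assign each annotation to train or test purely by the tile that
    contains its coordinate.  Order-independent and lossless."""
    test_tiles = set(test_tiles)
    if not test_tiles <= {0, 1, 2, 3}:
        raise ValueError("test_tiles must be a subset of {0, 1, 2, 3}")
    train: list[DotAnnotation] = []
    test: list[DotAnnotation] = []
    for ann in annotations:
        try:
            tile = partition.tile_of(ann.x, ann.y)
        except ValueError as exc:
            raise ValueError(f"annotation {ann} outside the slide extent") from exc
        (test if tile in test_tiles else train).append(ann)
    return train, test


def read_annotations(path: str | Path) -> list[DotAnnotation]:
    """Read a dot-annotation CSV (header slide_id,marker,x,y,label)."""
    out: list[DotAnnotation] = []
    with open(path, newline="") as fh:
        reader = csv.DictReader(fh)
        expected = {"slide_id", "marker", "x", "y", "label"}
        if reader.fieldnames is None or not expected <= set(reader.fieldnames):
            raise AnnotationParseError(1, f"header must contain {sorted(expected)}")
        for lineno, row in enumerate(reader, start=2):
            label = row["label"].strip()
            if label not in LABELS:
                raise AnnotationParseError(lineno, f"unknown label {label!r}")
            try:
                x, y = int(row["x"]), int(row["y"])
            except ValueError:
                raise AnnotationParseError(lineno, "x and y must be integers")
            out.append(DotAnnotation(row["slide_id"], row["marker"], x, y, label))
    return out


def write_annotations(annotations: Sequence[DotAnnotation], path: str | Path) -> None:
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(["slide_id", "marker", "x", "y", "label"])
        for a in annotations:
            writer.writerow([a.slide_id, a.marker, a.x, a.y, a.label])


def annotations_from_ground_truth(
    slide,
    positive_phenotypes: Sequence[str] = ("round_positive",),
    n_background: int = 0,
    background_margin: float = 24.0,
    seed: int = 0,
) -> list[DotAnnotation]:
    """Derive dot annotations from a synthetic slide's ground-truth cells.

    The listed phenotypes become red dots, every other cell a blue dot.
    ``n_background`` additional blue dots are sampled on unstained tissue at
    least ``background_margin`` px from any cell center — the equivalent of
    an annotator marking empty tissue for exclusion, which the classifier
    needs to reject confidently when scanning between cells.
    """
    dots = [
        DotAnnotation(
            slide.slide_id,
            slide.marker,
            c.x,
            c.y,
            "positive" if c.phenotype in positive_phenotypes else "negative",
        )
        for c in slide.cells
    ]
    if n_background > 0:
        import numpy as np

        rng = np.random.default_rng(seed + 1_000_003)
        h, w = slide.image.shape[:2]
        centers = np.array([(c.x, c.y) for c in slide.cells], dtype=float)
        placed = 0
        for _ in range(n_background * 200):
            if placed >= n_background:
                break
            x = int(rng.integers(0, w))
            y = int(rng.integers(0, h))
            if len(centers):
                d2 = ((centers - (x, y)) ** 2).sum(axis=1).min()
                if d2 < background_margin**2:
                    continue
            dots.append(DotAnnotation(slide.slide_id, slide.marker, x, y,
                                      "negative"))
            placed += 1
    return dots


def training_dots_from_ground_truth(
    slide,
    seed: int = 0,
    positive_phenotypes: Sequence[str] = ("round_positive",),
    n_background: int = 30,
    jitter_px: float = 5.0,
    ring_radii: tuple[float, float] = (15.0, 25.0),
    ring_dots: int = 2,
) -> list[DotAnnotation]:
    """Annotation-sampling policy for detector training.

    Beyond the plain center dots of :func:`annotations_from_ground_truth`,
    this adds the samples a detector scanning at a 10-px stride actually
    encounters: a positive dot jittered up to ``jitter_px`` from each
    positive center (scan windows are up to half a stride off-center), and
    ``ring_dots`` negative dots per positive at ``ring_radii`` px from its
    center (so near-misses score low and each cell yields one sharp blob
    rather than a broad plateau).  Non-positive cells also get one jittered
    negative dot for the same tolerance reason.
    """
    import numpy as np

    rng = np.random.default_rng(seed + 7_000_017)
    dots = annotations_from_ground_truth(
        slide, positive_phenotypes, n_background=n_background, seed=seed)
    h, w = slide.image.shape[:2]
    centers = [(c.x, c.y) for c in slide.cells]

    def at(cx, cy, r_lo, r_hi):
        ang = rng.uniform(0, 2 * np.pi)
        r = rng.uniform(r_lo, r_hi)
        return (int(np.clip(cx + r * np.cos(ang), 0, w - 1)),
                int(np.clip(cy + r * np.sin(ang), 0, h - 1)))

    for c in slide.cells:
        positive = c.phenotype in positive_phenotypes
        x, y = at(c.x, c.y, 0, jitter_px)
        dots.append(DotAnnotation(slide.slide_id, slide.marker, x, y,
                                  "positive" if positive else "negative"))
        if not positive:
            continue
        for _ in range(ring_dots):
            x, y = at(c.x, c.y, *ring_radii)
            near_other = any(
                (ox - x) ** 2 + (oy - y) ** 2 < ring_radii[0] ** 2
                for ox, oy in centers if (ox, oy) != (c.x, c.y)
            )
            if not near_other:
                dots.append(DotAnnotation(slide.slide_id, slide.marker,
                                          x, y, "negative"))
    return dots
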