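"""End-to-end pipeline: synthesize/ingest -> train -> scan -> fuse -> measure.

Each stage reads and writes plain files inside a workspace directory, so the
stages can be run individually (the CLI exposes one verb per stage) or all
at once with :func:`run_pipeline`.  Every stochastic step derives its seed
from the single pipeline seed, and all summary tables are written with fixed
float formatting, so a rerun with the same config is byte-identical.
"""

from __future__ import annotations

import json
import time
from dataclasses import dataclass, field, asdict
from pathlib import Path

import imageio.v3 as iio
import numpy as np
import pandas as pd
import yaml

from . import fusion as fusion_mod
from . import heatmap as heatmap_mod
from . import morphometry
from .annotations import (partition_slide, split_annotations,
                          training_dots_from_ground_truth)
from .classifier import ClassifierConfig, TrainedModel, train, write_training_log
from .patches import PreprocessConfig, ReferenceStats, augment, extract_dataset, preprocess_image
from .synthetic import (SerialPanelConfig, StainParams, generate_serial_panel,
                        write_panel_manifest, write_slide)


@dataclass
class PipelineConfig:
    output_dir: str = "histofuse_run"
    seed: int = 0
    markers: tuple = ("CD276", "Iba1", "CD163")
    image_size: tuple = (512, 512)
    n_round: int = 40
    n_ramified: int = 15
    n_negative: int = 30
    coloc_fraction: float = 0.5
    coloc_radius: float = 12.0
    section_offsets: dict = field(default_factory=dict)
    stride: int = 10
    thresholds: dict = field(default_factory=dict)
    epochs: int = 25
    learning_rate: float = 2e-3
    batch_size: int = 32
    fusion_search_radius: int = 40
    test_tiles: tuple = (3,)
    augment_copies: int = 1
    enabled_steps: tuple = ("background_subtract", "edge_enhance")
    n_permutations: int = 0

    def __post_init__(self) -> None:
        if self.stride < 1:
            raise ValueError("stride must be >= 1")
        if len(self.markers) < 2:
            raise ValueError("need at least 2 markers")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        data = yaml.safe_load(Path(path).read_text()) or {}
        cfg = cls(**data)
        for key in ("markers", "image_size", "test_tiles", "enabled_steps"):
            setattr(cfg, key, tuple(getattr(cfg, key)))
        return cfg

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(asdict(self)))

    @property
    def workspace(self) -> Path:
        return Path(self.output_dir)


def _panel_config(cfg: PipelineConfig) -> SerialPanelConfig:
    return SerialPanelConfig(
        markers=cfg.markers,
        image_size=tuple(cfg.image_size),
        n_round=cfg.n_round,
        n_ramified=cfg.n_ramified,
        n_negative=cfg.n_negative,
        coloc_fraction=cfg.coloc_fraction,
        coloc_radius=cfg.coloc_radius,
        section_offsets={k: tuple(v) for k, v in cfg.section_offsets.items()},
        stain=StainParams(),
    )


def _preprocess_config(cfg: PipelineConfig, reference: np.ndarray | None = None) -> PreprocessConfig:
    steps = tuple(cfg.enabled_steps)
    ref = ReferenceStats.from_image(reference) if reference is not None else None
    return PreprocessConfig(reference_stats=ref, enabled_steps=steps)


def stage_synth(cfg: PipelineConfig) -> dict:
    """Generate the serial-section panel and write slides + manifest."""
    ws = cfg.workspace / "slides"
    slides, manifest = generate_serial_panel(_panel_config(cfg), cfg.seed)
    paths = {}
    for slide in slides:
        paths[slide.marker] = {
            str(k): str(v) for k, v in write_slide(slide, ws).items()
        }
    manifest["slide_files"] = paths
    write_panel_manifest(manifest, ws / "panel.json")
    return manifest


def _load_slide(cfg: PipelineConfig, marker: str):
    ws = cfg.workspace / "slides"
    manifest = json.loads((ws / "panel.json").read_text())
    files = manifest["slide_files"][marker]
    image = iio.imread(files["image"])
    cells = pd.read_csv(files["cells"])
    return image, cells, manifest


def _slide_from_files(image: np.ndarray, cells: pd.DataFrame, marker: str):
    from .synthetic import CellGroundTruth, SyntheticSlide

    gt = [CellGroundTruth(int(r.x), int(r.y), r.phenotype,
                          float(r.radius_px),
                          0 if r.phenotype != "ramified_positive" else 2,
                          float(r.stain_intensity))
          for r in cells.itertuples()]
    slide_id = str(cells.slide_id.iloc[0]) if len(cells) else marker
    return SyntheticSlide(image=image, cells=gt, marker=marker, seed=0,
                          slide_id=slide_id)


def detector_training_patches(
    n_slides: int = 6,
    slide_size: int = 512,
    counts: dict | None = None,
    marker: str = "Iba1",
    seed: int = 0,
    preprocess: PreprocessConfig | None = None,
) -> list:
    """Labeled bifocal patches for detector training, from several seeded
    synthetic slides.

    Uses the full annotation-sampling policy (jittered positives, ring and
    background negatives) and adds 90-degree-rotated copies of every
    ramified-cell patch: the round-vs-ramified distinction is the hardest
    part of the task and rotation is label-preserving for it.
    """
    from .patches import rotate90
    from .synthetic import generate_slide

    counts = counts or {"round_positive": 40, "ramified_positive": 35,
                        "negative": 25}
    pp = preprocess or PreprocessConfig(
        enabled_steps=("background_subtract", "edge_enhance"))
    patches = []
    for i in range(n_slides):
        slide = generate_slide(slide_size, slide_size, counts, marker,
                               seed=seed + 101 * (i + 1))
        dots = training_dots_from_ground_truth(slide, seed=seed + i)
        ps = extract_dataset(slide.image, dots, pp)
        ram_centers = {(c.x, c.y) for c in slide.cells
                       if c.phenotype == "ramified_positive"}
        for p in list(ps):
            if p.center in ram_centers:
                ps.extend(rotate90(p, k) for k in (1, 2, 3))
        patches.extend(ps)
    return patches


def stage_train(cfg: PipelineConfig) -> TrainedModel:
    """Train the bifocal classifier on the base marker's dot annotations.

    Annotations are split train/test at tile level (the configured test
    tiles are held out); training patches are augmented ``augment_copies``
    times.
    """
    base = cfg.markers[0]
    image, cells, _ = _load_slide(cfg, base)
    slide = _slide_from_files(image, cells, base)
    anns = training_dots_from_ground_truth(slide, seed=cfg.seed)
    h, w = image.shape[:2]
    part = partition_slide(w, h, slide_id=slide.slide_id)
    train_anns, val_anns = split_annotations(anns, part, set(cfg.test_tiles))
    pp = _preprocess_config(cfg)
    train_patches = extract_dataset(image, train_anns, pp)
    val_patches = extract_dataset(image, val_anns, pp)
    augmented = list(train_patches)
    for i, p in enumerate(train_patches):
        for c in range(cfg.augment_copies):
            augmented.append(augment(p, seed=cfg.seed + 7919 * (i + 1) + c))
    clf_cfg = ClassifierConfig(
        epochs=cfg.epochs, learning_rate=cfg.learning_rate,
        batch_size=cfg.batch_size, seed=cfg.seed,
    )
    model = train(augmented, val_patches, clf_cfg)
    out = cfg.workspace / "model"
    out.mkdir(parents=True, exist_ok=True)
    model.save(out / "bifocal_model.npz")
    write_training_log(model, out / "training_log.csv")
    return model


def stage_scan(cfg: PipelineConfig, model: TrainedModel | None = None) -> dict:
    """Scan every marker's slide into a probability heatmap."""
    model_path = cfg.workspace / "model" / "bifocal_model.npz"
    if model is None:
        if not model_path.exists():
            raise FileNotFoundError(
                f"no trained model at {model_path}; run the train stage first")
        model = TrainedModel.load(model_path)
    hm_dir = cfg.workspace / "heatmaps"
    hm_dir.mkdir(parents=True, exist_ok=True)
    pp = _preprocess_config(cfg)
    out = {}
    for marker in cfg.markers:
        image, cells, _ = _load_slide(cfg, marker)
        hm = heatmap_mod.scan(image, model, stride=cfg.stride, preprocess=pp,
                              slide_id=str(cells.slide_id.iloc[0]) if len(cells) else marker,
                              marker=marker)
        if marker in cfg.thresholds:
            hm.threshold = cfg.thresholds[marker]
        heatmap_mod.save_heatmap(hm, hm_dir / f"{marker}.npz")
        iio.imwrite(hm_dir / f"{marker}.png", heatmap_mod.render_heatmap(hm))
        out[marker] = hm
    return out


def _load_heatmaps(cfg: PipelineConfig) -> dict:
    hm_dir = cfg.workspace / "heatmaps"
    return {m: heatmap_mod.load_heatmap(hm_dir / f"{m}.npz") for m in cfg.markers}


def stage_fuse(cfg: PipelineConfig, heatmaps: dict | None = None) -> pd.DataFrame:
    """Register and fuse the base marker against each other marker; write
    the fusion maps and the co-localization summary table."""
    heatmaps = heatmaps or _load_heatmaps(cfg)
    base = cfg.markers[0]
    fz_dir = cfg.workspace / "fusion"
    fz_dir.mkdir(parents=True, exist_ok=True)
    rows = []
    for marker in cfg.markers[1:]:
        tr = fusion_mod.register(heatmaps[base], heatmaps[marker],
                                 search_radius=cfg.fusion_search_radius)
        fm = fusion_mod.fuse(heatmaps[base], heatmaps[marker], tr,
                             thresholds=cfg.thresholds)
        fusion_mod.save_fusion(fm, fz_dir / f"{base}_x_{marker}")
        summary = fusion_mod.summarize(fm, n_permutations=cfg.n_permutations,
                                       seed=cfg.seed)
        rows.append({
            "pair": f"{base}x{marker}",
            "dx_px": tr.dx, "dy_px": tr.dy,
            "registration_score": round(tr.score, 6),
            "n_both": summary.n_both, "n_one": summary.n_one,
            "n_neither": summary.n_neither,
            "coloc_index": ("" if summary.coloc_index is None
                            else round(summary.coloc_index, 6)),
            "permutation_p": ("" if summary.permutation_p is None
                              else round(summary.permutation_p, 6)),
        })
    df = pd.DataFrame(rows)
    df.to_csv(fz_dir / "coloc_summary.csv", index=False)
    return df


def stage_measure(cfg: PipelineConfig, heatmaps: dict | None = None) -> pd.DataFrame:
    """Morphometry of detected cells on every marker's slide."""
    heatmaps = heatmaps or _load_heatmaps(cfg)
    pp = _preprocess_config(cfg)
    tables = []
    for marker in cfg.markers:
        image, cells, _ = _load_slide(cfg, marker)
        processed = preprocess_image(image, pp)
        detections = heatmap_mod.detect_cells(heatmaps[marker])
        table = morphometry.measure_detections(
            processed, detections,
            slide_id=str(cells.slide_id.iloc[0]) if len(cells) else marker,
            marker=marker)
        tables.append(table)
    features = pd.concat(tables, ignore_index=True)
    out = cfg.workspace / "features"
    out.mkdir(parents=True, exist_ok=True)
    features.to_csv(out / "features.csv", index=False,
                    float_format="%.4f")
    summary = (features.groupby(["slide_id", "marker"], sort=True)
               [["area_px2", "perimeter_px", "compactness", "min_intensity"]]
               .mean().round(4).reset_index())
    summary.insert(2, "n_cells",
                   features.groupby(["slide_id", "marker"], sort=True)
                   .size().values)
    summary.to_csv(out / "features_summary.csv", index=False,
                   float_format="%.4f")
    return features


def run_pipeline(cfg: PipelineConfig) -> dict:
    """Run all stages and write a JSON run report (seeds, timings, outputs)."""
    ws = cfg.workspace
    ws.mkdir(parents=True, exist_ok=True)
    report: dict = {"seed": cfg.seed, "config": asdict(cfg), "stages": {}}

    def timed(name, fn, *args):
        t0 = time.perf_counter()
        try:
            result = fn(*args)
        except Exception as exc:
            raise RuntimeError(f"pipeline stage {name!r} failed: {exc}") from exc
        report["stages"][name] = {"seconds": round(time.perf_counter() - t0, 3)}
        return result

    timed("synth", stage_synth, cfg)
    model = timed("train", stage_train, cfg)
    heatmaps = timed("scan", stage_scan, cfg, model)
    timed("fuse", stage_fuse, cfg, heatmaps)
    timed("measure", stage_measure, cfg, heatmaps)
    report["outputs"] = {
        "heatmaps": [str(ws / "heatmaps" / f"{m}.npz") for m in cfg.markers],
        "fusion_maps": [str(ws / "fusion" / f"{cfg.markers[0]}_x_{m}.npz")
                        for m in cfg.markers[1:]],
        "coloc_summary": str(ws / "fusion" / "coloc_summary.csv"),
        "features": str(ws / "features" / "features.csv"),
        "features_summary": str(ws / "features" / "features_summary.csv"),
    }
    (ws / "report.json").write_text(json.dumps(report, indent=2))
    return report
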