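# histofuse

AI-assisted co-localization mapping of immunohistochemical cell phenotypes
on whole-slide images.

Glioma tissue contains several kinds of macrophage-like cells that a single
stain cannot separate: resident microglia that have rounded up into
macrophage-like cells (Iba1⁺), recently blood-derived macrophages (CD163⁺),
and — on a third adjacent section — CD276(B7-H3)-high tumor stem-like
cells. Asking *where these populations sit relative to each other* requires
(1) detecting a specific **morphological** phenotype per marker (e.g. round
macrophage-like Iba1⁺ cells while ignoring ramified ones), and (2)
comparing detections **across adjacent serial sections** that are not
spatially aligned. `histofuse` implements that pipeline end to end for
researchers working with scanned IHC sections, plus a seeded synthetic
slide generator with exact ground truth so every stage is testable without
clinical material.

## Method

- **Bifocal patch classifier.** Each annotated coordinate ("red dot" =
  cell of interest, "blue dot" = excluded cell/tissue) yields a 32×32 px
  cell-scale crop nested in a 64×64 px context crop. Two convolutional
  pathways (3 conv blocks each, 16→32→64 channels) end in global average
  pooling; the GAP vectors are concatenated into a dense head producing the
  positive-class probability ȳ, trained with cross-entropy. A threshold
  function T (ȳ ≥ T → positive) makes the call.
- **Whole-slide heatmaps.** Slides are scanned at a 10 px stride into a
  probability grid; detections are one probability-weighted centroid per
  supra-threshold connected component.
- **Registration + fusion.** Two sections' binarized grids are registered
  by exhaustively minimizing the translation cost matrix E (mean squared
  grid difference over the overlap), then fused per grid cell: both
  markers present → red, exactly one → white, neither → turquoise. A
  co-localization index n_both/(n_both+n_one) and an optional
  toroidal-permutation p-value quantify the overlap.
- **Morphometry.** Detected cells are segmented (Otsu + contour tracing)
  and measured: area (shoelace), perimeter, compactness 4πA/P², minimum
  interior intensity, with per-slide means.

See `docs/methods.md` for assumptions, parameter defaults and limitations.

## Worked example

```python
import numpy as np
import histofuse as hf
from histofuse.patches import PreprocessConfig
from histofuse.pipeline import detector_training_patches
from histofuse.synthetic import SerialPanelConfig, generate_serial_panel
from histofuse.fusion import register, fuse, summarize

pp = PreprocessConfig(enabled_steps=("background_subtract", "edge_enhance"))
patches = detector_training_patches(n_slides=4, seed=0, preprocess=pp)
idx = np.random.default_rng(0).permutation(len(patches))
model = hf.train([patches[i] for i in idx[:800]],
                 [patches[i] for i in idx[800:1000]],
                 hf.ClassifierConfig(epochs=15, seed=0))
print("held-out accuracy:", round(model.training_log[-1]["val_accuracy"], 3))

panel = SerialPanelConfig(markers=("CD276", "Iba1"), image_size=(512, 512),
                          n_round=40, n_ramified=15, n_negative=20,
                          coloc_fraction=0.8, section_offsets={"Iba1": (15, -9)})
slides, manifest = generate_serial_panel(panel, seed=7)
hm = {s.marker: hf.scan(s.image, model, stride=10, preprocess=pp,
                        marker=s.marker) for s in slides}
tr = register(hm["CD276"], hm["Iba1"], search_radius=40)
print(f"registered offset: ({tr.dx:+.0f}, {tr.dy:+.0f}) px  (planted (+15, -9))")
fm = fuse(hm["CD276"], hm["Iba1"], tr)
s = summarize(fm, n_permutations=99, seed=1)
print(f"counts: both={s.n_both} one={s.n_one} neither={s.n_neither}")
print(f"coloc_index={s.coloc_index:.3f}  permutation_p={s.permutation_p:.3f}")
```

prints

```
held-out accuracy: 0.955
registered offset: (+10, -10) px  (planted (+15, -9))
counts: both=47 one=221 neither=2333
coloc_index=0.175  permutation_p=0.010
```

Reading the output: the patch classifier separates round stained cells
from ramified and unstained ones at 95.5% on held-out dots; registration
recovers the planted serial-section shift to within one grid cell
(10 px); 47 grid cells carry detections of both markers against 221
carried by exactly one, and the permutation test (99 toroidal shifts of
the second map) puts that overlap well above chance (p = 0.01).

The same stages are available as a CLI — one verb per stage, driven by a
YAML config:

```bash
histofuse synth --out run --seed 7     # synthetic serial panel + ground truth
histofuse train --out run              # train the bifocal classifier
histofuse scan  --out run              # per-marker probability heatmaps
histofuse fuse  --out run              # register + fuse + coloc summary
histofuse measure --out run            # per-cell morphometry tables
histofuse cases                        # cohort manifest bookkeeping
```

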