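# Methods

`histofuse` detects a user-defined morphological cell phenotype per
immunohistochemical (IHC) marker on whole-slide images, maps the detections
as probability heatmaps, registers heatmaps from adjacent serial sections,
fuses them into a categorical co-localization map, and quantifies the
detected cells morphometrically. This note records the model, the choices
made where the design was genuinely open, and what the synthetic benchmark
does and does not establish.

## The detection model

Cells are annotated as dots: red dots on cells of interest, blue dots on
unlabeled cells or tissue to exclude. Around each dot a *bifocal* patch
pair is extracted — a 32×32 px inner crop carrying cell-scale detail and a
64×64 px outer crop carrying tissue context. The 64×64 window spans
[x−32, x+32) × [y−32, y+32), so the annotated pixel sits at index (32, 32)
of the outer crop; the inner crop is always the central 32×32 of the outer
one, an invariant preserved by construction through every transform.
Borders are reflection-padded, so every slide pixel can be a window center.

The classifier runs two convolutional pathways, one per crop. Each pathway
is three 3×3 conv + ReLU blocks with 16→32→64 channels, ending in global
average pooling (GAP); the two 64-dimensional GAP vectors are concatenated
and passed to a dense head (128→32→2). The inner pathway's first block uses
stride 1 (the ramified phenotype's 1–2 px processes do not survive an
immediate 2× downsampling); all other conv blocks use stride 2. Training
minimizes 2-class cross-entropy with Adam (fixed learning rate 2·10⁻³,
batch 32, 25 epochs by default) and is exhaustively seeded: weight
initialization and batch shuffling derive from a single seed, so a rerun
reproduces the model bit for bit on a single CPU thread. The network layers
(im2col convolution, GAP, dense, softmax cross-entropy, Adam) are
implemented in numpy with explicit backward passes; the stack is small
enough that a framework would add more surface than it removes.

The positive-class probability ȳ is thresholded by T (``ȳ ≥ T`` is
positive). T defaults to 0.5 and is configurable per marker; the pipeline
can also calibrate T automatically by maximizing detection F1 on a
validation slide with known cell positions.

## Preprocessing and augmentation

Three optional steps run in a fixed order on whole slides before patch
extraction:

- **Color normalization** — Reinhard-style statistics transfer: per-channel
  mean/std in CIELAB matched to a reference slide. Stain deconvolution was
  deliberately avoided; statistics transfer satisfies the same purpose
  (cross-slide stain comparability) with fewer assumptions and is swappable
  behind `PreprocessConfig`.
- **Background subtraction** — a large-σ Gaussian estimate of the
  low-frequency background (default σ = 24 px) is removed and the image
  re-centered at its global mean.
- **Edge enhancement** — unsharp masking with amount 0.6 by default;
  amount 0 is the identity.

Training-time augmentation applies a seeded combination of rotation
(multiples of 90°, avoiding interpolation artifacts at 32 px scale),
contrast scaling (0.8–1.2) and sharpness adjustment (0.5–1.5). The outer
crop is transformed and the inner crop re-sliced from it, so the nesting
invariant survives augmentation.

## Training-dot sampling

A detector scanning at a 10 px stride sees windows the annotator never
clicked: empty tissue, windows a few pixels off a cell center, and windows
halfway between cells. The training-dot policy therefore samples, per
slide: the center dots themselves; one positive dot jittered ≤ 5 px per
positive cell (windows are up to half a stride off-center); two negative
dots per positive at 15–25 px (so near-misses score low and each cell
yields one sharp probability blob rather than a broad plateau); one
jittered negative per non-target cell; and ~30 negative dots on empty
tissue. Ramified-cell patches additionally get 90°-rotated copies — the
round-vs-ramified boundary is the hardest part of the task and rotation is
label-preserving for it.

## Scanning and detection

Slides are scanned at a 10 px stride: window centers start at pixel 0 and
step by the stride, giving a grid of ⌊(dim−1)/stride⌋+1 positions per axis
(a 512×512 slide at stride 10 yields 52×52). The scan is processed in
fixed-size batches of grid rows over a single reflect-padded copy of the
slide, which bounds memory for arbitrarily large slides without any effect
on the output. Heatmaps are persisted as raw float grids plus metadata;
renderings (red detections on turquoise background, monotone color ramp
with its midpoint at T) are derived views.

Detected cells are the probability-weighted centroids of the connected
components of the thresholded grid — one detection per supra-threshold
blob. Raw local maxima were rejected: saturated probabilities produce
plateaus of exact ties and hence duplicate maxima 1–2 grid cells apart.
The limitation is the mirror case: two true cells closer than about two
strides can merge into one component and are then counted once.

## Registration and fusion

Adjacent serial sections are registered by exhaustive integer-grid
translation search: the cost matrix E(dx, dy) is the mean squared
difference between the two binarized grids over their overlap, evaluated
over ±(search radius) and minimized; ties break toward the smallest
|dx|+|dy|, then lexicographically. Translation-only is the minimal model
for low-resolution heatmap alignment of adjacent sections; failure is
visible in the reported cost at optimum. Rotation/deformation are out of
scope.

Fusion is categorical on the registered overlap of the thresholded grids:
both markers positive → *both* (rendered red), exactly one → *one*
(white), neither → *neither* (turquoise). The per-side breakdown of *one*
(A-only vs B-only) is kept in the counts metadata. The co-localization
summary adds `coloc_index = n_both / (n_both + n_one)` (absent, not 0,
when the denominator vanishes) and an optional permutation p-value: the B
mask is toroidally shifted by uniform random offsets, preserving both
densities and within-section spatial structure while destroying
cross-alignment, and the one-sided rank p-value is reported with the +1
correction. The summary layer never alters the fusion map.

## Morphometry

Post-detection quantification crops a window around each accepted
detection, Otsu-thresholds the inverted luminance (stained cells become
bright foreground), traces one closed contour per connected component
(holes filled first and recorded; border-touching components kept and
flagged), and measures: area by the shoelace formula on the traced
polygon, perimeter as polygonal arc length, compactness as the
isoperimetric ratio 4πA/P² (1 for a circle; rasterization can push convex
shapes slightly above 1, tolerated up to 1.1), and minimum interior pixel
intensity on the preprocessed luminance channel (a recorded choice — the
original work does not state which channel it used). Per-slide,
per-marker arithmetic means summarize each population.

## The synthetic benchmark

The generator renders what the method needs to be sensitive to and nothing
more: DAB-brown discs (round macrophage-like positives, radius 5–9 px),
the same discs with 2–5 thin anti-aliased processes of length 2–4× radius
(ramified cells), faint blue blobs (unstained cells), all with
multiplicative Gaussian texture on a pale hematoxylin-like background,
placed by rejection sampling with non-overlap enforced (1000 attempts per
cell, deterministic failure naming the count achieved). Serial-section
panels plant a controllable co-localization fraction — each base-section
positive gets a partner within a set radius on the other section with that
probability — and a known rigid offset per section; the realized fraction
is written to the manifest. Everything is bit-reproducible from (config,
seed).

What passing the benchmark shows: the full chain (annotation → training →
scanning → registration → fusion → morphometry) recovers planted truth —
offsets to within one stride, co-localization ordering across generating
fractions, ≥ 90% of planted round cells with ≤ 10% spurious detections.
What it does not show: robustness to real-slide phenomena the generator
deliberately omits — stain batch variation, tissue folds, necrosis,
overlapping and touching cells, scanner optics, or genuinely ambiguous
morphologies. Performance numbers on synthetic panels are upper bounds,
not estimates, for clinical material.

## Problem sizes and numerical choices

Tests and the acceptance script use 512×512 training slides (≈100 cells
each, six slides → ≈2400 training dots), a 1024×1024 detection slide with
65 cells, 300-cell panels for co-localization recovery, and a 384×384
three-marker panel for the byte-identity rerun check — sizes chosen so the
whole battery runs on one CPU core in minutes while every estimate stays
comfortably away from its decision boundary. Probabilities are float32;
grids float64; ties in registration break deterministically as stated
above; a constant image yields an empty mask with a warning rather than an
exception throughout.
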