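# Methods

## The problem

Splenic filtration removes pits (membrane-bound vacuoles of cellular
waste) from circulating red blood cells. Under DIC microscopy pits look
like craters on the cell surface, and the fraction of cells carrying at
least one pit (%PIT) tracks splenic function: published rules call
%PIT ≥ 3.5 loss of function (Rogers) and, more recently, < 1.2 normal /
> 4.5 absent with an indeterminate band between (El Hoss). The package
implements the automated counting workflow end to end: pixel
classification of DIC images into background / cell / pit, macro-style
object filtering, %PIT and pit morphometrics, and the agreement
statistics used to compare automated with manual counts.

No public image corpus accompanies this workflow, so the package is
validated entirely on a synthetic scene generator with exhaustive ground
truth. Everything below is therefore stated twice: what the model
assumes, and what that implies about the evidence the tests provide.

## Scene model (simulate)

**Cells.** Digital discs with radius drawn uniformly from
`cell_radius_um_range` (default 2.7–3.4 µm, i.e. areas 22.9–36.3 µm²,
comfortably inside the default 20–80 µm² RBC size gate). The surface
height profile is a normalised biconcave (Evans–Fung style) thickness
function with amplitude 1 µm: higher at the rim, dimpled at the centre.
Cells are placed uniformly at random without mask overlap and with a
≥ 1 px clearance ring; a configurable fraction of cells
(`touching_fraction`, default 0.10) is instead placed tangent to an
already-placed cell — masks adjacent, never overlapping — to exercise
watershed separation. Placement failure after bounded retries raises an
explicit error naming the achievable density. All objects are placed
fully inside the frame; edge-touching cells do occur in real images but
are excluded by the macro anyway, so the generator does not produce
them.

**Pits.** A cell is pitted with probability `pitted_fraction`; a pitted
cell carries `1 + Poisson(pits_per_pitted_cell_mean − 1)` pits. Each pit
is a hemispherical crater subtracted from the height map, radius uniform
in `pit_radius_um_range` (default 0.35–0.60 µm, floored at 1.1 px so a
pit always covers at least one pixel centre), centre at least one pit
radius plus ~1.5 px inside the rim, and pits within a cell are kept
mutually non-adjacent so connected-component counting reproduces the
stored per-cell counts exactly. The default pit radii give pit areas of
roughly 1–5% of the cell — larger than the 0.21–0.76% mean pit sizes
measured on real samples — because a desk-scale grid needs pits several
pixels wide to be segmentable at all; consequences for interpretation
are listed under Limitations.

**Artefacts** (Poisson counts per scene via `artefact_rates`), chosen to
reproduce the documented failure modes of the real workflow:

| class | geometry | intended failure mode |
|---|---|---|
| platelet on cell | small high-relief dome (r 0.8–1.3 µm) tangent to an RBC | false pit on an otherwise normal cell |
| platelet aggregate | 2–4 fused overlapping domes | pit-bearing "cell" with low solidity |
| WBC | large textured dome (r 5.2–6.5 µm) | oversized object, caught by the size gate |
| wrinkled cell | RBC profile + sinusoidal ridges | false pits from surface texture |
| debris | tiny bump (r 0.25–0.5 µm) abutting an RBC | merged mask, lowered solidity |

In the truth label map every artefact pixel is coded *cell*: artefacts
are cellular material that the pixel classifier legitimately sees as
cells and that the macro, not the classifier, must reject by size, edge
or solidity. Truth statistics (`scene_truth_stats`) are computed over
rbc-class objects only, so the true %PIT is unaffected by artefacts.

**Rendering.** DIC contrast is emulated as the directional derivative of
the height map along the shear axis plus a mid-grey bias:
`I = 0.5 + gain · ∂h/∂s`, followed by isotropic Gaussian defocus
(`defocus_sigma_px`, default 1.0) and additive Gaussian noise
(`noise_sigma`, default 0.02), clipped to [0, 1]. The gain is calibrated
deterministically from the analytic profile of a mean-radius cell so
that the rim relief spans ≈ 0.3 intensity units. This reproduces the
shadow-cast relief appearance the classifier must learn; it is *not* a
physical Nomarski model (no polarisation, no bias retardation, no
coherent effects) — a deliberate non-goal.

Identical (config, seed) reproduces scenes, renders and statistics
bit-identically; all randomness flows from `SceneConfig.seed` through
two fixed substreams (sampling, rendering noise).

## Pixel classification (segment)

A classical multi-scale filter bank feeds a random forest, in the
ilastik / trainable-WEKA tradition. Features per Gaussian scale
(defaults 1, 2, 4, 8 px): smoothed intensity, gradient magnitude,
Laplacian, both Hessian eigenvalues, and local variance — 24 planes by
default, computed with reflective boundaries so prediction commutes with
image mirroring. The forest (default 100 trees, depth ≤ 20, seeded,
single-threaded) is trained on a stratified per-class, per-image pixel
sample (default cap 10 000 px/class/image) — the simple, exactly
reproducible answer to class imbalance, since pit pixels are rare. A
fifth of the sampled pixels per class is held out and the per-class
held-out accuracy stored in the fitted model's metadata. Prediction is
argmax of the forest's class posteriors; ties break toward the lower
class code (background < cell < pit), a fixed documented order.

`PixelClassifier` is a scikit-learn estimator (`fit` / `predict` /
`predict_proba`, `get_params`, underscore-suffixed fitted attributes),
so it composes with sklearn tooling; module-level `train_classifier` /
`predict_labels` are thin wrappers.

Out-of-focus degradation gets no special handling: the simulator's
defocus parameter exists precisely to characterise how performance
decays as blur grows.

As package acceptance constants (not literature values): on simulator
scenes at default noise the held-out cell-class IoU is required to be
≥ 0.85 and the pit-class IoU ≥ 0.4 — pit pixels are rare, small, and
partially blurred, so pixel-level pit IoU is intrinsically modest even
when cell-level pit *counts* are accurate.

## Macro-style postprocessing

Mirrors the classic ImageJ treatment of the three-channel segmentation:

- **split channels** — pit pixels are part of their cell, so the cell
  mask is the union of cell and pit codes (pits never read as holes).
- **fill holes** — background components not connected to the border.
- **separate cells** — Euclidean distance transform; peaks suppressed by
  depth `watershed_h` (default 3 px, h-maxima reconstruction); watershed
  of the inverted distance map seeded at the surviving peaks, restricted
  to the mask. Components whose peaks were all suppressed are seeded at
  their distance argmax so every foreground pixel receives exactly one
  label; seed labelling is raster-ordered, so output is deterministic.
- **measure** — per instance: pixel area → µm² via `pixel_size_um²`;
  solidity computed on the digital grid as pixel count over the number
  of pixel centres inside (tolerance 1e-9) the convex hull of the
  region's pixel centres (collinear regions have solidity 1); centroid;
  edge contact; pits as connected components (default 8-connectivity) of
  the pit mask within the instance with at least `min_pit_area_px`
  (default 4) pixels.
- **filter** — statuses assigned with precedence size → edge → solidity:
  area outside 20–80 µm², any pixel on the image border, or solidity
  < 0.90. Records are flagged, never deleted, and excluded records keep
  their measurements. The solidity threshold is a package default (the
  original macro's constant was never published); the tests assert the
  *direction* of its effect — on control scenes with platelet aggregates
  the filter must not increase %PIT — rather than any particular value.

Counting pit "maxima" is implemented as connected-component counting of
the binary pit mask within each cell; an intensity-maxima variant with a
noise tolerance would be a faithful alternative reading and is left as
an extension.

## Sample metrics and diagnosis

The %PIT denominator is the *included* cells only; excluded-by-any-gate
cells are tallied but never counted. A cell is pitted iff it has ≥ 1
accepted pit component. `sufficient_count` flags samples below the
configured minimum (default 500 cells, the manual-count convention).
Undefined quantities (empty denominators) are explicit `None` markers,
never NaNs, and classification of an undefined %PIT raises.

"Average pit size" is averaged **per pit** (each pit contributes its own
area as a percentage of its cell's area); a `per_cell` switch first
averages within each pitted cell. Both readings are defensible; per-pit
is the default and the one reported.

Diagnostic boundaries sit exactly where the printed inequalities put
them (≥ 3.5; < 1.2; > 4.5) with no epsilon fuzzing; the grid-sweep
acceptance check recovers 3.5 / 1.2 / 4.5 from the implementation.

## Agreement statistics

Differences are fixed as automated − manual. Bias is the mean
difference, LOAs are bias ± 1.96·sd (sample sd, n−1). The bias CI uses
t(n−1) with standard error sd/√n; each LOA CI uses the classical
approximation sd·√(3/n) with t(n−1) — the variant standard BA tooling
reports; the exact-variance alternative is noted but not implemented.
Zero-variance inputs yield degenerate width-0 CIs rather than errors.
The stratified acceptance rule asks both LOAs to lie within ±5 %PIT
overall and within ±1.5 for the stratum of samples with manual
%PIT < 5%; the caller subsets the pairs for the low stratum. Paired t
and Pearson r follow the textbook formulas with scipy's t distribution
supplying p-values; degenerate inputs (zero variance, constant vectors)
raise named errors.

## Problem sizes and numerical choices

The test and demonstration scenes use a 0.15 µm/px grid (512–600 px
frames, 8–50 cells) rather than the 0.065 µm/px default sampling, which
keeps a 50-cell scene within a 600×600 frame; the end-to-end recovery
check trains on 6 scenes and counts 6 held-out scenes of 50 cells
(300 cells pooled) at true pitted fraction 0.30 and default
noise/defocus, requiring the pooled automated %PIT within ±3 percentage
points of truth. The paired-t calibration uses 5000 null replicates of
n = 20. Statistical oracle comparisons are at 1e-10 (formula oracles)
and 1e-9 (solidity vs convex-hull oracle). Seeds are fixed constants
throughout; reruns are byte-identical.

## What passing tests do and do not show

The simulator emulates geometry, relief contrast, focus and noise, and
the documented artefact classes. It does **not** emulate: real DIC
optics (so the classifier's absolute accuracy on real micrographs is
unknown), stain/fixation variability, cell crowding beyond tangent
pairs, overlapping cells, pit size distributions at the small end of the
real range, or out-of-focus fields beyond a single isotropic blur.
Passing tests therefore demonstrate that the *pipeline logic* is correct
(exact truth passthrough, filter directions, statistic formulas) and
that the classifier can learn the pit/cell/background contrast the
renderer produces — not that a forest trained on synthetic scenes
transfers to a microscope. For real use, the classifier is retrained on
annotated real images through the same `fit` interface; the published
normal ranges may also need re-evaluation for automated counts, which is
why the thresholds are implemented verbatim rather than refitted.

## Open design points, resolved

- Pixel classifier: the commercial pretrained-CNN + forest stack is
  replaced by a filter bank + forest with the same contract
  (pixel → three classes); a CNN front end is an extension point.
- Automated counting measures *all* qualifying cells per image; it does
  not re-enact the "500 consecutive cells" manual protocol (the minimum
  count flag covers sufficiency instead).
- The %PIT denominator excludes cells removed by any gate, including
  solidity.
- Scene defaults (radii, rates, noise) were chosen once from the
  physiology (6–8 µm discs, sub-micron pits) and desk-scale legibility;
  they are configuration, not fitted constants.
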