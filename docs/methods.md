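# Methods

This note documents the models and procedures `pigadapt` implements, the
parameters that matter, the synthetic data the tests run on, and the
numerical choices made where the design was genuinely open.

## Problem setting

A detector trained on *source* pens (top-view cameras, daytime
illumination, various resolutions) is deployed on a *target* pen (here:
tilted view, infrared night footage, different resolution). The
distribution shift degrades detection badly. The pipeline adapts using
only (i) the unlabeled monitoring video of the target pen and (ii) one
manually annotated target frame.

## Key-frame selection and SLOT choice

Each frame is converted to grayscale (ITU-R BT.601 luma for RGB input)
and histogrammed over the 256 8-bit intensity levels. The frame's
normalized entropy is `e = −Σ p(l) log2 p(l) / 8 ∈ [0, 1]` (0·log 0 := 0;
8 bits is the maximum for 256 bins). A `raw_bits` mode skips the
normalization.

Key frames follow a sticky-reference rule: frame 0 is always stored and
initializes the reference; frame *i* is stored iff `|e_i − e_ref| ≥ τ_ent`,
and the reference moves to `e_i` only on storage. The comparison is
inclusive, so `τ_ent = 0` degenerates to keeping every frame — a useful
testing mode. Default `τ_ent = 0.05` on the normalized scale.

The SLOT frame is the stored frame with maximum entropy (ties to the
earliest). Entropy grows with the number of visible animals — a crowded
scene is both the most informative to annotate and the most representative
of the pen.

Caveat: the normalized scale and the 0.05 threshold interact. Entropy
differences between frames of a static pen are small; the threshold only
fires on real scene changes (animals entering/leaving, lighting
transitions). Both the normalization and the threshold are configuration
knobs.

## Background model

The animal-free pen background is the per-pixel cumulative moving average
of the video, computed as a streaming running mean in double precision
(`mean += (frame − mean)/n`), so arbitrarily long sequences never need to
be stacked; the result equals the batch mean to ≤1e-9. Output is kept
real-valued and quantized (round-half-even) only when exported as PNG.

## Copy-and-paste evaluation data

Object patches are cropped from the SLOT frame at its annotated boxes and
pasted onto the CMA background at uniform random positions; the object
count per image is uniform over a configured range (default 5–30, typical
pen occupancy) and a placement is rejected while its IoU with any placed
box exceeds 0.3 (≤200 attempts, then the object is skipped). Compositing
defaults to *polygon* mode: the patch is blended through a mask —
rasterized polygon labels when available, else the box's inscribed
ellipse, since pigs are roughly elliptical and the ellipse removes
rectangular paste seams. Plain-rectangle (`bbox`) mode is kept for
ablation. The default evaluation set holds 100 images; it is generated
through a path disjoint from any augmented training image, so the search
cannot overfit its own fitness data.

## The augmentation policy and its search

A policy (chromosome) has eight genes: `n_image` (10–500 augmented
copies), zoom-in and zoom-out probabilities (0–0.5, step 0.1) and
magnitudes (zoom-in 1.2–1.9, zoom-out 0.2–0.9, step 0.1), a per-object
transform flag (original / translateX / translateY / rotate / shear /
flipH / flipV), its probability (0.1–1.0) and magnitude (integer 1–8).
`p_original = 1 − p_zoom_in − p_zoom_out` is derived, never searched.
Flag constraints: flag 0 fixes probability and magnitude to 1; flips fix
the magnitude to 1. The space holds exactly
`491·6·6·8·8·(10·(4·8+2)+1) = 385,761,024` valid policies.

Frame-level zoom-in scales about the image center and crops back; a box
keeping less than 25% of its scaled area is dropped (the threshold is a
design choice — partially cropped objects are kept while they remain
learnable). Zoom-out letterboxes the shrunken frame centered on a canvas
filled with the per-image mean intensity. Per-object transforms crop the
object's patch, fill the vacancy from the background model (edge-ring
mean when no background is available), transform and re-composite. The
magnitude mapping is linear: translate shifts `round(0.05·m·extent)` px,
rotation is `3.75°·m` (30° at m=8), shear factor `0.04·m` (0.32 at m=8);
these follow the convention of magnitude-indexed augmentation search
spaces, calibrated so m=8 stays plausible for animal shapes. Per image,
one frame op is drawn from {zoom-in, zoom-out, original}; the flagged
transform is then applied to each object independently with its
probability.

The GA evaluates the random initial population as generation 1. Each
later generation is produced entirely by 10 one-point crossovers (cut
uniform over the 7 internal boundaries) of uniformly drawn elite parents
plus 10 single-gene mutations of uniformly drawn elite members, repaired
to satisfy flag constraints. The elite is the top-K of *everything*
evaluated so far (ties to earlier evaluation), which makes elitism
implicit; the search result is the argmax over the full log. Fitness
results are cached by the gene tuple — the GA revisits chromosomes and
detector training is the cost center. Defaults G=3, K=20 give exactly 60
fitness evaluations; with early stopping disabled at 30 epochs each,
exactly 1800 training epochs.

## Detection metric

11-point interpolated AP at IoU 0.5 (the classic VOC convention), with
greedy score-descending one-to-one matching; score ties break by input
order, IoU ties by lowest ground-truth index. AP is kept in [0, 1]
internally and printed as a percentage with two decimals. Dataset-level
AP merges per-image match results into one score-ordered list before
interpolating.

## The reference detector

A deliberately simple, fully deterministic CPU detector makes every
pipeline stage executable and testable: prediction thresholds
`|image − background| ≥ θ`, extracts 8-connected components, drops those
below `min_area` (default 50 px², lowered to 30 px² in the desk-scale
pipeline where the smallest far-side animals approach that size) and
scores each box by its mean normalized difference.

Training has honest epoch semantics so that early stopping and
continued training are meaningful:

* The background layer is fitted per image shape. A shape seen for the
  first time gets the per-pixel **median** of its training images —
  robust to the animals present in every frame. A background injected at
  construction (the pen's CMA background) is pinned and never
  re-estimated, and already-fitted shapes are kept on continued-training
  calls, like converged early layers of a network.
* Each epoch evaluates one θ candidate. A fresh model follows a dyadic
  coarse-to-fine schedule over [0, 255] (128; 64, 192; 32, 96, 160, 224;
  …), so successive epochs genuinely refine the resolution of the search
  and a validation plateau is a meaningful stopping signal. Continued
  training instead probes symmetric offsets around the current θ
  (±10, ±5, ±2, ±1, then growing radii), starting with the incumbent.
* The retained θ maximizes AP on a deterministic 80/20 train split;
  validation loss is `1 − AP` on the held-out split, and training stops
  when it fails to improve for `patience` consecutive epochs.
* Improvements smaller than `MIN_DELTA = 1e-3` AP are treated as ties:
  a challenger θ must beat the incumbent by a material margin, and
  negligible validation changes do not reset patience. Without this,
  continued training hops between θ values along wide AP plateaus, making
  before/after comparisons depend on ±1e-4 noise.

The detector state (θ, min_area, backgrounds) serializes to npz.
Anything satisfying the two-method contract can replace it; the contract
is exercised in the tests with a scripted mock.

## Self-training with data distillation

Each iteration regenerates pseudo-labels for every unlabeled key frame
with the *current* model: predictions on five views (identity, flipH,
flipV, flipHV, rot90 — clockwise by default, direction configurable) are
back-mapped through exact inverse box maps, pooled, and merged with
greedy NMS at IoU 0.5; each surviving box keeps its own (maximum) score.
Boxes with score ≥ τ_conf (inclusive) become hard labels; frames with no
surviving box stay in the set with empty labels. The same model state
then continues training on source ∪ SLOT ∪ pseudo for 5 epochs, for 5
iterations. `τ_conf = 0.01` by default — the super-low-threshold strategy:
after the augmentation-search stage the base model's weak detections are
predominantly real animals, and volume beats purity.

For the one-parameter reference detector, self-training converges to a
fixed point at the base model's threshold: the pseudo-labels are
generated by the model itself, so the training signal is self-consistent
and θ moves only when the mixed data genuinely prefer another value by
more than the tie margin. The expected desk-scale outcome is therefore
*parity or better* with the base model, while a gradient-trained deep
detector would continue to extract signal from pseudo-label volume.

## Synthetic data

The generator emulates infrared pen footage with controllable primitives,
not photorealism: a Gaussian-smoothed textured background (amplitude 5
gray levels) and bright soft-shaded elliptical blobs for pigs (semi-axes
5–8 × 8–12 px, contrast 80–140 above background). Domains:

* **source**: top view, day (background level 60), 160×160 px;
* **target**: tilted view, night, 192×192 px. The tilt scales objects
  linearly from 0.65× at the image top to 1× at the bottom; night
  multiplies background level and contrast by 0.8. The differing
  resolutions mirror real multi-farm datasets and exercise the detector's
  per-shape background handling.

Object counts are uniform in 5–30 per scene with a pairwise box-IoU cap
of 0.2 (relaxed after 200 rejections — pigs do pile up). Videos hold
objects persistent across frames; each moves with probability 0.2 per
frame (pigs rest ~80% of the time), the visible count tracks a slow
activity cycle across the configured range (animals enter and leave), and
illumination follows the same cycles with a gain dipping to 0.75. The
count and gain cycles are what give the entropy series realistic swings
for key-frame selection: crowded bright scenes sit ~0.1 above sparse dim
ones on the normalized entropy scale.

What passing tests on this generator do **not** show: robustness to
occlusion beyond ellipse overlap, to textured animals, to camera motion,
or to the pseudo-label noise regimes of deep detectors on real footage.
The generator validates the pipeline's logic and direction of effects,
not absolute AP levels.

## Desk-scale experiment

`run_experiment` wires everything together: 20 source scenes; a 480-frame
target video (6 activity/illumination cycles); 25 evenly spaced video
frames held out as the annotated benchmark (they never enter the
unlabeled pool, matching the protocol of annotating target key frames for
evaluation only); key-frame selection at τ_ent = 0.05 yields ~13–25
unlabeled frames plus the SLOT frame; the copy-paste evaluation set holds
100 images; the search uses the full G=3/K=20 budget over a miniature
space (`n_image` capped at 60 so 60 reference-detector trainings stay in
seconds). Adaptation-stage detectors receive the video's CMA background;
the source-only baseline has no access to target footage and estimates
its own. Typical results (seeds 1–11): source-only ≈ 14 AP, base ≈ 61–71
AP, self-trained equal or marginally above base — a ~50-point adaptation
gain from one annotated frame.

## Known limitations

* The reference detector cannot separate touching animals (8-connected
  components merge), which caps its AP well below a deep detector's; all
  cross-stage comparisons are directional, not absolute.
* A single global θ must serve all domains in the training mix; the
  per-shape background layer absorbs most of the cross-domain variation,
  but same-resolution multi-domain mixtures would strain it.
* YOLO-txt output at the default 6 decimals quantizes normalized
  coordinates at 5e-7 of the image size; round trips below 1e-6 px need
  `precision=12`.
* Video decoding depends on the imageio plugins available; frame
  directories are the tested path.
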