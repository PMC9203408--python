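# Methods

## The measurement problem

Sleep bruxism (SB) — grinding and clenching of the teeth during sleep — is
definitively diagnosed with polysomnography (PSG), which is expensive and
hard to scale. A cheaper proxy is a 0.5-mm thermoformed diagnostic sheet
built from five coloured layers (outermost first: white, blue, yellow, red,
green) worn over the maxillary arch at night. Grinding abrades the white
surface; the deeper the wear, the deeper the exposed colour. A calibrated
photograph of the worn sheet therefore encodes both the extent and the
depth of abrasive SB activity.

`bruxwear` implements the full chain: image → per-layer abrasion masks →
weighted **pixel score**; EMG burst events → rhythmic masticatory muscle
activity (RMMA) episodes → the PSG reference diagnosis; and cohort-level
validation of score against diagnosis (ROC, Youden cut-off, predictive
values, effect size, power).

## Image pipeline

Stages, in order (all tunables live in `PipelineParams`):

1. **White balance.** Per-channel gains are estimated from the brightest
   low-chroma pixels (value within 60% of the image maximum and above
   `brightness_floor` = 0.25; relative chroma ≤ `white_chroma_cap` = 0.35).
   On a sheet photograph this region is the intact white surface, so the
   estimate is self-calibrating and needs no grey card. Gains map the
   reference mean to neutral grey. A single global gain per channel is
   used: the dominant colour casts in this imaging setup (LED temperature,
   camera white point) are global, and a global estimate is idempotent to
   within one intensity level after 8-bit re-quantization.
2. **Plate extraction.** The largest 8-connected component of pixels with
   value ≥ `brightness_floor`, holes filled. Hole filling matters: darker
   abrasion patches sit inside the plate and must count toward the plate
   area. Components below `min_plate_area` = 500 px raise "no sheet
   detected".
3. **Layer detection.** The image is mapped to the HSV cylinder — chosen
   for its explicit hue/saturation separation. A pixel belongs to a
   colour layer when its hue falls in the layer's half-open band, its
   saturation is ≥ 0.25 (suppressing the neutral white surface) and its
   value ≥ 0.15 (suppressing background). Default bands (degrees):
   blue [190, 260), yellow [40, 75), red [330, 360) ∪ [0, 15),
   green [90, 160). Bands are half-open so adjacent bands tile the hue
   circle without double membership; a hue exactly at the upper edge
   belongs to the next band. All bands and thresholds are overridable per
   layer via YAML. The selection is median-filtered with a disk of radius
   2 px (for a binary image the median is a majority vote, implemented as
   a box-count threshold) and components under 5 px are removed as
   speckle.
4. **Deduplication.** Colour transitions at patch borders produce
   intermediate hues, so raw layer masks can overlap or leave fringe
   pixels ambiguous. Every pixel of the union of the raw masks is
   assigned to the *deepest* layer whose mask, dilated by 1 px, covers
   it: a pixel showing red cannot simultaneously count as blue, and the
   deeper layer absorbs the transition fringe. The outputs are pairwise
   disjoint and their union equals the raw union — no pixel double
   counted, none missed. This per-pixel "deepest claim" semantics is
   what the brute-force oracle in the tests implements independently.
5. **Score and geometry.** The pixel score is Σ_k weight_k · count_k over
   the four detectable layers. The layer weights of the original
   instrument were determined empirically and never published; the
   package defaults to depth-proportional weights (blue 0.2, yellow 0.4,
   red 0.6, green 0.8), consistent with published score/area ratios
   (≈0.2) under predominantly shallow wear, and fully configurable. At
   400 dpi one pixel is 25.4/400 = 0.0635 mm on a side; abraded area is
   the union pixel count times the pixel area, and abraded volume assumes
   each exposed pixel was milled to the midpoint of its exposed layer
   (0.15 mm for blue … 0.45 mm for green, with 0.1-mm layers). The
   midpoint model is an estimate — colour alone cannot resolve partial
   within-layer abrasion — and published volumes suggest real wear is
   often shallower than the midpoint; volumes should be read as
   order-of-magnitude.

## RMMA scoring

Scorable bursts have amplitude ≥ 20% of maximal voluntary contraction
(inclusive) and duration ≥ 0.25 s; overlapping events are merged;
artefact-flagged events (wakefulness, swallowing, repositioning — flagged
upstream from audio/video review) are dropped. Bursts are grouped
greedily left-to-right with a 3-s maximum inter-burst gap. A group is

* **phasic** if it contains ≥ 3 consecutive bursts each in [0.25, 2) s,
* **tonic** if it contains a burst ≥ 2 s (a burst of exactly 2.0 s is
  tonic, keeping the two duration bands disjoint),
* **mixed** if both occur in the same group — "closely related" phasic
  and tonic activity is operationalized as co-membership in one
  gap-bounded cluster, since no numeric definition exists,
* rejected (not an episode) if it is only one or two short bursts.

Per-night indices are episodes/h, bursts/h (members of scored episodes
only) and the count of episodes with grinding sounds. The diagnostic
cut-offs — ≥ 4 episodes/h, ≥ 25 bursts/h, ≥ 1 grinding episode — are
combined by conjunction, matching the Lavigne-style research criteria
they derive from; an OR combination is available as a sensitivity
analysis because the source description lists the cut-offs without an
explicit connective. Across multiple nights, the night with the most
episodes/h is selected (ties: higher bursts/h, then the first night).

## Validation statistics

* **ROC.** Thresholds run over all distinct observed scores; score ≥ t
  classifies positive, so the reported cut-off itself tests positive.
  The trapezoidal AUC equals the Mann–Whitney concordance probability
  with ties counted ½ (asserted exactly against an O(n²) oracle). The
  Youden cut-off maximizes J = Se + Sp − 1 with ties broken toward
  higher sensitivity and then the lower cut-off — the instrument is a
  screening tool, so missing true positives is the worse error.
* **Effect size.** Pooled-SD standardized difference; the small-sample
  correction 1 − 3/(4N − 9) gives Hedges g. For the study moments the
  uncorrected d is 1.54 and g is 1.52; both are reported.
* **Power.** Noncentral t with df = n₁+n₂−2 and noncentrality
  d·√(n₁n₂/(n₁+n₂)), cross-checked against statsmodels and a Monte-Carlo
  simulation of the test.
* **Group tests.** Shapiro–Wilk (α = 0.05) in each group routes to the
  Welch unequal-variance t-test (the fractional dfs in the published
  tables are only producible by Welch–Satterthwaite, so "Student's
  t-test" is implemented as Welch) or to the Wilcoxon rank-sum test. The
  rank-sum p-value is exact — a tie-capable permutation null computed by
  dynamic programming over doubled midranks — whenever both groups have
  ≤ 12 observations, and otherwise uses the normal approximation with
  tie and continuity corrections. Multiple endpoints are adjusted by
  Benjamini–Hochberg FDR (via statsmodels).
* **Confidence intervals** for group means are Student-t from summary
  statistics; they reproduce the published intervals to display
  rounding.

## Synthetic data

No wear-sheet dataset is publicly deposited, so the package ships
generators whose defaults are the study conditions:

* **Sheet renders.** An arch-shaped (annular-sector) white plate on a
  black background — at the default 800×800 px the plate covers ≈234,000
  px, inside the published plate-area range. Abrasion patches are placed
  at random arch sites with nested deeper exposure (blue, sometimes
  yellow/red/green inside), each patch realized as exactly its requested
  number of pixels so ground truth is exact by construction. Perturbations:
  a linear ±10% illumination ramp and Gaussian sensor noise (σ = 3/255).
  Not emulated: anti-aliased patch borders, specular gloss, lens
  distortion, partial-depth colour mixing, texture of real milled
  plastic. Recovery tests on these renders therefore demonstrate the
  correctness of the segmentation logic, not photographic robustness.
* **Cohorts.** Pixel scores are gamma-distributed, moment-matched per
  group (shape = mean²/SD², scale = SD²/mean; SB 1306 ± 913 n=10,
  non-SB 381 ± 483 n=35). Gamma was chosen over a normal model because
  scores are nonnegative and the non-SB SD exceeds its mean (shape
  0.62 < 1, strongly right-skewed), which no symmetric family can
  produce; a lognormal family is available.
* **EMG nights.** Planted phasic clusters (3–5 bursts of 0.3–1.5 s,
  gaps 0.5–2.5 s), tonic bursts (2.2–6 s) and mixed sequences, separated
  by ≥ 6 s (comfortably beyond the 3-s grouping gap), plus distractors
  that fail exactly one scoring criterion each: 15% MVC bursts and 0.1-s
  spikes. Default night: 6 h with 20/8/4 phasic/tonic/mixed episodes and
  5 grinding-flagged episodes.

All generators are deterministic given their seed.

## Problem sizes and numerical choices

Recovery suites use 50 seeded renders per condition at 800×800 px, 100
random 50×50 mask stacks for the deduplication oracle, 100 random
cohorts (n ≤ 50) for the AUC oracle, 100 planted nights for the RMMA
scorer, and 10,000 subjects per group for simulator moment checks —
sizes at which the law-of-large-numbers tolerances (2% mean, 4% SD) are
comfortable. Ties in ranks use midranks; ties in the Youden scan and
night selection have the explicit tie-breaks stated above; degenerate
inputs (all-black images, empty masks, zero-variance groups, undefined
ratios) return flagged values or named errors rather than NaNs.

## Known limitations

* The published primary results (AUC 0.88, cut-off 507 px) depend on the
  authors' 45 physical sheets and PSG recordings, which are not
  deposited; they are not recomputable from scratch. The package
  reproduces every number derivable from the printed summaries and
  validates the algorithms on ground-truthed synthetic data instead.
* Layer weights and exact filter parameters of the original software are
  unpublished; defaults are documented estimates and configurable.
* Abraded volume is a midpoint-depth model (see above).
* The RMMA scorer consumes burst *events*; raw-EMG processing
  (rectification, envelope, MVC calibration) and sleep staging are out
  of scope.
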