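# Methods

This note documents the models, parameters and design decisions behind
`lamina`: what each stage computes, what the synthetic benchmark does and
does not emulate, and where the genuinely open choices were made.

## The synthetic scene and cohort

The generator fabricates a sagittal medial entorhinal cortex (MEC) wedge on
a 300 × 225 px frame at 40 µm/px — a 4× scale-down of the 1200 × 900
full-resolution processing canvas (`SceneConfig` accepts the full-scale
convention directly; the default keeps a registration in well under a
second).  The wedge spans fixed width/height fractions of the frame with a
parabolic bowing of the laminar boundaries (default 8 px) so that boundaries
are curves, not axis-aligned lines.  Cortical depth `t` runs 0 → 1 from the
white-matter to the pial boundary and is partitioned into layers VI (0–0.18),
Vb (0.18–0.33), Va (0.33–0.47), lamina dissecans (0.47–0.55), III
(0.55–0.75), II (0.75–0.92) and the molecular layer I (0.92–1).  Three
neighbor regions (parasubiculum dorsally, ventral cortex, subiculum
medially) share the wedge's column profile.  All masks are computed
analytically, so label geometry is exact.

A gene is a `SyntheticTruth` record: a class (`layer_specific` for one of
the five cellular layers, `de` for a two-group pair, `island` /
`inter_island` layer-II substructure, `uniform`, `none`), per-layer base
intensities, a dorsoventral coefficient `g`, and a pixel-noise SD.  The
rendered field is base intensity × `2^(g·u)` where `u` is the dorsoventral
coordinate normalized so the dorsal and ventral sampling-box centers sit at
0 and 1; because the boxes have equal height and near-identical pixel
geometry, the log2 ratio of box means equals `g` up to pixelation and 8-bit
quantization (empirically within ~0.02 at the default intensities).  The
field is rescaled globally when it would exceed 255, which preserves all
ratios.  Island substructure is rendered as dart-throwing-placed ellipses
inside the layer-II band (minimum center distance 18 px, radii 5–8 px rows).
Island placement interacts with the sampling boxes, so for these genes the
ratio actually encoded in the image differs from `g`; the generator
therefore records the *realized* noise-free log2(V/D) per gene
(`realized_log2_dv`) and all ground-truth expectations, and the coupled FPKM
table, derive from it.

Pixel noise is mean-preserving lognormal with SD in intensity units
(default 2.0 on the 0–255 scale).  Artifact injection for the QC task adds
tissue bubbles — zeroed discs of radius 6–16 px (240–640 µm), centered on
stained pixels, since a bubble only reads as a hole where it occludes
signal — and/or a bright pial-surface streak (the "pial surface detected as
an expressing cell" failure mode).

FPKM tables emulate pooled dorsal/ventral RNA-Seq with 4 replicates per
group: group means are `fpkm_base · 2^(∓g/2)` and replicates carry
lognormal noise with log-SD 0.15 (a ~15% coefficient of variation,
realistic for pooled samples).  Unexpressed genes get FPKM 0.01.  The
emitted significance flag emulates an external differential-expression
caller; downstream code consumes it and never recomputes it.

What the benchmark does *not* emulate: brightfield ISH optics, cell-level
texture, section-to-section anatomical variability, plane misassignment, or
the atlas' own normalization pipeline.  Passing tests therefore demonstrate
the correctness and calibration of the algorithms under controlled truth,
not performance on the real corpus.

## Preprocessing and segmentation

The ISH preprocessing chain is scale → center-paste onto the canvas →
rolling-ball background subtraction at radius 1 px → minimum-error
binarization → 3×3 median filter → Gaussian blur (σ = 1).  At radius 1 the
rolling ball is implemented as grayscale morphological opening with a
radius-1 disc, which is equivalent at that scale.  The minimum-error
(Kittler–Illingworth) threshold minimizes
`J(T) = 1 + P₁ln σ₁² + P₂ln σ₂² − 2(P₁ln P₁ + P₂ln P₂)` over all 256
levels; class variances are floored at the quantization variance 1/12 so
delta-peaked histograms stay defined, and the midpoint of a minimizing
plateau is returned (placing the threshold between well-separated peaks —
the convention the tests' brute-force oracle shares).  Forebrain
segmentation is Sobel gradient magnitude → minimum-error threshold → hole
filling (8-connectivity) → keep the largest 4-connected component; failure
is a flagged status, not an exception.

## Registration

Deformations are cubic B-spline free-form deformations: control points every
16 px (configurable, floor 8 px) in fixed full-frame coordinates, zero
coefficients = identity.  The objective is mutual information (nats, 32
histogram bins, partial-volume weighting along the moving-intensity axis)
minus λ × a discrete bending energy — the mean squared second difference of
the control displacements *in units of the grid spacing* (dimensionless, so
λ = 0.1 bounds deformation scale without forbidding smooth few-pixel
warps).  The MI gradient is analytic: ∂MI/∂(warped value) is the difference
of joint/marginal log-ratios of the two straddled bins, chained with the
sampled moving-image gradient and projected onto the B-spline basis by two
matrix products.  Optimization is gradient ascent with a trust-radius line
search (max control update 2 px, halving on failure, up to 3 restarts)
through a 3-level image pyramid (factors 4/2/1; 120/80/50 iterations;
convergence at relative objective change < 1e-5).  Both images are smoothed
(σ = 2) before optimization; the model is applied to the originals.  Every
accepted step increases the penalized objective and the initial field is
identity (zero bending), so the final MI never falls below the initial MI.
Bit-identical inputs short-circuit to the exact identity.

Recovery is benchmarked against warps drawn from the same family (spacing
32 px, amplitude 8 px).  The error metric compares the recovered field with
the *exact inverse* of the ground-truth warp (computed by fixed-point
iteration), averaged over the tissue foreground — the background of the
synthetic scene is constant, so displacement there is unidentifiable for
any intensity-based method.  Across 20 seeds the mean error is ≈1.5 px
(every seed < 2 px) at ≈0.35 s per registration; identity registration
recovers < 0.01 px.

Reference building replaces true n-way groupwise registration with
rigid (two-point closed-form similarity) pre-alignment followed by two
rounds of register-to-the-evolving-pixelwise-median — a bounded-memory
groupwise surrogate adequate at this scale.

## Quality control

Three per-image metrics: the registration MI score (flag below a
configurable floor, default 0.15 — calibrated on synthetic cohorts, since
no published number exists); the normalized cross-correlation offset of the
MEC region against a 20 px-margin reference window (flag when the ∞-norm
offset exceeds 5 px at synthetic scale — again a configured value); and a
radial-basis SVM error probability (flag above 0.13, the published
operating point).  Features are 4-scale (σ = 1, 2, 4, 8) unsigned
gradient-orientation histograms on a 4×4 spatial grid, 8 orientation bins,
L1-normalized per scale — 512 dimensions, deterministic, a generic stand-in
for the dense multi-scale descriptor family with the same contract
(fixed-length, scale-aware, alignment-invariant).  C and gamma are chosen
by 3-fold stratified cross-validation and probabilities come from sigmoid
calibration.  An image fails QC iff the MI flag is raised or at least two
of the other flags are — a monotone rule.

## Quantification and patterning scores

Laminar statistics and both patterning scores follow the formulas in the
README exactly; the measurement step (`laminar_profile`) is separated from
the scoring arithmetic (`score_from_measurements`) so hand-specified
fixtures can be scored without an image.  Decisions worth stating:

- `w_mean` (the joint score's weight on the rel terms) is set to
  `w_rel` = 0.4, making the joint weights sum to 1 symmetrically with the
  single score.
- With no high-intensity pixels, the proportion terms vanish and `w_rel`
  rises to 0.9 (leaving `w_abs` = 0.1); the same override is applied to
  `w_mean` for the joint score so its weights still sum to 1 and the score
  stays in [0, 1].
- Ranking ties on `Lx_rel + Lx_prop` break by the fixed layer order
  II < III < V/VI, making output deterministic.
- `MEC_mean` is taken over the full MEC mask including layer I and the
  lamina dissecans; the high-intensity threshold uses the population SD.
- `Lmax_diff` is computed and reported but feeds no decision rule; it is
  retained for inspection only.
- Eligibility: overall MEC mean ≥ 1 and ≥ 2 in at least one layer;
  ineligible genes carry NaN scores and are never candidates.
- `average_series` implements the replicate-averaging product — mean
  relative regional pattern across series × mean whole-image intensity
  across series — verbatim; its output unit is this rescaled intensity,
  comparable across genes because overall staining strength enters exactly
  once.
- The similarity search prefilters candidates to a mean-intensity window
  (default [1, 5)) and, when region-mean vectors are supplied, to
  sum-of-squares difference ≤ 0 from the seed (exact zeros are attainable
  after integer quantization), then ranks by Pearson correlation of ROI
  pixels.

## Dorsoventral analysis

Image and FPKM classification share the inclusive threshold
log₂(1.2) = 0.26303 (stored as the computed constant, never a rounded
literal).  Images need a regional mean ≥ 2 in either box; when C and L1
planes both exist their box means are averaged with equal weight.  A zero
denominator with an expressed numerator classifies by sign with an
infinite-ratio sentinel.  FPKM genes are expressed at group mean ≥ 0.1,
tested at overall mean ≥ 1, and "significant" only with the externally
supplied flag.  Gradient slopes are ordinary least squares of mean
intensity on subregion index (5 equal dorsoventral bands, 0 = dorsal), per
layer and pooled.  Depth profiles assign each pixel
`d = D_in / (D_in + D_out)` from Euclidean distance transforms to the two
boundary polylines, 20 half-open bins (last closed); binning conserves
intensity mass by construction.  The deep/superficial statistic is the deep
share of intensity mass with cutoffs 0.4/0.6.  Parametric group inference
(mixed models, MANOVA, ANOVA + Tukey) is out of scope; a seeded label-
shuffling permutation test on group means (default 10,000 permutations,
add-one p) is provided alongside descriptive statistics as the testable
alternative.

## Enrichment statistics

Hypergeometric p-values are computed with exact integer arithmetic
(`math.comb`), so the two-sided convention — sum every table whose
probability does not exceed the observed table's — is tie-exact rather than
tolerance-based.  BH adjustment is applied within each analysis family
(statsmodels' step-up).  Note the step-up procedure is *not* idempotent;
the tests assert the true properties (adjusted ≥ raw, monotone, capped,
inflationary on reapplication).  Cohen's kappa compares term membership
vectors over the universe; terms with 5 ≤ K < 100 genes are clustered by
average linkage on 1 − κ, cut at cophenetic distance 1 − 0.35 (the cut
height is unpublished and exposed as configuration), and a term is reported
iff no more-significant term (ties broken lexicographically) overlaps it at
κ ≥ 0.7.  Flat term sets are consumed as given (GMT); ontology-graph
propagation is out of scope.

## Pipeline and problem sizes

`run_pipeline` executes simulate → preprocess → register → qc → quantify →
gradients → enrich from one validated config (unknown keys rejected); every
threshold defaults to the standard value and all randomness derives from
the run seed, so reports are bit-reproducible (timings go to the log
stream, never into the report).  The registration stage warps each image by
a known field and recovers it when `deform_amplitude` > 0; at 0 the cohort
is already in the reference frame and only MI scores are recorded.  The
standard recovery experiments run the cohort at n = 200 (default noise) and
n = 60 (zero noise) with the image-processing stages toggled off — those
stages are benchmarked separately (20-seed registration recovery, 100+100
QC cohort), which keeps each experiment's purpose, and its runtime, narrow.
The per-stage command-line interface is the set of numbered scripts under
`analysis/`; the `lamina` console script exposes `run` and `simulate` as
the two entry points a shell user needs.

## Known limitations

- The optimizer is first-order; pathological contrast reversals (which MI
  tolerates in principle) may need more iterations than the defaults.
- Recovery guarantees are measured on warps from the generator's own
  B-spline family; unmodeled deformation (tears, folds) is exercised only
  through the QC path.
- The synthetic benchmark's separability means classifier accuracies here
  are upper bounds, not estimates, for real-atlas performance.
- Plane assignment is taken from metadata; the medio-lateral plane
  classifier contract is covered by the generic feature + classifier pair
  in the QC module rather than a dedicated model.
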