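# Methods

## The model

The workflow estimates a habitat-suitability surface for a rarely
detected species from presence/absence camera-trap records. Detection at
station *i* is modelled as Bernoulli with

p_i = logit⁻¹( β₀ + Σⱼ βⱼ · z_{ij}(sⱼ) ),

where z_{ij}(sⱼ) is the z-standardized Gaussian focal mean of predictor
*j* around station *i* at that predictor's selected scale sⱼ. The model
makes the usual resource-selection assumptions: detections are
conditionally independent given the environment, the species responds to
each predictor at a single characteristic scale, and responses are
linear on the logit scale. Detection probability is not modelled
separately from occurrence (the data carry no repeat-visit structure),
so p is an index of *relative* suitability, not true occupancy.

## Focal smoothing

The scale ladder is 250, 500, 1000, 2000, 4000, 8000, 16000 m. The
kernel at scale *s* has σ = s/2 and is hard-truncated at radius = s
(≈ 2σ, retaining ~95% of the untruncated mass); weights are normalized
to sum to one. Truncation radius is fixed rather than configurable
per-call because every downstream contract (variance reduction, impulse
response) is stated against this kernel. Edges and nodata cells are
handled by renormalizing the kernel over the valid cells inside the
window — no values are invented outside the extent, at the cost of
slightly higher variance near edges. Smoothing preserves affine surfaces
in the interior and is variance-reducing, both of which are tested.

Point extraction takes the single containing pixel of the smoothed
raster (the smoothing already encodes the neighborhood average), with
half-open pixel intervals and row-major addressing from the top-left
corner. Year-indexed predictor layers are matched to the station's
survey year; a missing year falls back to the nearest year, ties
breaking toward the earlier layer (the landscape as it was, not as it
became).

## Station pipeline

Stations need ≥ 30 operational days. Spatial deduplication is a greedy
single pass with a 500 m buffer: presence stations are processed before
absences (discarding detections of a rare species is the worse error),
each class in station-id order, and a station is dropped if a kept one
lies strictly within the buffer. Surveys with zero detections are
removed entirely — their absences are uninformative for a species the
survey design evidently could not detect.

Because prevalence is far below 0.1, logistic models are fitted on
class-balanced replicate datasets: every presence is kept, and per
survey an equal number of absences is drawn — without replacement when
the survey has enough absences, with replacement (logged) otherwise. Ten
replicates differ only in the absence draw. Each replicate is split 4:1
train/test, stratified by class; the per-class test count is the nearest
integer to n/5 (at least 1). Nearest rounding is used because it keeps
the split exact for the canonical balanced sizes (138 presences → 110
train + 28 test per class) while never emptying a test class.

Balancing is case-control sampling on the outcome: slope estimates
remain consistent, the intercept absorbs the sampling-rate offset. Maps
predicted from a balanced fit are therefore calibrated to the balanced
prevalence (~0.5 at the mean), which is the intended behavior for a
relative suitability index.

## Scale selection and collinearity screening

For each predictor the univariate logistic AIC (−2ℓ̂ + 4) is computed at
every ladder scale on the training rows; since k = 2 throughout, the
minimum-AIC scale is the maximum-likelihood scale. Ties break to the
smallest scale. Scales with complete separation are flagged and excluded
rather than letting an unbounded likelihood win the scan.

Chosen-scale columns are then screened: while any pair has |r| > 0.7,
the most-correlated pair is resolved by dropping its higher-AIC member,
recomputing correlations after each drop (descending-severity order is
reproducible; a single-pass variant would depend on column order).
Constant columns, whose correlation is undefined, are dropped first with
a log entry. Finally VIF_j = 1/(1 − R²_j) is computed per column and the
largest is removed while any exceeds 5.

## Model selection

All 2^p subsets of the candidate set (p ≤ 20 guard) are fitted by
maximum likelihood (Newton iterations to gradient-norm tolerance, Wald
standard errors from the inverse observed information) and ranked by
AICc; AIC is reported alongside. Ties break toward the smaller model,
then lexicographic term names. The ΔAICc < 2 set is reported as the
support set, but the single best model generates the map — no model
averaging. Predictors are z-standardized to training mean/SD before
fitting so coefficient magnitudes are comparable; the constants persist
on the fitted model and are re-applied in map prediction.

Per replicate, the entire chain — scale scan, pruning, VIF, exhaustive
search, threshold evaluation — reruns from scratch on that replicate's
training split, and the replicate whose optimal threshold attains the
best test binary AUC (ties: higher κ, then the earlier replicate)
supplies the final model.

## Evaluation

Thresholds are t_i = i/31, i = 1..30 (an even interior grid; the
endpoints are degenerate classifiers). A prediction ≥ t is classified
presence. Per threshold the confusion matrix yields sensitivity,
specificity, κ, TSS = sens + spec − 1, and the binary AUC of the
thresholded classifier, (sens + spec)/2 — the only AUC computable from a
single confusion matrix; TSS = 2·AUC − 1 exactly. Rank-based ROC AUC
over the continuous scores is deliberately *not* the selection
criterion.

The continuous Boyce index slides 101 windows of width 0.1 × the
background suitability range across that range; P is the fraction of
validation points per window, E the fraction of background cells, and
the index is the Spearman correlation of F = P/E against the window
midpoint over windows with E > 0. Width and window count are common SDM
practice and are exposed as configuration. Two numerical notes: the
index is exactly invariant under affine rescaling of the suitability
values but only approximately under nonlinear monotone maps (fixed-width
windows are not rank-based even though Spearman is); and under the null
(validation points unrelated to suitability) the index has heavy tails —
overlapping windows make F a smooth random curve, so |index| can exceed
0.5 in roughly 15% of runs regardless of the number of points.

## Gap analysis

Suitability is binned into four equal-width classes with closed-left
intervals and a closed top bin (so 1.0 is classified High). Zones are
rasterized by pixel-center containment — deterministic, standard
zonal-statistics semantics — and per-zone, per-class areas are reported
in km² together with each class's protected fraction. Classes with zero
area report NaN fractions, never a spurious 0.

## Synthetic landscape

Predictor fields are Gaussian random fields built by FFT (circular)
convolution of white noise with a Gaussian kernel, standardized to mean
0 / SD 1; the kernel bandwidth is the field's correlation length.
Defaults: 256×256 pixels at 250 m (a 64 km square) and correlation
length 1.5 pixels (375 m). The fine grain is deliberate: environmental
products enter such analyses at near-pixel resolution, and the
multi-scale structure the scan must detect is *induced by the smoothing
ladder*. Fields much smoother than the ladder's lower rungs make
adjacent scales nearly collinear and the scale-optimization problem
unidentifiable.

Ground truth applies the logistic model to focal means at known ladder
scales (standardized over the raster). The default generative model —
three active predictors of five, β = (1.0, −0.8, 0.6) at scales (1000,
4000, 500) m, intercept −2.9 — uses effect sizes ≥ 0.5 on the
standardized scale (strong but realistic habitat effects) and an
intercept near logit of the target prevalence so the detection scaler
stays ≈ 1 (see below).

Surveys are circular clusters (default 7 clusters of 222 stations,
radius 10 km), mimicking a multi-team compilation; effort is uniform in
60–180 days. Detection is Bernoulli(q × truth) where the scaler q is
calibrated by bisection so the mean of min(q × truth, 1) over station
pixels matches the target prevalence (0.095 by default). A multiplicative
scaler is the simplest detection mechanism consistent with specifying
prevalence only; because truth probabilities are small at that
prevalence, q multiplication is nearly an intercept shift on the logit
scale, so slope recovery is unaffected. Validation points are rejection
sampling proportional to suitability — the opportunistic-encounter model
that the Boyce index assumes.

What the generator does *not* emulate: real predictor covariance
structure, nonstationarity, detection heterogeneity between camera
models or habitats, temporal detection histories, and spatially biased
opportunistic reporting. Passing recovery tests therefore shows the
estimator chain is correct and identifiable under its own assumptions,
not that any particular field system satisfies those assumptions.

## Problem sizes and reproducibility

The recovery experiment uses ten seeded landscapes at ~2000 stations
each (about 1300 after filtering), ten balanced replicates per
landscape — sizes at which all-subsets search over ≤ 5 candidates and
~70 logistic fits per replicate complete in about a second per
landscape. One master seed is expanded by SHA-256 into independent
per-stage streams (landscape, survey, validation, zones, balancing,
partitioning), so any stage can be re-run in isolation bit-identically;
every generator is a pure function of configuration plus seed.

## Known limitations

- Absolute probability calibration is sacrificed by class balancing;
  outputs are relative suitability indices.
- The greedy dedupe and greedy correlation pruning are order-dependent
  rules; both orders are fixed and documented rather than optimized.
- Complete separation in small subsets is excluded from rankings with a
  record, which can bias the support set when separation is frequent.
- The binary AUC used for threshold and replicate selection is a
  single-operating-point summary, not the rank-based ROC AUC.
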