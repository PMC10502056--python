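# Methods

## The scientific setting

Subjects view emotional and neutral pictures (interleaved with scrambled
pictures carrying simple geometrical figures as a perceptual control)
while BOLD fMRI is acquired, then freely recall as many pictures as
possible.  Two questions drive the analyses: *where* does encoding-phase
activity differ between later-recalled and later-forgotten items (the
subsequent memory effect), and *which* activations and functional networks
covary with a person's overall recall ability.  Because recall of an item
confounds the item's intrinsic memorability with the person's memory
skill, the subsequent-memory analysis is repeated with item memorability
(the across-subject mean recall of that item) as a parametric covariate.

## Synthetic cohorts

The generator produces cohorts with exactly the statistical structure the
analyses assume, so every stage can be tested end to end without any data
download.

**Events.**  Each trial is fixation (0.5 s) + picture (2.5 s) + a jittered
intertrial period drawn uniformly from 9–12 s, giving trial lengths of
12–15 s; a rating epoch of 1–4 s and a button-press delta event sit inside
the intertrial period.  Target pictures are interleaved with scrambled
figures under a cap on consecutive targets.  The design intent is at most
two targets in a row, but with 72 targets and 24 separators at most
2 × 25 = 50 targets would fit, so the cap is relaxed to
`ceil(n_items / (n_scrambled + 1))` (3 at study scale) and the relaxation
is logged.  Valences (negative/neutral/positive, balanced) are assigned
with runs capped at 4 by a greedy sampler with retries.  Two primacy and
two recency pictures flank the run and are excluded from all behavioral
scores.  Run length follows from the schedule; the volume count is
`ceil(run_length / TR)` rather than a fixed 420 volumes, which the
paper-scale profile approximately reproduces (100 trials × 12–15 s
slightly exceeds 420 × 3 s; the schedule wins).

**Recall.**  `P(recall_si) = logistic(ability_s + easiness_i)` — a
Rasch-style additive model chosen because it gives a closed-form link
between the latent item easiness and the observable memorability (the
column mean converges to `logistic(easiness)` when abilities centre on
zero), which the tests exploit.  Primacy/recency items get elevated
easiness (mean +1.5), mirroring their serial-position advantage.  Item
arousal is drawn with correlation 0.3 to easiness as a stand-in for
normative arousal ratings.

**BOLD.**  A run is baseline 100 plus HRF-convolved condition signals on
Gaussian-blob amplitude maps: a picture-vs-figure *encoding map*, a
*subsequent-memory map* driven by later-recalled items (which also carries
a memorability-proportional term, so the memorability modulator has
variance to absorb), and an *individual-difference map* whose amplitude is
proportional to the subject's latent ability (the source of voxel-level
brain–behavior correlation).  K spatially near-orthogonal (|r| < 0.3)
network components are added with time courses = gain × convolved picture
regressor + 0.3 × figure regressor + component-specific AR(1) fluctuation
(0.7 × the network amplitude); the spontaneous fluctuation is what renders
co-activated networks separable by spatial ICA.  For a configurable subset
of networks the per-subject gains correlate with ability (default r = 0.7),
planting the network–behavior association.  Noise is stationary AR(1)
(default sigma 1, rho 0.3); drift is a random combination of the three
slowest discrete-cosine modes per voxel; six smooth random motion series
are attached as nuisance regressors only (no actual motion is simulated).

**Seeding.**  One master seed; substreams via `SeedSequence` spawn keys:
(0,) ground truth (item-level and spatial draws precede subject-level
draws), (1, s) events, (2, s) recall row, (3, s) BOLD/motion for subject
s, (4,) phenotype.  Cohorts are bit-reproducible and extensible in
`n_subjects` without reshuffling earlier subjects' events or recall.

## First-level model

The canonical HRF is the difference of two gamma densities (peak delay
6 s, undershoot delay 16 s, unit dispersions, peak:undershoot 6:1),
sampled at 0.1 s over 32 s and peak-normalized.  Stimulus functions are
built on the microtime grid (boxcars for pictures and ratings, unit-area
impulses for button presses), convolved, and sampled at volume times
k·TR.  Parametric modulators are mean-centered at the event level,
multiply the event boxcar, are convolved, and the convolved column is then
residualized against the unmodulated column and all earlier modulator
columns in order (memorability first, the remembered indicator second; an
arousal-first variant is provided).  Orthogonalization happens after
convolution — the dominant convention — and provably leaves the joint
column space unchanged; the tests verify equality with an explicit
Gram–Schmidt construction to 1e-8.  A modulator that is constant over
events yields a zero column with a warning and is dropped from the design
to preserve full rank (this occurs for subjects who recalled everything or
nothing).  The high-pass filter is realized as discrete-cosine nuisance
columns inside the design (`floor(2·T·TR/cutoff)` columns, cutoff 128 s)
so degrees-of-freedom accounting stays explicit; motion series enter
unconvolved; temporal derivatives are deliberately omitted.

Estimation is two-pass: OLS, then a single pooled lag-1 residual
autocorrelation over all in-mask voxels (one Cochrane–Orcutt refinement),
exact AR(1) whitening including the `sqrt(1 − rho²)` first row, and a
second OLS pass.  A pooled rho was preferred over per-voxel estimates for
df bookkeeping; note the pooled estimate is biased toward zero when the
design contains smooth regressors (motion random walks, DCT columns)
because those absorb low-frequency noise power — beta estimates remain
unbiased.  Error df is T − rank(X).  Contrasts are weighted beta
combinations; the standardized option rescales to z-scored regressors and
data (`beta · sd(x)/sd(y)`), the scale used for network responsivity.
Smoothing is a separable Gaussian with `sigma = FWHM/(2·sqrt(2·ln 2))` per
axis and reflecting boundaries (mass-preserving); default 8 mm FWHM.

## Group inference

Per-voxel OLS over subjects with the predictor of interest (intercept for
mean effects, z-scored recall count for brain–behavior slopes) plus age,
sex and treatment-coded batch dummies (first level = reference).  Perfect
fits are capped at |t| = 1e6.  Family-wise error uses the permutation
distribution of the maximum |t| over the mask — Freedman–Lane: the outcome
is residualized against the nuisance covariates, residual rows permuted,
the nuisance fit added back, the full model refit — with the corrected
threshold at the (1 − alpha) quantile, alpha 0.05 two-sided.  This
replaces random-field-theory correction (the convention behind the
original thresholds) because it is assumption-light and exactly testable
at desk scale; printed parametric t-thresholds are therefore not
reproduction targets.  Surviving voxels are labeled by face connectivity
(18/26 selectable), positive and negative exceedances separately, and
clusters under 20 voxels are dropped.  Calibration: on 200 null cohorts
(30 subjects, 16×16×10 grid, 500 permutations) the empirical FWER lands
within [0.02, 0.08].

## Brain–behavior products

The standardized effect size is the partial correlation of an ROI-mean
activation and the recall count given covariates, computed as
`sign(b) · |t| / sqrt(t² + df)`; it equals the correlation of the two
covariate-residualized vectors (tested to 1e-10).  The resampling
experiment draws subjects without replacement, independently across
replicates (the original sampling scheme is unspecified; this is the
simplest exchangeable choice), over the printed size ladder
26…1000 — taken verbatim, as no single rounding rule regenerates it — with
200 replicates per size at desk scale (5000 at paper scale).  ROIs come
from a generic top-k-by-extent selector on any thresholded result (k = 4
by default).  Small subsamples can render a batch dummy constant; the
effect-size routine is rank-robust (pseudoinverse, df = n − rank).  The
t-on-t comparison fits one OLS line of brain–behavior t on
memorability-corrected subsequent-memory t over the voxels with a
significant predictor effect; negative residuals mark regions whose
brain–behavior association is weaker than the subsequent-memory effect
predicts.

## Network arm

Runs are concatenated in time after per-voxel temporal de-meaning, a
128 s discrete-cosine high-pass (matching the first-level filter — without
it the low-frequency drift modes dominate the PCA subspace), and
voxel-wise variance normalization.  Spatial ICA treats voxels as samples:
PCA-whitening to K followed by the fixed-point negentropy (logcosh)
contrast with symmetric decorrelation; map signs are fixed by positive
skewness; results are deterministic given the seed.  K is fixed by
configuration (10 desk / 60 paper); probabilistic order selection is out
of scope.  Per-volume spatial de-meaning is deliberately omitted because
it couples otherwise independent spatial sources; variance normalization
can be disabled for amplitude-structure analyses (it flattens amplitude
profiles, e.g. a rank-one amplitude map is only recoverable without it).

Split-half validation decomposes two disjoint subject halves (seeded
shuffle) and cross-correlates unthresholded voxel loadings; a component is
replicable at |r|max ≥ 0.7, inspected at 0.6–0.7.  Stage-1 dual regression
solves, per volume, a joint multiple regression of the voxel vector on all
K group maps plus an intercept (a joint solve, so correlated maps are
handled exactly; a condition-number guard rejects collinear map sets);
stage 2 (subject-specific maps) is not needed downstream.  Component
thresholding offers a z-score rule (|z| > 3) and a two-component Gaussian
mixture (signal = larger |mean|, posterior > 0.5) with z-score fallback.
Responsivity is the standardized-beta difference pictures − figures from a
GLM of each component time course on the first-level design; per-component
linear models of recall on responsivity (plus covariates) are
Bonferroni-corrected at alpha/K and report the R² increment of the
responsivity term.  RSN similarity cross-correlates component maps with
template maps at lenient (|r| > 0.1) and stringent (|r| > 0.2) thresholds.

## Problem sizes and what the tests show

Desk-scale defaults (30 subjects, 24 + 8 + 4 pictures, 12×12×8 grid, 500
permutations, K = 10, 200 resampling replicates) were chosen so the whole
pipeline and its validation experiments run in minutes on one CPU; the
paper profile restores study-scale settings.  The validation experiments
set their own cohort conditions: parameter recovery injects only the
encoding and individual-difference signals with noise SD equal to the
signal amplitude; the split-half and planted-network experiments use
noise at half the network amplitude (the replicability property is a
noise-below-signal property) and, in the planted-network chain, route the
behavior link exclusively through two network gains so that specificity is
well defined.  Passing tests demonstrate internal correctness and
calibration under the generative model — linear signals on static maps,
Gaussian AR(1) noise, no motion, registration error, physiological noise
or spatial autocorrelation of noise — and therefore bound, but do not
establish, behavior on real data.

## Known limitations

- The pooled AR(1) estimate is attenuated by smooth design columns;
  per-voxel or ReML covariance models are out of scope.
- Memorability norms are computed within the analyzed cohort (the original
  study used a larger superset cohort); an external norm table can be
  supplied instead.
- The mixture thresholding is a plain two-Gaussian fit, not a
  Gamma–Gaussian mixture.
- Cluster inference uses extent filtering only (no TFCE, no RESEL-based
  expected cluster counts).
- Scrambled-figure rating epochs share one rating regressor with picture
  ratings; modulators attach only to picture regressors.
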