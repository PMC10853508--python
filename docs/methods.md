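# Methods

`nirscv` reimplements, as a tested pipeline on synthetic data, a multivariate
analysis that classifies diagnostic group membership (autism-spectrum vs.
typically developed adults) from fNIRS responses to live eye-to-eye contact,
and predicts clinical symptom severity (ADOS) from the classifier's
continuous decision scores. Its scientific center of gravity is not the SVM
itself but the contrast between two feature-selection regimes inside
leave-one-out cross-validation: *nested* selection, which re-ranks features
inside every training fold, and *pooled* selection, which ranks once on all
subjects — a small leak that inflates null-data accuracy from chance to the
~75% regime.

## Signal model and generator

Each synthetic subject is a two-chromophore channel recording (default 54
channels, 30 samples/s, 180 s). The task design alternates 18-s gaze blocks
with 12-s rest, starting with a gaze block; the regressor is this boxcar
convolved with the canonical double-gamma HRF (peak 6 s, undershoot 16 s,
dispersions 1 s, peak:undershoot 6, kernel 32 s), rescaled to unit maximum.
The experiment this emulates presented gaze in 3-s epochs within each 18-s
block; the generator models the block as one continuous on-period because a
block-design hemodynamic regressor cannot resolve few-second sub-epochs. A
`sub_epoch` switch produces an alternating sub-epoch boxcar for sensitivity
analyses.

Per channel c:

    oxy_c(t)   = a_c * reg(t) + g(t) + d_c(t) + eps_c(t)
    deoxy_c(t) = r * a_c * reg(t) + g'(t) + d'_c(t) + eps'_c(t)

with `r = oxy_deoxy_ratio = -0.5` (HbR task response opposes HbO), one
shared systemic series g per chromophore (AR(1), coefficient 0.95, rescaled
to SD `global_sd = 1.0` — the generative form of the systemic component is
the package's choice; the literature this emulates cites a spatial filter
without one), per-channel drift d_c (centered random walk rescaled to SD
`drift_sd = 0.5`) and white noise (SD `noise_sd = 1.0`). Amplitudes are in
arbitrary beta units.

Group structure: controls carry the baseline amplitude map (all ones);
affected subjects carry `baseline - effect_scale * pattern * u_i`, where the
pattern is a contiguous quarter of the channels (a stand-in for the dorsal
parietal cluster reported for this paradigm) and `u_i ~ Gamma(4, 1/4)`
(mean 1, SD 0.5) is a per-subject expression factor. Severity is affine in
the same factor, `6 + 6*u_i + N(0, 1.5)`, spanning roughly 6–20 severity
units — the simplest mechanism that makes a score–severity correlation
recoverable while keeping severity out of training. Cohort sizes default to
19 controls / 17 affected.

What the generator does *not* emulate: dyadic coupling between partners,
eye-tracking behavior, optode geometry and scalp physics, motion artifacts,
heterogeneous spatial patterns across affected individuals, and any
between-subject variability in the control group beyond measurement noise.
Passing recovery tests therefore demonstrates that the pipeline's machinery
is correct and calibrated, not that real cohorts of this size yield similar
accuracies.

## Preprocessing

Per subject and chromophore: (1) drift removal — an OLS line is removed,
then the approximation coefficients of a periodized db4 wavelet
decomposition at the depth whose band lies below 1/cutoff Hz (cutoff 128 s)
are zeroed. The linear step exists because a periodized transform smears a
ramp's start/end discontinuity across detail bands; with it, a pure ramp
leaves <1e-15 residual and the 30-s task band is attenuated by 0.2% at the
default geometry. (2) Global-component removal — the first spatial principal
component's time series (or the channel mean, when its spatial loadings are
not >80% same-signed) is regressed out of every channel, after being
orthogonalized against the task regressor. The orthogonalization is
essential: on task-dominated data the leading spatial component *is* the
task response, and an unprotected filter would delete it. The estimated
global series inevitably absorbs the across-channel mean of channel-unique
signals (a 1/sqrt(n_channels) contamination inherent to any global-signal
estimate). (3) Hbdiff — the unweighted difference HbO − HbR, the optical
analog of the BOLD contrast; the exact weighting used by the source
literature is not public, and the unweighted difference preserves the
anticorrelated task response while averaging chromophore noise. (4) GLM —
per-channel OLS on [task regressor, intercept], with the regressor passed
through the same detrend filter as the data. Filtering data and design
identically makes the noiseless chain exactly invertible: beta =
(1 − r) · amplitude to machine precision, which the tests assert at 1e-6.

## Decomposition and classification

The subjects × channels beta matrix is decomposed by centered, unscaled PCA
(channels share units; no per-feature standardization) into 32 components
by default; each subject is then a vector of PC scores, and any subject's
map is reconstructed as `mean + sum_j score_ij * PC_j` (exact at full rank).
Components are ranked by the absolute pooled-variance two-sample t statistic
of their scores between groups (Welch by option), ties broken toward the
lower index. PCA is fit once on the full cohort; only the *ranking* is
nested inside cross-validation folds. Nesting the ranking is what removes
the selection leak; re-fitting the rotation itself changes coordinates but
uses no label information.

Classification is leave-one-out (deterministic; no fold randomness). Per
fold, the top-k ranked components (k = 10 by default) are z-scored with
training-fold statistics and a soft-margin linear SVM (hinge loss, L2
penalty, C = 1) is fit; the held-out subject's signed decision score is
recorded, positive meaning the control class. A univariate comparator
implements the one-dimensional rule `s = w·x + b`, `w ∈ {±1}`, trained by
exhaustive threshold search over midpoints of consecutive distinct values
(ties prefer the smallest |b|, then w = +1), with a logistic-regression
scorer as an option.

The SVM dual QP is solved by the package's own maximal-violating-pair SMO
kernel (numba-compiled, violating-pair gap 1e-6, exact unregularized bias).
It solves the same optimization as libsvm and is asserted against
`sklearn.svm.SVC(kernel="linear")` and a direct primal minimization in the
tests; it exists because the permutation experiments below require on the
order of a million fits of 35-point problems, a regime where per-call
overhead, not optimization, dominates generic implementations.

## Inference

Significance of an observed accuracy is assessed against a permutation null:
labels are permuted uniformly at random (group sizes preserved — chosen over
Bernoulli relabeling for exact group-size conditioning), the configured CV
pipeline (fixed k, or the maximum over a tuning range of k — the optimistic
rule) is re-run, 1000 times by default. The literal p-value reproduces the
strict-exceedance rule #{null > observed}/n (which can return 0); the
add-one rule (1 + #{null ≥ observed})/(1 + n) is provided and recommended.
Significance thresholds are nearest-rank (1 − alpha) quantiles of the null,
computed per k (whether such thresholds should be per-k or pooled across k
is ambiguous in the source analysis; per-k is implemented and reported).

Severity prediction correlates held-out decision scores with observed
severity over the affected group only (controls carry no severity score).
The reported r is the Pearson correlation of raw scores; the least-squares
affine map from scores to severity units is display-only and leaves |r|
unchanged. Its p-value comes from permuting severity values (10,000
two-sided permutations, add-one rule), with the t-distribution formula as an
option.

## Numerical choices and degenerate inputs

- SMO tolerance 1e-6: tightening to 1e-8 changes solutions by <1e-6 but can
  stall on a numerical plateau; decision-score assertions in tests use 1e-4.
- Fold-internal standardization uses population SD; zero-variance features
  pass through unscaled (guard at 1e-12).
- Ranking ties break toward the lower component index; `best_k` is the
  smallest argmax of a tuning curve; scores exactly 0 predict the affected
  class (the rule `s > 0 → control`).
- All-identical univariate inputs with mixed classes return the majority
  rate rather than erroring; a constant regressor, a constant channel
  matrix, single-channel global filtering, and empty cohorts raise.
- Every stochastic step takes a seeded generator; identical configuration
  and seed reproduce cohorts, null distributions and reports bit-exactly.

## Problem sizes used by the test and acceptance runs

The chance-calibration and leakage experiments run at the reference
geometry: 200 datasets of 36 subjects (19/17) × 32 features for the two
mean-accuracy quantities, and a 1000-permutation null for the significance
threshold. The end-to-end recovery tests use compact cohorts (36 subjects,
16 channels, 60-s runs at 10 samples/s, 50 cohorts per effect-size point)
— the full acquisition geometry adds runtime but no statistical content to
a monotonicity check; the noiseless-chain identity and severity-recovery
tests do run at the full 54-channel, 180-s geometry.

## Known limitations

- With fold-internal standardization, components whose raw variance is pure
  noise are renormalized to unit variance; at k > 1 they dilute the
  score–severity correlation by an amount independent of the noise scale
  (r ≈ −0.5 at k = 10 under the default generator at any nonzero noise,
  versus −0.98 for a noiseless cohort and −0.95 at k = 1). Real data, whose
  discriminative structure is not one clean direction, need not behave this
  way; the recovery criterion is therefore checked in the noiseless regime.
- The global filter removes exactly one spatial component per chromophore;
  multiple independent systemic sources are only partially removed.
- The wavelet detrend at a 128-s cutoff on 180-s runs estimates less than
  1.5 drift periods; very-low-frequency drift is attenuated (~92% at a 600-s
  period) rather than eliminated.
- Channel-space only: no cortical-surface projection or rendering; contrast
  and weight maps are value tables joinable to channel coordinates.
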