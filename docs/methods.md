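# Methods

This note records the models, numerical choices and known limitations of
the package, in the order the pipeline runs.

## Preprocessing

Raw intensities are floored at 1 and log2-transformed; the floor makes the
transform safe for near-zero background spots and maps them to 0. The
transform is monotone, and re-flooring already-floored data is a no-op.

Covariate correction fits, per feature, a robust linear regression of the
log2 value on age (years, continuous) and gender (0/1 indicator, reference
level = first alphabetically, i.e. F). The estimator is Huber IRLS with
tuning constant 1.345 and scale estimated by re-scaled MAD (statsmodels
`RLM`), iterated to a coefficient-change tolerance of 1e-8 or 50
iterations. The corrected value is intercept + residual, algebraically
`observed − age_coef·age − gender_coef·gender`. Choices worth knowing:

* the fit uses all retained samples jointly (no per-diagnosis
  stratification) and, by default, runs after restricting to the AD and
  control diagnoses; a flag (`correct_before_filter`) swaps the order;
* samples with missing age or gender are kept but left uncorrected, and
  features whose fit degenerates (no covariate variation, or a zero-MAD
  constant feature) are passed through unchanged and flagged — candidate
  markers are never silently dropped;
* because the corrected value is anchored at the *intercept* (the fitted
  value at age 0), slope-estimation noise on a high-variance feature moves
  the whole corrected feature by a location offset of order
  `SE(age_coef) × mean age`. This is intrinsic to the intercept+residual
  convention; it is harmless downstream because the SVM standardizes
  features and the banded thresholds are fitted to the corrected data, but
  corrected values should not be compared to raw-scale reference ranges.

## Classifier and scoring

One fixed SVM configuration is used everywhere: C-classification, RBF
kernel, cost 1, γ = 1/p for a p-feature panel, features standardized by
training-set mean and standard deviation with denominator n−1 (the R
convention, which the array-analysis tooling this pipeline mirrors uses; a
zero-variance feature gets scale 1). libsvm via scikit-learn is the solver
(tolerance 1e-3). Inside every LOOCV fold the standardization statistics
and γ are re-resolved from that fold's training samples only, so no
information leaks from the held-out sample. Training uses scikit-learn's
low-level libsvm bindings to avoid per-fit estimator overhead (the greedy
search needs ~10⁶ fits of 90-sample problems); a test pins exact agreement
of predictions and decision scores with the public `SVC` estimator, and
the public estimator is the automatic fallback if the low-level module is
unavailable.

Decision scores are oriented so that positive means AD; the orientation is
calibrated per fit against the model's own training predictions, which is
robust to the solver's internal label-ordering conventions.

## Forward selection

Both searches score candidate panels by LOOCV accuracy and admit a feature
only if the score improves by strictly more than the threshold (default 0),
so a tie never extends a panel — with duplicated features this provably
terminates, since a duplicate adds no information (γ rescaling by 1/p makes
the kernel on a duplicated pair identical to the single feature's kernel).
Equal-best candidates in SVMFS resolve to the lowest original column index;
single-feature ranking is a stable sort. SVMTFS by default stops at the
first non-improving ranked feature; a `skip_non_improving` flag instead
passes over it and tries the next, for users who read the ranking-walk
variant permissively. The selection LOOCV is computed on the full discovery
cohort, which embeds the usual wrapper-selection optimism; nested
cross-validation is deliberately out of scope, and the repeated-split
evaluation plus cross-cohort validation are the intended honesty checks.

## Evaluation battery

`metrics_from_counts` defines FDR and FOR as the confusion-matrix
complements 1−PPV and 1−NPV (rates among positive and negative calls) —
not multiple-testing quantities. Ratios with zero denominators are NaN and
are excluded per metric from repeat averages, with the exclusion count
logged. AUC is the Mann–Whitney rank statistic with half-credit for ties;
the emitted ROC point list integrates (trapezoid) to the same number, and
both facts are asserted in tests against brute-force pair counting.

`repeated_split_cv` draws the configured per-class training counts without
replacement (defaults 30+30, 5000 repeats; the validation-cohort default is
20+20), tests on the remainder, and spawns one RNG substream per repeat
from the master seed — so repeat k is identical whether 200 or 5000 repeats
are requested, and runs are byte-reproducible from the seed.

Cross-cohort validation trains once on the full discovery cohort and
predicts every sample of the second cohort; panel features are matched by
gene symbol first (the cohorts may be different platforms), falling back to
probe id, and ambiguity (several probes for one gene) resolves to the first
probe with a log note.

`fit_banded` searches all interval rules "inside (lower, upper] ⇒ healthy"
with thresholds at midpoints of sorted distinct values plus ±∞, maximizing
accuracy; ties prefer the widest interval, then the smallest lower
threshold. The family includes both single-threshold orientations and the
trivial all-healthy/all-AD rules (empty interval), so the interval optimum
can never fall below the best single threshold. A marker is called banded
when the interval beats the best single threshold by more than a margin
(default 0.05). Boundary values are assigned to healthy; the data never
sit exactly on a threshold because thresholds are midpoints.

## Synthetic cohorts

The generator emulates the data structure the pipeline assumes, with
defaults chosen as one coherent study condition:

* cohort sizes 50 AD / 40 healthy (discovery) and 36 / 57 (validation);
* 200 uninformative features, iid Gaussian in log2 space
  (mean 1.645, sd 1.0, class-independent), which puts ≈5% of raw noise
  values below 1 so the floor rule is genuinely exercised;
* two planted banded markers: healthy values are a truncated normal inside
  center ± halfwidth (6.0 ± 0.5 log2 units, sd = halfwidth/2); AD values
  sit at distance halfwidth + flank_gap (gap 0.5) on a low or high flank
  with bounded within-flank noise (sd 0.2, uniform on ±√3·sd drawn through
  a Gaussian copula). The flank is one latent variable shared by all
  markers (low with probability 0.5), so planted markers are co-banded;
* the target AD-group Pearson correlation between planted markers
  (default 0.99) is induced in closed form: the two-point flank mixture
  contributes μᵢμⱼ·Var(flank) to each covariance, and the residual is
  assigned to the within-flank noise correlation, solved exactly from the
  mixture algebra (including the confounder variance, below) and mapped to
  the copula's latent Gaussian scale by ρ_z = 2·sin(π·ρ/6). Infeasible
  targets (|ρ| > 1 or a non-PSD matrix) raise before sampling — note that
  targets refer to the *observed* values, so heavy confounding lowers the
  attainable range. Because the within-flank noise is bounded, AD values
  are strictly outside the healthy band whenever flank_gap > √3·sd (true
  at the defaults), making a planted marker exactly separable — which is
  also why the defaults land the repeated-split metrics in the
  mid-to-high-90s rather than lower;
* a `three_marker()` preset plants two positively and one negatively
  loaded marker with pairwise targets (+0.99, −0.95, −0.94); it uses a
  wider gap (0.75) and sd 0.3 because the weakest target must stay above
  the mixture's feasibility floor (μ²−σ²)/(μ²+σ²);
* optional one-sided markers (AD shifted by an effect size, default 1.5
  log2 units) model the classical single-threshold pattern;
* per-feature confounding: age slopes ~ N(0, 0.003 log2/year) applied to
  age − 75 (centered, so planted geometry sits where specified) and gender
  offsets ~ N(0, 0.05 log2) on the M indicator — the exact covariate coding
  the correction model uses, so the correction loop closes;
* the validation cohort applies a location/scale shift about each
  feature's generating center (defaults +0.25, ×1.5 in log2 space) *after*
  sampling, so runs with the same seed are common-random-number comparable
  across shift settings (this makes cross-cohort degradation monotone in
  the shift, sample by sample);
* grouped cohorts split the class sizes evenly across groups and plant
  marker effects only in designated signal groups, with the feature layout
  and confounder slopes shared across groups.

What the generator does **not** emulate: correlated noise among
uninformative features, platform-specific spot artifacts, age–diagnosis
confounding (ages are independent of class), missing values, and any
normalization pipeline differences beyond the location/scale shift. Tests
passing on these cohorts therefore demonstrate the pipeline's correctness
and its behavior under the assumed structure — not performance on real
serum arrays.

## Problem sizes and numerics

The test suite and the acceptance script run the full default geometry
(202 features × 90 samples) for selection and 5000-repeat resampling for
evaluation; recovery-rate style statements use 10–20 independent cohorts.
Ranking ties are resolved stably; all Monte-Carlo tolerances in tests were
set from the analytical noise scale of the quantity under test (e.g.
Pearson-r sampling error at n = 50) before asserting, and seeds are fixed
throughout.

## Pipeline and provenance

`run_discovery`/`run_validation` execute the stages above from a single
validated config (unknown keys are errors). One master seed derives the
generator seed and every resampling stream; the manifest (config hash,
seed, package versions) plus the TSV/JSON artifacts make every reported
number reproducible from the run directory alone. A failed stage leaves a
`FAILED` marker naming the stage alongside any partial outputs.
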