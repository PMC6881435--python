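# Methods

This note documents the statistical model behind each pipeline stage, the
defaults and why they were chosen, what the synthetic-data generator does
and does not emulate, and the numerical choices that a maintainer would
otherwise have to reverse-engineer from the code.

## Synthetic studies (`simdata`)

The generator emulates a two-class untargeted plasma lipidomics cohort with
a pooled-QC acquisition design. All noise is multiplicative (log-normal),
the standard error structure for LC-MS intensities; coefficients of
variation given on the natural scale are converted exactly to log-scale
sigma via σ = √log(1 + cv²).

Per feature j and study sample i:

    log x_ij = μ_j + (y_i − ½)·δ_j + β_j·(log a_i − mean log a)
             + ε_bio + order_i·log(1 + drift) + ε_tech

* μ_j ~ N(11, 1.8²): base log abundances spanning ~4 decades.
* δ_j = ±(effect_size)·σ_total for the planted discriminatory features
  (alternating up-in-bacterial / up-in-viral), 0 otherwise, with
  σ_total = √(σ_bio² + σ_tech²). `effect_size` is therefore a standardized
  (Cohen's d) class shift; default 1.0, matching a realistic single-lipid
  discriminator (point-biserial r ≈ 0.45, single-feature AUC ≈ 0.76).
* Ages are log-uniform on 1–102 months (median ≈ 10, mirroring a paediatric
  febrile cohort); sex is Bernoulli(½). The age slope β_j of the planted
  age-associated features is calibrated analytically so that an
  above/below-median-age split shows a standardized shift of
  `age_effect_size` on the observed scale — i.e. including the variance the
  age term itself adds. A feasibility guard rejects shifts a uniform
  covariate cannot produce.
* SQC = per-feature mean of the study samples on the natural scale (what
  pooling physically does) with technical noise only; the dilution series
  scales the SQC level by each relative concentration except for the
  planted artifact fraction (default 10%), which stays flat — these are the
  features the dilution filter exists to remove. LTR samples are an
  independent pool. Drift multiplies every injection by (1+drift)^order
  (default 0.1%/injection ≈ 7% across a run).
* Injection layout: half of each dilution replicate set at the start and
  end of the run; SQC and LTR alternate after every five study injections,
  reproducing the "QC every ten study samples, LTR offset by five" spacing.

Not emulated: missing values (off by default; the pipeline assumes the
filtered table is complete), feature-feature correlation blocks
(co-regulated lipid classes), retention-time structure, adducts/isotopes,
and batch boundaries. Because features are independent here, real data —
where lipid classes are strongly correlated — will show *higher* Q² for
the same per-feature effect and *easier* multivariate separation; passing
tests on this generator are therefore conservative about multivariate
detectability, but say nothing about annotation quality or drift
correction, which the pipeline does not attempt.

## QC filtering (`qc`)

CV is sd/mean of raw (pre-log) intensities across the undiluted SQC
injections only; dilution linearity is the Pearson correlation (Spearman
behind a config switch) of raw intensity with relative concentration across
all dilution injections. Thresholds are strict inequalities (CV < 0.15,
r > 0.9). Undefined values (zero-mean feature, constant dilution response)
drop the feature. The two filters are independent, hence order-free, and
study-sample values can never influence retention.

Sample outliers: Hotelling T² on the first k = 2 PCA scores of the
pareto-scaled study matrix, compared with the exact in-sample limit
T² ≤ (n−1)²/n · Beta₁₋α(k/2, (n−k−1)/2). The Beta form (not the F form
for future observations) is used because the tested samples are the same
ones the model was fit on, making the nominal level exact. Flags are
advisory: removal happens only for sample ids explicitly listed in the
pipeline config, a deliberate two-pass (flag → inspect → confirm) design
so that no sample silently disappears.

## Multivariate models (`multivariate`)

Pareto scaling (x − mean)/√sd is the metabolomics default: it de-weights
high-abundance lipids without blowing up noise features the way unit
variance scaling does. Zero-variance columns are rejected by name.

OPLS-DA uses the orthogonal-deflation scheme: w ∝ Xᵀy (unit norm); for
each orthogonal component the part of the current X-loading orthogonal to
w is extracted, its score/loading pair deflated from X; the predictive
component is then fit on the deflated matrix. n_ortho defaults to 1 — the
minimal O-PLS-DA — and with n_ortho = 0 the model reduces exactly to
single-component PLS regression (verified against scikit-learn to 1e-8).
R²X is the modelled fraction of the scaled matrix's sum of squares and
decomposes exactly (modelled + residual = total).

Q² = 1 − PRESS/SSY over 7-fold stratified cross-validation (the SIMCA
convention). Folds are assigned by one global random permutation with
round-robin dealing within each class, which makes the assignment a
function of the class *partition* only — so relabelling
bacterial ↔ viral provably cannot change Q² or the permutation p-value.
The scaling is computed once on the full matrix, not per fold; at these
sample sizes the difference is negligible and determinism is simpler to
audit. Under a pure-noise null with p ≫ n the inner regression coefficient
shrinks like 1/√p, so null Q² concentrates near −n/p with spread ≈ 0.1:
slightly negative on average but positive in a substantial minority of
draws. Q²'s *sign* is therefore not a reliable null/alternative separator
for very wide matrices — which is exactly why model validity additionally
requires the permutation test.

The permutation test refits model + Q² under n_perm (default 999) label
permutations and reports the add-one estimator
p = (1 + #{Q²_perm ≥ Q²_obs})/(1 + n_perm) — unbiased under
exchangeability and never zero. Validity = (Q² > 0 and p < 0.05); an
invalid model aborts the signature stages, so degenerate data cannot yield
a signature.

S-plot: x-axis p1 is the covariance loading normalized to a unit-length
loading vector; y-axis p(corr) is the Pearson correlation of each scaled
column with the predictive score. The unit-norm choice makes the fixed
0.05 cutoff transferable across feature-set sizes (typical null loadings
scale as 1/√p); on default synthetic cohorts it shortlists ~20–30 of
~3600 features. Shortlisting at |p1| ≥ 0.05 with a planted effect of one
biological SD recovers roughly half of the planted features at ~70%
precision; this is near the information-theoretic ceiling — with n = 40
the null spread of any per-feature association statistic (≈ 1/√39)
overlaps a d = 1 effect too much for any rule to reach high recall *and*
high precision against thousands of null features. Strong effects
(d ≳ 2.5) are recovered nearly completely.

## Selection (`selection`)

The covariate screen is a feature-wise equal-variance two-group t-test on
log abundances (class, sex, or median-age split) with Benjamini–Hochberg
FDR control; an optional empirical-Bayes variance squeeze (scaled-F moment
fit, as in moderated-t pipelines) is off by default because on
shortlist-sized feature sets (~30) with n ≈ 40 the moderation is minor.

FS-PLS: columns are z-scored internally; each step fits one univariate
model per remaining (deflated) column — logistic by default, matching the
binary class descriptor — picks the smallest Wald p (ties: higher
log-likelihood, then column order), stops if that p exceeds `p_thresh`
(default 0.01) or `max_features` (10) is reached, then deflates all
remaining columns by the selected column's direction. Deflated columns
with norm below 1e-8·√n are unselectable, which makes duplicated columns
provably one-shot. Perfect separation is detected (non-convergence or
|slope| > 15 on standardized columns) and handled by Firth's penalized
likelihood, recorded per step. Final coefficients come from one joint
(Firth-guarded) refit on the originally-scaled selected columns.

Two design points deserve emphasis. First, the step test judges each
candidate against the raw response after deflating only the predictor
side; a variant that additionally conditions on the already-selected model
via a GLM offset (a full partial-association test) is available as
`condition_on_selected=True`. The default is the more conservative rule:
it admits later features less readily, which on synthetic cohorts keeps
signatures essentially free of false features at the cost of usually
selecting 1–2 of 3 planted proxies. Second, when several features carry
the *same* class signal, their step-wise (residual) effects are
necessarily attenuated — three mutually uncorrelated features each at
d = 1.5 for one binary response are mathematically impossible (the squared
class correlations would sum past 1) — so a forward selection stopping at
p ≤ 0.01 genuinely should not always take all redundant proxies; this is
the method working as intended, not a power defect.

The robustness check re-runs FS-PLS on the shortlist minus
screen-significant features and reports whether the selected sets are
identical, the standard control that a signature is not an age or sex
artifact.

## Evaluation (`evaluate`)

DRS = Σ z(up-in-bacterial) − Σ z(up-in-viral) over study-sample z-scores
of log abundances; the z-scoring makes it invariant to per-feature affine
rescaling. This generalizes the published two-marker disease-risk-score
construction; the FS-PLS linear predictor is available separately via the
signature weights, and the DRS is the quantity evaluated by ROC.

AUC is computed by midrank Mann–Whitney with half credit for ties — the
exact concordance probability, verified against an exhaustive pair-count
oracle — so AUC(s) + AUC(−s) = 1 holds identically. ROC point sets come
from the sorted distinct thresholds. Confidence intervals are
class-stratified percentile bootstrap (default 500 draws; every draw keeps
both classes by construction); percentile rather than BCa because it is
the simplest defensible default, and measured coverage for a binormal
AUC of 0.8 at n = 20+20 is ~94–95%. Single-feature ranking folds AUC to
≥ 0.5 and records the orientation, since a consistently *lower* abundance
is as diagnostic as a higher one.

## Pipeline (`pipeline`)

Stage order: QC → confirmed outlier removal → log transform (natural log,
pseudocount 1.0 — negligible at LC-MS intensity scales; the transform can
be disabled to mimic raw-abundance analysis) → pareto scaling → PCA
summary → OPLS-DA + permutation validation (abort signature stages if
invalid) → S-plot shortlist → age/sex screen → FS-PLS + robustness check →
DRS + bootstrap ROC. Every stage seed derives deterministically from the
single config seed; re-running an identical config reproduces the report
byte for byte. The run report carries feature counts per stage
(monotonically non-increasing by construction), all model metrics, the
signature with directions and weights, and warnings for any skipped stage.

## Problem sizes in the test suite

The suite exercises the generator at its default size (4000 features,
20+20 samples) for end-to-end checks (20 seeds at 999 permutations),
and smaller matrices (40×50 to 40×500) for calibration studies: 100-repeat
permutation-level checks, 100-seed null-Q² sign rates, 200-seed FS-PLS
null runs and 200-repeat bootstrap coverage. These sizes give Monte-Carlo
standard errors comfortably below the asserted margins while keeping the
default test run to a few minutes.

## Known limitations

* No drift correction, batch correction or retention-time alignment — the
  pipeline assumes a single well-behaved run, as its QC design implies.
* The S-plot cutoff operates on one fixed normalization; data scaled
  differently upstream would need a re-derived cutoff.
* Logistic Wald p-values are first-order; for n ≲ 20 per class the exact
  conditional test would be preferable but is not implemented.
* The generator's independent-feature assumption understates multivariate
  detectability relative to real, correlated lipidomes (see above).
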