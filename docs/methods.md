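# Methods

This note records the statistical model the package implements, the
defaults and why they are what they are, the numerical choices, and what
the synthetic generator does and does not emulate.

## Replicate-variance law and QC

Technical triplicates of a qRT-PCR assay are modelled with iid normal
replicate noise. The package adopts the scale convention
`s² / σ² ~ χ²(ν=2)` for the n−1 sample variance of a triplicate, with CDF
`F(s²) = 1 − exp(−s²/(2σ²))`. Under iid replicate noise of SD `σ_rep,raw`,
the textbook law is `(n−1) s² / σ_rep,raw² ~ χ²(2)`, so the convention's σ
equals `σ_rep,raw / √2`; the synthetic generator draws replicate noise with
SD `σ·√2` so that its variances follow the convention exactly and the QC
fit recovers the configured σ directly. This factor changes what σ *means*
(it is the law's scale, not the per-replicate SD) and is applied
consistently everywhere.

A consequence worth stating: under this law both `⟨s²⟩^{1/2}` and
`[⟨s⁴⟩−⟨s²⟩²]^{1/4}` converge to `√2·σ`, and their mutual agreement — not
their agreement with σ itself — is the internal-consistency check the
moment summary provides. The tests assert the `√2` relation on generated
data.

σ is estimated by minimizing the two-sided K-S distance D between the
empirical CDF of the variances and the law. Rationale: the estimator must
be robust to the very outliers the fit is used to detect; the parametric
`σ̂ = √(⟨s²⟩/2)` is not (one wild triplicate moves it arbitrarily), and a
test asserts the K-S fit beats it on a spiked sample. The minimizer runs a
512-point geometric pre-scan over `[10⁻⁴·max(s), 10·max(s)]` followed by
golden-section refinement to 10⁻⁶, ties toward the smaller σ; D(σ) is
piecewise-smooth and can have shallow secondary dips, which the pre-scan
steps over, and a test pins the result to a 10⁻⁴-step brute-force grid
within 10⁻³. The goodness-of-fit p-value uses the asymptotic Kolmogorov
distribution at `√n·D` *without* correcting for the estimated scale; it is
therefore mildly anti-conservative and is used as a descriptive fit
indicator, not as a gate.

The outlier rule flags a triplicate when `s > σ_max = √(−2 ln α)·σ`
(≈ 2.448 σ at the default α = 0.05). α is exactly the type-I false-alarm
rate on clean data; the calibration is asserted at n = 10⁴. An equivalent
F-test formulation of the same rule exists and is not implemented
separately. Flagged triplicates are excluded from all downstream fitting;
a sample whose *reference* triplicate is flagged loses its normalized
measures and is reported, not silently dropped.

## Normalization and session audit

`dx_A = x_A − x_ref` per sample. An additive shift applied to all assays of
a session cancels exactly (property-tested); this is the entire rationale
for single-reference normalization here. Multi-reference (geometric-mean)
normalization is out of scope. The session audit reports per-(session,
class) mean/SD/SE and between-session differences with SEs combined in
quadrature (sessions independent); "stable" means `|Δ| < 2·SE` (p > 0.05
under normality). Audits are per class only — pooled audits would confound
class imbalance with session bias. Difference rows use only samples
possessing both assays involved. Note the 2·SE rule falsely flags ~5% of
truly stable differences; the test suite therefore checks its behaviour as
a calibration across seeds.

## Class models and measure screening

Per-class Gaussians use the sample mean and n−1 SD, with normal-theory
standard errors `σ/√N` and `σ/√(2(N−1))`. Normality is screened with
Shapiro–Wilk (off the shelf from scipy; constant input raises a degenerate
error rather than returning the test's undefined statistic). Class
separation uses the two-sided Welch t-test, variance per group,
Welch–Satterthwaite degrees of freedom, t > 0 when the target mean is
higher. A measure with Welch p ≥ 0.05 triggers a warning — not an error —
when summarized: such measures (the helper and the raw reference in the
study conditions) are legitimate inputs to normalization and noise
reduction but poor discriminators on their own.

## Threshold, odds, uncertainty

The quadratic threshold equation and its coefficients are given in the
README. Numerical choices:

- **Root selection.** Prefer the real root inside `[μ_V, μ_T]`; if none or
  both qualify, take the root nearest the midpoint of the means. The
  decision boundary relevant to classification lies between the means for
  balanced and near-balanced priors; the far root is the spurious crossing
  of the unequal-variance tails.
- **η-degeneracy.** `|η| < 10⁻¹²·max(1/σ_T², 1/σ_V²)` switches to the
  linear solution `χ = (γ − 2 ln(p_T/p_V))/(2β)`, avoiding catastrophic
  cancellation in the quadratic formula when the class variances are equal.
- **Orientation.** A measure whose target mean lies below the versus mean
  is negated before fitting (orientation −1), exactly as one would classify
  on the negated reference; all public functions accept raw values and
  apply the stored orientation.
- **Boundary.** `y = χ` is a target call with odds exactly 1 (the rule's
  `≥`). Odds-band edges are closed on the reliable side: odds exactly 9
  count as high-reliability.
- **χ SE.** First-order propagation over (μ_T, σ_T, μ_V, σ_V) with central
  finite differences, step `10⁻⁴ ×` each parameter's SE, contributions
  combined in quadrature assuming independence. Finite differences avoid
  hand-derived implicit differentiation of the root; at these steps the FD
  error is far below the propagated uncertainty.
- **Accuracy SE.** Monte-Carlo propagation (default 10⁵ draws, seeded):
  draw the four parameters from independent normals at their SEs, re-solve
  χ, recompute p_c, report the SD. p_c is flat in χ at the optimum, which
  makes chained first-order propagation through χ fragile; the MC route is
  insensitive to that. Draws with non-positive SDs or no real root are
  rejected (negligible at realistic SEs).
- **Priors.** Balanced by default (`p_T/p_V = 1`), overridable; priors are
  user inputs throughout — the package does not estimate epidemiological
  priors.

Bias outliers: given a class Gaussian, `t = (y − μ)/σ` with ν = n−1 gives
the one-tailed probability of a value at least as displaced from the class
mean; p below the configured level (default 1%) flags the sample. The
prediction-interval variant `σ√(1+1/n)` in the denominator is exposed as an
option; the plain form is the default.

Confusion reporting: samples are tallied into true-class × odds-band cells.
`accuracy` counts all correct calls over all classified samples;
`high_reliability_accuracy` counts only correct calls with predicted-class
odds ≥ 9, still over all classified samples — the fraction of the cohort
receiving a call that is both reliable and right.

## Noise reduction

Closed form `c = −r σ_a/σ_b` with the *overall* (both classes pooled)
Pearson r, and σ_a, σ_b the size-weighted mixture SDs including the
between-class mean spread. With the study-condition class statistics this
pooling reproduces the reference coefficient −0.8; a per-class alternative
is available through the per-class correlation reports since the
correlation may live mostly in one class. The numerical optimizer searches
`c ∈ [−5, 5]` at step 0.01 with golden-section refinement (deterministic,
no seed), objective |Welch t| by default or model-predicted accuracy; a
test pins it to an independent brute-force grid. The variance-reduction law
`σ → √(1−r²)·σ_a` and the r = 0 detriment law are property-tested. ROC AUC
comes from the rank formulation (equivalent to trapezoidal with midpoint
ties), target class positive; AUC < 0.5 warns about orientation instead of
silently flipping. Multi-helper admixtures, PCA and SVM combinations are
out of scope.

## Synthetic cohorts

The generator draws, per sample: a class; latent normalized deltas of the
two markers from the class's bivariate normal (configured means, SDs,
correlation); a latent reference level from the class's Gaussian; raw
marker levels as delta + reference (markers share the reference's
sample-to-sample variation — the raw-measure joint law is not otherwise
pinned down, and this is one consistent choice); per-assay additive session
offsets; and three replicates with noise SD `σ_rep·√2` (see above).
Variability outliers multiply one triplicate's noise by an inflation
factor; bias outliers shift the discriminating marker's three replicates
jointly by a configured amount with random sign. One seeded stream is split
per sample in sample order, so cohorts are bit-reproducible.

Defaults are the reference study conditions: class sizes 18/15; deltas
(1.7, 2.2)/(−4.6, 2.4) for the discriminating marker and
(−6.5, 1.4)/(−6.6, 2.4) for the helper; reference (25.0, 1.4)/(25.8, 1.9);
within-class correlations 0.49/0.75; replicate scales 0.25/0.19/0.19; two
sessions with offsets of 3.0 (helper marker), 2.4 (reference) and 2.7 Ct
(discriminating marker — unreported in the audited conditions, chosen
midway between the two observed offsets); injection rates 0 with
inflation 5 and bias shift 6 Ct available as dials. Test problem sizes are
scaled to the property being checked: 10⁴ triplicates for rate
calibrations, 10³–10⁴ per class for recovery, the study sizes (18/15) for
screening behaviour.

`study_like_cohort()` is a *deterministic synthetic stand-in* for the
reference study dataset, which is not distributed with the package. It
moment-matches exactly what the analysis consumes — per-class sample
means/SDs and within-class correlations of the normalized measures, the
reference Gaussians, set sizes (39/37/39), four inflated reference
triplicates — and places clean replicate SDs at stratified quantiles of the
variance law (compressed below the α = 0.05 threshold so exactly the
injected outliers flag). What it does **not** reproduce: the individual
sample values of the real cohort, hence per-sample confusion counts, the
exact training AUC, and the independent 9-sample test set. Pipeline results
on the stand-in (e.g. training accuracy, AUC, the empirical overall
correlation) therefore agree with the reference numbers only to within
sampling-level tolerances, and the tests assert them at such tolerances.
More generally, passing tests on generated cohorts validate the method
under its own assumptions (normality, additive session offsets, the χ²(2)
replicate law); they cannot certify behaviour on real data that violates
them — heavy-tailed replicate noise, amplification-efficiency drift, or
plate effects are all outside the generative model.

## Known limitations

- The K-S p-value ignores the estimated-parameter effect
  (anti-conservative); the variance law itself is an empirical convention.
- One scalar measure at a time; no full-covariance discriminant, no
  cross-validation machinery (evaluation is training-set plus an
  independent set, when one exists).
- The session audit requires ≥ 2 sessions with ≥ 2 samples per cell and
  treats sessions as independent.
- Accuracy SEs assume independent normal parameter uncertainties; with
  n ≈ 15–20 per class these SEs are themselves rough.
- Vendor instrument exports and plate-layout handling are out of scope; the
  input is the documented TSV schema.
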