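# mirbayes

Two-class Bayesian classification of small qRT-PCR miRNA panels, with the
statistical plumbing that published classifiers usually leave out: replicate
quality control with a fitted variance law, reference normalization,
per-class Gaussian modelling with explicit parameter uncertainty, an
optimal decision threshold with a propagated standard error, posterior-odds
reliability bands, bias-outlier detection, and noise reduction of the
discriminating score through a correlated helper measure.

The worked setting is the discrimination of two lung-tumor histologies —
adenocarcinoma (*ADC*, the **target** class) versus squamous cell carcinoma
(*SQC*, the **versus** class) — from Ct triplicates of miR-205 (the
discriminating marker), miR-21 (the helper) and snRNA U6 (the reference).
Everything is generic over assay names and class labels; the tool is aimed
at anyone building a threshold classifier from a handful of qRT-PCR assays
and wanting honest uncertainties on it.

## The model

**Replicate QC.** The sample variance s² of a triplicate follows a scaled
chi-square law, `s²/σ² ~ χ²(ν=2)`, with CDF `F(s²) = 1 − exp(−s²/(2σ²))`.
The per-assay scale σ is fitted by minimizing the Kolmogorov–Smirnov
statistic D — robust to the very outliers being hunted. A triplicate is a
*variability outlier* when its SD exceeds

```
σ_max = √(−2 ln α) · σ  ≈ 2.448 σ   (α = 0.05)
```

making α exactly the false-alarm rate on clean data.

**Normalization.** Raw Ct means drift additively between experimental
sessions; subtracting the reference assay cancels the drift:
`Δx_205 = x_205 − x_U6`, `Δx_21 = x_21 − x_U6`. A session audit verifies
that raw measures are unstable across sessions while the deltas are not.

**The classifier.** Each class of a scalar measure y is Gaussian,
`T ~ N(μ_T, σ_T²)`, `V ~ N(μ_V, σ_V²)`; the rule is `y ≥ χ → target`. The
accuracy `p_c = p_T H + p_V C`, with `H = Φ((μ_T−χ)/σ_T)` and
`C = Φ((χ−μ_V)/σ_V)`, is maximized by the root of

```
η χ² − 2 β χ + γ − 2 ln(p_T/p_V) = 0
η = 1/σ_T² − 1/σ_V²,  β = μ_T/σ_T² − μ_V/σ_V²,
γ = μ_T²/σ_T² − μ_V²/σ_V² + 2 ln(σ_T/σ_V)
```

The posterior odds of a new sample,
`ρ = exp[−½(η y² − 2 β y + γ − 2 ln(p_T/p_V))]`, are 1 exactly at χ; the
thresholds where ρ = 9 and ρ = 1/9 bound the high-reliability bands. χ and
the band edges carry standard errors propagated from the class-parameter
SEs (`σ/√N`, `σ/√(2(N−1))`); the predicted accuracy's SE is propagated by
Monte Carlo.

**Noise reduction.** A non-discriminating helper y_b correlated (Pearson r)
with the discriminating y_a shrinks the within-class SD via
`y = y_a + c·y_b` with `c ≈ −r σ_a/σ_b`, by the factor `√(1−r²)`, while
leaving the class-mean gap alone. The package reports the closed-form c and
a numerically optimized c\* (|Welch t| or predicted-accuracy objective),
plus before/after Welch p and ROC AUC.

## Worked example

`mirbayes.synthetic.study_like_cohort()` builds a deterministic *synthetic*
cohort whose summary structure matches the reference study conditions
(39 samples, the discriminating marker measured on 37, exact class
means/SDs/correlations, four inflated reference triplicates). Running the
full pipeline on it:

```
$ python -c "import mirbayes as mb; mb.write_cohort(mb.study_like_cohort(), 'cohort.tsv')"
$ mirbayes qc --cohort cohort.tsv --out qc.json
miR-205: sigma=0.2184 D=0.057 p=1.000 sigma_max=0.5347 outliers=0
miR-21: sigma=0.1660 D=0.056 p=1.000 sigma_max=0.4062 outliers=0
U6: sigma=0.2139 D=0.098 p=0.851 sigma_max=0.5235 outliers=4
$ mirbayes run --cohort cohort.tsv --out-dir out
measure y_opt: chi = 3.196 +- 0.409; predicted accuracy 96.2% +- 2.3%; training accuracy 97.0% (high-reliability 84.8%)
```

Reading: the K-S fit finds replicate scales near the generating values and
flags exactly the four inflated U6 triplicates (their samples then carry no
normalized measures). The pipeline normalizes, picks the admixture
coefficient for `y_opt = Δx_205 + c·Δx_21` by maximizing |Welch t|
(c\* = −0.74 here; the closed form gives −0.78), fits the class Gaussians,
and solves the threshold: a sample with y_opt ≥ 3.20 is called *target*,
with odds ≥ 9:1 outside the `3.20 ± band` region. The predicted maximum
accuracy 96.2% ± 2.3% is the Gaussian-model expectation; 97.0% is the
realized training accuracy, and 84.8% of samples get a call that is both
correct and high-reliability (odds ≥ 9:1).

From the library, the headline threshold computed from the study's printed
class statistics:

```python
>>> import mirbayes as mb
>>> from mirbayes.class_stats import ClassGaussian
>>> chi, se = mb.solve_threshold(ClassGaussian(6.9, 1.9, 18), ClassGaussian(0.7, 1.6, 15))
>>> round(chi, 1), round(se, 1)
(3.6, 0.4)
```

## Layout

```
src/mirbayes/       data_io, triplicate_qc, normalization, class_stats,
                    bayes, noise_reduction, synthetic, cli
tests/              unit + property + acceptance suites
scripts/acceptance.py
docs/methods.md     modelling assumptions, numerical choices, limitations
```
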