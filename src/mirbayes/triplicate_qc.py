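"""Replicate-variance quality control.

For each assay, the sample variances s^2 of the technical triplicates are
modelled as ``s^2 / sigma^2 ~ chi-square(nu=2)``, i.e. with cumulative
distribution::

    F(s^2; sigma) = 1 - exp(-s^2 / (2 sigma^2))

The population scale sigma is fitted by minimizing the two-sided
Kolmogorov-Smirnov statistic D between this CDF and the empirical CDF of the
observed variances. The K-S route is deliberately robust: a handful of wild
variances barely moves the fit, unlike the parametric
``sigma_hat = sqrt(mean(s^2)/2)`` estimator.

A triplicate is a *variability outlier* when its sample SD exceeds::

    sigma_max = sqrt(-2 ln alpha) * sigma          (~= 2.448 sigma at alpha=0.05)

which makes alpha exactly the rate of type-I false alarms on clean data.

Conventions inherited by the whole package: the sample SD uses the n-1
denominator, and the variance law is taken verbatim as s^2/sigma^2 ~
chi-square(2) (the textbook triplicate law is (n-1)s^2/sigma_rep^2 ~
chi-square(2), so sigma here equals the per-replicate noise SD divided by
sqrt(2); the synthetic generator applies the matching sqrt(2) factor). The
K-S p-value uses the asymptotic Kolmogorov distribution without correction
for the estimated scale and is therefore mildly anti-conservative.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy import special

from .data_io import Cohort, TriplicateRecord
from .errors import ConfigurationError, DegenerateDataError, InsufficientDataError

_GOLDEN = (math.sqrt(5.0) - 1.0) / 2.0


@dataclass(frozen=True)
class VarianceScaleFit:
    """Fitted population scale sigma for one assay's triplicate variances."""

    sigma: float
    D: float
    p_value: float
    n: int
    assay: str = ""

    def to_dict(self) -> dict:
        return {
            "assay": self.assay,
            "sigma": self.sigma,
            "D": self.D,
            "p": self.p_value,
            "n": self.n,
        }


@dataclass(frozen=True)
class QCPolicy:
    """Per-assay critical SDs sigma_max at significance level alpha."""

    alpha: float
    sigma_max: dict[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not (0.0 < self.alpha < 1.0):
            raise ConfigurationError(f"alpha must lie in (0, 1), got {self.alpha}")

    def threshold(self, assay: str) -> float:
        try:
            return self.sigma_max[assay]
        except KeyError:
            raise ConfigurationError(f"no sigma_max configured for assay {assay!r}") from None


def variance_cdf(s2: float, sigma: float):
    """CDF of the variance law: ``1 - exp(-s^2 / (2 sigma^2))``."""
    if sigma <= 0:
        raise DegenerateDataError(f"sigma must be positive, got {sigma}")
    s2 = np.asarray(s2, dtype=float)
    if np.any(s2 < 0):
        raise ValueError("variances must be non-negative")
    out = -np.expm1(-s2 / (2.0 * sigma * sigma))
    return float(out) if out.ndim == 0 else out


def ks_distance(variances: np.ndarray, sigma: float) -> float:
    """Two-sided K-S distance between the empirical CDF and the fitted law.

    ``variances`` must be sorted ascending.
    """
    n = variances.size
    f = variance_cdf(variances, sigma)
    i = np.arange(1, n + 1, dtype=float)
    d_plus = np.max(i / n - f)
    d_minus = np.max(f - (i - 1.0) / n)
    return float(max(d_plus, d_minus))


def fit_variance_scale(variances, assay: str = "", tol: float = 1e-6) -> VarianceScaleFit:
    """Fit sigma by K-S minimization over a bracketed scale range.

    The objective D(sigma) is piecewise-smooth; a coarse geometric pre-scan
    over ``[1e-4 * max(s), 10 * max(s)]`` locates the global basin and a
    golden-section refinement polishes it to ``tol``. Ties break toward the
    smaller sigma. The p-value is the asymptotic Kolmogorov survival
    probability at ``sqrt(n) * D``.
    """
    arr = np.sort(np.asarray(variances, dtype=float))
    if arr.size < 1:
        raise InsufficientDataError("need at least one variance")
    if np.any(arr < 0):
        raise ValueError("variances must be non-negative")
    if arr[-1] <= 0:
        raise DegenerateDataError("all variances are zero; scale unidentifiable")

    s_max = math.sqrt(arr[-1])
    lo, hi = 1e-4 * s_max, 10.0 * s_max

    # coarse pre-scan on a geometric grid (D can have shallow secondary dips)
    grid = np.geomspace(lo, hi, 512)
    dvals = np.array([ks_distance(arr, s) for s in grid])
    k = int(np.argmin(dvals))
    a = grid[max(k - 1, 0)]
    b = grid[min(k + 1, grid.size - 1)]

    # golden-section refinement; final tie broken toward smaller sigma
    c = b - _GOLDEN * (b - a)
    d = a + _GOLDEN * (b - a)
    fc, fd = ks_distance(arr, c), ks_distance(arr, d)
    while (b - a) > tol:
        if fc <= fd:  # "<=" pushes ties toward the left (smaller sigma)
            b, d, fd = d, c, fc
            c = b - _GOLDEN * (b - a)
            fc = ks_distance(arr, c)
        else:
            a, c, fc = c, d, fd
            d = a + _GOLDEN * (b - a)
            fd = ks_distance(arr, d)
    sigma = a if ks_distance(arr, a) <= ks_distance(arr, b) else b
    big_d = ks_distance(arr, sigma)
    p = float(special.kolmogorov(math.sqrt(arr.size) * big_d))
    return VarianceScaleFit(sigma=float(sigma), D=big_d, p_value=p, n=int(arr.size), assay=assay)


def variability_threshold(sigma: float, alpha: float) -> float:
    """Critical SD ``sigma_max = sqrt(-2 ln alpha) * sigma``."""
    if sigma <= 0:
        raise DegenerateDataError(f"sigma must be positive, got {sigma}")
    if not (0.0 < alpha <= 1.0):
        raise ValueError(f"alpha must lie in (0, 1], got {alpha}")
    return math.sqrt(-2.0 * math.log(alpha)) * sigma


def fit_qc(cohort: Cohort, alpha: float = 0.05) -> tuple[dict[str, VarianceScaleFit], QCPolicy]:
    """Fit the variance scale of every assay and derive the QC policy."""
    fits: dict[str, VarianceScaleFit] = {}
    sigma_max: dict[str, float] = {}
    for assay in cohort.assays:
        variances = [r.variance for r in cohort.by_assay(assay)]
        fits[assay] = fit_variance_scale(variances, assay=assay)
        sigma_max[assay] = variability_threshold(fits[assay].sigma, alpha)
    return fits, QCPolicy(alpha=alpha, sigma_max=sigma_max)


def flag_variability_outliers(cohort: Cohort, policy: QCPolicy) -> dict[str, list[str]]:
    """Sample ids whose triplicate SD exceeds sigma_max, per assay (sorted)."""
    flagged: dict[str, list[str]] = {}
    for assay in cohort.assays:
        threshold = policy.threshold(assay)
        ids = [r.sample_id for r in cohort.by_assay(assay) if r.sd > threshold]
        flagged[assay] = sorted(ids)
    return flagged


def apply_qc(cohort: Cohort, policy: QCPolicy) -> tuple[Cohort, dict[str, list[str]]]:
    """Drop flagged triplicates; returns the clean cohort and the exclusions."""
    flagged = flag_variability_outliers(cohort, policy)
    flagged_keys = {(sid, assay) for assay, ids in flagged.items() for sid in ids}
    keep = [r for r in cohort.records if (r.sample_id, r.assay) not in flagged_keys]
    clean = Cohort(records=keep, assays=list(cohort.assays), priors=cohort.priors)
    clean.rejected.extend(cohort.rejected)
    return clean, flagged


def variance_moment_summary(variances) -> tuple[float, float]:
    """``(<s^2>^(1/2), [<s^4> - <s^2>^2]^(1/4))`` — the RMS sample SD and the
    fourth root of the variance of the variances. Under the fitted
    chi-square(2) law both converge to ``sqrt(2) * sigma``.
    """
    arr = np.asarray(variances, dtype=float)
    if arr.size < 2:
        raise InsufficientDataError("need at least 2 variances for moment summary")
    m2 = float(np.mean(arr))
    m4 = float(np.mean(arr**2))
    spread = max(m4 - m2 * m2, 0.0)
    return math.sqrt(m2), spread**0.25


def qc_report(
    fits: dict[str, VarianceScaleFit],
    policy: QCPolicy,
    flagged: dict[str, list[str]],
) -> dict:
    """Machine-readable QC report section (per assay)."""
    return {
        assay: {
            "sigma": fit.sigma,
            "sigma_max": policy.sigma_max[assay],
            "D": fit.D,
            "p": fit.p_value,
            "n": fit.n,
            "outlier_sample_ids": sorted(flagged.get(assay, [])),
        }
        for assay, fit in fits.items()
    }


def false_alarm_rate(records: list[TriplicateRecord], sigma: float, alpha: float) -> float:
    """Fraction of triplicates flagged at the given true scale (type-I rate)."""
    threshold = variability_threshold(sigma, alpha)
    flags = [r.sd > threshold for r in records]
    return float(np.mean(flags)) if flags else 0.0
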