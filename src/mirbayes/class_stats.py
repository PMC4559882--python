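"""Per-class Gaussian fits, normality screening and class-separation tests.

The classifier machinery downstream assumes each class of a scalar measure is
normally distributed. This module estimates the per-class Gaussians
(sample mean and n-1 sample SD, with their standard errors), screens
normality with the Shapiro-Wilk test, and tests class separation with the
two-sided Welch t-test (variances estimated separately per group,
Welch-Satterthwaite degrees of freedom).
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np
from scipy import stats

from .errors import DegenerateDataError, InsufficientDataError
from .normalization import MeasureVector


@dataclass(frozen=True)
class ClassGaussian:
    """Normal model N(mu, sigma^2) of one class, fitted from n samples.

    The standard errors follow the normal-theory formulas
    ``se_mu = sigma/sqrt(n)`` and ``se_sigma = sigma/sqrt(2(n-1))``.
    """

    mu: float
    sigma: float
    n: int

    def __post_init__(self) -> None:
        if self.n < 2:
            raise InsufficientDataError(f"class Gaussian needs n >= 2, got {self.n}")
        if not self.sigma > 0:
            raise DegenerateDataError("class SD must be strictly positive")

    @property
    def se_mu(self) -> float:
        return self.sigma / math.sqrt(self.n)

    @property
    def se_sigma(self) -> float:
        return self.sigma / math.sqrt(2 * (self.n - 1))

    def to_dict(self) -> dict:
        return {
            "mu": self.mu,
            "sigma": self.sigma,
            "n": self.n,
            "se_mu": self.se_mu,
            "se_sigma": self.se_sigma,
        }


@dataclass(frozen=True)
class SeparationReport:
    """Welch t-test of class separation plus per-class normality screens."""

    t_statistic: float
    welch_df: float
    p_value: float
    shapiro_p: dict[str, float | None]

    def to_dict(self) -> dict:
        return {
            "t_statistic": self.t_statistic,
            "welch_df": self.welch_df,
            "p_value": self.p_value,
            "shapiro_p": dict(self.shapiro_p),
        }


def fit_class_gaussian(values) -> ClassGaussian:
    """Fit N(mu, sigma^2) by the sample mean and the n-1 sample SD."""
    arr = np.asarray(values, dtype=float)
    if arr.size < 2:
        raise InsufficientDataError(f"need >= 2 values to fit a class Gaussian, got {arr.size}")
    sigma = float(np.std(arr, ddof=1))
    if sigma == 0.0:
        raise DegenerateDataError("all class values identical; SD is zero")
    return ClassGaussian(mu=float(np.mean(arr)), sigma=sigma, n=int(arr.size))


def normality_screen(values) -> float:
    """Shapiro-Wilk p-value; p >= 0.05 reads as consistent with normality.

    Constant input is degenerate for the test and raises
    :class:`DegenerateDataError` (rather than returning the test's undefined
    statistic). Requires 3 <= n; above 5000 the p-value is known to be
    unreliable and a warning is issued by the underlying routine.
    """
    arr = np.asarray(values, dtype=float)
    if arr.size < 3:
        raise InsufficientDataError("Shapiro-Wilk needs at least 3 values")
    if np.ptp(arr) == 0.0:
        raise DegenerateDataError("Shapiro-Wilk undefined for constant input")
    return float(stats.shapiro(arr).pvalue)


def welch_separation(values_target, values_versus, screen_normality: bool = True) -> SeparationReport:
    """Two-sided Welch t-test between the two classes.

    Sign convention: ``t > 0`` when the target mean exceeds the versus mean.
    """
    a = np.asarray(values_target, dtype=float)
    b = np.asarray(values_versus, dtype=float)
    if a.size < 2 or b.size < 2:
        raise InsufficientDataError("each class needs n >= 2 for the Welch t-test")
    va, vb = np.var(a, ddof=1), np.var(b, ddof=1)
    if va == 0.0 or vb == 0.0:
        raise DegenerateDataError("a class has zero variance; Welch t undefined")
    res = stats.ttest_ind(a, b, equal_var=False)
    sa, sb = va / a.size, vb / b.size
    df = (sa + sb) ** 2 / (sa**2 / (a.size - 1) + sb**2 / (b.size - 1))
    shapiro: dict[str, float | None] = {}
    if screen_normality:
        for name, arr in (("target", a), ("versus", b)):
            try:
                shapiro[name] = normality_screen(arr)
            except (InsufficientDataError, DegenerateDataError):
                shapiro[name] = None
    return SeparationReport(
        t_statistic=float(res.statistic),
        welch_df=float(df),
        p_value=float(res.pvalue),
        shapiro_p=shapiro,
    )


def collect_by_class(measures: list[MeasureVector], name: str) -> dict[str, np.ndarray]:
    """Gather the values of one measure per class label, skipping absences."""
    out: dict[str, list[float]] = {}
    for mv in measures:
        if name in mv.values and mv.class_label:
            out.setdefault(mv.class_label, []).append(mv.values[name])
    return {k: np.asarray(v, dtype=float) for k, v in out.items()}


def measure_statistics(measures: list[MeasureVector], names: list[str]) -> list[dict]:
    """Per-measure, per-class summary rows mirroring the statistics table the
    tool reports: n, mean, SD, Shapiro-Wilk p, and the Welch p of the
    target/versus comparison (repeated on both class rows).
    """
    rows: list[dict] = []
    for name in names:
        grouped = collect_by_class(measures, name)
        welch_p: float | None = None
        tgt, vs = grouped.get("target"), grouped.get("versus")
        if tgt is not None and vs is not None and tgt.size >= 2 and vs.size >= 2:
            try:
                report = welch_separation(tgt, vs, screen_normality=False)
                welch_p = report.p_value
            except DegenerateDataError:
                welch_p = None
            if welch_p is not None and welch_p >= 0.05:
                warnings.warn(
                    f"measure {name!r}: Welch p = {welch_p:.2g} >= 0.05 — the classes "
                    "are not separated; this measure is a poor discriminator",
                    stacklevel=2,
                )
        for cls, vals in grouped.items():
            try:
                shap = normality_screen(vals)
            except (InsufficientDataError, DegenerateDataError):
                shap = None
            rows.append(
                {
                    "measure": name,
                    "class": cls,
                    "n": int(vals.size),
                    "mean": float(np.mean(vals)),
                    "sd": float(np.std(vals, ddof=1)) if vals.size > 1 else None,
                    "shapiro_p": shap,
                    "welch_p": welch_p,
                }
            )
    return rows
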