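"""Two-class Gaussian Bayes discriminator on a scalar measure.

Model. Each class of the working measure y is Gaussian: the target class
T ~ N(mu_T, sigma_T^2), the versus class V ~ N(mu_V, sigma_V^2), with prior
probabilities p_T + p_V = 1. The classification rule is a fixed threshold::

    y >= chi  ->  target        y < chi  ->  versus

The accuracy p_c = p_T H + p_V C, with sensitivity H = Phi((mu_T - chi)/sigma_T)
and specificity C = Phi((chi - mu_V)/sigma_V), is maximized by the root of::

    eta chi^2 - 2 beta chi + gamma - 2 ln(p_T/p_V) = 0

where::

    eta   = 1/sigma_T^2 - 1/sigma_V^2
    beta  = mu_T/sigma_T^2 - mu_V/sigma_V^2
    gamma = mu_T^2/sigma_T^2 - mu_V^2/sigma_V^2 + 2 ln(sigma_T/sigma_V)

Root selection: the real root inside [mu_V, mu_T] is taken; if none or both
fall inside, the root nearest the midpoint of the means wins — the decision
boundary relevant to classification lies between the means for balanced and
near-balanced priors. When |eta| is negligible (equal class variances) the
linear solution chi = (gamma - 2 ln(p_T/p_V)) / (2 beta) is used.

Posterior odds. Bayes' theorem gives the odds that a sample with value y is
a target::

    rho = P_T/P_V = exp[-(eta y^2 - 2 beta y + gamma - 2 ln(p_T/p_V)) / 2]

so rho(chi) = 1 by construction; the thresholds where rho = 9 and rho = 1/9
bound the high-reliability bands used in reporting.

Uncertainty. mu and sigma of each class are sample estimates with standard
errors sigma/sqrt(N) and sigma/sqrt(2(N-1)); the SE of chi follows by
first-order propagation with central finite differences of the root with
respect to the four parameters, combined in quadrature. The SE of the
predicted accuracy is propagated by Monte Carlo (the accuracy is flat at the
optimum, so chained first-order propagation is fragile there).

Orientation. The rule assumes mu_T >= mu_V on the working measure; a measure
whose target mean lies below the versus mean is auto-negated before fitting
(orientation = -1), and every public function accepts raw values, applying
the stored orientation internally.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy import stats

from .class_stats import ClassGaussian, fit_class_gaussian
from .errors import DegenerateDataError, InfeasibleThresholdError

#: odds bands, most target-reliable first; edges closed on the reliable side
BANDS = ("rho>9", "9>rho>1", "1>rho>1/9", "rho<1/9")

_ETA_TOL = 1e-12


def quadratic_coefficients(target: ClassGaussian, versus: ClassGaussian) -> tuple[float, float, float]:
    """(eta, beta, gamma) of the quadratic log-likelihood-ratio form."""
    st2, sv2 = target.sigma**2, versus.sigma**2
    eta = 1.0 / st2 - 1.0 / sv2
    beta = target.mu / st2 - versus.mu / sv2
    gamma = target.mu**2 / st2 - versus.mu**2 / sv2 + 2.0 * math.log(target.sigma / versus.sigma)
    return eta, beta, gamma


def _solve_root(
    mu_t: float, sigma_t: float, mu_v: float, sigma_v: float,
    prior_ratio: float, odds_level: float = 1.0,
) -> float:
    """Root of eta y^2 - 2 beta y + gamma - 2 ln(prior_ratio) = -2 ln(odds_level)."""
    st2, sv2 = sigma_t**2, sigma_v**2
    eta = 1.0 / st2 - 1.0 / sv2
    beta = mu_t / st2 - mu_v / sv2
    gamma = mu_t**2 / st2 - mu_v**2 / sv2 + 2.0 * math.log(sigma_t / sigma_v)
    const = gamma - 2.0 * math.log(prior_ratio) + 2.0 * math.log(odds_level)

    if abs(eta) < _ETA_TOL * max(1.0 / st2, 1.0 / sv2):
        if beta == 0.0:
            raise DegenerateDataError("identical class distributions; threshold undefined")
        return const / (2.0 * beta)

    disc = beta * beta - eta * const
    if disc < 0.0:
        raise InfeasibleThresholdError(
            f"no real root at odds level {odds_level} (discriminant {disc:.3g})"
        )
    sq = math.sqrt(disc)
    roots = ((beta + sq) / eta, (beta - sq) / eta)
    lo, hi = min(mu_v, mu_t), max(mu_v, mu_t)
    inside = [r for r in roots if lo <= r <= hi]
    if len(inside) == 1:
        return inside[0]
    mid = 0.5 * (mu_t + mu_v)
    return min(roots, key=lambda r: abs(r - mid))


def solve_threshold(
    target: ClassGaussian,
    versus: ClassGaussian,
    prior_ratio: float = 1.0,
    odds_level: float = 1.0,
) -> tuple[float, float]:
    """Solve for the decision threshold and its propagated standard error.

    ``odds_level`` generalizes the optimum (level 1) to the odds-band
    thresholds: the returned chi satisfies rho(chi) = odds_level.
    """
    if prior_ratio <= 0:
        raise ValueError(f"prior_ratio must be positive, got {prior_ratio}")
    params = [target.mu, target.sigma, versus.mu, versus.sigma]
    ses = [target.se_mu, target.se_sigma, versus.se_mu, versus.se_sigma]
    chi = _solve_root(*params, prior_ratio, odds_level)

    # first-order propagation via central finite differences, step 1e-4 * SE
    var = 0.0
    for i, (p, se) in enumerate(zip(params, ses)):
        h = 1e-4 * se
        if h == 0.0:
            continue
        up, dn = params.copy(), params.copy()
        up[i] = p + h
        dn[i] = p - h
        try:
            grad = (_solve_root(*up, prior_ratio, odds_level)
                    - _solve_root(*dn, prior_ratio, odds_level)) / (2.0 * h)
        except InfeasibleThresholdError:
            continue
        var += (grad * se) ** 2
    return chi, math.sqrt(var)


@dataclass(frozen=True)
class ClassifierModel:
    """Fitted two-class Gaussian discriminator for one scalar measure.

    ``target``/``versus`` describe the *working* measure, i.e. after the
    orientation sign was applied; public functions take raw values.
    """

    target: ClassGaussian
    versus: ClassGaussian
    prior_ratio: float
    eta: float
    beta: float
    gamma: float
    chi: float
    chi_se: float
    orientation: int = 1
    measure: str = "y"

    def to_dict(self) -> dict:
        return {
            "measure": self.measure,
            "orientation": self.orientation,
            "target": self.target.to_dict(),
            "versus": self.versus.to_dict(),
            "prior_ratio": self.prior_ratio,
            "eta": self.eta,
            "beta": self.beta,
            "gamma": self.gamma,
            "chi": self.chi,
            "chi_se": self.chi_se,
        }


def model_from_stats(
    target: ClassGaussian,
    versus: ClassGaussian,
    prior_ratio: float = 1.0,
    measure: str = "y",
    orientation: int = 1,
) -> ClassifierModel:
    """Build the classifier from already-estimated class Gaussians."""
    if orientation not in (1, -1):
        raise ValueError("orientation must be +1 or -1")
    eta, beta, gamma = quadratic_coefficients(target, versus)
    chi, chi_se = solve_threshold(target, versus, prior_ratio)
    return ClassifierModel(
        target=target,
        versus=versus,
        prior_ratio=prior_ratio,
        eta=eta,
        beta=beta,
        gamma=gamma,
        chi=chi,
        chi_se=chi_se,
        orientation=orientation,
        measure=measure,
    )


def fit_model(
    values_target,
    values_versus,
    prior_ratio: float = 1.0,
    measure: str = "y",
) -> ClassifierModel:
    """Fit class Gaussians from labeled values and build the classifier.

    If the target mean lies below the versus mean the measure is negated
    before fitting (orientation = -1) so that the threshold rule keeps its
    ``y >= chi -> target`` form on the working measure.
    """
    a = np.asarray(values_target, dtype=float)
    b = np.asarray(values_versus, dtype=float)
    orientation = 1
    if np.mean(a) < np.mean(b):
        orientation = -1
        a, b = -a, -b
    return model_from_stats(
        fit_class_gaussian(a),
        fit_class_gaussian(b),
        prior_ratio=prior_ratio,
        measure=measure,
        orientation=orientation,
    )


def posterior_odds(y, model: ClassifierModel):
    """Posterior odds rho = P_T/P_V for a raw measure value y."""
    w = model.orientation * np.asarray(y, dtype=float)
    q = model.eta * w * w - 2.0 * model.beta * w + model.gamma - 2.0 * math.log(model.prior_ratio)
    out = np.exp(-0.5 * q)
    return float(out) if out.ndim == 0 else out


@dataclass(frozen=True)
class OddsBandThresholds:
    """Band-edge thresholds (working orientation), each with its SE.

    ``chi_10_90`` is the threshold where the odds are 1:9, ``chi`` the 1:1
    optimum, ``chi_90_10`` the 9:1 edge. An unreachable level is ``None``.
    """

    chi_10_90: tuple[float, float] | None
    chi: tuple[float, float]
    chi_90_10: tuple[float, float] | None

    def to_dict(self) -> dict:
        def pack(t):
            return None if t is None else {"value": t[0], "se": t[1]}

        return {
            "chi_10_90": pack(self.chi_10_90),
            "chi": pack(self.chi),
            "chi_90_10": pack(self.chi_90_10),
        }


def odds_thresholds(model: ClassifierModel) -> OddsBandThresholds:
    """Thresholds at odds 1:9, 1:1 and 9:1 with propagated SEs."""
    def attempt(level):
        try:
            return solve_threshold(model.target, model.versus, model.prior_ratio, level)
        except InfeasibleThresholdError:
            return None

    return OddsBandThresholds(
        chi_10_90=attempt(1.0 / 9.0),
        chi=(model.chi, model.chi_se),
        chi_90_10=attempt(9.0),
    )


def sensitivity_specificity(model: ClassifierModel, chi: float | None = None) -> tuple[float, float]:
    """(H, C) at the given (working-orientation) threshold; default model.chi."""
    chi = model.chi if chi is None else chi
    h = float(stats.norm.cdf((model.target.mu - chi) / model.target.sigma))
    c = float(stats.norm.cdf((chi - model.versus.mu) / model.versus.sigma))
    return h, c


def predicted_accuracy(
    model: ClassifierModel,
    n_draws: int = 100_000,
    seed: int = 0,
) -> tuple[float, float]:
    """Predicted maximum accuracy p_c = p_T H + p_V C and its Monte-Carlo SE.

    The SE re-draws (mu_T, sigma_T, mu_V, sigma_V) from independent normals
    at their standard errors, re-solves the threshold and recomputes p_c;
    the SD over draws is reported. Draws with non-positive sigmas or an
    infeasible threshold are rejected.
    """
    p_t = model.prior_ratio / (1.0 + model.prior_ratio)
    p_v = 1.0 - p_t
    h, c = sensitivity_specificity(model)
    p_c = p_t * h + p_v * c

    rng = np.random.default_rng(seed)
    gt, gv = model.target, model.versus
    mus_t = rng.normal(gt.mu, gt.se_mu, n_draws)
    sds_t = rng.normal(gt.sigma, gt.se_sigma, n_draws)
    mus_v = rng.normal(gv.mu, gv.se_mu, n_draws)
    sds_v = rng.normal(gv.sigma, gv.se_sigma, n_draws)
    samples = []
    for mt, st, mv, sv in zip(mus_t, sds_t, mus_v, sds_v):
        if st <= 0 or sv <= 0:
            continue
        try:
            chi = _solve_root(mt, st, mv, sv, model.prior_ratio)
        except (InfeasibleThresholdError, DegenerateDataError):
            continue
        hh = stats.norm.cdf((mt - chi) / st)
        cc = stats.norm.cdf((chi - mv) / sv)
        samples.append(p_t * hh + p_v * cc)
    se = float(np.std(samples, ddof=1)) if len(samples) > 1 else float("nan")
    return float(p_c), se


def band_of(odds: float) -> str:
    """Odds band label; edges at 9 and 1/9 are closed on the reliable side."""
    if odds >= 9.0:
        return BANDS[0]
    if odds >= 1.0:
        return BANDS[1]
    if odds > 1.0 / 9.0:
        return BANDS[2]
    return BANDS[3]


@dataclass(frozen=True)
class ClassificationResult:
    predicted: str
    odds: float
    band: str

    def to_dict(self) -> dict:
        return {"predicted": self.predicted, "odds": self.odds, "band": self.band}


def classify(y: float, model: ClassifierModel) -> ClassificationResult:
    """Apply the threshold rule to a raw measure value.

    The boundary ``y == chi`` (working orientation) is a target call with
    odds exactly 1, band ``9>rho>1``.
    """
    if not math.isfinite(y):
        raise ValueError("measure value must be finite")
    w = model.orientation * y
    predicted = "target" if w >= model.chi else "versus"
    odds = posterior_odds(y, model)
    return ClassificationResult(predicted=predicted, odds=odds, band=band_of(odds))


@dataclass(frozen=True)
class BandedConfusion:
    """2 x 4 confusion counts over the odds bands, plus derived accuracies.

    ``accuracy`` counts any correct call; ``high_reliability_accuracy``
    counts only correct calls whose predicted-class odds are at least 9:1,
    still divided by all classified samples — the fraction of samples
    receiving a *reliable and correct* call.
    """

    counts: dict[str, dict[str, int]]
    n: int
    n_excluded: int

    @property
    def accuracy(self) -> float:
        correct = sum(
            self.counts["target"][b] for b in BANDS[:2]
        ) + sum(self.counts["versus"][b] for b in BANDS[2:])
        return correct / self.n if self.n else 0.0

    @property
    def high_reliability_accuracy(self) -> float:
        correct = self.counts["target"][BANDS[0]] + self.counts["versus"][BANDS[3]]
        return correct / self.n if self.n else 0.0

    def to_dict(self) -> dict:
        return {
            "counts": {cls: dict(row) for cls, row in self.counts.items()},
            "n": self.n,
            "n_excluded": self.n_excluded,
            "accuracy": self.accuracy,
            "high_reliability_accuracy": self.high_reliability_accuracy,
        }


def banded_confusion(values, labels, model: ClassifierModel) -> BandedConfusion:
    """Tally labeled samples into true-class x odds-band cells.

    Samples whose label is neither ``target`` nor ``versus`` are excluded
    (counted in ``n_excluded``).
    """
    counts = {cls: {b: 0 for b in BANDS} for cls in ("target", "versus")}
    n = 0
    excluded = 0
    for y, label in zip(values, labels):
        if label not in counts:
            excluded += 1
            continue
        counts[label][band_of(posterior_odds(y, model))] += 1
        n += 1
    return BandedConfusion(counts=counts, n=n, n_excluded=excluded)


def bias_outlier_p(
    y: float,
    class_gaussian: ClassGaussian,
    prediction_interval: bool = False,
) -> float:
    """One-tailed Student-t tail probability of a value at least as displaced
    from the class mean as y.

    ``t = (y - mu) / sigma`` with n-1 degrees of freedom; with
    ``prediction_interval=True`` the denominator becomes
    ``sigma * sqrt(1 + 1/n)`` (accounts for the new sample's own spread).
    A small p (e.g. < 0.01) marks y as a bias outlier: a triplicate whose
    level is implausible for the class it was assigned to.
    """
    scale = class_gaussian.sigma
    if prediction_interval:
        scale *= math.sqrt(1.0 + 1.0 / class_gaussian.n)
    t = (y - class_gaussian.mu) / scale
    return float(stats.t.sf(abs(t), df=class_gaussian.n - 1))
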