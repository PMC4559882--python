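"""Threshold solving, posterior odds, bands, confusion and bias outliers."""

import math

import numpy as np
import pytest
from scipy import stats

import mirbayes as mb
from mirbayes.bayes import BANDS, band_of
from mirbayes.class_stats import ClassGaussian
from mirbayes.errors import DegenerateDataError
from tests.conftest import DX205, XU6, YOPT

SYMMETRIC = {"target": ClassGaussian(1.0, 1.0, 50), "versus": ClassGaussian(-1.0, 1.0, 50)}


def _quadratic_oracle(gt, gv, prior_ratio=1.0, odds=1.0):
    """Independent quadratic-formula solution, root inside the mean interval."""
    eta = 1 / gt.sigma**2 - 1 / gv.sigma**2
    beta = gt.mu / gt.sigma**2 - gv.mu / gv.sigma**2
    gamma = (
        gt.mu**2 / gt.sigma**2 - gv.mu**2 / gv.sigma**2
        + 2 * math.log(gt.sigma / gv.sigma)
    )
    const = gamma - 2 * math.log(prior_ratio) + 2 * math.log(odds)
    disc = math.sqrt(beta**2 - eta * const)
    roots = [(beta + disc) / eta, (beta - disc) / eta]
    inside = [r for r in roots if min(gv.mu, gt.mu) <= r <= max(gv.mu, gt.mu)]
    return inside[0] if inside else min(roots, key=lambda r: abs(r - (gt.mu + gv.mu) / 2))


class TestQuadraticCoefficients:
    def test_symmetric_equal_variance(self):
        assert mb.quadratic_coefficients(SYMMETRIC["target"], SYMMETRIC["versus"]) == pytest.approx(
            (0.0, 2.0, 0.0)
        )

    def test_study_combined_measure(self):
        eta, beta, gamma = mb.quadratic_coefficients(YOPT["target"], YOPT["versus"])
        assert eta == pytest.approx(-0.11361, abs=1e-4)
        assert beta == pytest.approx(1.63792, abs=1e-4)
        assert gamma == pytest.approx(13.341, abs=1e-3)

    def test_identical_classes(self):
        g = ClassGaussian(2.0, 1.5, 30)
        assert mb.quadratic_coefficients(g, g) == pytest.approx((0.0, 0.0, 0.0))


class TestSolveThreshold:
    def test_symmetric_midpoint(self):
        chi, _ = mb.solve_threshold(SYMMETRIC["target"], SYMMETRIC["versus"])
        assert chi == pytest.approx(0.0, abs=1e-12)

    def test_study_combined_measure(self):
        chi, se = mb.solve_threshold(YOPT["target"], YOPT["versus"])
        assert round(chi, 1) == 3.6
        assert chi == pytest.approx(3.6184, abs=1e-3)
        assert 0.2 < se < 0.7  # prints as 0.4 at the study sample sizes

    def test_equal_variance_prior_shift_closed_form(self):
        gt, gv = ClassGaussian(2.0, 1.2, 40), ClassGaussian(-1.0, 1.2, 40)
        for prior_ratio in (0.25, 1.0, 4.0):
            chi, _ = mb.solve_threshold(gt, gv, prior_ratio)
            expected = 0.5 - 1.2**2 * math.log(prior_ratio) / 3.0
            assert chi == pytest.approx(expected, rel=1e-9)

    @pytest.mark.parametrize("stats_pair", [YOPT, DX205, XU6, SYMMETRIC])
    def test_root_residual(self, stats_pair):
        gt, gv = stats_pair["target"], stats_pair["versus"]
        if gt.mu < gv.mu:  # orientation flip, as fit_model would do
            gt, gv = ClassGaussian(-gt.mu, gt.sigma, gt.n), ClassGaussian(-gv.mu, gv.sigma, gv.n)
        model = mb.model_from_stats(gt, gv)
        residual = model.eta * model.chi**2 - 2 * model.beta * model.chi + model.gamma
        assert abs(residual) < 1e-8

    @pytest.mark.parametrize("stats_pair", [YOPT, DX205])
    def test_matches_quadratic_oracle(self, stats_pair):
        gt, gv = stats_pair["target"], stats_pair["versus"]
        chi, _ = mb.solve_threshold(gt, gv)
        assert chi == pytest.approx(_quadratic_oracle(gt, gv), rel=1e-9)

    def test_prior_monotonicity(self):
        """A larger target prior can only grow the target region (chi down)."""
        last = math.inf
        for prior_ratio in (0.2, 0.5, 1.0, 2.0, 5.0):
            chi, _ = mb.solve_threshold(YOPT["target"], YOPT["versus"], prior_ratio)
            assert chi <= last + 1e-12
            last = chi

    def test_identical_classes_error(self):
        g = ClassGaussian(2.0, 1.5, 30)
        with pytest.raises(DegenerateDataError):
            mb.solve_threshold(g, g)


class TestPosteriorOdds:
    def test_odds_one_at_threshold(self):
        model = mb.model_from_stats(YOPT["target"], YOPT["versus"])
        assert abs(mb.posterior_odds(model.chi, model) - 1.0) < 1e-9

    def test_near_identical_classes_give_prior_ratio(self):
        gt = ClassGaussian(1.0 + 1e-9, 1.5, 30)
        gv = ClassGaussian(1.0, 1.5, 30)
        model = mb.model_from_stats(gt, gv, prior_ratio=3.0)
        for y in (-2.0, 0.0, 5.0):
            assert mb.posterior_odds(y, model) == pytest.approx(3.0, rel=1e-6)

    def test_odds_at_band_thresholds(self):
        model = mb.model_from_stats(YOPT["target"], YOPT["versus"])
        bands = mb.odds_thresholds(model)
        assert mb.posterior_odds(bands.chi_90_10[0], model) == pytest.approx(9.0, rel=1e-6)
        assert mb.posterior_odds(bands.chi_10_90[0], model) == pytest.approx(1 / 9, rel=1e-6)


class TestOddsThresholds:
    def test_level_one_equals_optimum(self):
        model = mb.model_from_stats(DX205["target"], DX205["versus"])
        bands = mb.odds_thresholds(model)
        assert bands.chi[0] == model.chi

    def test_ordering(self):
        for pair in (YOPT, DX205, SYMMETRIC):
            model = mb.model_from_stats(pair["target"], pair["versus"])
            bands = mb.odds_thresholds(model)
            assert bands.chi_10_90[0] < bands.chi[0] < bands.chi_90_10[0]

    def test_symmetric_equidistant(self):
        model = mb.model_from_stats(SYMMETRIC["target"], SYMMETRIC["versus"])
        bands = mb.odds_thresholds(model)
        assert bands.chi[0] - bands.chi_10_90[0] == pytest.approx(
            bands.chi_90_10[0] - bands.chi[0], rel=1e-9
        )

    def test_study_combined_measure_band_values(self):
        model = mb.model_from_stats(YOPT["target"], YOPT["versus"])
        bands = mb.odds_thresholds(model)
        assert bands.chi_90_10[0] == pytest.approx(4.66, abs=0.01)
        assert bands.chi_10_90[0] == pytest.approx(2.51, abs=0.01)


class TestSensitivitySpecificityAccuracy:
    def test_half_at_class_means(self):
        model = mb.model_from_stats(YOPT["target"], YOPT["versus"])
        h, _ = mb.sensitivity_specificity(model, chi=model.target.mu)
        _, c = mb.sensitivity_specificity(model, chi=model.versus.mu)
        assert h == pytest.approx(0.5) and c == pytest.approx(0.5)

    def test_study_combined_measure(self):
        model = mb.model_from_stats(YOPT["target"], YOPT["versus"])
        h, c = mb.sensitivity_specificity(model)
        assert h == pytest.approx(0.958, abs=0.001)
        assert c == pytest.approx(0.966, abs=0.001)

    def test_predicted_accuracy_values(self):
        model = mb.model_from_stats(YOPT["target"], YOPT["versus"])
        p_c, se = mb.predicted_accuracy(model, n_draws=50_000, seed=1)
        assert 100 * p_c == pytest.approx(96.1, abs=0.3)
        assert 0.015 < se < 0.035  # prints as 2.4% at the study sizes
        model_dx = mb.model_from_stats(DX205["target"], DX205["versus"])
        p_c_dx, _ = mb.predicted_accuracy(model_dx, n_draws=10_000, seed=1)
        assert 100 * p_c_dx == pytest.approx(91.4, abs=0.3)

    def test_near_identical_classes_coin_flip(self):
        gt = ClassGaussian(1e-9, 1.5, 30)
        gv = ClassGaussian(0.0, 1.5, 30)
        model = mb.model_from_stats(gt, gv)
        p_c, _ = mb.predicted_accuracy(model, n_draws=100, seed=0)
        assert p_c == pytest.approx(0.5, abs=1e-6)

    @pytest.mark.parametrize("stats_pair", [YOPT, DX205, SYMMETRIC])
    def test_threshold_maximizes_accuracy(self, stats_pair):
        model = mb.model_from_stats(stats_pair["target"], stats_pair["versus"])
        p_t = model.prior_ratio / (1 + model.prior_ratio)

        def p_c(chi):
            h, c = mb.sensitivity_specificity(model, chi)
            return p_t * h + (1 - p_t) * c

        best = p_c(model.chi)
        for delta in (0.01, 0.1, 1.0):
            assert best >= p_c(model.chi + delta) - 1e-12
            assert best >= p_c(model.chi - delta) - 1e-12


class TestClassify:
    @pytest.fixture()
    def model(self):
        return mb.model_from_stats(YOPT["target"], YOPT["versus"])

    def test_boundary_is_target_with_unit_odds(self, model):
        res = mb.classify(model.chi, model)
        assert res.predicted == "target"
        assert res.odds == pytest.approx(1.0, abs=1e-9)
        assert res.band == "9>rho>1"

    def test_band_edges_closed_on_reliable_side(self, model):
        bands = mb.odds_thresholds(model)
        assert band_of(9.0) == "rho>9"
        assert band_of(1 / 9) == "rho<1/9"
        assert mb.classify(bands.chi_90_10[0] + 1e-6, model).band == "rho>9"

    def test_below_threshold_versus(self, model):
        res = mb.classify(model.chi - 0.5, model)
        assert res.predicted == "versus" and res.odds < 1.0

    def test_orientation_equivalence(self):
        """Fitting on a sign-flipped measure reproduces the same calls."""
        rng = np.random.default_rng(10)
        t = rng.normal(25.0, 1.4, 60)
        v = rng.normal(25.8, 1.9, 50)
        # reference-like measure: target mean *below* versus mean
        flipped = mb.fit_model(-t, -v)  # manual negation -> orientation +1
        auto = mb.fit_model(t, v)  # auto-negation -> orientation -1
        assert auto.orientation == -1 and flipped.orientation == 1
        values = np.concatenate([t, v])
        labels = ["target"] * t.size + ["versus"] * v.size
        conf_auto = mb.banded_confusion(values, labels, auto)
        conf_manual = mb.banded_confusion(-values, labels, flipped)
        assert conf_auto.counts == conf_manual.counts


class TestBandedConfusion:
    def test_everything_at_threshold_lands_in_middle_bands(self):
        model = mb.model_from_stats(YOPT["target"], YOPT["versus"])
        conf = mb.banded_confusion(
            [model.chi] * 6, ["target"] * 3 + ["versus"] * 3, model
        )
        middle = {"9>rho>1"}
        for cls, row in conf.counts.items():
            assert sum(row[b] for b in BANDS if b not in middle) == 0

    def test_unlabeled_excluded(self):
        model = mb.model_from_stats(YOPT["target"], YOPT["versus"])
        conf = mb.banded_confusion([5.0, 1.0], ["target", "unknown"], model)
        assert conf.n == 1 and conf.n_excluded == 1


class TestParameterRecoveryAndCalibration:
    def test_large_sample_threshold_recovery(self):
        rng = np.random.default_rng(31)
        t = rng.normal(6.9, 1.9, 10_000)
        v = rng.normal(0.7, 1.6, 10_000)
        model = mb.fit_model(t, v)
        analytic = _quadratic_oracle(YOPT["target"], YOPT["versus"])
        assert model.chi == pytest.approx(analytic, abs=0.05)

    def test_empirical_accuracy_matches_prediction(self):
        rng = np.random.default_rng(32)
        n = 10_000
        t = rng.normal(6.9, 1.9, n)
        v = rng.normal(0.7, 1.6, n)
        model = mb.fit_model(t, v)
        p_c, _ = mb.predicted_accuracy(model, n_draws=100, seed=0)
        hits = np.sum(t >= model.chi) + np.sum(v < model.chi)
        empirical = hits / (2 * n)
        binom_sd = math.sqrt(p_c * (1 - p_c) / (2 * n))
        assert abs(empirical - p_c) <= 3 * binom_sd


class TestBiasOutlier:
    def test_half_at_class_mean(self):
        g = YOPT["target"]
        assert mb.bias_outlier_p(g.mu, g) == pytest.approx(0.5)

    def test_inverse_cdf_oracle(self):
        g = ClassGaussian(10.0, 2.0, 16)
        y = g.mu + g.sigma * stats.t.ppf(0.99, df=g.n - 1)
        assert mb.bias_outlier_p(y, g) == pytest.approx(0.01, rel=1e-9)
        # symmetric on the low side
        y_low = g.mu - g.sigma * stats.t.ppf(0.99, df=g.n - 1)
        assert mb.bias_outlier_p(y_low, g) == pytest.approx(0.01, rel=1e-9)

    def test_prediction_interval_variant_is_milder(self):
        g = ClassGaussian(10.0, 2.0, 16)
        y = g.mu + 3 * g.sigma
        assert mb.bias_outlier_p(y, g, prediction_interval=True) > mb.bias_outlier_p(y, g)

    def test_extreme_displacement_is_small(self):
        """A value ~5 within-class SDs out is flagged far below the 1% level."""
        g = YOPT["target"]
        assert mb.bias_outlier_p(g.mu - 5 * g.sigma, g) < 5e-4
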