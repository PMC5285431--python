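"""Constrained LQ fitting: recovery, constraints, uncertainty."""

import numpy as np
import pytest
import scipy.optimize

import lemsurv as lv
from conftest import SUITE_SEED, lq_grid_objective_min, noiseless_curve
from lemsurv.errors import ConfigurationError, DataError, InsufficientDataError
from lemsurv.fitting import _nnls2_batch, _nnls_design


def _random_curve(rng, n_points=None):
    n = n_points or rng.integers(3, 9)
    doses = np.sort(rng.uniform(0.5, 6.0, size=n))
    doses += np.arange(n) * 1e-3  # ensure strictly increasing
    alpha, beta = rng.uniform(0.0, 0.3, size=2)
    sf = np.exp(-(alpha * doses + beta * doses**2))
    sf = sf * np.exp(rng.normal(0.0, 0.1, size=n))
    return lv.SurvivalCurve(
        "x", 0.0, tuple(lv.SurvivalMeasurement(float(d), float(s)) for d, s in zip(doses, sf))
    )


class TestFitLQ:
    @pytest.mark.parametrize("params", lv.benchmark_parameters(), ids=str)
    def test_noiseless_benchmark_rows_recovered(self, params):
        curve = noiseless_curve(params, range(1, 7))
        fit = lv.fit_lq(curve)
        assert fit.params.alpha == pytest.approx(params.alpha, abs=1e-8)
        assert fit.params.beta == pytest.approx(params.beta, abs=1e-8)

    def test_noiseless_recovery_arbitrary_doses(self):
        rng = np.random.default_rng(SUITE_SEED)
        for _ in range(20):
            truth = lv.LQParameters(*rng.uniform(0.005, 0.3, 2), spectrum_label="x")
            doses = np.sort(rng.uniform(0.2, 8.0, rng.integers(2, 7)))
            doses += np.arange(doses.size) * 1e-3
            fit = lv.fit_lq(noiseless_curve(truth, doses))
            assert fit.params.alpha == pytest.approx(truth.alpha, abs=1e-8)
            assert fit.params.beta == pytest.approx(truth.beta, abs=1e-8)
            assert fit.active_constraints == (False, False)
            assert fit.sum_sq == pytest.approx(0.0, abs=1e-16)

    def test_rising_survival_clamps_both_to_zero(self):
        curve = lv.SurvivalCurve(
            "x",
            0.0,
            (
                lv.SurvivalMeasurement(1.0, 1.05),
                lv.SurvivalMeasurement(2.0, 1.10),
                lv.SurvivalMeasurement(3.0, 1.20),
            ),
        )
        fit = lv.fit_lq(curve)
        assert fit.params.alpha == 0.0 and fit.params.beta == 0.0
        assert fit.active_constraints == (True, True)
        # grid-search oracle on the same objective confirms (0, 0) is optimal
        y = -np.log(curve.sf_means)
        oracle = lq_grid_objective_min(curve.doses, y, step=1e-3)
        assert fit.sum_sq <= oracle + 1e-12

    def test_constrained_fit_never_beaten_by_grid_oracle(self):
        rng = np.random.default_rng(SUITE_SEED + 1)
        for _ in range(15):
            curve = _random_curve(rng)
            fit = lv.fit_lq(curve)
            y = -np.log(curve.sf_means)
            oracle = lq_grid_objective_min(curve.doses, y, step=1e-3)
            assert fit.sum_sq <= oracle * (1.0 + 1e-6) + 1e-12

    def test_matches_unconstrained_when_interior(self):
        rng = np.random.default_rng(SUITE_SEED + 2)
        checked = 0
        for _ in range(40):
            curve = _random_curve(rng)
            design = _nnls_design(curve.doses)
            y = -np.log(curve.sf_means)
            unconstrained, *_ = np.linalg.lstsq(design, y, rcond=None)
            if np.all(unconstrained > 1e-6):
                fit = lv.fit_lq(curve)
                assert fit.params.alpha == pytest.approx(unconstrained[0], abs=1e-10)
                assert fit.params.beta == pytest.approx(unconstrained[1], abs=1e-10)
                checked += 1
        assert checked >= 5

    def test_sf_space_agrees_on_noiseless_data(self):
        truth = lv.LQParameters(0.05, 0.012, spectrum_label="x")
        curve = noiseless_curve(truth, range(1, 7))
        fit = lv.fit_lq(curve, fit_space="sf")
        assert fit.fit_space == "sf"
        assert fit.params.alpha == pytest.approx(0.05, abs=1e-8)
        assert fit.params.beta == pytest.approx(0.012, abs=1e-8)

    def test_means_above_one_are_retained_not_clipped(self):
        curve = lv.SurvivalCurve(
            "x",
            0.0,
            (
                lv.SurvivalMeasurement(1.0, 1.02),
                lv.SurvivalMeasurement(2.0, 0.90),
                lv.SurvivalMeasurement(4.0, 0.70),
            ),
        )
        fit = lv.fit_lq(curve)  # no error; the log of 1.02 is just negative
        assert fit.params.alpha >= 0.0

    def test_insufficient_positive_doses(self):
        curve = lv.SurvivalCurve(
            "x", 0.0, (lv.SurvivalMeasurement(0.0, 1.0), lv.SurvivalMeasurement(2.0, 0.8))
        )
        with pytest.raises(InsufficientDataError):
            lv.fit_lq(curve)

    def test_nonpositive_sf_rejected_or_dropped(self):
        curve = lv.SurvivalCurve(
            "x",
            0.0,
            (
                lv.SurvivalMeasurement(1.0, 0.9),
                lv.SurvivalMeasurement(2.0, -0.1),
                lv.SurvivalMeasurement(3.0, 0.5),
            ),
        )
        with pytest.raises(DataError):
            lv.fit_lq(curve)
        with pytest.warns(UserWarning):
            fit = lv.fit_lq(curve, drop_nonpositive=True)
        assert fit.residuals.size == 2

    def test_control_row_does_not_change_optimum(self):
        truth = lv.LQParameters(0.04, 0.008, spectrum_label="x")
        with_control = noiseless_curve(truth, [0, 1, 2, 3, 4, 5])
        without = noiseless_curve(truth, [1, 2, 3, 4, 5])
        f1, f2 = lv.fit_lq(with_control), lv.fit_lq(without)
        assert f1.params.alpha == pytest.approx(f2.params.alpha, abs=1e-12)
        assert f1.params.beta == pytest.approx(f2.params.beta, abs=1e-12)

    def test_unknown_fit_space(self):
        curve = noiseless_curve(lv.LQParameters(0.02, 0.01), [1, 2, 3])
        with pytest.raises(ConfigurationError):
            lv.fit_lq(curve, fit_space="bogus")


class TestNnls2Batch:
    def test_agrees_with_scipy_nnls(self):
        rng = np.random.default_rng(SUITE_SEED + 3)
        for _ in range(300):
            doses = np.sort(rng.uniform(0.3, 6.0, 5)) + np.arange(5) * 1e-3
            design = _nnls_design(doses)
            y = rng.normal(0.0, 1.0, 5)
            ours = _nnls2_batch(design, y[None, :])[0]
            ref, _ = scipy.optimize.nnls(design, y)
            assert np.allclose(ours, ref, atol=1e-9), (ours, ref)


class TestParameterUncertainty:
    def test_zero_residual_fit_has_zero_analytic_se(self):
        curve = noiseless_curve(lv.LQParameters(0.05, 0.01), range(1, 7))
        fit = lv.parameter_uncertainty(lv.fit_lq(curve), curve, method="analytic")
        assert fit.params.alpha_se == pytest.approx(0.0, abs=1e-12)
        assert fit.params.beta_se == pytest.approx(0.0, abs=1e-12)

    def test_active_constraint_reports_absent_not_zero(self):
        curve = lv.SurvivalCurve(
            "x",
            0.0,
            tuple(lv.SurvivalMeasurement(float(d), 1.0 + 0.02 * d) for d in (1, 2, 3, 4)),
        )
        fit = lv.fit_lq(curve)
        assert any(fit.active_constraints)
        out = lv.parameter_uncertainty(fit, curve, method="analytic")
        assert out.params.alpha_se is None and out.params.beta_se is None

    def test_bootstrap_deterministic_given_seed(self, fixture_dataset):
        curves, _ = fixture_dataset
        curve = curves[3]
        fit = lv.fit_lq(curve)
        a = lv.parameter_uncertainty(fit, curve, b=300, seed=42)
        b = lv.parameter_uncertainty(fit, curve, b=300, seed=42)
        assert a.params.alpha_se == b.params.alpha_se
        assert a.alpha_ci == b.alpha_ci and a.beta_ci == b.beta_ci

    def test_bootstrap_requires_seed(self, fixture_dataset):
        curves, _ = fixture_dataset
        fit = lv.fit_lq(curves[0])
        with pytest.raises(ConfigurationError):
            lv.parameter_uncertainty(fit, curves[0])

    def test_unknown_method(self, fixture_dataset):
        curves, _ = fixture_dataset
        fit = lv.fit_lq(curves[0])
        with pytest.raises(ConfigurationError):
            lv.parameter_uncertainty(fit, curves[0], method="jackknife")

    def test_analytic_and_bootstrap_agree_on_average(self):
        # many-dose curves with Gaussian log-space noise: the two SE routes
        # estimate the same quantity and should agree closely on average
        rng = np.random.default_rng(SUITE_SEED + 4)
        doses = np.linspace(1.0, 6.0, 18)
        truth = lv.LQParameters(0.05, 0.015, spectrum_label="x")
        ratios_a, ratios_b = [], []
        for i in range(100):
            sf = np.exp(-(truth.mean_lesions(doses)) + rng.normal(0, 0.05, doses.size))
            curve = lv.SurvivalCurve(
                "x", 0.0,
                tuple(lv.SurvivalMeasurement(float(d), float(s)) for d, s in zip(doses, sf)),
            )
            fit = lv.fit_lq(curve)
            if any(fit.active_constraints):
                continue
            ana = lv.parameter_uncertainty(fit, curve, method="analytic")
            boot = lv.parameter_uncertainty(fit, curve, b=300, seed=1000 + i)
            ratios_a.append(boot.params.alpha_se / ana.params.alpha_se)
            ratios_b.append(boot.params.beta_se / ana.params.beta_se)
        assert abs(np.mean(ratios_a) - 1.0) < 0.25
        assert abs(np.mean(ratios_b) - 1.0) < 0.25


class TestFitStudy:
    def test_empty_input_warns_and_returns_empty(self):
        with pytest.warns(UserWarning):
            assert lv.fit_study([]) == []

    def test_order_preserved(self, fixture_dataset):
        curves, _ = fixture_dataset
        outcomes = lv.fit_study(curves[:4])
        assert len(outcomes) == 4
        assert all(o.ok for o in outcomes)
        assert [o.concentration for o in outcomes] == [c.concentration for c in curves[:4]]

    def test_bad_curve_flagged_without_aborting(self, fixture_dataset):
        curves, _ = fixture_dataset
        bad = lv.SurvivalCurve(
            "x", 0.0, (lv.SurvivalMeasurement(0.0, 1.0), lv.SurvivalMeasurement(1.0, 0.9))
        )
        outcomes = lv.fit_study([curves[0], bad, curves[1]])
        assert [o.ok for o in outcomes] == [True, False, True]
        assert "positive doses" in outcomes[1].error
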