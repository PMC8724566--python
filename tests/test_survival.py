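"""Log-logistic curves, hazard-ratio adjustment, and MLE fitting."""
import math

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from icicea.survival import (
    FitError,
    FitResult,
    LogLogisticParams,
    SurvivalCurve,
    apply_hazard_ratio,
    curve_from_shape_params,
    fit_parametric,
    loglogistic_median,
    loglogistic_survival,
    select_best_fit,
)
from icicea.synthetic import SyntheticCohortSpec, simulate_ipd

OS = LogLogisticParams(theta=0.02432, kappa=1.11748)
PFS = LogLogisticParams(theta=0.09810, kappa=1.14350)


class TestLogLogistic:
    def test_survival_starts_at_one(self):
        assert loglogistic_survival(OS, 0.0) == 1.0

    @pytest.mark.parametrize(
        "params, expected_median",
        [(OS, (1 / 0.02432) ** (1 / 1.11748)), (PFS, (1 / 0.09810) ** (1 / 1.14350))],
    )
    def test_median_solves_half_survival(self, params, expected_median):
        # closed form: lam * t^kappa = 1  =>  t = (1/lam)^(1/kappa)
        t_med = loglogistic_median(params)
        assert t_med == pytest.approx(expected_median)
        assert loglogistic_survival(params, t_med) == pytest.approx(0.5, abs=1e-12)

    def test_documented_medians_are_plausible(self):
        # ~27.8 time units for OS, ~7.6 for PFS
        assert loglogistic_median(OS) == pytest.approx(27.77, abs=0.05)
        assert loglogistic_median(PFS) == pytest.approx(7.62, abs=0.05)

    def test_negative_time_rejected(self):
        with pytest.raises(ValueError):
            loglogistic_survival(OS, -1.0)

    def test_exp_theta_form_shifts_lambda(self):
        s_direct = loglogistic_survival(OS, 10.0, form="lambda_direct")
        s_exp = loglogistic_survival(OS, 10.0, form="exp_theta")
        assert s_exp < s_direct  # exp(0.024) ~ 1.02 >> 0.024

    def test_month_unit_rescales_cycle_axis(self):
        months = curve_from_shape_params(OS, time_unit="months", cycle_days=21.0)
        cycles = curve_from_shape_params(OS, time_unit="cycles")
        t = 10.0
        assert months(t) == pytest.approx(
            loglogistic_survival(OS, t * 21.0 / 30.44)
        )
        assert months(t) > cycles(t)

    def test_monotone_and_bounded_on_dense_grid(self):
        grid = np.linspace(0, 2000, 10_000)
        for curve in (
            curve_from_shape_params(OS),
            curve_from_shape_params(OS).power(1.17),
        ):
            s = np.asarray(curve(grid))
            assert np.all((0.0 <= s) & (s <= 1.0))
            assert np.all(np.diff(s) <= 1e-15)


class TestHazardRatio:
    def test_identity_at_one(self):
        curve = curve_from_shape_params(OS)
        adjusted = apply_hazard_ratio(curve, 1.0)
        t = np.linspace(0, 100, 50)
        np.testing.assert_allclose(adjusted(t), curve(t))

    @pytest.mark.parametrize("s, hr", [(0.8, 1.17), (0.8, 1.04), (0.3, 0.5)])
    def test_power_evaluation(self, s, hr):
        curve = SurvivalCurve(fn=lambda t: np.full_like(np.asarray(t, float), s))
        assert apply_hazard_ratio(curve, hr)(1.0) == pytest.approx(s**hr)

    def test_invalid_hr_rejected(self):
        curve = curve_from_shape_params(OS)
        with pytest.raises(ValueError):
            apply_hazard_ratio(curve, 0.0)
        with pytest.raises(ValueError):
            apply_hazard_ratio(curve, -1.2)

    @given(
        hr1=st.floats(0.3, 3.0),
        hr2=st.floats(0.3, 3.0),
        t=st.floats(0.0, 500.0),
    )
    def test_composition_multiplies_hazard_ratios(self, hr1, hr2, t):
        curve = curve_from_shape_params(OS)
        chained = apply_hazard_ratio(apply_hazard_ratio(curve, hr1), hr2)
        direct = apply_hazard_ratio(curve, hr1 * hr2)
        assert chained(t) == pytest.approx(direct(t), abs=1e-12)


class TestFitting:
    def test_loglogistic_parameter_recovery(self):
        spec = SyntheticCohortSpec(
            n_patients=2000,
            true_params={"lam": 0.0243, "kappa": 1.117},
            censoring_rate=0.2,
            max_followup=80.0,
            seed=1,
        )
        fit = fit_parametric(simulate_ipd(spec), "loglogistic")
        assert fit.params["lam"] == pytest.approx(0.0243, rel=0.10)
        assert fit.params["kappa"] == pytest.approx(1.117, rel=0.10)
        assert fit.aic == pytest.approx(2 * 2 - 2 * fit.loglik)
        assert fit.bic == pytest.approx(2 * math.log(fit.n) - 2 * fit.loglik)

    def test_exponential_matches_closed_form_mle(self):
        # the exponential MLE rate is events / total exposure
        spec = SyntheticCohortSpec(
            n_patients=500,
            family="exponential",
            true_params={"rate": 0.05},
            censoring_rate=0.3,
            max_followup=60.0,
            seed=3,
        )
        data = simulate_ipd(spec)
        fit = fit_parametric(data, "exponential")
        closed_form = data["event"].sum() / data["time_months"].sum()
        assert fit.params["rate"] == pytest.approx(closed_form, rel=1e-4)

    def test_model_selection_prefers_generating_family(self):
        # exponential data should win on AIC against the log-logistic in
        # the vast majority of replicates
        wins = 0
        n_rep = 40
        for seed in range(n_rep):
            spec = SyntheticCohortSpec(
                n_patients=300,
                family="exponential",
                true_params={"rate": 0.08},
                seed=seed,
            )
            data = simulate_ipd(spec)
            fits = [fit_parametric(data, f) for f in ("exponential", "loglogistic")]
            if fits[0].aic < fits[1].aic:
                wins += 1
        assert wins >= 0.9 * n_rep

    def test_all_families_fit(self):
        spec = SyntheticCohortSpec(
            n_patients=400, true_params={"lam": 0.05, "kappa": 1.3}, seed=11
        )
        data = simulate_ipd(spec)
        for family in ("exponential", "weibull", "lognormal", "loglogistic", "gompertz"):
            fit = fit_parametric(data, family)
            assert math.isfinite(fit.aic) and fit.n == 400

    def test_degenerate_inputs_rejected(self):
        import pandas as pd

        single = pd.DataFrame({"time_months": [3.0], "event": [1]})
        with pytest.raises(FitError):
            fit_parametric(single, "exponential")
        censored = pd.DataFrame({"time_months": np.arange(1.0, 21.0), "event": 0})
        with pytest.raises(FitError, match="censored"):
            fit_parametric(censored, "weibull")


class TestSelection:
    def _fr(self, aic, bic=0.0, n=100, k=2):
        return FitResult(
            family="x", params={str(i): 0.0 for i in range(k)},
            loglik=0.0, aic=aic, bic=bic, n=n,
        )

    def test_minimum_aic_wins(self):
        best = select_best_fit([self._fr(100.0), self._fr(90.0)])
        assert best.aic == 90.0

    def test_aic_tie_broken_by_bic_then_k(self):
        assert select_best_fit([self._fr(90, bic=80), self._fr(90, bic=70)]).bic == 70
        assert select_best_fit(
            [self._fr(90, bic=70, k=3), self._fr(90, bic=70, k=2)]
        ).k == 2

    def test_mismatched_datasets_rejected(self):
        with pytest.raises(ValueError, match="mismatched"):
            select_best_fit([self._fr(90, n=100), self._fr(80, n=200)])
        with pytest.raises(ValueError):
            select_best_fit([])
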