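"""Cohort engine: conversions, discounting, blending, state bookkeeping."""
import math

import numpy as np
import pytest

import icicea
from icicea.config import CEASettings
from icicea.engine import (
    LifeTable,
    blend_life_table,
    discount_factor,
    per_cycle_probability,
    rate_to_probability,
    run_cohort,
    state_memberships,
)
from icicea.survival import LogLogisticParams, SurvivalCurve, curve_from_shape_params
from icicea.synthetic import jitter_config


class TestConversions:
    def test_no_events_stay_zero(self):
        assert per_cycle_probability(0.0, 21.0) == 0.0

    def test_trial_probability_to_cycle_probability(self):
        # r = -ln(1-0.0617)/21, p = 1-exp(-r): the published per-cycle input
        assert per_cycle_probability(0.0617, 21.0) == pytest.approx(0.00303, abs=5e-6)

    def test_rate_to_probability(self):
        assert rate_to_probability(0.1, 3.0) == pytest.approx(1 - math.exp(-0.3))

    def test_domain_errors(self):
        with pytest.raises(ValueError):
            per_cycle_probability(1.0, 21.0)
        with pytest.raises(ValueError):
            per_cycle_probability(0.5, 0.0)
        with pytest.raises(ValueError):
            rate_to_probability(-0.1)


class TestDiscounting:
    def test_factor_examples(self):
        st = CEASettings()
        assert discount_factor(0, st) == 1.0
        one_year = 365.25 / 21.0
        assert discount_factor(one_year, st) == pytest.approx(1 / 1.03)

    def test_monotone_decreasing(self):
        st = CEASettings()
        f = discount_factor(np.arange(100.0), st)
        assert np.all(np.diff(f) < 0)


def _flat_lt(years=20, s_end=1.0):
    return LifeTable(rows=[(0.0, 1.0), (float(years), s_end)])


class TestBlending:
    def test_zero_hazard_table_is_identity(self):
        curve = curve_from_shape_params(LogLogisticParams(0.02432, 1.11748))
        blended = blend_life_table(curve, _flat_lt(), blend_cycle=36)
        t = np.arange(0, 500.0)
        np.testing.assert_allclose(blended(t), curve(t), atol=1e-12)

    def test_absorbing_table_forces_zero(self):
        curve = curve_from_shape_params(LogLogisticParams(0.02432, 1.11748))
        lt = LifeTable(rows=[(0.0, 1.0), (1.0, 1e-12)])
        blended = blend_life_table(curve, lt, blend_cycle=36)
        # one table-year past the blend point survival is essentially gone
        assert blended(36 + 2 * 365.25 / 21) < 1e-9

    def test_hazard_max_shortens_median(self):
        # a tail hazard floor can only pull survival down
        curve = curve_from_shape_params(LogLogisticParams(0.02432, 1.11748))
        lt = LifeTable(rows=[(0.0, 1.0), (1.0, 0.5), (10.0, 0.5**10)])
        blended = blend_life_table(curve, lt, blend_cycle=10)
        t = np.arange(0.0, 1000.0)
        assert np.all(np.asarray(blended(t)) <= np.asarray(curve(t)) + 1e-12)
        assert np.all(np.asarray(blended(t[:10])) == pytest.approx(curve(t[:10])))

    def test_blend_point_must_be_in_horizon(self):
        curve = curve_from_shape_params(LogLogisticParams(0.02432, 1.11748))
        with pytest.raises(ValueError):
            blend_life_table(curve, _flat_lt(), blend_cycle=10_000)

    def test_life_table_validation(self):
        with pytest.raises(ValueError):
            LifeTable(rows=[])
        with pytest.raises(ValueError):
            LifeTable(rows=[(0.0, 1.0), (1.0, 1.2)])
        with pytest.raises(ValueError):
            LifeTable(rows=[(0.0, 0.8)])


class TestStateMemberships:
    def _curves(self):
        os_c = curve_from_shape_params(LogLogisticParams(0.02432, 1.11748))
        pfs_c = curve_from_shape_params(LogLogisticParams(0.09810, 1.14350))
        return os_c, pfs_c

    def test_initial_state_is_all_pfs(self):
        os_c, pfs_c = self._curves()
        trace = state_memberships(os_c, pfs_c, 0.5, _flat_lt(), CEASettings())
        assert trace.pfs[0] == 1.0
        assert trace.pd[0] == trace.endstage[0] == trace.dead[0] == 0.0

    def test_no_progression_limit(self):
        os_c, _ = self._curves()
        trace = state_memberships(os_c, os_c, 0.5, _flat_lt(), CEASettings())
        # the blend rebuilds OS from accumulated hazards, so allow float dust
        assert np.all(trace.pd <= 1e-12)
        assert np.all(trace.endstage <= 1e-12)

    def test_mass_conservation_and_monotone_death(self):
        os_c, pfs_c = self._curves()
        trace = state_memberships(os_c, pfs_c, 0.3, _flat_lt(), CEASettings())
        assert trace.max_mass_error() <= 1e-9
        assert np.all(np.diff(trace.dead) >= -1e-15)

    def test_curve_not_starting_at_one_rejected(self):
        os_c, pfs_c = self._curves()
        bad = SurvivalCurve(fn=lambda t: 0.9 * np.ones_like(np.asarray(t, float)))
        with pytest.raises(ValueError, match="S\\(0\\)"):
            state_memberships(bad, pfs_c, 0.5, _flat_lt(), CEASettings())


class TestRunCohort:
    def test_mass_conserved_every_cycle(self, base_traces):
        for trace in base_traces.values():
            assert trace.max_mass_error() <= 1e-9

    def test_on_treatment_never_exceeds_pfs(self, base_traces):
        for trace in base_traces.values():
            assert np.all(trace.on_treatment <= trace.pfs + 1e-12)

    def test_unit_hazard_ratios_reproduce_reference_states(self, fresh_config):
        for p in ("hr_os_pembrolizumab", "hr_pfs_pembrolizumab"):
            fresh_config.parameters[p].baseline = 1.0
            fresh_config.parameters[p].low = 1.0
            fresh_config.parameters[p].high = 1.0
        ref = run_cohort("cemiplimab", fresh_config)
        alt = run_cohort("pembrolizumab", fresh_config)
        np.testing.assert_allclose(alt.pfs, ref.pfs, atol=1e-12)
        np.testing.assert_allclose(alt.dead, ref.dead, atol=1e-12)

    def test_undiscounted_life_years_match_trapezoid_integral(self, fresh_config):
        fresh_config.settings.discount_rate_annual = 0.0
        trace = run_cohort("cemiplimab", fresh_config)
        alive = 1.0 - trace.dead
        trapz = np.trapezoid(alive, trace.t) * fresh_config.settings.cycle_years
        assert trace.total_life_years == pytest.approx(trapz, rel=1e-3)

    def test_zero_utilities_zero_qalys(self, fresh_config):
        for p in ("u_ge12m", "u_6_12m", "u_1_6m", "u_le1m"):
            fresh_config.parameters[p].baseline = 0.0
            fresh_config.parameters[p].low = 0.0
        trace = run_cohort("cemiplimab", fresh_config)
        assert trace.total_qaly == 0.0

    def test_zero_unit_costs_zero_total_cost(self, fresh_config):
        for name, spec in fresh_config.parameters.items():
            if name.startswith(("price_", "cost_", "ae_cost", "admin_")):
                spec.baseline = 0.0
                if spec.low is not None:
                    spec.low = 0.0
        trace = run_cohort("cemiplimab", fresh_config)
        assert trace.total_cost == 0.0

    def test_alive_fraction_exhausted_at_horizon(self, base_traces):
        for trace in base_traces.values():
            assert trace.alive[-1] < 1e-3

    def test_jittered_configs_all_run(self, fresh_config):
        failures = 0
        for seed in range(100):
            cfg = jitter_config(fresh_config, 0.2, seed=seed)
            trace = run_cohort("cemiplimab", cfg)
            ok = (
                math.isfinite(trace.total_cost)
                and math.isfinite(trace.total_qaly)
                and trace.max_mass_error() <= 1e-9
            )
            failures += not ok
        assert failures == 0

    def test_trace_export_columns(self, base_traces):
        df = base_traces["cemiplimab"].to_frame()
        assert list(df.columns) == [
            "cycle", "pfs", "pd", "endstage", "dead",
            "on_treatment", "cost_increment", "qaly_increment",
        ]
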