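"""One-way DSA (tornado) and probabilistic sensitivity analysis."""
import numpy as np
import pytest

from icicea.config import ParameterSpec
from icicea.engine import run_cohort
from icicea.outcomes import icer
from icicea.sensitivity import (
    dsa_ranges,
    psa_distribution,
    run_dsa,
    run_psa,
)

CONTRAST = ("cemiplimab", "pembrolizumab")


def _spec(baseline, low=None, high=None, dist="fixed", name="x"):
    return ParameterSpec(
        name=name, baseline=baseline, low=low, high=high, distribution=dist
    )


class TestDsaRanges:
    def test_stored_range_used(self, config):
        assert dsa_ranges(config.parameters["price_cemiplimab"]) == (13.79, 41.37)
        assert dsa_ranges(config.parameters["hr_os_pembrolizumab"]) == (0.82, 1.27)

    def test_plus_minus_half_fallback(self):
        assert dsa_ranges(_spec(100.0)) == (50.0, 150.0)


@pytest.fixture(scope="module")
def small_dsa(config):
    params = [
        "price_cemiplimab",
        "price_pembrolizumab",
        "price_ramucirumab",
        "hr_os_pembrolizumab",
        "u_ge12m",
        "price_atezolizumab",  # unused in this contrast: zero swing
    ]
    return run_dsa(config, CONTRAST, parameters=params)


class TestDsa:
    def test_sorted_by_swing_descending(self, small_dsa):
        swings = [r.swing for r in small_dsa]
        assert swings == sorted(swings, reverse=True)

    def test_unused_parameter_has_zero_swing_and_ranks_last(self, small_dsa):
        assert small_dsa[-1].parameter == "price_atezolizumab"
        assert small_dsa[-1].swing == pytest.approx(0.0, abs=1e-6)

    def test_swing_matches_independent_recomputation(self, config, small_dsa):
        from icicea.outcomes import icer_value

        rec = next(r for r in small_dsa if r.parameter == "price_ramucirumab")
        wtp = config.settings.wtp_threshold
        nums = []
        for bound in (rec.low, rec.high):
            values = config.baseline_values()
            values["price_ramucirumab"] = bound
            a = run_cohort("cemiplimab", config, values)
            b = run_cohort("pembrolizumab", config, values)
            nums.append(
                icer_value(a.total_cost - b.total_cost, a.total_qaly - b.total_qaly, wtp)
            )
        assert rec.swing == pytest.approx(abs(nums[1] - nums[0]), rel=1e-9)

    def test_baseline_bounds_reproduce_base_case(self, config):
        spec = config.parameters["price_ramucirumab"]
        frozen = spec.model_copy(
            update={"low": spec.baseline, "high": spec.baseline}
        )
        cfg = config.model_copy(deep=True)
        cfg.parameters["price_ramucirumab"] = frozen
        [rec] = run_dsa(cfg, CONTRAST, parameters=["price_ramucirumab"])
        a = run_cohort("cemiplimab", config)
        b = run_cohort("pembrolizumab", config)
        base_icer = icer(a.total_cost - b.total_cost, a.total_qaly - b.total_qaly)
        assert rec.icer_at_low == pytest.approx(base_icer, rel=1e-12)
        assert rec.icer_at_high == pytest.approx(base_icer, rel=1e-12)
        assert rec.swing == 0.0


class TestPsaDistributions:
    def test_normal_sigma_from_range(self):
        spec = _spec(70.32, 69.71, 70.93, "normal")
        draws = psa_distribution(spec)(np.random.default_rng(0), 200_000)
        assert draws.std() == pytest.approx((70.93 - 69.71) / 3.92, rel=0.01)
        assert draws.mean() == pytest.approx(70.32, abs=0.01)

    def test_gamma_moment_matching(self):
        spec = _spec(637.0, 318.5, 955.5, "gamma")
        draws = psa_distribution(spec)(np.random.default_rng(1), 1_000_000)
        assert draws.mean() == pytest.approx(637.0, rel=0.005)
        sigma = (955.5 - 318.5) / 3.92
        assert draws.std() == pytest.approx(sigma, rel=0.01)
        assert np.all(draws > 0)

    def test_lognormal_mean_matches_baseline(self):
        spec = _spec(1.17, 0.82, 1.27, "lognormal")
        draws = psa_distribution(spec)(np.random.default_rng(2), 500_000)
        assert draws.mean() == pytest.approx(1.17, rel=0.005)
        assert np.all(draws > 0)

    def test_beta_support(self):
        spec = _spec(0.805, 0.767, 0.843, "beta")
        draws = psa_distribution(spec)(np.random.default_rng(3), 100_000)
        assert np.all((draws >= 0) & (draws <= 1))
        assert draws.mean() == pytest.approx(0.805, abs=0.002)

    def test_infeasible_beta_falls_back_with_warning(self):
        spec = _spec(0.5, 0.0, 2.5, "beta")  # sigma too large for the support
        with pytest.warns(UserWarning, match="infeasible"):
            draws = psa_distribution(spec)(np.random.default_rng(4), 1000)
        assert np.all((draws >= 0) & (draws <= 1))

    def test_fixed_is_degenerate(self):
        draws = psa_distribution(_spec(0.5, 0.25, 0.75, "fixed"))(
            np.random.default_rng(5), 100
        )
        assert np.all(draws == 0.5)

    def test_sample_means_converge_to_baselines(self, config):
        rng_master = np.random.default_rng(99)
        for name in ("price_cemiplimab", "u_ge12m", "hr_os_pembrolizumab",
                     "cost_bsc_monthly", "body_weight"):
            spec = config.parameters[name]
            draws = psa_distribution(spec)(rng_master, 100_000)
            assert draws.mean() == pytest.approx(spec.baseline, rel=0.01), name


@pytest.fixture(scope="module")
def psa_small(config):
    return run_psa(config, n_draws=200, seed=123)


class TestPsa:
    def test_seed_reproducibility(self, config, psa_small):
        again = run_psa(config, n_draws=200, seed=123)
        assert psa_small.ceac.equals(again.ceac)
        assert psa_small.draws.equals(again.draws)

    def test_different_seed_differs(self, config, psa_small):
        other = run_psa(config, n_draws=200, seed=124)
        assert not psa_small.draws.equals(other.draws)

    def test_ceac_rows_sum_to_one(self, psa_small):
        sums = psa_small.ceac.groupby("wtp")["probability"].sum()
        assert np.allclose(sums, 1.0)

    def test_degenerate_psa_collapses_to_base_case(self, fresh_config):
        from icicea.config import Distribution

        for spec in fresh_config.parameters.values():
            spec.distribution = Distribution.fixed
        res = run_psa(fresh_config, n_draws=1, seed=0)
        a = run_cohort("cemiplimab", fresh_config)
        b = run_cohort("pembrolizumab", fresh_config)
        assert res.draws.loc[0, "cost_cemiplimab"] == pytest.approx(a.total_cost)
        assert res.draws.loc[0, "qaly_pembrolizumab"] == pytest.approx(b.total_qaly)

    def test_summary_fractions_are_consistent(self, psa_small):
        s = psa_small.summary["pembrolizumab"]
        assert 0.0 <= s["dominant_frac"] <= s["acceptable_frac"] <= 1.0
        assert s["cost_effective_frac"] + s["dominant_frac"] <= s["acceptable_frac"] + 1e-12

    def test_manifest_fields(self, psa_small):
        m = psa_small.manifest()
        assert m["seed"] == 123 and m["n_draws"] == 200
        assert isinstance(m["config_hash"], str) and len(m["config_hash"]) == 16
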