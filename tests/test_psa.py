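"""PSA sampling, reproducibility, degenerate limits and CEAC behaviour."""

import numpy as np
import pytest

from bcscea import (
    Strategy,
    ceac,
    default_parameters,
    run_cohort,
    run_psa,
    sample_draw,
)
from bcscea.errors import ParameterError
from bcscea.parameters import PSADistributionSpec
from bcscea.psa import DEFAULT_WTP_GRID


class TestSampleDraw:
    def test_fixed_seed_reproducible(self, params):
        a, sampled_a = sample_draw(params.psa_specs,
                                   np.random.default_rng(11), params)
        b, sampled_b = sample_draw(params.psa_specs,
                                   np.random.default_rng(11), params)
        assert sampled_a == sampled_b
        assert a == b

    def test_base_parameters_untouched(self, params):
        before = params.copy()
        sample_draw(params.psa_specs, np.random.default_rng(0), params)
        assert params == before

    def test_sampled_values_within_domains(self, params):
        rng = np.random.default_rng(5)
        for _ in range(200):
            draw, sampled = sample_draw(params.psa_specs, rng, params)
            tr = draw.transitions
            for name in ("tpA2D", "tpB2C", "tpB2F", "tpC2D", "tpD2E", "tpD2F"):
                assert 0.0 <= getattr(tr, name) <= 1.0
            assert tr.tpB2C + tr.tpB2F <= 1.0
            assert tr.tpD2E + tr.tpD2F <= 1.0
            assert 18 <= draw.entry_age <= 100
            assert all(v >= 0 for v in draw.costs.baseline_cost.values())
            for strat in Strategy:
                assert 0.0 <= draw.utilities.state_a[strat] <= 1.0

    def test_recurrence_shift_applies_to_all_periods(self, params):
        draw, sampled = sample_draw(params.psa_specs,
                                    np.random.default_rng(3), params)
        shift = sampled["tpA2B_shift"]
        for strat in Strategy:
            base = params.transitions.recurrence_schedules[strat]
            new = draw.transitions.recurrence_schedules[strat]
            for (_, _, r0), (_, _, r1) in zip(base.periods, new.periods):
                assert r1 == pytest.approx(r0 * shift)

    def test_lumpectomy_arms_share_draws(self, params):
        draw, _ = sample_draw(params.psa_specs, np.random.default_rng(4),
                              params)
        u = draw.utilities.state_a
        assert u[Strategy.LUMPECTOMY_NO_RT] == u[Strategy.LUMPECTOMY_RT]
        c = draw.costs.stateB_cost
        assert c[Strategy.LUMPECTOMY_NO_RT] == c[Strategy.LUMPECTOMY_RT]

    def test_sample_moments_match_specs(self):
        """Long-run sample means recover the published parameter means."""
        rng = np.random.default_rng(0)
        uam = PSADistributionSpec("uam", "beta", (839.16, 159.84))
        draws = rng.beta(*uam.params, size=10_000)
        assert draws.mean() == pytest.approx(0.84, abs=0.01)
        cam = PSADistributionSpec("cam", "gamma", (656.50, 133.54))
        draws = rng.gamma(*cam.params, size=10_000)
        assert draws.mean() == pytest.approx(87_670, rel=0.01)


class TestRunPsa:
    def test_zero_iterations_rejected(self, params, lifetable):
        with pytest.raises(ParameterError):
            run_psa(params, lifetable, n_iter=0)

    def test_fixed_seed_bitwise_reproducible(self, params, lifetable):
        a = run_psa(params, lifetable, n_iter=5, seed=9)
        b = run_psa(params, lifetable, n_iter=5, seed=9)
        assert a.draws.equals(b.draws)

    def test_point_mass_distributions_reproduce_deterministic(self, params,
                                                              lifetable):
        """All-fixed specs make the PSA collapse onto the base-case run."""
        params.psa_specs = [
            PSADistributionSpec(s.name, "fixed") for s in params.psa_specs
        ]
        psa = run_psa(params, lifetable, n_iter=1, seed=0)
        for strat in Strategy:
            reference = run_cohort(strat, params, lifetable)
            assert psa.mean_qaly(strat) == pytest.approx(reference.qaly)
            assert psa.mean_cost(strat, "healthcare") == pytest.approx(
                reference.cost_healthcare
            )
            assert psa.mean_cost(strat, "societal") == pytest.approx(
                reference.cost_societal
            )

    def test_percentiles_consistent_with_sorted_draws(self, psa_result):
        values = psa_result.qalys(Strategy.MASTECTOMY)
        lo, hi = psa_result.interval(values)
        assert lo == pytest.approx(np.quantile(values, 0.025))
        assert hi == pytest.approx(np.quantile(values, 0.975))
        assert lo <= values.mean() <= hi

    def test_age_sampling_drags_means_below_deterministic(self, psa_result,
                                                          base_results):
        """Older sampled entry ages interact with mortality nonlinearly, so
        PSA mean QALYs sit below the age-58 deterministic values."""
        for strat in Strategy:
            assert psa_result.mean_qaly(strat) < base_results[strat].qaly

    def test_summary_shape(self, psa_result):
        summary = psa_result.summary()
        assert len(summary) == 3
        assert (summary["qaly_lo"] <= summary["mean_qaly"]).all()
        assert (summary["mean_qaly"] <= summary["qaly_hi"]).all()


class TestCeac:
    def test_probabilities_bounded(self, psa_result):
        curve = ceac(psa_result, Strategy.LUMPECTOMY_RT,
                     Strategy.LUMPECTOMY_NO_RT)
        assert np.all((curve.probability >= 0) & (curve.probability <= 1))
        assert curve.wtp.shape == curve.probability.shape

    def test_zero_wtp_reduces_to_cost_comparison(self, psa_result):
        curve = ceac(psa_result, Strategy.LUMPECTOMY_RT,
                     Strategy.LUMPECTOMY_NO_RT, wtp_grid=np.array([0.0]))
        cheaper = (
            psa_result.costs(Strategy.LUMPECTOMY_RT)
            < psa_result.costs(Strategy.LUMPECTOMY_NO_RT)
        ).mean()
        assert curve.probability[0] == pytest.approx(cheaper)

    def test_limit_when_alternative_always_gains(self, psa_result):
        """RT always gains QALYs and costs more here, so the curve climbs to ~1."""
        curve = ceac(psa_result, Strategy.LUMPECTOMY_RT,
                     Strategy.LUMPECTOMY_NO_RT,
                     wtp_grid=np.array([0.0, 1e8]))
        assert curve.probability[0] < 0.05
        assert curve.probability[-1] > 0.95

    def test_non_increasing_grid_rejected(self, psa_result):
        with pytest.raises(ParameterError):
            ceac(psa_result, Strategy.LUMPECTOMY_RT,
                 Strategy.LUMPECTOMY_NO_RT, wtp_grid=np.array([1.0, 1.0]))

    def test_default_grid_covers_published_range(self):
        assert DEFAULT_WTP_GRID[0] == 0
        assert DEFAULT_WTP_GRID[-1] == 2_000_000
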