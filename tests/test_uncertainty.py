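"""Probabilistic and one-way sensitivity analyses."""

import dataclasses

import numpy as np
import pytest

from statincea import (
    DEFAULT_WTP_THRESHOLDS,
    ModelConfig,
    builtin_table1,
    ceac,
    evaluate_strategy,
    export_ce_plane,
    icer,
    owsa,
    run_psa,
    sample_parameter_set,
)
from statincea.uncertainty import _draw_beta, _draw_gamma, _draw_lognormal


def _zero_se(p):
    """Copy of a parameter set with every SE nulled out."""
    scalars = {
        name: dataclasses.replace(getattr(p, name), se=None)
        for name in p.SCALAR_FIELDS
    }
    mortality = {
        state: tuple(
            dataclasses.replace(b, value=dataclasses.replace(b.value, se=None))
            for b in bands
        )
        for state, bands in p.mortality.items()
    }
    return dataclasses.replace(p, mortality=mortality, **scalars)


class TestSampling:
    def test_zero_se_collapses_to_means(self, table1):
        rng = np.random.default_rng(0)
        sampled = sample_parameter_set(_zero_se(table1), rng)
        assert sampled == _zero_se(table1)

    def test_same_seed_same_draw(self, table1):
        a = sample_parameter_set(table1, np.random.default_rng(11))
        b = sample_parameter_set(table1, np.random.default_rng(11))
        assert a == b

    def test_residual_keeps_ra_row_stochastic(self, table1):
        for seed in range(50):
            s = sample_parameter_set(table1, np.random.default_rng(seed))
            total = (s.tpRA_RA.mean + s.tpRA_MI.mean
                     + s.tpRA_CAr.mean + s.tpRA_Rv.mean)
            assert total == pytest.approx(1.0, abs=1e-12)

    def test_sampled_sets_validate(self, table1):
        from statincea import validate_parameter_set

        for seed in range(200):
            s = sample_parameter_set(table1, np.random.default_rng(seed))
            assert validate_parameter_set(s) == []

    @pytest.mark.parametrize(
        "drawer, mean, se",
        [
            (_draw_beta, 0.012, 0.001),    # RA -> MI transition probability
            (_draw_beta, 0.65, 0.065),     # MI utility
            (_draw_gamma, 19_728_100.0, 197_281.0),  # resolved-ACS cost
            (_draw_gamma, 3_908_568.0, 390_856.8),   # HIS annual drug cost
            (_draw_lognormal, 0.77, 0.07),           # MI hazard ratio
        ],
    )
    def test_moment_recovery(self, drawer, mean, se):
        """Method-of-moments samplers reproduce the table's mean and SE."""
        rng = np.random.default_rng(123)
        draws = np.array([drawer(rng, mean, se) for _ in range(10_000)])
        assert abs(draws.mean() - mean) < 3 * se / np.sqrt(len(draws))
        assert abs(draws.std(ddof=1) - se) / se < 0.10


class TestPsa:
    def test_zero_se_psa_equals_deterministic(self, table1):
        p = _zero_se(table1)
        cfg = ModelConfig()
        psa = run_psa(p, cfg, n=3, seed=5)
        det = icer(evaluate_strategy(p, "HIS", cfg), evaluate_strategy(p, "LMIS", cfg))
        for it in psa:
            assert it.delta_cost == pytest.approx(det.delta_cost, abs=1e-6)
            assert it.delta_qaly == pytest.approx(det.delta_qaly, abs=1e-12)

    def test_reproducible_from_seed(self, table1):
        a = run_psa(table1, n=5, seed=9)
        b = run_psa(table1, n=5, seed=9)
        np.testing.assert_array_equal(a.delta_cost, b.delta_cost)
        np.testing.assert_array_equal(a.delta_qaly, b.delta_qaly)

    def test_iterations_independent_of_run_length(self, table1):
        """Iteration i depends on (seed, i) only, so prefixes agree."""
        short = run_psa(table1, n=3, seed=9)
        longer = run_psa(table1, n=5, seed=9)
        np.testing.assert_array_equal(short.delta_cost, longer.delta_cost[:3])

    def test_his_gains_qalys_on_average(self, table1):
        psa = run_psa(table1, n=200, seed=1)
        assert psa.delta_qaly.mean() > 0

    def test_quadrant_and_nmb_agree(self, table1):
        """NMB sign matches the CE-plane quadrant on every iteration:
        dominant draws are always cost-effective, dominated never, and in
        the ambiguous quadrants the ICER-vs-threshold rule decides."""
        psa = run_psa(table1, n=200, seed=2)
        for wtp in DEFAULT_WTP_THRESHOLDS:
            for dc, dq in zip(psa.delta_cost, psa.delta_qaly):
                nmb_pos = wtp * dq - dc > 0
                if dc < 0 and dq > 0:        # dominant (SE quadrant)
                    assert nmb_pos
                elif dc > 0 and dq < 0:      # dominated (NW quadrant)
                    assert not nmb_pos
                elif dq != 0:
                    assert nmb_pos == ((dc / dq < wtp) == (dq > 0))


class TestCeac:
    def test_zero_threshold_with_extra_cost(self, table1):
        psa = run_psa(table1, n=50, seed=3)
        assert all(psa.delta_cost > 0)
        assert ceac(psa, [0.0])[0].probability_cost_effective == 0.0

    def test_large_threshold_limit(self, table1):
        psa = run_psa(table1, n=50, seed=3)
        assert all(psa.delta_qaly > 0)
        assert ceac(psa, [1e15])[0].probability_cost_effective == 1.0

    def test_monotone_in_wtp_when_qalys_gained(self, table1):
        psa = run_psa(table1, n=100, seed=4)
        grid = [0, 1e7, 5e7, 1e8, 2e8, 1e9]
        probs = [c.probability_cost_effective for c in ceac(psa, grid)]
        assert probs == sorted(probs)

    def test_empty_psa_rejected(self, table1):
        psa = run_psa(table1, n=1, seed=0)
        empty = dataclasses.replace(psa, iterations=())
        with pytest.raises(ValueError):
            ceac(empty, [0.0])


class TestCePlane:
    def test_one_row_per_iteration(self, table1):
        psa = run_psa(table1, n=40, seed=6)
        df = export_ce_plane(psa, list(DEFAULT_WTP_THRESHOLDS))
        assert len(df) == 40
        assert df.attrs["wtp_thresholds"] == list(DEFAULT_WTP_THRESHOLDS)

    def test_effectiveness_points_right_of_axis(self, table1):
        """QALY gains are essentially certain; cost gains are not."""
        psa = run_psa(table1, n=300, seed=7)
        df = export_ce_plane(psa)
        assert (df["delta_qaly"] > 0).mean() > 0.95


class TestTornado:
    def test_sorted_by_spread_and_deterministic(self, table1):
        a = owsa(table1)
        b = owsa(table1)
        assert [e.parameter for e in a] == [e.parameter for e in b]
        spreads = [e.spread for e in a]
        assert spreads == sorted(spreads, reverse=True)
        assert all(s >= 0 for s in spreads)

    def test_zero_se_parameter_has_zero_spread(self, table1):
        entries = {e.parameter: e for e in owsa(table1)}
        # outcome discounting is off in the base case, so drO cannot move
        # the ICER even over its full guideline range
        assert entries["drO"].spread == 0.0

    def test_ci95_bounds_clipped_to_domain(self, table1):
        entries = {e.parameter: e for e in owsa(table1)}
        e = entries["tpRA_CAr"]  # mean 0.001, se 0.001: CI crosses zero
        assert e.low_value == 0.0

    def test_pct20_rule(self, table1):
        entries = {e.parameter: e for e in owsa(table1, range_rule="pct20")}
        e = entries["dmcRA"]
        assert e.low_value == pytest.approx(0.8 * 19_728_100)
        assert e.high_value == pytest.approx(1.2 * 19_728_100)

    def test_cost_discount_rate_is_influential(self, table1):
        """The cost discount rate swings the ICER more than any single
        cost or probability parameter, mirroring its prominence in the
        one-way analysis."""
        entries = owsa(table1)
        assert entries[0].parameter == "drC"
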