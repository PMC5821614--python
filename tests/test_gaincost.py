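import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from confscreen import (
    DEFAULT_GRID,
    GainCostParams,
    InputError,
    ParameterError,
    PValueTable,
    decide,
    evaluate_significance_grid,
    total_gain,
)
from confscreen.gaincost import attach_low_gain_warning


def brute_force_gain(train_flags, test_flags, params):
    """Per-compound sum: +hit_gain for each screened active, -cost per well."""
    gain = 0.0
    for is_hit in list(train_flags) + list(test_flags):
        gain += params.hit_gain * is_hit - params.screen_cost
    return gain


class TestTotalGain:
    def test_screen_with_no_hits_is_pure_cost(self):
        params = GainCostParams(hit_gain=400, screen_cost=14)
        assert total_gain(0, 250, 0, 0, params) == -14 * 250

    def test_five_hits_in_hundred_wells(self):
        params = GainCostParams(hit_gain=400, screen_cost=10)
        assert total_gain(0, 0, 5, 100, params) == 1000

    def test_additivity_over_disjoint_sets(self):
        params = GainCostParams(hit_gain=400, screen_cost=6)
        whole = total_gain(3, 50, 7, 200, params)
        assert whole == total_gain(3, 50, 0, 0, params) + total_gain(0, 0, 7, 200, params)

    def test_hits_cannot_exceed_screened(self):
        with pytest.raises(InputError):
            total_gain(5, 3, 0, 0, GainCostParams())
        with pytest.raises(InputError):
            total_gain(0, 0, -1, 5, GainCostParams())

    @settings(max_examples=1000, deadline=None, derandomize=True)
    @given(
        n_tr=st.integers(0, 50), n_te=st.integers(0, 50),
        hit_gain=st.floats(1, 1000), cost=st.floats(1, 50),
        data=st.data(),
    )
    def test_matches_per_compound_brute_force(self, n_tr, n_te, hit_gain, cost, data):
        train_flags = data.draw(st.lists(st.booleans(), min_size=n_tr, max_size=n_tr))
        test_flags = data.draw(st.lists(st.booleans(), min_size=n_te, max_size=n_te))
        params = GainCostParams(hit_gain=hit_gain, screen_cost=cost)
        value = total_gain(sum(train_flags), n_tr, sum(test_flags), n_te, params)
        assert value == pytest.approx(brute_force_gain(train_flags, test_flags, params))

    def test_params_validated(self):
        with pytest.raises(ParameterError):
            GainCostParams(hit_gain=0)
        with pytest.raises(ParameterError):
            GainCostParams(screen_cost=-1)


def perfect_table(truth):
    """p_active=1 for actives / 0 for inactives, and vice versa."""
    truth = np.asarray(truth)
    return PValueTable(
        ids=np.arange(len(truth)),
        p_active=np.where(truth == 1, 1.0, 0.0),
        p_inactive=np.where(truth == 1, 0.0, 1.0),
    )


class TestSignificanceGrid:
    def test_default_grid_spans_confidence_90_to_60(self):
        assert DEFAULT_GRID == (0.1, 0.2, 0.3, 0.4)

    def test_degenerate_both_predictor_selects_nothing(self):
        n = 40
        table = PValueTable(ids=np.arange(n), p_active=np.full(n, 0.9),
                            p_inactive=np.full(n, 0.9))
        truth = np.zeros(n, dtype=int); truth[:4] = 1
        evals = evaluate_significance_grid(
            table, truth, DEFAULT_GRID, GainCostParams(screen_cost=10),
            n_remaining=160, n_train=n, n_train_hits=4,
        )
        levels = [ev for ev in evals if ev.kind == "level"]
        assert all(ev.n_selected == 0 and ev.estimated_test_gain == 0 for ev in levels)
        screen_all = next(ev for ev in evals if ev.kind == "screen_all")
        assert screen_all.estimated_test_gain == pytest.approx(
            160 * (0.1 * 400 - 10)
        )

    def test_perfect_separation_matches_closed_form(self):
        truth = np.array([1] * 10 + [0] * 90)
        table = perfect_table(truth)
        params = GainCostParams(hit_gain=400, screen_cost=10)
        n_remaining = 500
        evals = evaluate_significance_grid(
            table, truth, DEFAULT_GRID, params,
            n_remaining=n_remaining, n_train=100, n_train_hits=10,
        )
        hit_rate = 0.1
        expected = n_remaining * hit_rate * (400 - 10)
        for ev in evals:
            if ev.kind == "level":
                assert ev.n_selected == ev.n_hits_selected == 10
                assert ev.estimated_test_gain == pytest.approx(expected)

    def test_missing_internal_pvalues_are_excluded(self):
        table = PValueTable(
            ids=np.arange(4),
            p_active=np.array([1.0, np.nan, 0.0, 0.0]),
            p_inactive=np.array([0.0, np.nan, 1.0, 1.0]),
        )
        evals = evaluate_significance_grid(
            table, np.array([1, 1, 0, 0]), [0.2], GainCostParams(),
            n_remaining=30, n_train=4, n_train_hits=2,
        )
        assert evals[0].n_evaluated == 3
        # rates scale from the 3 observed compounds: 1 of 3 selected
        assert evals[0].est_screened == pytest.approx(10.0)

    def test_grid_validation(self):
        table = perfect_table([1, 0])
        with pytest.raises(ParameterError):
            evaluate_significance_grid(table, [1, 0], [], GainCostParams(),
                                       10, 2, 1)
        with pytest.raises(ParameterError):
            evaluate_significance_grid(table, [1, 0], [0.0], GainCostParams(),
                                       10, 2, 1)


def make_evals(truth, params, n_remaining=400, grid=DEFAULT_GRID, table=None):
    truth = np.asarray(truth)
    if table is None:
        table = perfect_table(truth)
    return evaluate_significance_grid(
        table, truth, grid, params,
        n_remaining=n_remaining, n_train=len(truth),
        n_train_hits=int((truth == 1).sum()),
    )


class TestDecide:
    def test_all_losses_mean_stop(self):
        truth = np.array([1] + [0] * 199)  # 0.5% hits
        # degenerate predictor: everything dual-labelled -> no subset gain
        table = PValueTable(ids=np.arange(200), p_active=np.full(200, 0.9),
                            p_inactive=np.full(200, 0.9))
        evals = make_evals(truth, GainCostParams(screen_cost=14), table=table)
        decision = decide(evals)
        assert decision.mode == "stop"
        assert decision.estimated_test_gain == 0.0

    def test_screen_all_when_library_rich(self):
        truth = np.array([1] * 50 + [0] * 50)  # 50% hit rate
        table = PValueTable(ids=np.arange(100), p_active=np.full(100, 0.9),
                            p_inactive=np.full(100, 0.9))
        evals = make_evals(truth, GainCostParams(screen_cost=10), table=table)
        assert decide(evals).mode == "screen_all"

    def test_subset_beats_screen_all_under_perfect_separation(self):
        truth = np.array([1] * 10 + [0] * 90)
        evals = make_evals(truth, GainCostParams(screen_cost=10))
        decision = decide(evals)
        assert decision.mode == "screen_subset"
        assert decision.significance == 0.1  # tie over levels -> lowest

    def test_equal_gain_ties_break_to_lower_significance(self):
        evals = make_evals(np.array([1] * 5 + [0] * 45), GainCostParams())
        decision = decide(evals)
        gains = {ev.significance: ev.estimated_test_gain
                 for ev in evals if ev.kind == "level"}
        assert len(set(gains.values())) == 1  # constructed tie
        assert decision.significance == min(gains)

    def test_baselines_required(self):
        evals = make_evals(np.array([1, 0, 0, 0]), GainCostParams())
        with pytest.raises(InputError):
            decide([ev for ev in evals if ev.kind == "level"])

    def test_raising_cost_never_turns_stop_into_screen_all(self):
        truth = np.array([1] * 2 + [0] * 198)
        for low, high in [(6, 10), (10, 14), (6, 14)]:
            d_low = decide(make_evals(truth, GainCostParams(screen_cost=low)))
            d_high = decide(make_evals(truth, GainCostParams(screen_cost=high)))
            if d_low.mode == "stop":
                assert d_high.mode == "stop"


class TestLowGainWarning:
    def test_warning_when_training_cost_dwarfs_subset_gain(self):
        # sparse-hit library: an imperfect predictor selects 10 internal
        # compounds of which 1 is a hit, a small positive subset gain
        n = 1000
        truth = np.zeros(n, dtype=int)
        truth[:2] = 1
        p_active = np.zeros(n)
        p_inactive = np.full(n, 0.9)
        chosen = np.arange(1, 11)  # contains hit index 1
        p_active[chosen] = 0.9
        p_inactive[chosen] = 0.0
        table = PValueTable(ids=np.arange(n), p_active=p_active,
                            p_inactive=p_inactive)
        params = GainCostParams(hit_gain=400, screen_cost=10)
        evals = make_evals(truth, params, n_remaining=4000, table=table)
        decision = attach_low_gain_warning(decide(evals), evals, params, n_train=n)
        best_subset = max(ev.estimated_test_gain for ev in evals if ev.kind == "level")
        assert 0 < best_subset * 5 < 10 * n
        assert any("low expected gain" in w for w in decision.warnings)

    def test_no_warning_when_gain_healthy(self):
        truth = np.array([1] * 30 + [0] * 70)
        params = GainCostParams(screen_cost=6)
        evals = make_evals(truth, params, n_remaining=400)
        decision = attach_low_gain_warning(decide(evals), evals, params, n_train=100)
        assert decision.warnings == []
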