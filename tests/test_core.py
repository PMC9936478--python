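"""Unit and property tests for the household simulation engine."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as hs

from amews.core import (
    Household,
    SimulationParams,
    Strategy,
    StrategySet,
    adapt,
    aggregate_prevalence,
    compute_food_availability,
    evaluate_sufficiency,
    filter_catalog,
    initialize_model,
    select_strategy,
    simplex_catalog,
    simulate,
    step,
    update_malnutrition,
)


def make_table(n, ward="w1", children=1, caps=(1.0, 1.0, 1.0), h_p=1.0, h_a=1.0, wards=None):
    rows = []
    for i in range(n):
        rows.append(
            {
                "id": f"h{i}",
                "ward_id": wards[i] if wards is not None else ward,
                "x": float(i % 10),
                "y": float(i // 10),
                "cap_own": caps[0],
                "cap_network": caps[1],
                "cap_market": caps[2],
                "h_p": h_p,
                "h_a": h_a,
                "n_children": children,
            }
        )
    return pd.DataFrame(rows)


def uniform_factors(wards, months, x=(1.0, 1.0, 1.0)):
    rows = [
        {"ward_id": w, "month": m, "x_own": x[0], "x_net": x[1], "x_buy": x[2]}
        for m in months
        for w in wards
    ]
    return pd.DataFrame(rows)


MONTHS_12 = [f"2019-{i:02d}" for i in range(1, 13)]


class TestStrategy:
    @pytest.mark.parametrize(
        "weights", [(0.5, 0.5), (0.2, 0.2, 0.2), (-0.1, 0.6, 0.5), (1.1, 0.0, -0.1)]
    )
    def test_invalid_weights_raise(self, weights):
        with pytest.raises(ValueError):
            Strategy(weights)

    def test_simplex_catalog_grid(self):
        cat = simplex_catalog(0.25)
        assert len(cat) == 15
        assert all(abs(sum(s.weights) - 1) < 1e-12 for s in cat)
        assert len({s.weights for s in cat}) == 15

    def test_zone_mask_filters_high_own_production(self):
        cat = simplex_catalog(0.25)
        kept = filter_catalog(cat, {"own_production": (0.0, 0.5)})
        assert all(s.weights[0] <= 0.5 for s in kept)
        with pytest.raises(ValueError):
            filter_catalog(cat, {"own_production": (0.99, 1.0), "buy_barter": (0.99, 1.0)})

    def test_strategy_set_rejects_duplicates_and_bad_memory(self):
        with pytest.raises(ValueError):
            StrategySet([(1, 0, 0), (1.0, 1e-12, -1e-12)])
        with pytest.raises(ValueError):
            StrategySet([(1, 0, 0)], memory=[1.0, 2.0])
        with pytest.raises(ValueError):
            StrategySet([])


class TestFoodAndSufficiency:
    @pytest.mark.parametrize(
        "s,h,x,children,expected",
        [
            ((1, 0, 0), (1, 1, 1), (1, 1, 1), 1, 1.0),  # normalization anchor
            ((1, 0, 0), (1, 1, 1), (0.2, 1, 1), 1, 0.2),  # 80% shock on own production
            ((0.5, 0.5, 0), (1, 0, 1), (1, 1, 1), 2, 0.25),
        ],
    )
    def test_food_availability(self, s, h, x, children, expected):
        assert compute_food_availability(s, h, x, children) == pytest.approx(expected)

    def test_food_availability_rejects_negatives(self):
        with pytest.raises(ValueError):
            compute_food_availability((1, 0, 0), (1, 1, 1), (-0.1, 1, 1), 1)
        with pytest.raises(ValueError):
            compute_food_availability((1, 0, 0), (1, 1, 1), (1, 1, 1), 0)

    @pytest.mark.parametrize(
        "food,h_p,h_a,n0,ns,suff",
        [
            (1.0, 1.0, 1.0, 0.5, 1.0, True),
            (1.0, 0.0, 1.0, 0.5, 0.0, False),  # multiplicative annihilation
            (0.8, 0.9, 0.8, 0.5, 0.576, True),
        ],
    )
    def test_sufficiency(self, food, h_p, h_a, n0, ns, suff):
        got_ns, got_suff = evaluate_sufficiency(food, h_p, h_a, n0)
        assert got_ns == pytest.approx(ns)
        assert got_suff is suff

    @pytest.mark.parametrize(
        "history,K,expected",
        [
            ([False, False], 2, True),
            ([True, False], 2, False),
            ([False, True, False], 2, False),  # a sufficient round resets the run
            ([False], 2, False),  # short history: missing rounds count as sufficient
        ],
    )
    def test_update_malnutrition(self, history, K, expected):
        assert update_malnutrition(history, K) is expected


class TestSelection:
    def test_singleton_always_selected(self):
        ss = StrategySet([(1, 0, 0)], memory=[0.0])
        rng = np.random.default_rng(0)
        assert all(select_strategy(ss, rng) == 0 for _ in range(100))

    def test_equal_memory_is_uniform(self):
        ss = StrategySet([(1, 0, 0), (0, 1, 0)], memory=[1.0, 1.0])
        rng = np.random.default_rng(1)
        n = 10_000
        ones = sum(select_strategy(ss, rng) for _ in range(n))
        sigma = np.sqrt(n * 0.25)
        assert abs(ones - n / 2) < 3 * sigma

    def test_memory_ratio_drives_selection(self):
        # memories (2, 1) with zero floor: selection probabilities 2/3 vs 1/3
        ss = StrategySet([(1, 0, 0), (0, 1, 0)], memory=[2.0, 1.0])
        rng = np.random.default_rng(2)
        n = 30_000
        first = sum(1 for _ in range(n) if select_strategy(ss, rng, floor=0.0) == 0)
        p = 2 / 3
        sigma = np.sqrt(n * p * (1 - p))
        assert abs(first - n * p) < 3 * sigma

    def test_zero_memory_zero_floor_falls_back_to_uniform(self):
        ss = StrategySet([(1, 0, 0), (0, 1, 0)], memory=[0.0, 0.0])
        rng = np.random.default_rng(3)
        n = 10_000
        ones = sum(select_strategy(ss, rng, floor=0.0) for _ in range(n))
        assert abs(ones - n / 2) < 3 * np.sqrt(n * 0.25)


def _household(strategies, memory=None, **kw):
    ss = StrategySet(strategies, memory=memory, max_size=kw.pop("max_size", 8))
    hh = Household(
        id="h0",
        ward_id="w1",
        coords=(0, 0),
        capabilities=kw.pop("capabilities", (1, 1, 1)),
        h_p=kw.pop("h_p", 1.0),
        h_a=kw.pop("h_a", 1.0),
        n_children=kw.pop("n_children", 1),
        strategy_set=ss,
        active_strategy=kw.pop("active", 0),
    )
    return hh


class TestAdapt:
    def _neighbor(self, weights, last_ns):
        nb = _household([weights])
        nb.last_ns = last_ns
        return nb

    def test_no_learning_no_spawn_leaves_household_unchanged(self):
        hh = _household([(1, 0, 0)])
        hh.last_ns = 0.1
        before = [tuple(s) for s in hh.strategy_set.strategies]
        params = SimulationParams(learning_rate=0.0, spawn_rate=0.0)
        adapt(hh, [self._neighbor((0, 1, 0), 0.9)], params, np.random.default_rng(0))
        assert [tuple(s) for s in hh.strategy_set.strategies] == before
        assert hh.active_strategy == 0

    def test_certain_learning_copies_strictly_better_neighbor(self):
        hh = _household([(1, 0, 0)])
        hh.last_ns = 0.1
        params = SimulationParams(learning_rate=1.0, spawn_rate=0.0)
        adapt(hh, [self._neighbor((0, 1, 0), 0.9)], params, np.random.default_rng(0))
        assert hh.strategy_set.strategies[hh.active_strategy] == (0, 1, 0)

    def test_not_copied_when_neighbor_is_not_better(self):
        hh = _household([(1, 0, 0)])
        hh.last_ns = 0.9
        params = SimulationParams(learning_rate=1.0, spawn_rate=0.0)
        adapt(hh, [self._neighbor((0, 1, 0), 0.9)], params, np.random.default_rng(0))
        assert hh.strategy_set.strategies[hh.active_strategy] == (1, 0, 0)

    def test_tied_neighbors_split_evenly(self):
        params = SimulationParams(learning_rate=1.0, spawn_rate=0.0)
        rng = np.random.default_rng(4)
        n = 10_000
        picks = 0
        nb_a = self._neighbor((0, 1, 0), 0.9)
        nb_b = self._neighbor((0, 0, 1), 0.9)
        for _ in range(n):
            hh = _household([(1, 0, 0)])
            hh.last_ns = 0.1
            adapt(hh, [nb_a, nb_b], params, rng)
            if hh.strategy_set.strategies[hh.active_strategy] == (0, 1, 0):
                picks += 1
        assert abs(picks - n / 2) < 3 * np.sqrt(n * 0.25)

    def test_empty_neighbors_only_spawn_branch_fires(self):
        hh = _household([(1, 0, 0)])
        hh.last_ns = 0.0
        params = SimulationParams(learning_rate=1.0, spawn_rate=1.0)
        adapt(hh, [], params, np.random.default_rng(5))
        assert len(hh.strategy_set) == 2  # spawned, nothing copied
        assert hh.strategy_set.strategies[hh.active_strategy] == (1, 0, 0)

    def test_spawn_eviction_respects_cap_and_active(self):
        hh = _household([(1, 0, 0), (0, 1, 0)], memory=[0.5, 0.01], max_size=2)
        params = SimulationParams(learning_rate=0.0, spawn_rate=1.0)
        adapt(hh, [], params, np.random.default_rng(6))
        assert len(hh.strategy_set) == 2
        # lowest-memory non-active strategy was evicted, active retained
        assert hh.strategy_set.strategies[hh.active_strategy] == (1, 0, 0)


class TestInitialization:
    def test_singleton_catalog_forces_strategy(self):
        table = make_table(20)
        params = SimulationParams(seed=1)
        state = initialize_model(table, params, [Strategy((0, 1, 0))])
        assert all(
            hh.strategy_set.strategies == [(0, 1, 0)] and hh.active_strategy == 0
            for hh in state.households
        )

    def test_same_seed_identical_assignments(self):
        table = make_table(50)
        cat = simplex_catalog()
        a = initialize_model(table, SimulationParams(seed=7), cat)
        b = initialize_model(table, SimulationParams(seed=7), cat)
        for ha, hb in zip(a.households, b.households):
            assert ha.strategy_set.strategies == hb.strategy_set.strategies
            assert ha.active_strategy == hb.active_strategy
            assert ha.coords == hb.coords

    def test_initial_active_frequencies_uniform(self):
        # catalog of 6, 10,000 households: active-strategy counts within
        # 3 sigma of the uniform multinomial
        table = make_table(10_000)
        cat = simplex_catalog(0.25)[:6]
        params = SimulationParams(seed=11, neighborhood_k=0, init_set_size=1)
        state = initialize_model(table, params, cat)
        counts = np.zeros(6)
        lookup = {s.weights: i for i, s in enumerate(cat)}
        for hh in state.households:
            counts[lookup[hh.strategy_set.strategies[hh.active_strategy]]] += 1
        n, p = 10_000, 1 / 6
        sigma = np.sqrt(n * p * (1 - p))
        assert np.all(np.abs(counts - n * p) < 3 * sigma)

    def test_empty_table_and_empty_catalog_raise(self):
        with pytest.raises(ValueError):
            initialize_model(make_table(0), SimulationParams(), simplex_catalog())
        with pytest.raises(ValueError):
            initialize_model(make_table(3), SimulationParams(), [])


class TestStepAndAggregation:
    def test_fixed_seed_reproduces_trajectory(self):
        table = make_table(60, caps=(0.8, 0.5, 0.3), h_a=0.7, children=2)
        fac = uniform_factors(["w1"], MONTHS_12, x=(0.4, 1.0, 1.0))
        params = SimulationParams(sufficiency_threshold=0.2, seed=3)
        a = simulate(table, fac, params)
        b = simulate(table, fac, params)
        pd.testing.assert_frame_equal(a, b)

    def test_each_household_updates_exactly_once_per_step(self):
        table = make_table(30)
        fac = uniform_factors(["w1"], MONTHS_12)
        params = SimulationParams(sufficiency_threshold=0.4, seed=5)
        state = initialize_model(table, params, simplex_catalog())
        by_month = {m: {"w1": (1, 1, 1)} for m in MONTHS_12}
        for m in MONTHS_12[:4]:
            step(state, by_month[m])
        assert all(len(hh.sufficiency_history) == 4 for hh in state.households)

    def test_benign_world_zero_prevalence(self):
        # all factors 1, full capabilities, n_0 < 1/max children
        table = make_table(40, children=2)
        fac = uniform_factors(["w1"], MONTHS_12)
        params = SimulationParams(sufficiency_threshold=0.4, seed=9)
        out = simulate(table, fac, params)
        assert (out["prevalence_pct"] == 0).all()

    def test_missing_stressor_ward_raises(self):
        table = make_table(10)
        params = SimulationParams(seed=0)
        state = initialize_model(table, params, simplex_catalog())
        with pytest.raises(KeyError):
            step(state, {"other_ward": (1, 1, 1)})

    def test_strategy_weights_conserved_through_dynamics(self):
        # spawning and adoption keep every strategy on the simplex
        table = make_table(40, caps=(0.9, 0.4, 0.2), h_a=0.6, children=2)
        fac = uniform_factors(["w1"], MONTHS_12, x=(0.3, 1.0, 1.0))
        params = SimulationParams(
            learning_rate=0.1, spawn_rate=0.1, sufficiency_threshold=0.3, seed=13
        )
        state = initialize_model(table, params, simplex_catalog())
        by_month = {m: {"w1": (0.3, 1.0, 1.0)} for m in MONTHS_12}
        for m in MONTHS_12:
            step(state, by_month[m])
            for hh in state.households:
                for s in hh.strategy_set.strategies:
                    assert abs(sum(s) - 1) < 1e-9
                    assert all(v >= 0 for v in s)
                assert len(hh.strategy_set) <= hh.strategy_set.max_size

    def test_prevalence_bounds_and_child_weighting(self):
        table = make_table(6, children=1)
        table.loc[3:, "n_children"] = [2, 3, 4]
        params = SimulationParams(seed=0)
        state = initialize_model(table, params, simplex_catalog())
        for i, hh in enumerate(state.households):
            hh.malnourished = i in (1, 4)  # 1 child + 3 children malnourished
        roster_total = 1 + 1 + 1 + 2 + 3 + 4
        roster_mal = 1 + 3
        assert aggregate_prevalence(state, "w1") == pytest.approx(100 * roster_mal / roster_total)
        with pytest.raises(KeyError):
            aggregate_prevalence(state, "nowhere")

    def test_zero_and_simple_fraction_prevalence(self):
        table = make_table(30)
        state = initialize_model(table, SimulationParams(seed=0), simplex_catalog())
        assert aggregate_prevalence(state, "w1") == 0.0
        for hh in state.households[:3]:
            hh.malnourished = True
        assert aggregate_prevalence(state, "w1") == pytest.approx(10.0)


class TestStochasticProperties:
    def _mean_prevalence(self, x_mult, lam=0.05, seeds=range(20)):
        table = make_table(60, caps=(0.85, 0.5, 0.25), h_a=0.7, children=2)
        months = MONTHS_12
        out = []
        for s in seeds:
            fac = uniform_factors(["w1"], months, x=x_mult)
            params = SimulationParams(
                learning_rate=lam,
                spawn_rate=0.01,
                sufficiency_threshold=0.12,
                init_set_size=1,
                seed=1000 + s,
            )
            out.append(simulate(table, fac, params)["prevalence_pct"].mean())
        return float(np.mean(out))

    def test_shock_monotonicity_in_each_dimension(self):
        # lowering any effectiveness factor never lowers mean prevalence
        base = self._mean_prevalence((1.0, 1.0, 1.0))
        for d in range(3):
            x_mid = tuple(0.6 if i == d else 1.0 for i in range(3))
            x_low = tuple(0.3 if i == d else 1.0 for i in range(3))
            mid = self._mean_prevalence(x_mid)
            low = self._mean_prevalence(x_low)
            assert base <= mid + 1e-9
            assert mid <= low + 1e-9

    def test_higher_learning_rate_mitigates_sustained_shock(self):
        shocked = (0.35, 1.0, 1.0)
        means = [self._mean_prevalence(shocked, lam=m * 0.05) for m in (0.5, 1.0, 1.5)]
        assert means[0] >= means[1] >= means[2]


@settings(derandomize=True, max_examples=30, deadline=None)
@given(
    hs.lists(hs.floats(min_value=0.01, max_value=1.0), min_size=3, max_size=3),
)
def test_strategy_normalization_roundtrip(raw):
    total = sum(raw)
    s = Strategy([v / total for v in raw])
    assert abs(sum(s.weights) - 1) < 1e-9
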