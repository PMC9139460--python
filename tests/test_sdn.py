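"""Storage distribution network: routing order, capacity, FIFO forgetting.

The independent oracle used here is a discrete-event bookkeeper that knows
only the storage rules (plateau, exact exponential decay, lowest-rate
eviction, threshold forgetting) and tracks items analytically, without any
circuit machinery.
"""

import math

import pytest
from hypothesis import given, settings, strategies as st

from wmcircuit import (SdnParams, advance_time, build_sdn, feature_rate,
                       present_stimulus, route_stimulus, store_or_update)
from wmcircuit.sdn import GATES, SET_IDS


class DecayOracle:
    """Analytic discrete-event model of a 4-slot FIFO store."""

    def __init__(self, params: SdnParams):
        self.plateau = params.plateau_rate
        self.tau = params.decay_time_constant
        self.threshold = params.forget_threshold
        self.items = {}  # feature -> (last_refresh_time, order)
        self.order = 0
        self.evictions = []

    def rate(self, feature, t):
        t0, _ = self.items[feature]
        return self.plateau * math.exp(-(t - t0) / self.tau)

    def _forget(self, t):
        horizon = self.tau * math.log(self.plateau / self.threshold)
        for f in [f for f, (t0, _) in self.items.items() if t - t0 > horizon]:
            del self.items[f]

    def present(self, feature, t):
        self._forget(t)
        self.order += 1
        if feature in self.items:
            self.items[feature] = (t, self.items[feature][1])
            return
        if len(self.items) == 4:
            victim = min(self.items, key=lambda f: (self.rate(f, t),
                                                    -self.items[f][0],
                                                    self.items[f][1]))
            self.evictions.append(victim)
            del self.items[victim]
        self.items[feature] = (t, self.order)

    def held(self, t):
        self._forget(t)
        return set(self.items)


class TestBuild:
    def test_initial_state_has_four_free_sets(self):
        state = build_sdn()
        assert state.free_sets() == list(SET_IDS)
        assert state.held_count() == 0
        assert all(v == 0.0 for v in state.node_states.values())

    def test_weak_inhibition_rejected_with_edge_named(self):
        params = SdnParams(weight_overrides={"I11->E22": 0.5})
        with pytest.raises(ValueError, match="I11->E22"):
            build_sdn(params)

    def test_rebuild_is_deterministic(self):
        assert build_sdn() == build_sdn()


class TestRouting:
    def test_first_stimulus_selects_set11_and_silences_siblings(self):
        state, selected = route_stimulus(build_sdn(), "a", 1.0)
        assert selected == "set11"
        for node in ("E22", "E32", "E42"):
            assert state.node_states[node] == 0.0
        for node in ("E00", "E11", "E12", "I11", "I12"):
            assert state.node_states[node] > 0.0

    def test_sequential_stimuli_fill_branches_in_order_then_wrap(self):
        state = build_sdn()
        selections = []
        for i in range(6):
            state, set_id = present_stimulus(state, f"f{i}")
            selections.append(set_id)
            state = advance_time(state, 500.0)
        assert selections == ["set11", "set21", "set31", "set41",
                              "set11", "set21"]

    def test_third_stimulus_takes_branch_three_when_two_are_locked(self):
        state = build_sdn()
        for f in ("a", "b"):
            state, _ = present_stimulus(state, f)
            state = advance_time(state, 100.0)
        state, selected = route_stimulus(state, "c", 1.0)
        assert selected == "set31"
        assert state.node_states["E12"] == 0.0  # E11 branch locked
        assert state.node_states["E23"] == 0.0  # E21 branch locked
        assert state.node_states["E34"] > 0.0

    def test_exactly_one_gate_fires_per_routing(self):
        state = build_sdn()
        for i in range(4):
            state, _ = present_stimulus(state, f"f{i}")
            gates_on = [g for g in GATES if state.node_states[g] > 0.0]
            assert len(gates_on) == 1
            state = advance_time(state, 200.0)

    def test_repeated_feature_reselects_its_original_set(self):
        state = build_sdn()
        state, first = present_stimulus(state, "a")
        state = advance_time(state, 2000.0)
        state, _ = present_stimulus(state, "b")
        state = advance_time(state, 2000.0)
        decayed = feature_rate(state, "a")
        state, again = present_stimulus(state, "a")
        assert again == first
        assert feature_rate(state, "a") == state.params.plateau_rate > decayed
        assert state.held_count() == 2

    def test_subthreshold_amplitude_does_not_route(self):
        state = build_sdn()
        new, selected = route_stimulus(state, "a", 0.1)
        assert selected is None
        assert new.sets == state.sets
        assert new.events[-1]["event"] == "subthreshold"

    def test_rate_mode_routes_like_logic_mode(self):
        state = build_sdn(SdnParams(mode="rate"))
        selections = []
        for i in range(4):
            state, set_id = present_stimulus(state, f"f{i}")
            selections.append(set_id)
            state = advance_time(state, 500.0)
        assert selections == ["set11", "set21", "set31", "set41"]

    def test_forgotten_branch_reopens(self):
        state = build_sdn()
        for f in ("a", "b", "c"):
            state, _ = present_stimulus(state, f)
            state = advance_time(state, 100.0)
        # push every item past total forgetting, then store again
        horizon = state.params.decay_time_constant * math.log(
            1.0 / state.params.forget_fraction)
        state = advance_time(state, horizon + 1000.0)
        assert state.held_count() == 0
        state, selected = present_stimulus(state, "d")
        assert selected == "set11"


class TestStorage:
    def test_capacity_never_exceeds_four(self):
        state = build_sdn()
        counts = []
        for i in range(6):
            state, _ = present_stimulus(state, f"f{i}")
            counts.append(state.held_count())
            state = advance_time(state, 300.0)
        assert counts == [1, 2, 3, 4, 4, 4]

    def test_fifth_item_evicts_the_earliest_stored(self):
        state = build_sdn()
        for i in range(5):
            state, _ = present_stimulus(state, f"f{i}")
            state = advance_time(state, 300.0)
        evicted = [e for e in state.events if e["event"] == "evicted"]
        assert [e["feature_id"] for e in evicted] == ["f0"]

    def test_rehearsal_redirects_eviction_to_the_now_weakest_item(self):
        state = build_sdn()
        for i in range(4):
            state, _ = present_stimulus(state, f"f{i}")
            state = advance_time(state, 300.0)
        state, _ = present_stimulus(state, "f0")  # rehearse the oldest
        state = advance_time(state, 300.0)
        state, _ = present_stimulus(state, "f4")
        evicted = [e["feature_id"] for e in state.events if e["event"] == "evicted"]
        assert evicted == ["f1"]

    def test_refreshing_twice_keeps_the_held_count(self):
        state = build_sdn()
        state, _ = present_stimulus(state, "a")
        state = advance_time(state, 50.0)
        state, _ = present_stimulus(state, "a")
        state = advance_time(state, 50.0)
        state, _ = present_stimulus(state, "a")
        assert state.held_count() == 1

    def test_unknown_set_handle_rejected(self):
        with pytest.raises(ValueError, match="set99"):
            store_or_update(build_sdn(), "set99", "a")


class TestDecay:
    def test_advancing_an_empty_network_only_moves_the_clock(self):
        state = build_sdn()
        new = advance_time(state, 1000.0)
        assert new.clock == 1000.0
        assert new.sets == state.sets and new.events == []

    def test_rates_decay_monotonically_and_cross_the_threshold(self):
        params = SdnParams()
        state = build_sdn(params)
        state, _ = present_stimulus(state, "a")
        rates = [feature_rate(state, "a")]
        for _ in range(10):
            state = advance_time(state, 5000.0)
            rates.append(feature_rate(state, "a"))
        positive = [r for r in rates if r > 0]
        assert positive == sorted(positive, reverse=True)
        assert state.held_count() == 0
        forgotten = [e for e in state.events if e["event"] == "forgotten"]
        assert len(forgotten) == 1
        expected_cross = params.decay_time_constant * math.log(
            1.0 / params.forget_fraction)
        assert forgotten[0]["t"] == pytest.approx(expected_cross, rel=1e-9)

    def test_earlier_item_is_always_the_weaker_one(self):
        state = build_sdn()
        state, _ = present_stimulus(state, "first")
        state = advance_time(state, 1000.0)
        state, _ = present_stimulus(state, "second")
        for _ in range(5):
            state = advance_time(state, 2000.0)
            r1, r2 = feature_rate(state, "first"), feature_rate(state, "second")
            assert r1 < r2

    def test_nonpositive_advance_rejected(self):
        with pytest.raises(ValueError):
            advance_time(build_sdn(), 0.0)


@st.composite
def schedules(draw):
    n = draw(st.integers(min_value=1, max_value=12))
    feats = [draw(st.integers(min_value=0, max_value=6)) for _ in range(n)]
    gaps = [draw(st.floats(min_value=10.0, max_value=30000.0)) for _ in range(n)]
    return list(zip(feats, gaps))


class TestFifoOracle:
    @settings(max_examples=40, deadline=None, derandomize=True)
    @given(schedules())
    def test_eviction_order_and_held_set_match_the_analytic_oracle(self, schedule):
        params = SdnParams()
        state = build_sdn(params)
        oracle = DecayOracle(params)
        t = 0.0
        for feat, gap in schedule:
            state, _ = present_stimulus(state, f"f{feat}")
            oracle.present(f"f{feat}", t)
            assert state.held_count() <= 4
            held = {it.feature_id for it in state.held_items()}
            assert held == oracle.held(t)
            state = advance_time(state, gap)
            t += gap
        evicted = [e["feature_id"] for e in state.events if e["event"] == "evicted"]
        assert evicted == oracle.evictions

    @settings(max_examples=25, deadline=None, derandomize=True)
    @given(schedules())
    def test_evicted_set_always_has_the_minimal_rate(self, schedule):
        state = build_sdn()
        for feat, gap in schedule:
            before = {it.set_id: it.stored_rate for it in state.held_items()}
            state, _ = present_stimulus(state, f"f{feat}")
            if state.events and state.events[-2:][0]["event"] == "evicted":
                victim = state.events[-2]["set_id"]
                assert before[victim] == min(before.values())
            state = advance_time(state, gap)
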