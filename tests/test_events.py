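"""Rearrangement event model: legality, state effects, shortest paths.

The minimum-cost search is checked against an independent oracle:
exhaustive enumeration of all event sequences up to a fixed length on a
small state grid.
"""

import itertools

import numpy as np
import pytest

from karyokit.events import (
    CF,
    FISSION,
    INV_GAIN,
    INV_LOSS,
    TF,
    EventModel,
    KaryoState,
    apply_event,
    event_distance,
    fusion_dominated_model,
    is_legal,
    legal_moves,
    unit_cost_model,
)


def enumerate_min_cost(s_from, s_to, model, max_events=8):
    """Oracle: breadth-first enumeration of all legal event sequences up
    to ``max_events``, tracking the cheapest cost reaching each state."""
    frontier = {s_from: 0.0}
    best = {s_from: 0.0}
    for _ in range(max_events):
        nxt = {}
        for state, cost in frontier.items():
            for ev, succ in legal_moves(state, model):
                c = cost + model.cost(ev)
                if c < best.get(succ, np.inf):
                    best[succ] = c
                    nxt[succ] = c
                elif c < nxt.get(succ, np.inf) and c <= best[succ]:
                    nxt[succ] = c
        frontier = nxt
    return best.get(s_to, np.inf)


class TestApplyEvent:
    def test_centric_fusion_reduces_2n_by_2(self):
        s = apply_event(KaryoState(24, 0), CF)
        assert s == KaryoState(23, 1)
        assert s.diploid_number == 46

    def test_state_effects_and_arm_bookkeeping(self):
        s = KaryoState(10, 4)
        assert apply_event(s, CF) == KaryoState(9, 5)  # arms 14 -> 14
        assert apply_event(s, TF) == KaryoState(9, 4)  # arms 14 -> 13
        assert apply_event(s, FISSION) == KaryoState(11, 3)  # arms kept
        assert apply_event(s, INV_GAIN) == KaryoState(10, 5)
        assert apply_event(s, INV_LOSS) == KaryoState(10, 3)

    def test_fusion_then_fission_roundtrip(self):
        s = KaryoState(10, 4)
        assert apply_event(apply_event(s, CF), FISSION) == s

    @pytest.mark.parametrize(
        "state,event",
        [
            (KaryoState(2, 1), CF),  # only one acrocentric
            (KaryoState(5, 0), FISSION),  # nothing to split
            (KaryoState(5, 0), INV_LOSS),
            (KaryoState(5, 5), INV_GAIN),
            (KaryoState(1, 0), TF),
            (KaryoState(3, 3), TF),  # no acrocentric participant
        ],
    )
    def test_illegal_events_rejected(self, state, event):
        assert not is_legal(state, event)
        with pytest.raises(ValueError):
            apply_event(state, event)

    def test_invalid_state_rejected(self):
        with pytest.raises(ValueError):
            KaryoState(3, 4)
        with pytest.raises(ValueError):
            KaryoState(0, 0)


class TestEventDistance:
    def test_identity_zero(self):
        path = event_distance(KaryoState(12, 3), KaryoState(12, 3))
        assert path.cost == 0 and path.events == ()

    def test_single_fusion_step(self):
        path = event_distance(KaryoState(24, 0), KaryoState(23, 1), unit_cost_model())
        assert path.cost == 1 and path.events == (CF,)

    def test_fusions_plus_inversions_to_summary_state(self):
        # (24,0) -> (21,6): 3 centric fusions give (21,3), then 3 inversions
        path = event_distance(KaryoState(24, 0), KaryoState(21, 6), unit_cost_model())
        assert path.cost == 6
        assert path.events.count(CF) == 3 and path.events.count(INV_GAIN) == 3

    def test_deterministic_tiebreak_prefers_cf_first(self):
        path = event_distance(KaryoState(24, 0), KaryoState(21, 6), unit_cost_model())
        # lexicographic event order puts the fusions before the inversions
        assert path.events == (CF, CF, CF, INV_GAIN, INV_GAIN, INV_GAIN)

    def test_unreachable_reported(self):
        model = EventModel(enabled=frozenset({CF}), n_max=30)
        res = event_distance(KaryoState(10, 2), KaryoState(12, 0), model)
        assert not res.reachable and res.cost == np.inf

    def test_arm_bookkeeping_along_path(self):
        delta = {CF: 0, TF: -1, FISSION: 0, INV_GAIN: 1, INV_LOSS: -1}
        path = event_distance(KaryoState(24, 0), KaryoState(17, 7), unit_cost_model())
        arms = 24
        for ev in path.events:
            arms += delta[ev]
        assert arms == 17 + 7

    def test_matches_enumeration_oracle_on_random_pairs(self):
        """Dijkstra equals exhaustive sequence enumeration (unit costs,
        <= 8 events, n <= 10) on 100 random state pairs."""
        rng = np.random.default_rng(2024)
        model = unit_cost_model(n_max=10)
        states = [KaryoState(n, b) for n in range(1, 11) for b in range(n + 1)]
        for _ in range(100):
            a, b = rng.choice(len(states), size=2)
            s_from, s_to = states[int(a)], states[int(b)]
            oracle = enumerate_min_cost(s_from, s_to, model, max_events=8)
            got = event_distance(s_from, s_to, model)
            if np.isfinite(oracle):
                assert got.cost == oracle, (s_from, s_to)
                assert len(got.events) == oracle  # unit costs
            else:
                assert got.cost > 8 or not got.reachable

    def test_weighted_costs_respected(self):
        # going up one chromosome costs a fission (3), not a fusion
        model = fusion_dominated_model()
        up = event_distance(KaryoState(23, 1), KaryoState(24, 0), model)
        assert up.cost == 3 and up.events == (FISSION,)

    def test_triangle_inequality(self):
        rng = np.random.default_rng(5)
        model = fusion_dominated_model(n_max=12)
        states = [KaryoState(n, b) for n in range(2, 12) for b in range(n + 1)]
        for _ in range(50):
            a, b, c = (states[int(i)] for i in rng.choice(len(states), size=3))
            dab = event_distance(a, b, model).cost
            dbc = event_distance(b, c, model).cost
            dac = event_distance(a, c, model).cost
            assert dac <= dab + dbc + 1e-12

    def test_symmetry_under_symmetric_costs_only(self):
        a, b = KaryoState(12, 2), KaryoState(9, 5)
        sym = unit_cost_model()
        assert (
            event_distance(a, b, sym).cost == event_distance(b, a, sym).cost
        )
        directional = fusion_dominated_model()
        assert (
            event_distance(a, b, directional).cost
            < event_distance(b, a, directional).cost
        )
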