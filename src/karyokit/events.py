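"""Chromosome rearrangement event model on abstract karyotype states.

A karyotype is summarized as a state (n, b): haploid chromosome count n
and haploid biarmed count b (0 <= b <= n). Pair identity is deliberately
discarded — genus-level reasoning about chromosome-number evolution
operates on 2n and the biarmed count alone, and per-pair ancestral
assignment is unidentifiable from karyotype morphology.

Moves and their state effects (haploid arm number is n + b, FN = 2(n+b)):

=====================  ==============  =============  ============
event                  state change    requires       arm change
=====================  ==============  =============  ============
centric fusion (cF)    (n-1, b+1)      n - b >= 2     0
tandem fusion (tF)     (n-1, b)        n >= 2         -1
fission                (n+1, b-1)      b >= 1         0
inversion a->biarmed   (n,   b+1)      n - b >= 1     +1
inversion biarmed->a   (n,   b-1)      b >= 1         -1
=====================  ==============  =============  ============

A centric (Robertsonian) fusion joins two acrocentrics into one biarmed
chromosome; a tandem fusion joins two chromosomes end to end, losing one
arm; a fission splits a biarmed chromosome into two acrocentrics; a
pericentric inversion moves the centromere, converting acrocentric <->
biarmed without changing n. Both inversion directions share one cost.

Minimum-cost event paths between states are found by Dijkstra search on
the bounded state grid, with a lexicographic tie-break over event labels
(cF < tF < Inv < fission) so co-optimal paths resolve deterministically.
"""

from __future__ import annotations

import heapq
from dataclasses import dataclass, field
from typing import Iterable, Mapping

CF = "cF"
TF = "tF"
FISSION = "fission"
INV_GAIN = "Inv+"  # acrocentric -> biarmed
INV_LOSS = "Inv-"  # biarmed -> acrocentric

#: deterministic tie-break order among co-optimal paths
EVENT_ORDER = {CF: 0, TF: 1, INV_GAIN: 2, INV_LOSS: 3, FISSION: 4}

#: events sharing a configured cost key
_COST_KEY = {CF: CF, TF: TF, FISSION: FISSION, INV_GAIN: "Inv", INV_LOSS: "Inv"}


@dataclass(frozen=True, order=True)
class KaryoState:
    """Abstract karyotype state: haploid count n, haploid biarmed count b."""

    n: int
    b: int

    def __post_init__(self) -> None:
        if self.n < 1:
            raise ValueError(f"n must be >= 1, got {self.n}")
        if not (0 <= self.b <= self.n):
            raise ValueError(f"b must satisfy 0 <= b <= n, got b={self.b}, n={self.n}")

    @property
    def diploid_number(self) -> int:
        return 2 * self.n

    @property
    def arm_number(self) -> int:
        """Haploid arm count n + b (fundamental number is twice this)."""
        return self.n + self.b

    @property
    def fundamental_number(self) -> int:
        return 2 * self.arm_number


@dataclass(frozen=True)
class EventModel:
    """Move set with per-event non-negative costs.

    ``costs`` keys: cF, tF, Inv, fission. ``enabled`` lists the usable
    events; the two inversion directions are enabled together via "Inv".
    ``n_max`` bounds the searched state grid (haploid count).
    """

    costs: Mapping[str, float] = field(
        default_factory=lambda: {CF: 1.0, TF: 1.0, "Inv": 1.0, FISSION: 1.0}
    )
    enabled: frozenset[str] = frozenset({CF, TF, "Inv", FISSION})
    n_max: int = 40

    def __post_init__(self) -> None:
        for key in (CF, TF, "Inv", FISSION):
            if key not in self.costs:
                raise ValueError(f"missing cost for event {key!r}")
            if self.costs[key] < 0:
                raise ValueError(f"negative cost for event {key!r}")
        unknown = set(self.enabled) - {CF, TF, "Inv", FISSION}
        if unknown:
            raise ValueError(f"unknown enabled events: {sorted(unknown)}")
        if not self.enabled:
            raise ValueError("at least one event must be enabled")
        if self.n_max < 1:
            raise ValueError("n_max must be >= 1")

    def enabled_moves(self) -> list[str]:
        moves = []
        for ev in (CF, TF, INV_GAIN, INV_LOSS, FISSION):
            if _COST_KEY[ev] in self.enabled or ev in self.enabled:
                moves.append(ev)
        return moves

    def cost(self, event: str) -> float:
        return float(self.costs[_COST_KEY[event]])


def unit_cost_model(n_max: int = 40, enabled: Iterable[str] | None = None) -> EventModel:
    """All enabled events cost 1; all events enabled by default."""
    en = frozenset(enabled) if enabled is not None else frozenset({CF, TF, "Inv", FISSION})
    return EventModel(enabled=en, n_max=n_max)


def fusion_dominated_model(n_max: int = 40) -> EventModel:
    """Headline preset: fission cost 3, other events cost 1.

    Encodes the directional hypothesis that karyotype evolution in this
    group proceeded mostly by fusions and inversions (chromosome count
    down, biarmed count up); fissions stay possible but expensive.
    """
    return EventModel(
        costs={CF: 1.0, TF: 1.0, "Inv": 1.0, FISSION: 3.0},
        enabled=frozenset({CF, TF, "Inv", FISSION}),
        n_max=n_max,
    )


def is_legal(state: KaryoState, event: str) -> bool:
    if event == CF:
        return state.n - state.b >= 2
    if event == TF:
        # needs an acrocentric participant so the b <= n invariant survives
        return state.n >= 2 and state.n - state.b >= 1
    if event == FISSION:
        return state.b >= 1
    if event == INV_GAIN:
        return state.n - state.b >= 1
    if event == INV_LOSS:
        return state.b >= 1
    raise ValueError(f"unknown event {event!r}")


def apply_event(state: KaryoState, event: str) -> KaryoState:
    """Apply one rearrangement event; raises if it is illegal in ``state``."""
    if event == CF:
        if state.n - state.b < 2:
            raise ValueError(
                f"centric fusion needs two acrocentrics (n - b >= 2), "
                f"state has n - b = {state.n - state.b}"
            )
        return KaryoState(state.n - 1, state.b + 1)
    if event == TF:
        if state.n < 2 or state.n - state.b < 1:
            raise ValueError(
                "tandem fusion needs n >= 2 and an acrocentric participant "
                "(n - b >= 1)"
            )
        return KaryoState(state.n - 1, state.b)
    if event == FISSION:
        if state.b < 1:
            raise ValueError("fission needs a biarmed chromosome (b >= 1)")
        return KaryoState(state.n + 1, state.b - 1)
    if event == INV_GAIN:
        if state.n - state.b < 1:
            raise ValueError("inversion a->biarmed needs an acrocentric (n - b >= 1)")
        return KaryoState(state.n, state.b + 1)
    if event == INV_LOSS:
        if state.b < 1:
            raise ValueError("inversion biarmed->a needs a biarmed chromosome (b >= 1)")
        return KaryoState(state.n, state.b - 1)
    raise ValueError(f"unknown event {event!r}")


def legal_moves(state: KaryoState, model: EventModel) -> list[tuple[str, KaryoState]]:
    """Enabled, legal (event, successor) moves from ``state`` within n_max."""
    out = []
    for ev in model.enabled_moves():
        if is_legal(state, ev):
            nxt = apply_event(state, ev)
            if nxt.n <= model.n_max:
                out.append((ev, nxt))
    return out


@dataclass(frozen=True)
class EventPath:
    """A minimum-cost event sequence between two states."""

    cost: float
    events: tuple[str, ...]
    states: tuple[KaryoState, ...]
    reachable: bool = True


def event_distance(
    s_from: KaryoState, s_to: KaryoState, model: EventModel | None = None
) -> EventPath:
    """Minimum total cost from ``s_from`` to ``s_to`` under ``model``.

    Dijkstra on the state grid bounded by ``model.n_max``; among
    co-optimal paths the lexicographically smallest event sequence
    (cF < tF < Inv < fission order) is returned. If no path exists
    within the grid, returns ``EventPath(inf, (), (), reachable=False)``.
    """
    if model is None:
        model = unit_cost_model()
    if s_from.n > model.n_max or s_to.n > model.n_max:
        raise ValueError(
            f"state outside grid (n_max={model.n_max}): {s_from}, {s_to}"
        )
    if s_from == s_to:
        return EventPath(0.0, (), (s_from,))

    # priority: (cost, event-rank tuple) gives the deterministic tie-break
    heap: list[tuple[float, tuple[int, ...], KaryoState]] = [(0.0, (), s_from)]
    best: dict[KaryoState, tuple[float, tuple[int, ...]]] = {s_from: (0.0, ())}
    parent: dict[KaryoState, tuple[KaryoState, str]] = {}
    while heap:
        cost, ranks, state = heapq.heappop(heap)
        if best.get(state) != (cost, ranks):
            continue
        if state == s_to:
            events: list[str] = []
            states = [state]
            cur = state
            while cur != s_from:
                prev, ev = parent[cur]
                events.append(ev)
                states.append(prev)
                cur = prev
            return EventPath(cost, tuple(reversed(events)), tuple(reversed(states)))
        for ev, nxt in legal_moves(state, model):
            ncost = cost + model.cost(ev)
            nranks = ranks + (EVENT_ORDER[ev],)
            if nxt not in best or (ncost, nranks) < best[nxt]:
                best[nxt] = (ncost, nranks)
                parent[nxt] = (state, ev)
                heapq.heappush(heap, (ncost, nranks, nxt))
    return EventPath(float("inf"), (), (), reachable=False)


def state_grid(model: EventModel) -> list[KaryoState]:
    """All states (n, b) with 1 <= n <= n_max, 0 <= b <= n, in fixed order."""
    return [
        KaryoState(n, b) for n in range(1, model.n_max + 1) for b in range(n + 1)
    ]


_DMAT_CACHE: dict[tuple, tuple] = {}


def _model_key(model: EventModel) -> tuple:
    return (
        tuple(sorted((k, float(v)) for k, v in model.costs.items())),
        tuple(sorted(model.enabled)),
        model.n_max,
    )


def distance_matrix(model: EventModel) -> tuple[list[KaryoState], "object"]:
    """All-pairs minimum costs over the state grid.

    Returns (states, D) with D[i, j] the cost from states[i] to states[j]
    (inf where unreachable). Computed by running Dijkstra from every
    source over the sparse move graph; used as the transition-cost matrix
    in ancestral reconstruction. Cached per model configuration.
    """
    import numpy as np

    key = _model_key(model)
    if key in _DMAT_CACHE:
        return _DMAT_CACHE[key]

    states = state_grid(model)
    index = {s: i for i, s in enumerate(states)}
    m = len(states)
    D = np.full((m, m), np.inf)
    # plain Dijkstra per source; the grid is small (O(n_max^2) states)
    adj: list[list[tuple[int, float]]] = [[] for _ in range(m)]
    for s, i in index.items():
        for ev, nxt in legal_moves(s, model):
            adj[i].append((index[nxt], model.cost(ev)))
    for src in range(m):
        dist = D[src]
        dist[src] = 0.0
        heap = [(0.0, src)]
        while heap:
            d, u = heapq.heappop(heap)
            if d > dist[u]:
                continue
            for v, w in adj[u]:
                nd = d + w
                if nd < dist[v]:
                    dist[v] = nd
                    heapq.heappush(heap, (nd, v))
    _DMAT_CACHE[key] = (states, D)
    return states, D


def project_karyotype(karyotype) -> KaryoState:
    """Project a Karyotype onto its (n, b) summary state."""
    n = len(karyotype.pairs)
    b = sum(1 for p in karyotype.pairs if p.biarmed)
    return KaryoState(n, b)
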