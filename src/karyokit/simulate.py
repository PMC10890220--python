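"""Synthetic data generators for the two pipeline stages.

Two generators make every stage testable without laboratory data:

1. ``simulate_measurements`` draws noisy per-metaphase arm measurements
   from a "true" karyotype, emulating the mean ± SD structure a
   karyotype table reports. Per metaphase, each pair's CI is drawn from
   a truncated normal on [0, 50] and its RL weight from a normal
   (renormalized so RL sums to 100); lengths are then L ∝ RL with
   p = CI/100 · L, q = L − p, times a global per-metaphase scale jitter.
   CI and RL noise are independent — the summaries being emulated report
   no covariance, so the simplest model matching them is used.

2. ``simulate_evolution`` evolves karyotype states (n, b) down a tree
   under the rearrangement event model, drawing per-branch event counts
   (Poisson or fixed) and event types from configured probabilities.
   The full truth record (internal states, branch events, skipped draws)
   is returned for recovery experiments.

Both are deterministic given their seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import dendropy
import numpy as np
from scipy import stats

from karyokit.events import (
    EventModel,
    KaryoState,
    apply_event,
    fusion_dominated_model,
    is_legal,
)
from karyokit.morphometrics import ArmMeasurement, Karyotype

#: event-type draw probabilities reflecting the fusion-dominated
#: hypothesis (fusions and inversions dominate; fissions are rare)
FUSION_DOMINATED_PROBS: dict[str, float] = {
    "cF": 0.45,
    "Inv": 0.35,
    "tF": 0.10,
    "fission": 0.10,
}


@dataclass(frozen=True)
class MeasurementNoiseSpec:
    """Noise model for synthetic metaphase measurements.

    ``n_metaphases`` defaults to 15, the minimum plate count the
    measurement protocol scores per sample. Per-pair SDs default to the
    karyotype's own recorded SDs. ``scale_jitter_sd`` is the SD of the
    multiplicative log-normal factor applied to each metaphase's total
    length (absolute lengths vary plate to plate; relative ones do not).
    """

    n_metaphases: int = 15
    rl_sd: Mapping[int, float] | float | None = None
    ci_sd: Mapping[int, float] | float | None = None
    scale_jitter_sd: float = 0.1
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_metaphases < 1:
            raise ValueError("n_metaphases must be >= 1")
        if self.scale_jitter_sd < 0:
            raise ValueError("scale_jitter_sd must be >= 0")
        for name in ("rl_sd", "ci_sd"):
            val = getattr(self, name)
            if isinstance(val, (int, float)) and val < 0:
                raise ValueError(f"{name} must be >= 0")


def _pair_sd(spec_val, pair_id: int, default: float) -> float:
    if spec_val is None:
        return default
    if isinstance(spec_val, (int, float)):
        return float(spec_val)
    return float(spec_val.get(pair_id, default))


def _trunc_normal(rng, mean: float, sd: float, lo: float, hi: float) -> float:
    if sd == 0:
        return float(np.clip(mean, lo, hi))
    a, b = (lo - mean) / sd, (hi - mean) / sd
    return float(stats.truncnorm.rvs(a, b, loc=mean, scale=sd, random_state=rng))


def simulate_measurements(
    karyotype: Karyotype, spec: MeasurementNoiseSpec
) -> list[ArmMeasurement]:
    """Draw a synthetic per-metaphase measurement table from a karyotype.

    The output parses back through the morphometrics pipeline
    (``aggregate_pairs``); with all SDs at zero the round trip recovers
    the karyotype's CI means exactly and its RL means up to a global
    renormalization to a 100% total.
    """
    rng = np.random.default_rng(spec.seed)
    out: list[ArmMeasurement] = []
    for k in range(spec.n_metaphases):
        mid = f"mp{k + 1:03d}"
        scale = float(np.exp(rng.normal(0.0, spec.scale_jitter_sd))) if spec.scale_jitter_sd else 1.0
        weights = []
        cis = []
        for p in karyotype.pairs:
            rl_sd = _pair_sd(spec.rl_sd, p.pair_id, p.rl_sd)
            ci_sd = _pair_sd(spec.ci_sd, p.pair_id, p.ci_sd)
            w = _trunc_normal(rng, p.rl_mean, rl_sd, 1e-6, np.inf)
            ci = _trunc_normal(rng, p.ci_mean, ci_sd, 0.0, 50.0)
            weights.append(w)
            cis.append(ci)
        total = sum(weights)
        for p, w, ci in zip(karyotype.pairs, weights, cis):
            L = 100.0 * w / total * scale
            short = ci / 100.0 * L
            out.append(
                ArmMeasurement(
                    metaphase_id=mid, pair_id=p.pair_id, p=short, q=L - short
                )
            )
    return out


@dataclass(frozen=True)
class EvolutionSimSpec:
    """Specification for simulated karyotype evolution along a tree.

    ``events_per_branch`` is either a Poisson mean (float) or an exact
    per-branch count (int, applied to every branch) — or a mapping from
    branch child-label to a fixed count for targeted scenarios.
    ``event_probs`` gives draw probabilities over event types
    {cF, tF, Inv, fission}; they must sum to 1 over the model's enabled
    events. Illegal draws are resampled up to ``max_retries`` and then
    recorded as skips, never silently dropped.
    """

    tree: dendropy.Tree
    root_state: KaryoState
    events_per_branch: float | int | Mapping[str, int] = 1.0
    poisson: bool = True
    event_probs: Mapping[str, float] = field(
        default_factory=lambda: dict(FUSION_DOMINATED_PROBS)
    )
    model: EventModel = field(default_factory=fusion_dominated_model)
    seed: int = 0
    max_retries: int = 20

    def __post_init__(self) -> None:
        probs = {k: v for k, v in self.event_probs.items() if k in self.model.enabled}
        total = sum(probs.values())
        if not probs or abs(total - 1.0) > 1e-9:
            raise ValueError(
                f"event probabilities over enabled events must sum to 1, got {total}"
            )


@dataclass
class EvolutionRecord:
    """Ground truth from one simulated history."""

    tip_states: dict[str, KaryoState]
    internal_states: dict[str, KaryoState]
    branch_events: dict[str, tuple[str, ...]]  # keyed by child label
    skipped: dict[str, int]  # branches where a drawn event had to be skipped


_DIRECTIONAL = {"Inv": ("Inv+", "Inv-")}


def simulate_evolution(spec: EvolutionSimSpec) -> EvolutionRecord:
    """Evolve states from the root down the tree, recording full truth.

    Event types are drawn by configured probability; a drawn "Inv" picks
    uniformly between its two directions (a→biarmed, biarmed→a),
    restricted to the legal ones. A draw with no legal realization is
    retried, then recorded as a skip.
    """
    rng = np.random.default_rng(spec.seed)
    probs = {k: v for k, v in spec.event_probs.items() if k in spec.model.enabled}
    kinds = sorted(probs)
    pvec = np.array([probs[k] for k in kinds])
    pvec = pvec / pvec.sum()

    counter = {"i": 0}
    state_of: dict[int, KaryoState] = {}
    tip_states: dict[str, KaryoState] = {}
    internal_states: dict[str, KaryoState] = {}
    branch_events: dict[str, tuple[str, ...]] = {}
    skipped: dict[str, int] = {}

    def label_of(node) -> str:
        if node.taxon is not None:
            return node.taxon.label
        if node.label:
            return node.label
        counter["i"] += 1
        node.label = f"anc{counter['i']}"
        return node.label

    root = spec.tree.seed_node
    state_of[id(root)] = spec.root_state
    for node in spec.tree.preorder_node_iter():
        label = label_of(node)
        state = state_of[id(node)]
        if node.is_leaf():
            tip_states[label] = state
        else:
            internal_states[label] = state
        for child in node.child_nodes():
            clabel = label_of(child)
            if isinstance(spec.events_per_branch, Mapping):
                k = int(spec.events_per_branch.get(clabel, 0))
            elif spec.poisson:
                k = int(rng.poisson(float(spec.events_per_branch)))
            else:
                k = int(spec.events_per_branch)
            cur = state_of[id(node)]
            events: list[str] = []
            skips = 0
            for _ in range(k):
                applied = False
                for _try in range(spec.max_retries):
                    kind = kinds[int(rng.choice(len(kinds), p=pvec))]
                    options = _DIRECTIONAL.get(kind, (kind,))
                    legal = [
                        ev
                        for ev in options
                        if is_legal(cur, ev) and apply_event(cur, ev).n <= spec.model.n_max
                    ]
                    if legal:
                        ev = legal[int(rng.integers(len(legal)))]
                        cur = apply_event(cur, ev)
                        events.append(ev)
                        applied = True
                        break
                if not applied:
                    skips += 1
            state_of[id(child)] = cur
            branch_events[clabel] = tuple(events)
            if skips:
                skipped[clabel] = skips
    return EvolutionRecord(
        tip_states=tip_states,
        internal_states=internal_states,
        branch_events=branch_events,
        skipped=skipped,
    )


def random_topology(n_tips: int, rng: np.random.Generator) -> dendropy.Tree:
    """Random rooted binary topology by sequential random attachment."""
    if n_tips < 1:
        raise ValueError("need at least one tip")
    # grow by splitting a uniformly chosen current leaf of a nested-list tree;
    # a node is either ["label"] (leaf) or [None, left, right] (internal)
    root: list = ["t1"]
    leaves: list[list] = [root]
    for i in range(2, n_tips + 1):
        target = leaves[int(rng.integers(len(leaves)))]
        left, right = [target[0]], [f"t{i}"]
        target[0] = None
        target.append(left)
        target.append(right)
        leaves.remove(target)
        leaves.extend([left, right])

    def render(node: list) -> str:
        if node[0] is not None:
            return node[0]
        return "(" + ",".join(render(c) for c in node[1:]) + ")"

    tree = dendropy.Tree.get(data=render(root) + ";", schema="newick")
    tree.is_rooted = True
    return tree
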