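"""Weighted-parsimony (Sankoff) reconstruction of ancestral karyotypes.

Given a rooted tree with a karyotype state (n, b) at every tip and a
rearrangement event model, the dynamic program assigns each internal node
the state(s) minimizing the total event cost over the tree, where the
cost of a branch is the minimum-cost event path between the parent and
child states (``karyokit.events.event_distance``).

Leaf cost is 0 at the observed state and infinite elsewhere; a tip may
also carry a *set* of states (e.g. when only 2n is published and the
biarmed count is unknown), all at leaf cost 0. Internal node costs:

    cost_v(s) = sum over children c of min over s' [ d(s, s') + cost_c(s') ]

All co-optimal root states are reported; a single scenario (with
per-branch event paths) is produced by a deterministic traceback that
prefers higher n, then lower b, among ties.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import dendropy
import numpy as np

from karyokit.events import EventModel, EventPath, KaryoState, distance_matrix, event_distance


def parse_newick(text: str) -> dendropy.Tree:
    """Parse a Newick string into a rooted dendropy tree.

    Branch lengths are accepted and ignored downstream. Duplicate tip
    labels are rejected.
    """
    try:
        tree = dendropy.Tree.get(
            data=text,
            schema="newick",
            suppress_internal_node_taxa=True,
            preserve_underscores=True,
        )
    except Exception as exc:  # dendropy raises several parse error types
        raise ValueError(f"malformed Newick: {exc}") from exc
    labels = [leaf.taxon.label for leaf in tree.leaf_node_iter() if leaf.taxon]
    if len(labels) != len(set(labels)):
        dupes = sorted({l for l in labels if labels.count(l) > 1})
        raise ValueError(f"duplicate tip labels: {dupes}")
    if any(leaf.taxon is None for leaf in tree.leaf_node_iter()):
        raise ValueError("unlabeled tip in tree")
    tree.is_rooted = True
    return tree


@dataclass
class BranchAssignment:
    """One branch of the chosen scenario: parent/child states and events."""

    parent_label: str
    child_label: str
    parent_state: KaryoState
    child_state: KaryoState
    path: EventPath


@dataclass
class AnnotatedTree:
    """A tree with Sankoff reconstruction results attached."""

    tree: dendropy.Tree
    model: EventModel
    total_cost: float
    root_states: tuple[KaryoState, ...]  # all co-optimal, sorted
    root_state: KaryoState  # deterministic representative
    node_states: dict[str, KaryoState]  # traceback assignment per node label
    branches: list[BranchAssignment]

    @property
    def total_events(self) -> int:
        return sum(len(b.path.events) for b in self.branches)


def _node_label(node: dendropy.Node, counter: dict) -> str:
    if node.taxon is not None:
        return node.taxon.label
    if node.label:
        return node.label
    counter["i"] += 1
    label = f"node{counter['i']}"
    node.label = label
    return label


def sankoff_reconstruct(
    tree: dendropy.Tree,
    tip_states: Mapping[str, KaryoState | Sequence[KaryoState]],
    model: EventModel,
) -> AnnotatedTree:
    """Run the Sankoff dynamic program over the bounded (n, b) state grid.

    ``tip_states`` maps each tip label to its observed state, or to a
    sequence of equally acceptable states (an unresolved tip). Every tip
    of the tree must be covered. Multifurcations are allowed (the DP sums
    over all children).
    """
    states, D = distance_matrix(model)
    index = {s: i for i, s in enumerate(states)}
    m = len(states)

    tips = [leaf.taxon.label for leaf in tree.leaf_node_iter()]
    missing = [t for t in tips if t not in tip_states]
    if missing:
        raise ValueError(f"missing tip states for: {missing}")

    counter = {"i": 0}
    cost: dict[int, np.ndarray] = {}  # node id -> cost vector over states
    # postorder DP
    for node in tree.postorder_node_iter():
        label = _node_label(node, counter)
        if node.is_leaf():
            obs = tip_states[label]
            if isinstance(obs, KaryoState):
                obs_list = [obs]
            else:
                obs_list = list(obs)
                if not obs_list:
                    raise ValueError(f"empty state set for tip {label!r}")
            vec = np.full(m, np.inf)
            for s in obs_list:
                if s not in index:
                    raise ValueError(
                        f"tip {label!r} state {s} outside the model grid "
                        f"(n_max={model.n_max})"
                    )
                vec[index[s]] = 0.0
            cost[id(node)] = vec
        else:
            vec = np.zeros(m)
            for child in node.child_nodes():
                child_vec = cost[id(child)]
                # min over child states s' of D[s, s'] + cost_child(s')
                contrib = np.min(D + child_vec[None, :], axis=1)
                vec = vec + contrib
            if not np.isfinite(vec).any():
                bad = _node_label(node, counter)
                raise ValueError(
                    f"no reachable joint assignment at node {bad!r}: some state "
                    "pairs are mutually unreachable under the enabled events"
                )
            cost[id(node)] = vec

    root = tree.seed_node
    root_vec = cost[id(root)]
    total = float(np.min(root_vec))
    opt_idx = np.flatnonzero(root_vec <= total + 1e-9)
    root_states = tuple(sorted(states[i] for i in opt_idx))
    # deterministic representative: higher n, then lower b
    rep = max(root_states, key=lambda s: (s.n, -s.b))

    # traceback: choose child states minimizing d(parent, s') + cost_child(s'),
    # ties broken by higher n then lower b
    node_states: dict[str, KaryoState] = {}
    branches: list[BranchAssignment] = []
    assignment: dict[int, KaryoState] = {id(root): rep}
    for node in tree.preorder_node_iter():
        label = _node_label(node, counter)
        state = assignment[id(node)]
        node_states[label] = state
        pi = index[state]
        for child in node.child_nodes():
            child_vec = cost[id(child)]
            totals = D[pi] + child_vec
            mbest = np.min(totals)
            cands = [states[i] for i in np.flatnonzero(totals <= mbest + 1e-9)]
            chosen = max(cands, key=lambda s: (s.n, -s.b))
            assignment[id(child)] = chosen
            branches.append(
                BranchAssignment(
                    parent_label=label,
                    child_label=_node_label(child, counter),
                    parent_state=state,
                    child_state=chosen,
                    path=event_distance(state, chosen, model),
                )
            )
    return AnnotatedTree(
        tree=tree,
        model=model,
        total_cost=total,
        root_states=root_states,
        root_state=rep,
        node_states=node_states,
        branches=branches,
    )


# display names in the figure-legend vocabulary
_EVENT_DISPLAY = {
    "cF": "cF",
    "tF": "tF",
    "Inv+": "Inv",
    "Inv-": "Inv",
    "fission": "fission",
}


def summarize_scenario(annotated: AnnotatedTree) -> str:
    """Human-readable report of one reconstructed scenario.

    Lists per-branch event labels (cF = centric fusion, tF = tandem
    fusion, Inv = pericentric inversion), the total event count and cost,
    and the full co-optimal root set (the reconstruction's ambiguity).
    """
    lines = []
    lines.append(f"Total cost: {annotated.total_cost:g}")
    lines.append(f"Total events: {annotated.total_events}")
    root_desc = ", ".join(
        f"(n={s.n}, b={s.b}, 2n={s.diploid_number})" for s in annotated.root_states
    )
    lines.append(f"Co-optimal root states: {root_desc}")
    s = annotated.root_state
    lines.append(
        f"Displayed root: 2n = {s.diploid_number}, "
        f"{s.b} biarmed ({'all acrocentric' if s.b == 0 else f'{s.n - s.b} acrocentric'})"
    )
    lines.append("Branch events:")
    for br in annotated.branches:
        if br.path.events:
            evts = " + ".join(_EVENT_DISPLAY[e] for e in br.path.events)
        else:
            evts = "-"
        lines.append(
            f"  {br.parent_label} (2n={br.parent_state.diploid_number}) -> "
            f"{br.child_label} (2n={br.child_state.diploid_number}): {evts}"
        )
    return "\n".join(lines)
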