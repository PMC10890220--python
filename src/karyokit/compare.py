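"""Pairwise karyotype comparison.

Diffs two karyotypes of equal diploid number pair-by-pair (pairs matched by
size rank) and expresses the differences as morphology-changing events. At
karyotype-morphology resolution a pericentric inversion and a centromere
repositioning are indistinguishable, so a single event label carries both
names. Karyotypes with unequal 2n cannot be compared this way and are
routed to the rearrangement event model instead.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Iterable, Literal

from karyokit.morphometrics import BIARMED_CLASSES, Karyotype, PairSummary

EVENT_LABEL = "Inv (or centromere repositioning)"

DiffMode = Literal["exact-class", "biarmed"]


@dataclass(frozen=True)
class KaryotypeDiff:
    """Result of a rank-matched comparison of two equal-2n karyotypes."""

    left_label: str
    right_label: str
    mode: DiffMode
    matched_pairs: tuple[tuple[int, str, str], ...]
    differing_pairs: frozenset[int]
    hypothesized_events: tuple[tuple[int, str], ...]

    @property
    def identical(self) -> bool:
        return not self.differing_pairs


def _differs(left: PairSummary, right: PairSummary, mode: DiffMode) -> bool:
    if mode == "exact-class":
        return left.morph_class != right.morph_class
    if mode == "biarmed":
        return left.biarmed != right.biarmed
    raise ValueError(f"unknown diff mode {mode!r}")


def diff_karyotypes(
    k_left: Karyotype, k_right: Karyotype, mode: DiffMode = "biarmed"
) -> KaryotypeDiff:
    """Diff two karyotypes pair-by-pair, matching pairs by rank.

    ``mode="biarmed"`` compares the one-armed vs biarmed dichotomy (m/sm
    against st/a); ``mode="exact-class"`` compares the full Levan class.
    Each differing pair is annotated with the inversion/centromere-shift
    event label.
    """
    if len(k_left.pairs) != len(k_right.pairs):
        raise ValueError(
            f"unequal pair counts ({len(k_left.pairs)} vs {len(k_right.pairs)}; "
            f"2n = {k_left.diploid_number} vs {k_right.diploid_number}): "
            "rank-matched diff undefined, use the event model "
            "(karyokit.events.event_distance) instead"
        )
    matched = []
    differing = set()
    for pl in k_left.pairs:
        pr = k_right.pair(pl.pair_id)
        matched.append((pl.pair_id, pl.morph_class, pr.morph_class))
        if _differs(pl, pr, mode):
            differing.add(pl.pair_id)
    events = tuple((pid, EVENT_LABEL) for pid in sorted(differing))
    return KaryotypeDiff(
        left_label=k_left.label,
        right_label=k_right.label,
        mode=mode,
        matched_pairs=tuple(matched),
        differing_pairs=frozenset(differing),
        hypothesized_events=events,
    )


def apply_pair_inversions(
    karyotype: Karyotype,
    pair_ids: Iterable[int],
    biarmed_target: str = "m",
) -> Karyotype:
    """Toggle one-armed <-> biarmed morphology on the named pairs.

    Models a pericentric inversion (or centromere shift) per pair: an
    acrocentric/subtelocentric pair becomes biarmed (class
    ``biarmed_target``, default m, with CI moved to the band midpoint),
    and a biarmed pair becomes acrocentric. 2n is unchanged; FN changes by
    +-2 per toggled pair. Applying the same set twice restores the
    original biarmed pattern.
    """
    if biarmed_target not in BIARMED_CLASSES:
        raise ValueError(f"biarmed_target must be m or sm, got {biarmed_target!r}")
    wanted = set(pair_ids)
    valid = {p.pair_id for p in karyotype.pairs}
    bad = wanted - valid
    if bad:
        raise ValueError(f"invalid pair ids: {sorted(bad)}")
    # representative CI at the band midpoint keeps class/CI consistency
    target_ci = {"m": 43.75, "sm": 31.25, "a": 6.25}
    new_pairs = []
    for p in karyotype.pairs:
        if p.pair_id not in wanted:
            new_pairs.append(p)
            continue
        new_class = "a" if p.biarmed else biarmed_target
        new_pairs.append(
            replace(p, morph_class=new_class, ci_mean=target_ci[new_class], ci_sd=0.0)
        )
    return replace(karyotype, pairs=tuple(new_pairs))
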