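"""Chromosome morphometrics from metaphase arm measurements.

Computes relative length (RL, percent of total haploid complement length)
and centromeric index (CI, percent short arm of whole chromosome length)
from raw short-/long-arm measurements, aggregates them across metaphase
plates as mean ± SD, classifies each chromosome pair by centromere
position (Levan's scheme: metacentric m, submetacentric sm, subtelocentric
st, acrocentric a), and derives the karyotype-level diploid number (2n)
and fundamental number (FN, total arm count; m and sm chromosomes carry
two arms, st and a one).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Iterable, Mapping, Sequence

MORPH_CLASSES = ("a", "st", "sm", "m")

#: CI band lower edges (percent) for a/st/sm/m. Bands are half-open upward:
#: a [0, 12.5), st [12.5, 25), sm [25, 37.5), m [37.5, 50]. Equivalent to
#: arm-ratio cut points 7.0 / 3.0 / ~1.67.
DEFAULT_CI_BANDS: tuple[float, float, float] = (12.5, 25.0, 37.5)

#: Classes counted as two-armed ("biarmed") in the fundamental number.
BIARMED_CLASSES = frozenset({"m", "sm"})


@dataclass(frozen=True)
class ArmMeasurement:
    """One chromosome's arm lengths in one metaphase plate.

    Lengths are in arbitrary units, comparable within a single metaphase.
    By convention ``p`` is the short arm, so ``0 <= p <= q``.
    """

    metaphase_id: str
    pair_id: int
    p: float
    q: float

    def __post_init__(self) -> None:
        if self.pair_id < 1:
            raise ValueError(f"pair_id must be >= 1, got {self.pair_id}")
        if not self.q > 0:
            raise ValueError(f"long arm q must be > 0, got {self.q}")
        if not (0 <= self.p <= self.q):
            raise ValueError(
                f"short arm p must satisfy 0 <= p <= q, got p={self.p}, q={self.q}"
            )

    @property
    def length(self) -> float:
        return self.p + self.q


@dataclass(frozen=True)
class PairSummary:
    """Per-pair morphometric summary: RL and CI as mean ± SD (percent),
    Levan class, and cytological annotations (NOR, heterochromatin)."""

    pair_id: int
    rl_mean: float
    rl_sd: float
    ci_mean: float
    ci_sd: float
    morph_class: str
    nor: bool = False
    het_blocks: frozenset[str] = frozenset()

    def __post_init__(self) -> None:
        if self.morph_class not in MORPH_CLASSES:
            raise ValueError(f"unknown morph class {self.morph_class!r}")
        if not (0 < self.rl_mean <= 100):
            raise ValueError(f"rl_mean out of (0, 100]: {self.rl_mean}")
        if not (0 <= self.ci_mean <= 50):
            raise ValueError(f"ci_mean out of [0, 50]: {self.ci_mean}")

    @property
    def biarmed(self) -> bool:
        return self.morph_class in BIARMED_CLASSES


@dataclass(frozen=True)
class Karyotype:
    """An ordered set of chromosome-pair summaries for one species/sample.

    Pairs are ordered by descending mean RL (rank order). Derived
    quantities: diploid number 2n = 2 x pair count; fundamental number
    FN = 2n + 2 x (number of biarmed pairs).
    """

    label: str
    pairs: tuple[PairSummary, ...]

    def __post_init__(self) -> None:
        if not self.pairs:
            raise ValueError("karyotype needs at least one pair")
        ids = [p.pair_id for p in self.pairs]
        if sorted(ids) != list(range(1, len(ids) + 1)):
            raise ValueError(f"pair_ids must be ranks 1..{len(ids)}, got {ids}")

    @property
    def diploid_number(self) -> int:
        return 2 * len(self.pairs)

    @property
    def fundamental_number(self) -> int:
        return fundamental_number(self)

    @property
    def biarmed_pair_ids(self) -> frozenset[int]:
        return frozenset(p.pair_id for p in self.pairs if p.biarmed)

    def pair(self, pair_id: int) -> PairSummary:
        for p in self.pairs:
            if p.pair_id == pair_id:
                return p
        raise KeyError(f"no pair with id {pair_id}")


def relative_length(
    measurements: Sequence[ArmMeasurement],
) -> dict[int, float]:
    """RL (percent) per pair for one metaphase: 100*(p+q)/sum of lengths.

    The denominator is the haploid complement (one chromosome per pair),
    so the values sum to 100.
    """
    if not measurements:
        raise ValueError("need at least one measurement")
    plates = {m.metaphase_id for m in measurements}
    if len(plates) > 1:
        raise ValueError(f"measurements span multiple metaphases: {sorted(plates)}")
    seen: dict[int, float] = {}
    for m in measurements:
        if m.pair_id in seen:
            raise ValueError(f"duplicate pair_id {m.pair_id} within metaphase")
        seen[m.pair_id] = m.length
    total = sum(seen.values())
    if total <= 0:
        raise ValueError("zero total karyotype length")
    return {pid: 100.0 * length / total for pid, length in seen.items()}


def centromeric_index(p: float, q: float) -> float:
    """CI (percent): 100 * short arm / whole chromosome length; in [0, 50]."""
    if p + q <= 0:
        raise ValueError("chromosome length p + q must be > 0")
    if p > q:
        raise ValueError(f"p > q (arms mislabeled): p={p}, q={q}")
    if p < 0:
        raise ValueError(f"negative arm length p={p}")
    return 100.0 * p / (p + q)


def classify_levan(
    ci: float, bands: tuple[float, float, float] = DEFAULT_CI_BANDS
) -> str:
    """Levan morphology class from CI percent.

    Bands (half-open upward): a [0, b0), st [b0, b1), sm [b1, b2),
    m [b2, 50] with defaults b0, b1, b2 = 12.5, 25, 37.5.
    """
    if not (0 <= ci <= 50):
        raise ValueError(f"CI out of [0, 50]: {ci}")
    b0, b1, b2 = bands
    if not (0 < b0 < b1 < b2 < 50):
        raise ValueError(f"bands must be increasing within (0, 50): {bands}")
    if ci < b0:
        return "a"
    if ci < b1:
        return "st"
    if ci < b2:
        return "sm"
    return "m"


def _mean_sd(values: Sequence[float]) -> tuple[float, float]:
    # sample SD (n-1 denominator); single observation reports SD 0
    n = len(values)
    mean = sum(values) / n
    if n < 2:
        return mean, 0.0
    var = sum((v - mean) ** 2 for v in values) / (n - 1)
    return mean, math.sqrt(var)


def aggregate_pairs(
    measurements: Iterable[ArmMeasurement],
    min_metaphases: int = 15,
    bands: tuple[float, float, float] = DEFAULT_CI_BANDS,
) -> list[PairSummary]:
    """Aggregate arm measurements across metaphase plates into pair summaries.

    Per metaphase, RL and CI are computed for every pair; per pair, mean and
    sample SD are taken across metaphases. The Levan class is assigned from
    the mean CI. Pairs are re-ranked by descending mean RL (ties broken by
    higher mean CI, then original pair id), and pair_ids are reassigned to
    the new ranks.

    Every pair must be observed in at least ``min_metaphases`` plates
    (the measurement protocol this mirrors scores >= 15 plates per sample).
    """
    by_plate: dict[str, list[ArmMeasurement]] = {}
    for m in measurements:
        by_plate.setdefault(m.metaphase_id, []).append(m)
    if not by_plate:
        raise ValueError("no measurements")

    rl_per_pair: dict[int, list[float]] = {}
    ci_per_pair: dict[int, list[float]] = {}
    order: list[int] = []
    for plate_ms in by_plate.values():
        rls = relative_length(plate_ms)
        for m in plate_ms:
            if m.pair_id not in rl_per_pair:
                rl_per_pair[m.pair_id] = []
                ci_per_pair[m.pair_id] = []
                order.append(m.pair_id)
            rl_per_pair[m.pair_id].append(rls[m.pair_id])
            ci_per_pair[m.pair_id].append(centromeric_index(m.p, m.q))

    for pid in order:
        cov = len(rl_per_pair[pid])
        if cov < min_metaphases:
            raise ValueError(
                f"pair {pid} observed in {cov} metaphases, "
                f"fewer than min_metaphases={min_metaphases}"
            )

    summaries = []
    for pid in order:
        rl_mean, rl_sd = _mean_sd(rl_per_pair[pid])
        ci_mean, ci_sd = _mean_sd(ci_per_pair[pid])
        summaries.append(
            PairSummary(
                pair_id=pid,
                rl_mean=rl_mean,
                rl_sd=rl_sd,
                ci_mean=ci_mean,
                ci_sd=ci_sd,
                morph_class=classify_levan(ci_mean, bands),
            )
        )
    ranked = sorted(
        summaries, key=lambda s: (-s.rl_mean, -s.ci_mean, order.index(s.pair_id))
    )
    return [replace(s, pair_id=rank) for rank, s in enumerate(ranked, start=1)]


def fundamental_number(karyotype: Karyotype) -> int:
    """Total diploid arm count: FN = 2n + 2 x (pairs classed m or sm).

    Subtelocentric and acrocentric chromosomes count as one-armed; only
    this convention is used throughout the package.
    """
    biarmed = sum(1 for p in karyotype.pairs if p.biarmed)
    return karyotype.diploid_number + 2 * biarmed


def assign_nor(karyotype: Karyotype, bearing_pair_rank: int) -> Karyotype:
    """Return a karyotype with the NOR flag on exactly one pair.

    The flag marks the nucleolus-organizer-bearing pair; assigning it again
    moves the single flag to the newly named pair.
    """
    ids = {p.pair_id for p in karyotype.pairs}
    if bearing_pair_rank not in ids:
        raise ValueError(
            f"pair rank {bearing_pair_rank} out of range 1..{len(ids)}"
        )
    new_pairs = tuple(
        replace(p, nor=(p.pair_id == bearing_pair_rank)) for p in karyotype.pairs
    )
    return replace(karyotype, pairs=new_pairs)
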