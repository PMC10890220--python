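"""Readers and writers for the package's plain-text formats.

Formats (all UTF-8, tab-separated, ``#`` comment lines allowed):

- measurement table: ``metaphase_id  pair_id  p  q``
- karyotype table:   ``pair_id  rl_mean  rl_sd  ci_mean  ci_sd  class  nor``
  (class in {m, sm, st, a}; nor in {0, 1})
- tip-state table:   ``label  n  b`` (b may be ``?`` for an unresolved
  biarmed count, expanded to all states 0..n)
- trees: Newick; event-model config: YAML.

Pair ids are 1-based throughout. Reports round to one decimal place;
machine-readable outputs keep full precision.
"""

from __future__ import annotations

import warnings
from pathlib import Path
from typing import Mapping, Sequence

import pandas as pd
import yaml

from karyokit.events import EventModel, KaryoState
from karyokit.morphometrics import (
    ArmMeasurement,
    Karyotype,
    PairSummary,
    classify_levan,
)

MEASUREMENT_COLUMNS = ["metaphase_id", "pair_id", "p", "q"]
KARYOTYPE_COLUMNS = ["pair_id", "rl_mean", "rl_sd", "ci_mean", "ci_sd", "class", "nor"]


def _read_tsv(path: str | Path, columns: list[str]) -> pd.DataFrame:
    path = Path(path)
    try:
        df = pd.read_csv(path, sep="\t", comment="#")
    except pd.errors.EmptyDataError:
        raise ValueError(f"{path}: empty file") from None
    missing = [c for c in columns if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing columns {missing} (header must be {columns})")
    if df.empty:
        raise ValueError(f"{path}: no data rows")
    return df


def read_measurement_table(path: str | Path) -> list[ArmMeasurement]:
    df = _read_tsv(path, MEASUREMENT_COLUMNS)
    out = []
    for lineno, row in enumerate(df.itertuples(index=False), start=2):
        try:
            out.append(
                ArmMeasurement(
                    metaphase_id=str(row.metaphase_id),
                    pair_id=int(row.pair_id),
                    p=float(row.p),
                    q=float(row.q),
                )
            )
        except (TypeError, ValueError) as exc:
            raise ValueError(f"{path}: line {lineno}: {exc}") from None
    return out


def write_measurement_table(measurements: Sequence[ArmMeasurement], path: str | Path) -> None:
    df = pd.DataFrame(
        [(m.metaphase_id, m.pair_id, m.p, m.q) for m in measurements],
        columns=MEASUREMENT_COLUMNS,
    )
    df.to_csv(path, sep="\t", index=False, float_format="%.10g")


def read_karyotype_table(path: str | Path, label: str | None = None) -> Karyotype:
    """Load a karyotype table; 2n and FN are derived on the result.

    A pair whose recorded class disagrees with its mean CI under the
    default classification bands triggers a warning (not an error): the
    recorded class wins, since published tables may follow a different
    band convention.
    """
    df = _read_tsv(path, KARYOTYPE_COLUMNS).rename(columns={"class": "morph_class"})
    pairs = []
    for lineno, row in enumerate(df.itertuples(index=False), start=2):
        try:
            cls = str(row.morph_class)
            summary = PairSummary(
                pair_id=int(row.pair_id),
                rl_mean=float(row.rl_mean),
                rl_sd=float(row.rl_sd),
                ci_mean=float(row.ci_mean),
                ci_sd=float(row.ci_sd),
                morph_class=cls,
                nor=bool(int(row.nor)),
            )
        except (TypeError, ValueError) as exc:
            raise ValueError(f"{path}: line {lineno}: {exc}") from None
        expected = classify_levan(summary.ci_mean)
        if expected != summary.morph_class:
            warnings.warn(
                f"{path}: pair {summary.pair_id}: recorded class "
                f"{summary.morph_class!r} disagrees with CI {summary.ci_mean} "
                f"(bands give {expected!r})",
                stacklevel=2,
            )
        pairs.append(summary)
    pairs.sort(key=lambda p: p.pair_id)
    return Karyotype(label=label or Path(path).stem, pairs=tuple(pairs))


def write_karyotype_table(karyotype: Karyotype, path: str | Path) -> None:
    df = pd.DataFrame(
        [
            (p.pair_id, p.rl_mean, p.rl_sd, p.ci_mean, p.ci_sd, p.morph_class, int(p.nor))
            for p in karyotype.pairs
        ],
        columns=KARYOTYPE_COLUMNS,
    )
    df.to_csv(path, sep="\t", index=False, float_format="%.10g")


def read_tip_states(path: str | Path) -> dict[str, KaryoState | list[KaryoState]]:
    """Read a tip-state table; ``b = ?`` expands to the full 0..n range."""
    df = _read_tsv(path, ["label", "n", "b"])
    out: dict[str, KaryoState | list[KaryoState]] = {}
    for lineno, row in enumerate(df.itertuples(index=False), start=2):
        label = str(row.label)
        if label in out:
            raise ValueError(f"{path}: line {lineno}: duplicate label {label!r}")
        n = int(row.n)
        if str(row.b).strip() == "?":
            out[label] = [KaryoState(n, b) for b in range(n + 1)]
        else:
            out[label] = KaryoState(n, int(row.b))
    return out


def write_tip_states(
    states: Mapping[str, KaryoState], path: str | Path
) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("label\tn\tb\n")
        for label, s in states.items():
            fh.write(f"{label}\t{s.n}\t{s.b}\n")


def read_event_model(path: str | Path) -> EventModel:
    """Load an event-model config (YAML: costs, enabled, n_max)."""
    with open(path, encoding="utf-8") as fh:
        raw = yaml.safe_load(fh)
    if not isinstance(raw, dict):
        raise ValueError(f"{path}: expected a mapping")
    known = {"costs", "enabled", "n_max"}
    unknown = set(raw) - known
    if unknown:
        raise ValueError(f"{path}: unknown keys {sorted(unknown)}")
    kwargs = {}
    if "costs" in raw:
        kwargs["costs"] = {str(k): float(v) for k, v in raw["costs"].items()}
    if "enabled" in raw:
        kwargs["enabled"] = frozenset(str(e) for e in raw["enabled"])
    if "n_max" in raw:
        kwargs["n_max"] = int(raw["n_max"])
    return EventModel(**kwargs)


def format_karyotype_report(karyotype: Karyotype) -> str:
    """One-decimal human-readable summary of a karyotype."""
    lines = [
        f"Karyotype: {karyotype.label}",
        f"2n = {karyotype.diploid_number}, FN = {karyotype.fundamental_number}",
        f"biarmed pairs: {sorted(karyotype.biarmed_pair_ids) or 'none'}",
        "pair\tRL\tCI\tclass\tNOR",
    ]
    for p in karyotype.pairs:
        lines.append(
            f"{p.pair_id}\t{p.rl_mean:.1f} ± {p.rl_sd:.1f}\t"
            f"{p.ci_mean:.1f} ± {p.ci_sd:.1f}\t{p.morph_class}\t"
            f"{'*' if p.nor else ''}"
        )
    return "\n".join(lines)
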