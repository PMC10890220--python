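"""Bundled fixtures: published karyotype tables and the genus-level tree.

``mercatorius_karyotype()`` is transcribed from the published table
(21 pairs, 2n = 42, FN = 54, NOR pair 14). ``mabouia_karyotype()`` is a
synthetic numeric stand-in for the published chromosome *formula* (2n =
42, biarmed pairs 1, 4, 6, 13, 15, 19, 21) — see the fixture file header.
``genus_tree()``/``genus_tip_states()`` give the Hemidactylus +
Cyrtodactylus topology and per-tip (n, b) states used in the ancestral
reconstruction; non-focal tip states are fixture metadata.
"""

from __future__ import annotations

from importlib import resources

import dendropy

from karyokit.events import EventModel, KaryoState
from karyokit.io import read_event_model, read_karyotype_table, read_tip_states
from karyokit.morphometrics import Karyotype
from karyokit.reconstruct import parse_newick

_PKG = resources.files(__name__)


def fixture_path(name: str):
    """Filesystem path of a bundled fixture file."""
    from pathlib import Path

    return Path(str(_PKG / name))


def mercatorius_karyotype() -> Karyotype:
    return read_karyotype_table(fixture_path("mercatorius_karyotype.tsv"), label="H_mercatorius")


def mabouia_karyotype() -> Karyotype:
    return read_karyotype_table(fixture_path("mabouia_synthetic.tsv"), label="H_mabouia")


def genus_tree() -> dendropy.Tree:
    return parse_newick(fixture_path("genus_tree.nwk").read_text())


def genus_tip_states() -> dict[str, KaryoState]:
    return read_tip_states(fixture_path("genus_tips.tsv"))


def fusion_dominated_preset() -> EventModel:
    return read_event_model(fixture_path("fusion_dominated.yaml"))
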