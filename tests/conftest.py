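import pytest

from karyokit.data import (
    fusion_dominated_preset,
    genus_tip_states,
    genus_tree,
    mabouia_karyotype,
    mercatorius_karyotype,
)


@pytest.fixture(scope="session")
def mercatorius():
    return mercatorius_karyotype()


@pytest.fixture(scope="session")
def mabouia():
    return mabouia_karyotype()


@pytest.fixture()
def fig_tree():
    # function-scoped: reconstruction mutates node labels in place
    return genus_tree()


@pytest.fixture(scope="session")
def fig_tips():
    return genus_tip_states()


@pytest.fixture(scope="session")
def fusion_model():
    return fusion_dominated_preset()
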