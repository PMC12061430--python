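import pytest

from hypoxemt import (
    emt_switch_fixture,
    emt_switch_signatures,
    hypoxia_demo_model,
    hypoxia_demo_signatures,
    toggle_switch,
)

BASE_ENV = {
    "Hypoxia": 0, "GF": 1, "TGFb_ext": 0,
    "Stiff_ECM": 1, "ECM_attached": 1, "Density_High": 0,
}
# epithelial cells are stable at high density (contact inhibition)
EPI_ENV = {**BASE_ENV, "Density_High": 1}
SOFT_ENV = {**BASE_ENV, "Stiff_ECM": 0}


@pytest.fixture(scope="session")
def toggle():
    return toggle_switch()


@pytest.fixture(scope="session")
def emt():
    return emt_switch_fixture()


@pytest.fixture(scope="session")
def emt_sigs(emt):
    return emt_switch_signatures(emt)


@pytest.fixture(scope="session")
def demo():
    return hypoxia_demo_model()


@pytest.fixture(scope="session")
def demo_sigs(demo):
    return hypoxia_demo_signatures(demo)


@pytest.fixture(scope="session")
def epithelial_start(demo, demo_sigs):
    from hypoxemt import resolve_initial_state

    return resolve_initial_state(demo, "Epithelial", EPI_ENV, demo_sigs)
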