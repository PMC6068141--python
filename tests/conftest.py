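import pytest

from phifba.fixtures import ToySpec, make_profiles, make_screen_panel, make_toy_model
from phifba.screen import PanelConfig


@pytest.fixture(scope="session")
def toy_model():
    """Default toy cell: glycolysis + split junction + oxphos + ppp."""
    return make_toy_model(ToySpec())


@pytest.fixture(scope="session")
def cancer_db(toy_model):
    return make_profiles(toy_model, "cancer_like", seed=0, jitter=0.0)


@pytest.fixture(scope="session")
def normal_db(toy_model):
    return make_profiles(toy_model, "normal_like", seed=0, jitter=0.0)


@pytest.fixture(scope="session")
def padded_model():
    """Toy cell diluted with inert gene-bearing reactions (GSMM-like)."""
    return make_toy_model(ToySpec(n_padding_genes=24))


@pytest.fixture(scope="session")
def mini_model():
    """Single-junction 12-reaction variant, small enough for the vertex
    enumeration oracle."""
    return make_toy_model(
        ToySpec(split_junction=False, include_ppp=False, include_ros=False)
    )


@pytest.fixture(scope="session")
def fermentation_model():
    """Oxphos-free variant: biomass requires lactate secretion."""
    return make_toy_model(
        ToySpec(split_junction=False, include_ppp=False, include_ros=False,
                include_oxphos=False)
    )


@pytest.fixture(scope="session")
def screen_panel():
    """(PanelConfig, shared profile db) for the KO screen fixtures."""
    cancer, normal, db = make_screen_panel(2, 3, seed=0)
    return PanelConfig(cancer_models=cancer, normal_models=normal), db
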