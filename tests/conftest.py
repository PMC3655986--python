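import pytest

from navmarkov import (
    KineticScheme,
    LawSpec,
    ModelParameters,
    SimConfig,
    Transition,
    build_model_I,
    build_model_II,
    default_parameters,
)


@pytest.fixture(scope="session")
def params():
    return default_parameters()


@pytest.fixture(scope="session")
def model_I(params):
    return build_model_I(params)


@pytest.fixture(scope="session")
def model_II(params):
    return build_model_II(params)


@pytest.fixture(scope="session")
def config():
    return SimConfig()


def two_state(r1=1.0, r2=1.0):
    """C <-> O toy scheme with voltage-independent rates r1 (C->O), r2 (O->C)."""
    scheme = KineticScheme(
        states=["C", "O"],
        conducting="O",
        transitions=[
            Transition("C", "O", LawSpec(kind="fixed", value=r1)),
            Transition("O", "C", LawSpec(kind="fixed", value=r2)),
        ],
        name="two_state",
    )
    return scheme, ModelParameters({})


@pytest.fixture
def toy():
    return two_state()
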