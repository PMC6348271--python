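import pytest

from nutlogic.engine import (
    And,
    Atom,
    ComponentSpec,
    Effect,
    ModelDefinition,
    Rule,
    phos,
    present,
)
from nutlogic.yeast_model import build_full_model, build_glucose_model, build_wt_model


def two_protein_model(rules=None) -> ModelDefinition:
    """Minimal kinase cascade: Prt1 (phosphorylated) phosphorylates Prt2."""
    default_rules = (
        Rule(
            id="x1",
            pathway="PathwayX",
            condition=And(present("Prt2"), present("Prt1"), phos("Prt1")),
            effects=(Effect("Prt2", "phosphorylation", 1),),
            citation="example",
        ),
    )
    return ModelDefinition(
        name="two-protein",
        pathways=("PathwayX",),
        components=(
            ComponentSpec("Prt1", "protein", "PathwayX", "cytosol"),
            ComponentSpec("Prt2", "protein", "PathwayX", "cytosol"),
        ),
        rules=rules if rules is not None else default_rules,
        crosstalk={},
    )


@pytest.fixture
def tiny_model():
    return two_protein_model()


@pytest.fixture(scope="session")
def glucose_wt():
    return build_wt_model("glucose")


@pytest.fixture(scope="session")
def glucose_base():
    """61-rule literature reconstruction: no gap fillers, crosstalks off."""
    return build_glucose_model(include_gap_fillers=False)


@pytest.fixture(scope="session")
def glucose_gaps_only():
    """Gap-filler phosphatases present but crosstalks 7/9 off."""
    return build_glucose_model(include_gap_fillers=True)


@pytest.fixture(scope="session")
def full_model():
    return build_full_model()
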