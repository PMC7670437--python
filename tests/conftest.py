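import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from cosmopharm import Component, ToyMoleculeSpec, make_toy_molecule

settings.register_profile(
    "repro",
    deadline=None,
    derandomize=True,
    max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("repro")


@pytest.fixture(scope="session")
def apolar_molecule():
    """Toy molecule with every |sigma| below the hydrogen-bond cutoff."""
    return make_toy_molecule(ToyMoleculeSpec(seed=1))


@pytest.fixture(scope="session")
def hb_molecule():
    """Toy molecule with donor/acceptor patches beyond the cutoff."""
    return make_toy_molecule(
        ToyMoleculeSpec(
            charge_pattern="donor-acceptor-pair", hb_fraction=0.3, seed=2
        )
    )


@pytest.fixture(scope="session")
def apolar_component(apolar_molecule):
    return Component.from_molecule(apolar_molecule)


@pytest.fixture(scope="session")
def hb_component(hb_molecule):
    return Component.from_molecule(hb_molecule)


@pytest.fixture(scope="session")
def binary_components(apolar_component, hb_component):
    return [apolar_component, hb_component]


@pytest.fixture(scope="session")
def second_apolar_component():
    mol = make_toy_molecule(
        ToyMoleculeSpec(n_segments=48, total_area=120.0, seed=7)
    )
    return Component.from_molecule(mol)
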