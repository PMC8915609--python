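import numpy as np
import pytest

from ljfit.forcefield import (
    AtomTypeDef,
    MoleculeSpec,
    ParameterSet,
    SiteSpec,
    SystemSpec,
)
from ljfit.synthetic import ToyReferenceEngine, build_toy_library, synthesize_reference


@pytest.fixture()
def simple_params() -> ParameterSet:
    p = ParameterSet(label="test")
    p.add_type(AtomTypeDef("A", 0.65, 0.34, "generic LJ site"))
    p.add_type(AtomTypeDef("B", 0.30, 0.28, "small LJ site"))
    return p


@pytest.fixture()
def mono_a() -> MoleculeSpec:
    return MoleculeSpec("monoA", (SiteSpec("A"),), group_tags=("alkane",), molar_mass=40.0)


@pytest.fixture()
def mono_b() -> MoleculeSpec:
    return MoleculeSpec("monoB", (SiteSpec("B"),), group_tags=("ether",), molar_mass=30.0)


@pytest.fixture()
def five_particle_system(mono_a) -> SystemSpec:
    return SystemSpec(
        "five", ((mono_a, 5, "solvent"),), temperature=150.0, box_edge=2.0
    )


@pytest.fixture(scope="session")
def toy_library():
    """Canonical 2-type library shared across the suite (seed 1)."""
    return build_toy_library(n_types=2, seed=1)


@pytest.fixture(scope="session")
def toy_engine(toy_library):
    return ToyReferenceEngine(toy_library)


@pytest.fixture(scope="session")
def toy_reference_dg(toy_library, toy_engine):
    """Noise-free reference over the solvation systems only (fast)."""
    ids = [
        sid
        for sid, prop in toy_library.system_properties.items()
        if prop == "dGsolv"
    ]
    return synthesize_reference(toy_library, engine=toy_engine, system_ids=ids)


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(1234)
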