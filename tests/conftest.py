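import pytest

from molcabinet import (
    FixtureSpec,
    Project,
    create_project,
    generate_library,
    library_to_project,
)
from molcabinet.fixtures import CAS_FIXTURE_MAP
from molcabinet.cas import FixtureResolverClient


@pytest.fixture
def small_library():
    """100 molecules, 20 planted coumarin cores, seeded."""
    return generate_library(FixtureSpec(n=100, seed=1, coumarin_fraction=0.2,
                                        nitrogen_fraction=0.5, nitro_fraction=0.15))


@pytest.fixture
def small_project(small_library):
    return library_to_project(small_library, "small")


@pytest.fixture
def disk_project(tmp_path):
    """A persisted 3-entry project opened read/write."""
    project = create_project(tmp_path / "proj", "demo", identity="alice@host")
    project.add_molecule("mol1", "CCO", {"IC50_nM": "120"})
    project.add_molecule("mol2", "c1ccccc1", {"IC50_nM": "350"})
    project.add_molecule("mol3", "CC(=O)O", {})
    return project


@pytest.fixture
def cas_client():
    return FixtureResolverClient(CAS_FIXTURE_MAP)
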