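import pytest

from mybkit.domain import CONSENSUS, DomainModel, scan_protein
from mybkit.synthdata import FamilySpec, generate_family


@pytest.fixture(scope="session")
def model() -> DomainModel:
    return DomainModel()


@pytest.fixture(scope="session")
def consensus() -> str:
    return CONSENSUS


@pytest.fixture(scope="session")
def family():
    """Default-condition synthetic family (24 genes, 3 subgroups)."""
    return generate_family(FamilySpec(seed=1))


@pytest.fixture(scope="session")
def divergent_family():
    """Family with strong subgroup separation for phylogenetic recovery."""
    return generate_family(FamilySpec(seed=1, subgroup_divergence=0.15))


@pytest.fixture(scope="session")
def family_domains(family):
    return {gid: scan_protein(prot, min_score=6)[0]
            for gid, prot in family.proteins.items()}
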