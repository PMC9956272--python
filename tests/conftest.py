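import numpy as np
import pytest

from tcme.profile import build_profile_from_seeds, calibrate_threshold
from tcme.synth import (GroupPriors, SimulationConfig, make_outgroup_proteins,
                        make_seed_proteins, make_templates, reference_library,
                        simulate_dataset)

NT = "ACGT"
AA = "ACDEFGHIKLMNPQRSTVWY"


def random_dna(rng: np.random.Generator, n: int) -> str:
    return "".join(NT[i] for i in rng.integers(0, 4, n))


def random_protein(rng: np.random.Generator, n: int) -> str:
    return "".join(AA[i] for i in rng.integers(0, 20, n))


@pytest.fixture(scope="session")
def priors():
    return GroupPriors()


@pytest.fixture(scope="session")
def templates(priors):
    return make_templates(priors, seed=11)


@pytest.fixture(scope="session")
def templates_by_subgroup(templates):
    return {t.subgroup: t for t in templates}


@pytest.fixture(scope="session")
def seed_proteins():
    return make_seed_proteins(seed=101)


@pytest.fixture(scope="session")
def profile(seed_proteins):
    return build_profile_from_seeds(seed_proteins)


@pytest.fixture(scope="session")
def references(templates):
    return reference_library(templates, include=("IS605a", "IS607a", "IS1341"))


@pytest.fixture(scope="session")
def outgroup():
    return make_outgroup_proteins(seed=77)


@pytest.fixture(scope="session")
def small_dataset(templates):
    """Two pseudo-species, three 120-kb genomes each, 3% divergence."""
    cfg = SimulationConfig(
        species=("Synthetica alpha", "Synthetica bravo"),
        n_genomes_per_species=3, genome_length=120_000, n_contigs=2,
        divergence=0.03, seed=7)
    genomes, ledger = simulate_dataset(cfg, templates)
    return cfg, genomes, ledger


@pytest.fixture(scope="session")
def scan_threshold(profile, small_dataset):
    _cfg, genomes, _ledger = small_dataset
    return calibrate_threshold(profile, genomes, seed=42, n_decoys=300)
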