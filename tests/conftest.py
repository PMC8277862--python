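"""Shared fixtures: small simulated datasets reused across test modules."""

import numpy as np
import pytest

from packtir.scan import run_scan
from packtir.simulate import SimulationConfig, plant_genome


@pytest.fixture(scope="session")
def small_config():
    return SimulationConfig(genome_len=240_000, n_te_copies=40, n_packtirs=8,
                            n_multicopy_families=1, multicopy_copy_count=3)


@pytest.fixture(scope="session")
def small_sim(small_config):
    """A 240 kb genome with 8 gap-fill captures and one 3-copy family."""
    genome, annotations, genes, library, truths = plant_genome(small_config, seed=11)
    return {
        "config": small_config,
        "genome": genome,
        "annotations": annotations,
        "genes": genes,
        "library": {c.name: c for c in library},
        "truths": truths,
    }


@pytest.fixture(scope="session")
def small_scan(small_sim):
    candidates, families = run_scan(
        small_sim["annotations"], small_sim["genome"], small_sim["library"],
        small_sim["genes"])
    return candidates, families


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)


def random_dna(rng, n):
    return "".join(rng.choice(list("ACGT"), size=n))
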