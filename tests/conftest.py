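import numpy as np
import pytest

from meatseq import build_reference_db
from meatseq.synth_fixtures import (
    CategorySpec,
    ConservedBlock,
    SynthWorld,
    make_world,
)


@pytest.fixture(scope="session")
def small_world():
    """3 categories x 2 species, 3 kb genomes, CYTB cassette implanted."""
    spec = SynthWorld(
        seed=11,
        categories=[
            CategorySpec("Pork", n_species=2, between_divergence=0.15, within_divergence=0.03),
            CategorySpec("Beef", n_species=2, between_divergence=0.15, within_divergence=0.03),
            CategorySpec("Mutton", n_species=2, between_divergence=0.15, within_divergence=0.03),
        ],
        genome_length=3000,
    )
    return make_world(spec)


@pytest.fixture(scope="session")
def small_db(small_world):
    return build_reference_db(small_world.records, small_world.cmap, k=21, length_gate=None)


@pytest.fixture(scope="session")
def conserved_world():
    """Like small_world but Mutton and Venison share a 120 bp block inside the amplicon."""
    spec = SynthWorld(
        seed=23,
        categories=[
            CategorySpec("Pork", n_species=2, between_divergence=0.15, within_divergence=0.03),
            CategorySpec("Mutton", n_species=2, between_divergence=0.15, within_divergence=0.03),
            CategorySpec("Venison", n_species=2, between_divergence=0.15, within_divergence=0.03),
        ],
        genome_length=3000,
        conserved_blocks=[ConservedBlock(120, frozenset({"Mutton", "Venison"}), in_amplicon=True)],
    )
    return make_world(spec)


@pytest.fixture(scope="session")
def conserved_db(conserved_world):
    return build_reference_db(conserved_world.records, conserved_world.cmap, k=21, length_gate=None)


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)


def random_dna(rng, n):
    return "".join(np.array(list("ACGT"))[rng.integers(0, 4, size=n)])
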