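import numpy as np
import pytest

from enzopt import (
    AlignedFamily,
    AlignedSequence,
    SyntheticSpec,
    attach_labels,
    generate_synthetic_family,
    partition_by_threshold,
)
from enzopt.embedding_model import EmbeddingTable
from enzopt.site_statistics import N_SYMBOLS


@pytest.fixture
def toy_family():
    """Four sequences, two columns of which separate the classes."""
    seqs = [
        AlignedSequence("h1", "KRKAA-", label=8.5),
        AlignedSequence("h2", "KRRAG-", label=9.0),
        AlignedSequence("l1", "DEKAA-", label=5.5),
        AlignedSequence("l2", "DERAG-", label=6.0),
    ]
    return AlignedFamily(seqs)


@pytest.fixture
def toy_partition(toy_family):
    return partition_by_threshold(toy_family, 7.0)


@pytest.fixture
def small_synthetic():
    family, planted = generate_synthetic_family(
        SyntheticSpec(n_sequences=40, l=20, n_planted=4, effect=0.9, seed=11)
    )
    return family, planted


def random_table(l: int, d: int, rng: np.random.Generator) -> EmbeddingTable:
    return EmbeddingTable(
        site_vectors=rng.normal(size=(l, d)),
        symbol_vectors=rng.normal(size=(N_SYMBOLS, d)),
        C=float(rng.normal()),
        C_pair=float(rng.normal()),
    )


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
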