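import random

import numpy as np
import pytest
from hypothesis import settings

settings.register_profile("suite", deadline=None, derandomize=True, max_examples=40)
settings.load_profile("suite")


@pytest.fixture
def rng():
    return random.Random(12345)


@pytest.fixture
def nprng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def small_corpus():
    """A small divergent two-class corpus shared across tests.

    Training: 8 genomes x 20 kb per class; testing: 4 genomes x 20 kb per
    class from fresh seeds, ids disjoint from training.
    """
    import phagelift as pl

    spec_a, spec_b = pl.divergent_source_pair(genome_length=20_000, n_genomes=8, seed=11)
    train_t, train_l = pl.generate_synthetic_classes(spec_a, spec_b)
    spec_a2, spec_b2 = pl.divergent_source_pair(genome_length=20_000, n_genomes=4, seed=97)
    test_t, test_l = pl.generate_synthetic_classes(spec_a2, spec_b2)
    test_t = [pl.SequenceRecord("q" + r.id, r.sequence, r.label) for r in test_t]
    test_l = [pl.SequenceRecord("q" + r.id, r.sequence, r.label) for r in test_l]
    return train_t, train_l, test_t, test_l
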