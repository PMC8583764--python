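import numpy as np
import pytest

import q8fuse as q


@pytest.fixture
def toy_dataset():
    """Small labelled dataset shared by I/O, metrics and ensemble tests."""
    return q.make_toy_dataset(n_proteins=12, length_range=(15, 40), seed=101)


@pytest.fixture
def complementary_pset(toy_dataset):
    """Two planted classifiers with complementary reliable classes."""
    profiles = [
        q.SkillProfile.reliable_on("A", ["E", "H"]),
        q.SkillProfile.reliable_on("B", ["L", "T"]),
    ]
    return q.make_planted_predictions(toy_dataset, profiles, seed=202)


@pytest.fixture
def small_ga_config():
    """A scaled-down GA configuration for fast unit tests."""
    return q.GAConfig(
        population_size=120,
        n_parents=12,
        n_crossover=48,
        max_generations=25,
        patience=8,
        ls_max_generations=15,
        ls_pool=12,
        seed=5,
    )


def record_from_labels(labels, seed=0, rid="rec"):
    """Build a valid ProteinRecord carrying the given label indices."""
    rng = np.random.default_rng(seed)
    labels = np.asarray(labels, dtype=np.int64)
    L = labels.size
    onehot = np.zeros((L, 21))
    onehot[np.arange(L), rng.integers(0, 20, size=L)] = 1.0
    return q.ProteinRecord(id=rid, aa_onehot=onehot, pssm=onehot * 0.9, labels=labels)
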