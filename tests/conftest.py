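import numpy as np
import pandas as pd
import pytest

from semcoh.embedding import HashingEncoder
from semcoh.experiments import simulation_spec
from semcoh.features import default_lexicon
from semcoh.synthetic import default_topic_model, generate_corpus


@pytest.fixture(scope="session")
def encoder16():
    return HashingEncoder(dim=16)


@pytest.fixture(scope="session")
def encoder512():
    return HashingEncoder(dim=512)


@pytest.fixture(scope="session")
def lexicon():
    return default_lexicon()


@pytest.fixture(scope="session")
def topics():
    return default_topic_model()


@pytest.fixture(scope="session")
def two_group_corpus(topics):
    """Small two-group corpus with a real drift difference."""
    specs = [
        simulation_spec("calm", 120, 0.1, seed=101),
        simulation_spec("drifty", 120, 0.8, seed=202),
    ]
    return generate_corpus(specs, topics)


def random_design(rng, n=None, k=None, n_cov=5):
    """Random full-rank group+covariate design with a noisy linear response."""
    n = int(rng.integers(60, 200)) if n is None else n
    k = int(rng.integers(2, 6)) if k is None else k
    groups = np.array([f"g{i}" for i in rng.integers(k, size=n)])
    # ensure every level appears at least twice
    for i in range(k):
        groups[2 * i] = f"g{i}"
        groups[2 * i + 1] = f"g{i}"
    cov = rng.normal(size=(n, n_cov))
    beta = rng.normal(size=n_cov)
    effects = rng.normal(size=k)
    y = cov @ beta + np.take(effects, [int(g[1:]) for g in groups]) + rng.normal(size=n)
    df = pd.DataFrame(cov, columns=[f"x{j}" for j in range(n_cov)])
    df["group"] = groups
    df["coherence"] = y
    return df, [f"x{j}" for j in range(n_cov)]
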