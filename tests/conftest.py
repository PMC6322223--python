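import numpy as np
import pytest

from weaktext import (
    Corpus,
    FeaturizerSpec,
    GeneratorConfig,
    generate_corpus,
    generate_embeddings,
    load_builtin,
)


@pytest.fixture(scope="session")
def mayo():
    return load_builtin("mayo_smoking")


@pytest.fixture(scope="session")
def hip():
    return load_builtin("hip_fracture")


@pytest.fixture(scope="session")
def i2b2():
    return load_builtin("i2b2_smoking")


@pytest.fixture(scope="session")
def smoking_bundle():
    """A mid-size smoking corpus with misspellings, shared across tests."""
    return generate_corpus(
        GeneratorConfig(task="smoking_binary", n=600, seed=1234, p_miss=0.1)
    )


@pytest.fixture(scope="session")
def smoking_table(smoking_bundle):
    return generate_embeddings(smoking_bundle, k=50, cluster_sd=0.2, seed=99)


@pytest.fixture(scope="session")
def smoking_featurizer(smoking_table):
    return FeaturizerSpec("embedding_mean", embedding_table=smoking_table)


def split_corpus(corpus: Corpus, n_train: int):
    docs = corpus.documents
    return Corpus(docs[:n_train]), Corpus(docs[n_train:])


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(7)
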