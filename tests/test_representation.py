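import math
from collections import Counter

import numpy as np
import pytest

from weaktext import (
    Corpus,
    Document,
    EmbeddingTable,
    embed_mean,
    fit_tfidf,
    fit_topics,
    nearest_neighbors,
    tokenize,
    transform_tfidf,
    transform_topics,
)
from weaktext.representation import FeaturizerSpec


class TestTokenize:
    @pytest.mark.parametrize(
        "text,expected",
        [
            ("No smoking after age 40", ["no", "smoking", "after", "age", "40"]),
            ("tobacco use: yes", ["tobacco", "use", "yes"]),
            ("", []),
            ("Naïve-Café!!", ["naïve", "café"]),
        ],
    )
    def test_examples(self, text, expected):
        assert tokenize(text) == expected


@pytest.fixture
def tiny_table():
    return EmbeddingTable({"a": np.array([1.0, 2.0]), "b": np.array([3.0, 4.0])})


class TestEmbedMean:
    def test_single_token_identity(self, tiny_table):
        np.testing.assert_allclose(embed_mean(["a"], tiny_table).vector, [1, 2])

    def test_arithmetic_mean(self, tiny_table):
        np.testing.assert_allclose(embed_mean(["a", "b"], tiny_table).vector, [2, 3])

    def test_oov_skipped_and_counted(self, tiny_table):
        fv = embed_mean(["a", "zzz", "b"], tiny_table)
        np.testing.assert_allclose(fv.vector, [2, 3])
        assert fv.oov_count == 1 and fv.token_count == 3 and not fv.degenerate

    def test_all_oov_is_zero_vector_with_flag(self, tiny_table):
        fv = embed_mean(["x", "y"], tiny_table)
        np.testing.assert_array_equal(fv.vector, [0, 0])
        assert fv.degenerate

    def test_matches_direct_summation_oracle(self, rng):
        vocab = {f"w{i}": rng.normal(size=7) for i in range(60)}
        table = EmbeddingTable(vocab)
        for _ in range(20):
            tokens = [f"w{rng.integers(80)}" for _ in range(50)]  # some OOV
            fv = embed_mean(tokens, table)
            found = [vocab[t] for t in tokens if t in vocab]
            if found:
                expected = sum(found) / len(found)  # plain running sum
                np.testing.assert_allclose(fv.vector, expected, atol=1e-12)
            else:
                assert fv.degenerate

    def test_permutation_invariance_and_linearity(self, rng):
        vocab = {f"w{i}": rng.normal(size=5) for i in range(10)}
        table = EmbeddingTable(vocab)
        doubled = EmbeddingTable({k: 2 * v for k, v in vocab.items()})
        tokens = ["w1", "w3", "w3", "w7"]
        perm = ["w3", "w7", "w1", "w3"]
        np.testing.assert_allclose(
            embed_mean(tokens, table).vector, embed_mean(perm, table).vector
        )
        np.testing.assert_allclose(
            embed_mean(tokens, doubled).vector, 2 * embed_mean(tokens, table).vector
        )


def tfidf_oracle(texts, query):
    """Direct textbook computation: tf * (ln((1+N)/(1+df)) + 1), L2-normalized."""
    N = len(texts)
    docs = [tokenize(t) for t in texts]
    vocab = sorted({w for d in docs for w in d})
    df = {w: sum(1 for d in docs if w in d) for w in vocab}
    tf = Counter(tokenize(query))
    raw = {w: tf[w] * (math.log((1 + N) / (1 + df[w])) + 1) for w in vocab}
    norm = math.sqrt(sum(v * v for v in raw.values()))
    return {w: (v / norm if norm else 0.0) for w, v in raw.items()}


class TestTfidf:
    def corpus(self, texts):
        return Corpus([Document(str(i), t) for i, t in enumerate(texts)])

    def test_identical_one_word_docs_are_unit_vectors(self):
        spec = fit_tfidf(self.corpus(["smoke", "smoke"]))
        v = transform_tfidf("smoke", spec).vector
        np.testing.assert_allclose(v, [1.0])

    def test_ubiquitous_word_has_smaller_idf(self):
        texts = ["common rare", "common", "common", "common"]
        spec = fit_tfidf(self.corpus(texts))
        v = transform_tfidf("common rare", spec).vector
        vocab = spec._tfidf.vocabulary_
        assert v[vocab["common"]] < v[vocab["rare"]]

    def test_matches_hand_oracle_on_toy_corpus(self):
        texts = [
            "no smoking today",
            "smokes two packs",
            "denies tobacco use",
            "tobacco use yes",
            "no tobacco no smoking",
        ]
        spec = fit_tfidf(self.corpus(texts))
        vocab = spec._tfidf.vocabulary_
        for query in texts:
            got = transform_tfidf(query, spec).vector
            want = tfidf_oracle(texts, query)
            for w, val in want.items():
                assert got[vocab[w]] == pytest.approx(val, abs=1e-10)

    def test_unseen_words_contribute_zero(self):
        spec = fit_tfidf(self.corpus(["alpha beta"]))
        fv = transform_tfidf("alpha gamma", spec)
        assert fv.oov_count == 1
        assert np.linalg.norm(fv.vector) == pytest.approx(1.0)

    def test_unit_norm_when_nonzero(self):
        spec = fit_tfidf(self.corpus(["a b c", "b c d"]))
        v = transform_tfidf("a d", spec).vector
        assert np.linalg.norm(v) == pytest.approx(1.0)

    def test_transform_before_fit_errors(self):
        with pytest.raises(ValueError):
            transform_tfidf("x", FeaturizerSpec("tfidf"))


class TestTopics:
    def corpus_two_themes(self):
        rng = np.random.default_rng(0)
        va = ["apple", "pear", "plum", "grape"]
        vb = ["nail", "screw", "bolt", "rivet"]
        docs = []
        for i in range(30):
            voc = va if i % 2 == 0 else vb
            words = [voc[j] for j in rng.integers(0, 4, size=12)]
            docs.append(Document(str(i), " ".join(words)))
        return Corpus(docs)

    def test_features_on_simplex(self):
        c = self.corpus_two_themes()
        spec = fit_topics(c, K=4, seed=0)
        for d in list(c)[:5]:
            v = transform_topics(d.text, spec).vector
            assert v.min() >= 0
            assert v.sum() == pytest.approx(1.0, abs=1e-6)

    def test_disjoint_vocabularies_separate(self):
        c = self.corpus_two_themes()
        spec = fit_topics(c, K=2, seed=0)
        fa = transform_topics("apple pear plum", spec).vector
        fb = transform_topics("nail screw bolt", spec).vector
        # each theme concentrates on a different topic axis
        assert np.argmax(fa) != np.argmax(fb)

    def test_seeded_determinism(self):
        c = self.corpus_two_themes()
        s1 = fit_topics(c, K=3, seed=5)
        s2 = fit_topics(c, K=3, seed=5)
        np.testing.assert_allclose(
            transform_topics("apple nail", s1).vector,
            transform_topics("apple nail", s2).vector,
        )

    def test_k_below_two_rejected(self):
        with pytest.raises(ValueError):
            fit_topics(self.corpus_two_themes(), K=1, seed=0)


class TestNearestNeighbors:
    def test_colinear_vector_is_top(self):
        t = EmbeddingTable(
            {"a": np.array([1.0, 1.0]), "b": np.array([2.0, 2.0]), "c": np.array([1.0, -1.0])}
        )
        (tok, sim), *_ = nearest_neighbors("a", t, 2)
        assert tok == "b" and sim == pytest.approx(1.0)

    def test_orthogonal_similarity_zero(self):
        t = EmbeddingTable(
            {"x": np.array([1.0, 0.0]), "y": np.array([0.0, 1.0]), "z": np.array([0.0, -2.0])}
        )
        sims = dict(nearest_neighbors("x", t, 2))
        assert all(abs(s) < 1e-12 for s in sims.values())

    def test_ties_break_lexicographically(self):
        t = EmbeddingTable(
            {"q": np.array([1.0, 0.0]), "bb": np.array([2.0, 0.0]), "aa": np.array([3.0, 0.0])}
        )
        assert [tok for tok, _ in nearest_neighbors("q", t, 2)] == ["aa", "bb"]

    def test_oov_query_errors_with_token(self):
        t = EmbeddingTable({"a": np.array([1.0, 2.0])})
        with pytest.raises(KeyError, match="zzz"):
            nearest_neighbors("zzz", t, 1)
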