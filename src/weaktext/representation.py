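"""Document feature representations.

The primary representation is the mean-pooled word embedding: a document
``d = {w_1, ..., w_M}`` is represented as ``x = (1/M') Σ x_i`` over the
``M'`` tokens found in a pre-trained embedding table (out-of-vocabulary
tokens are skipped and counted; an all-OOV document gets the zero vector
and a degenerate flag).  Two sparse/latent baselines are provided for
comparison: tf-idf (smoothed idf, L2-normalized rows) and an LDA
topic-mixture feature, where each in-vocabulary token contributes its
word-topic mixture distribution and the document feature is their mean
(a point on the K-simplex).

A cosine nearest-neighbor query over an embedding table supports
similar-word reports (misspellings such as "tobaco" land next to
"tobacco" in a well-trained space).
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from typing import List, Optional, Sequence, Tuple

import numpy as np
from sklearn.decomposition import LatentDirichletAllocation
from sklearn.feature_extraction.text import TfidfVectorizer

from .corpus_io import Corpus, EmbeddingTable

__all__ = [
    "tokenize",
    "FeatureVector",
    "FeaturizerSpec",
    "embed_mean",
    "fit_tfidf",
    "transform_tfidf",
    "fit_topics",
    "transform_topics",
    "nearest_neighbors",
    "featurize_corpus",
]

_TOKEN_RE = re.compile(r"[^\W_]+", re.UNICODE)


def tokenize(text: str) -> List[str]:
    """Lowercase and split on non-alphanumeric runs; deterministic."""
    return _TOKEN_RE.findall(text.lower())


@dataclass
class FeatureVector:
    """A dense document feature with bookkeeping diagnostics.

    ``token_count`` is the document length M; ``oov_count`` how many tokens
    had no vector (or were outside the fitted vocabulary); ``degenerate``
    marks documents with no usable tokens (zero vector returned).
    """

    vector: np.ndarray
    feature_mode: str
    token_count: int = 0
    oov_count: int = 0
    degenerate: bool = False


@dataclass
class FeaturizerSpec:
    """A feature mapping f: document -> vector, with its fitted state.

    ``feature_mode`` is one of ``embedding_mean``, ``tfidf`` or ``topic``.
    """

    feature_mode: str
    embedding_table: Optional[EmbeddingTable] = None
    n_topics: int = 100
    _tfidf: Optional[TfidfVectorizer] = field(default=None, repr=False)
    _lda: Optional[LatentDirichletAllocation] = field(default=None, repr=False)
    _topic_vocab: Optional[dict] = field(default=None, repr=False)
    _word_topic: Optional[np.ndarray] = field(default=None, repr=False)

    def transform(self, text: str) -> FeatureVector:
        if self.feature_mode == "embedding_mean":
            if self.embedding_table is None:
                raise ValueError("embedding_mean requires an EmbeddingTable")
            return embed_mean(tokenize(text), self.embedding_table)
        if self.feature_mode == "tfidf":
            return transform_tfidf(text, self)
        if self.feature_mode == "topic":
            return transform_topics(text, self)
        raise ValueError(f"unknown feature mode {self.feature_mode!r}")


def embed_mean(tokens: Sequence[str], table: EmbeddingTable) -> FeatureVector:
    """Mean of the embedding vectors of the in-vocabulary tokens.

    OOV tokens are skipped; a document with no in-vocabulary token maps to
    the zero vector with ``degenerate=True``.
    """
    found = []
    oov = 0
    for tok in tokens:
        vec = table.get(tok)
        if vec is None:
            oov += 1
        else:
            found.append(vec)
    if not found:
        return FeatureVector(
            vector=np.zeros(table.dimension),
            feature_mode="embedding_mean",
            token_count=len(tokens),
            oov_count=oov,
            degenerate=True,
        )
    return FeatureVector(
        vector=np.mean(np.asarray(found, dtype=float), axis=0),
        feature_mode="embedding_mean",
        token_count=len(tokens),
        oov_count=oov,
    )


# ---------------------------------------------------------------------------
# tf-idf baseline
# ---------------------------------------------------------------------------

def fit_tfidf(corpus: Corpus) -> FeaturizerSpec:
    """Fit the tf-idf weighting on a corpus.

    Element for word w in document d is tf(w,d) * (ln((1+N)/(1+df(w))) + 1),
    with the row L2-normalized (the smoothed-idf convention).
    """
    if len(corpus) < 1:
        raise ValueError("fit_tfidf requires at least one document")
    vec = TfidfVectorizer(
        analyzer=tokenize, norm="l2", smooth_idf=True, sublinear_tf=False
    )
    vec.fit([doc.text for doc in corpus])
    return FeaturizerSpec(feature_mode="tfidf", _tfidf=vec)


def transform_tfidf(text: str, spec: FeaturizerSpec) -> FeatureVector:
    if spec._tfidf is None:
        raise ValueError("tf-idf featurizer has not been fitted")
    row = spec._tfidf.transform([text]).toarray()[0]
    tokens = tokenize(text)
    vocab = spec._tfidf.vocabulary_
    oov = sum(1 for t in tokens if t not in vocab)
    return FeatureVector(
        vector=row,
        feature_mode="tfidf",
        token_count=len(tokens),
        oov_count=oov,
        degenerate=not np.any(row),
    )


# ---------------------------------------------------------------------------
# LDA topic-mixture baseline
# ---------------------------------------------------------------------------

def fit_topics(
    corpus: Corpus,
    K: int = 100,
    seed: int = 0,
    max_iter: int = 20,
) -> FeaturizerSpec:
    """Fit a K-topic LDA model (symmetric priors alpha=50/K, eta=0.01).

    The per-word topic mixture p(topic | word) is derived from the fitted
    topic-word matrix by column normalization and cached for transforms.
    """
    if K < 2:
        raise ValueError("the number of topics K must be at least 2")
    from sklearn.feature_extraction.text import CountVectorizer

    counts = CountVectorizer(analyzer=tokenize)
    X = counts.fit_transform([doc.text for doc in corpus])
    lda = LatentDirichletAllocation(
        n_components=K,
        # 50/K heuristic, clipped to the solver's (0, 1] admissible range
        doc_topic_prior=min(1.0, 50.0 / K),
        topic_word_prior=0.01,
        random_state=seed,
        max_iter=max_iter,
    )
    lda.fit(X)
    # components_: pseudo-counts n(topic, word); column-normalize for p(t|w)
    comp = lda.components_
    word_topic = comp / comp.sum(axis=0, keepdims=True)
    return FeaturizerSpec(
        feature_mode="topic",
        n_topics=K,
        _lda=lda,
        _topic_vocab=counts.vocabulary_,
        _word_topic=word_topic,
    )


def transform_topics(text: str, spec: FeaturizerSpec) -> FeatureVector:
    """Mean word-topic mixture over the in-vocabulary tokens (K-simplex)."""
    if spec._word_topic is None or spec._topic_vocab is None:
        raise ValueError("topic featurizer has not been fitted")
    tokens = tokenize(text)
    cols = [spec._topic_vocab[t] for t in tokens if t in spec._topic_vocab]
    oov = len(tokens) - len(cols)
    if not cols:
        return FeatureVector(
            vector=np.zeros(spec.n_topics),
            feature_mode="topic",
            token_count=len(tokens),
            oov_count=oov,
            degenerate=True,
        )
    mix = spec._word_topic[:, cols].mean(axis=1)
    return FeatureVector(
        vector=mix,
        feature_mode="topic",
        token_count=len(tokens),
        oov_count=oov,
    )


# ---------------------------------------------------------------------------
# Nearest neighbors (similar-word reports)
# ---------------------------------------------------------------------------

def nearest_neighbors(
    token: str, table: EmbeddingTable, n: int = 5
) -> List[Tuple[str, float]]:
    """The n vocabulary tokens most cosine-similar to ``token``.

    The query itself is excluded; ties are broken lexicographically.
    Raises ``KeyError`` for an out-of-vocabulary query.
    """
    if n < 1:
        raise ValueError("n must be at least 1")
    tok = token.lower()
    if tok not in table:
        raise KeyError(f"token {token!r} not in the embedding table")
    query = table[tok]
    qn = np.linalg.norm(query)
    scored = []
    for other, vec in table.items():
        if other == tok:
            continue
        denom = qn * np.linalg.norm(vec)
        sim = float(query @ vec / denom) if denom > 0 else 0.0
        scored.append((other, sim))
    scored.sort(key=lambda p: (-p[1], p[0]))
    return scored[:n]


def featurize_corpus(corpus: Corpus, spec: FeaturizerSpec) -> np.ndarray:
    """Stack per-document features into an (n_docs, dim) dense matrix."""
    return np.asarray([spec.transform(doc.text).vector for doc in corpus])
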