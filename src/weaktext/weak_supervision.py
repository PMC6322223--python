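"""Weak-supervision training: rules → weak labels → features → classifier.

Classifiers follow fixed, conventional settings: a linear SVM with cost
C = 10, a random forest of 5 trees, and a single-hidden-layer perceptron
with 15 ReLU units.  A fourth kind, a word-level CNN consuming token-index
sequences through an embedding layer, is defined as an optional plugin:
requesting it without a neural-network backend installed raises a clear
:class:`CapabilityError`.  Everything the package's evaluations need is
achievable with the three core models.

``run_paradigm`` is the single end-to-end entry point: it weak-labels the
training corpus with a rule set, fits the featurizer on training text
only, trains the classifier on the weak labels, predicts the test corpus,
and evaluates both the model and the rule labeler against gold labels.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Dict, List, Optional, Sequence

import joblib
import numpy as np
from sklearn.ensemble import RandomForestClassifier
from sklearn.neural_network import MLPClassifier
from sklearn.svm import LinearSVC

from .corpus_io import Corpus, EmbeddingTable
from .evaluation import (
    DisagreementReport,
    EvalReport,
    SignificanceResult,
    disagreement_report,
    prf,
    significance_test,
)
from .representation import FeaturizerSpec, featurize_corpus, fit_tfidf, fit_topics
from .rule_labeler import RuleSet, label_corpus

__all__ = [
    "CapabilityError",
    "ClassifierSpec",
    "TrainedModel",
    "train",
    "predict",
    "run_paradigm",
    "ParadigmResult",
]

CLASSIFIER_KINDS = ("svm_linear", "random_forest", "mlp", "cnn")


class CapabilityError(RuntimeError):
    """An optional capability (the CNN plugin) is not available."""


@dataclass
class ClassifierSpec:
    """Classifier kind, fixed hyperparameters and the training seed.

    Defaults: linear SVM C=10; random forest with 5 trees; MLP with one
    hidden layer of 15 rectified-linear units; CNN with 128 convolution
    filters over an embedding layer (optional plugin).
    """

    kind: str
    seed: int
    svm_C: float = 10.0
    rf_trees: int = 5
    mlp_hidden: int = 15
    cnn_filters: int = 128
    cnn_window: int = 3
    max_seq_len: int = 100
    embedding_table: Optional[EmbeddingTable] = None

    def __post_init__(self) -> None:
        if self.kind not in CLASSIFIER_KINDS:
            raise ValueError(
                f"unknown classifier kind {self.kind!r}; valid: {CLASSIFIER_KINDS}"
            )


@dataclass
class TrainedModel:
    """A fitted classifier bound to a feature mode and label set."""

    spec: ClassifierSpec
    estimator: object
    feature_mode: str
    label_set: List[str]
    n_features: int
    n_train: int
    label_source: str = "weak"

    def save(self, path: str) -> None:
        joblib.dump(self, path)

    @staticmethod
    def load(path: str) -> "TrainedModel":
        model = joblib.load(path)
        if not isinstance(model, TrainedModel):
            raise ValueError(f"{path} does not contain a TrainedModel")
        return model


def _build_estimator(spec: ClassifierSpec):
    if spec.kind == "svm_linear":
        return LinearSVC(C=spec.svm_C, random_state=spec.seed, max_iter=20000)
    if spec.kind == "random_forest":
        return RandomForestClassifier(
            n_estimators=spec.rf_trees, random_state=spec.seed
        )
    if spec.kind == "mlp":
        return MLPClassifier(
            hidden_layer_sizes=(spec.mlp_hidden,),
            activation="relu",
            random_state=spec.seed,
            max_iter=1000,
        )
    raise CapabilityError(
        "the cnn classifier is an optional plugin requiring a neural-network "
        "backend, which is not installed; use svm_linear, random_forest or mlp"
    )


def train(
    features: np.ndarray,
    labels: Sequence[str],
    spec: ClassifierSpec,
    feature_mode: str = "embedding_mean",
    label_source: str = "weak",
) -> TrainedModel:
    """Fit a classifier on (features, labels); reproducible given the seed."""
    X = np.asarray(features, dtype=float)
    y = list(labels)
    if X.ndim != 2:
        raise ValueError("features must be a 2-D array (n_docs, n_features)")
    if X.shape[0] != len(y):
        raise ValueError(
            f"feature/label length mismatch: {X.shape[0]} != {len(y)}"
        )
    classes = sorted(set(y))
    if len(classes) < 2:
        raise ValueError("training labels must contain at least 2 classes")
    est = _build_estimator(spec)
    est.fit(X, y)
    return TrainedModel(
        spec=spec,
        estimator=est,
        feature_mode=feature_mode,
        label_set=classes,
        n_features=X.shape[1],
        n_train=X.shape[0],
        label_source=label_source,
    )


def predict(model: TrainedModel, inputs: np.ndarray) -> List[str]:
    """One label per input row, each from the model's bound label set."""
    X = np.asarray(inputs, dtype=float)
    if X.size == 0:
        return []
    if X.ndim != 2 or X.shape[1] != model.n_features:
        raise ValueError(
            f"input features must have shape (n, {model.n_features}); got {X.shape}"
        )
    return [str(lab) for lab in model.estimator.predict(X)]


@dataclass
class ParadigmResult:
    """Everything the end-to-end run produces."""

    model: TrainedModel
    predictions: List[str]
    report: EvalReport  # model vs gold, with the model-vs-rules comparison
    rule_report: EvalReport  # rule labeler vs gold on the same test set
    disagreements: DisagreementReport
    weak_label_distribution: Dict[str, int]


def run_paradigm(
    train_corpus: Corpus,
    test_corpus: Corpus,
    ruleset: RuleSet,
    featurizer_spec: FeaturizerSpec,
    classifier_spec: ClassifierSpec,
    n_boot: int = 1000,
) -> ParadigmResult:
    """Run the full weak-supervision paradigm.

    Weak-labels the training corpus with ``ruleset``, fits the featurizer
    on training text only (tf-idf and topic modes are refitted here; the
    embedding mode uses its pre-trained table), trains the classifier on
    the weak labels, predicts the test corpus, and evaluates both the
    model and the rule labeler against the test corpus's gold labels.
    """
    gold = [d.gold_label for d in test_corpus]
    if any(g is None for g in gold):
        raise ValueError("every test document must carry a gold label")

    weak = label_corpus(train_corpus, ruleset)
    weak_labels = weak.weak_labels()

    fspec = featurizer_spec
    if fspec.feature_mode == "tfidf" and fspec._tfidf is None:
        fspec = fit_tfidf(train_corpus)
    elif fspec.feature_mode == "topic" and fspec._word_topic is None:
        fspec = fit_topics(
            train_corpus, K=fspec.n_topics, seed=classifier_spec.seed
        )

    X_train = featurize_corpus(train_corpus, fspec)
    model = train(
        X_train,
        weak_labels,
        classifier_spec,
        feature_mode=fspec.feature_mode,
        label_source="weak",
    )

    X_test = featurize_corpus(test_corpus, fspec)
    predictions = predict(model, X_test)

    rule_test = label_corpus(test_corpus, ruleset).weak_labels()
    labels = list(ruleset.label_set.categories)
    report = prf(gold, predictions, labels=labels)
    rule_report = prf(gold, rule_test, labels=labels)
    report.comparison = significance_test(
        gold,
        predictions,
        rule_test,
        n_boot=n_boot,
        seed=classifier_spec.seed,
        system_a="model",
        system_b="rules",
    )

    rule_by_id = {d.id: lab for d, lab in zip(test_corpus, rule_test)}
    model_by_id = {d.id: lab for d, lab in zip(test_corpus, predictions)}
    disagreements = disagreement_report(test_corpus, rule_by_id, model_by_id)

    dist: Dict[str, int] = {}
    for lab in weak_labels:
        dist[lab] = dist.get(lab, 0) + 1

    return ParadigmResult(
        model=model,
        predictions=predictions,
        report=report,
        rule_report=rule_report,
        disagreements=disagreements,
        weak_label_distribution=dist,
    )
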