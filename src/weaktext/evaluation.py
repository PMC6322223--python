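"""Evaluation: precision/recall/F1, significance testing, error reports.

Metrics follow the standard confusion-matrix definitions.  Per-class
precision, recall and F1 are always reported together with micro and macro
averages; for single-label classification micro-F1 equals accuracy.

Two classifiers are compared with a paired bootstrap test on F1: the test
set is resampled with replacement ``n_boot`` times, the F1 difference A−B
is computed on each resample, and the observed mean difference is referred
to its bootstrap standard error through a t distribution with
``n_boot − 1`` degrees of freedom.  The disagreement report lists every
document where the rule labeler and the trained model disagree, and
tallies which system was right — the shape of a manual error analysis.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence

import numpy as np
from scipy import stats
from sklearn.metrics import confusion_matrix, precision_recall_fscore_support

from .corpus_io import Corpus

__all__ = [
    "EvalReport",
    "ClassMetrics",
    "prf",
    "micro_f1",
    "significance_test",
    "SignificanceResult",
    "DisagreementCase",
    "DisagreementReport",
    "disagreement_report",
]


@dataclass(frozen=True)
class ClassMetrics:
    precision: float
    recall: float
    f1: float
    support: int
    zero_division: bool = False


@dataclass
class EvalReport:
    """Per-class and aggregate precision/recall/F1 with the confusion matrix."""

    labels: List[str]
    per_class: Dict[str, ClassMetrics]
    micro: ClassMetrics
    macro: ClassMetrics
    confusion: np.ndarray
    n: int
    averaging: str = "micro"
    comparison: Optional["SignificanceResult"] = None

    @property
    def precision(self) -> float:
        return self.micro.precision if self.averaging == "micro" else self.macro.precision

    @property
    def recall(self) -> float:
        return self.micro.recall if self.averaging == "micro" else self.macro.recall

    @property
    def f1(self) -> float:
        return self.micro.f1 if self.averaging == "micro" else self.macro.f1

    def to_dict(self) -> Dict[str, object]:
        d: Dict[str, object] = {
            "n": self.n,
            "averaging": self.averaging,
            "labels": self.labels,
            "per_class": {
                k: {
                    "precision": v.precision,
                    "recall": v.recall,
                    "f1": v.f1,
                    "support": v.support,
                }
                for k, v in self.per_class.items()
            },
            "micro": {"precision": self.micro.precision, "recall": self.micro.recall, "f1": self.micro.f1},
            "macro": {"precision": self.macro.precision, "recall": self.macro.recall, "f1": self.macro.f1},
            "confusion": self.confusion.tolist(),
        }
        if self.comparison is not None:
            d["comparison"] = self.comparison.to_dict()
        return d

    def to_json(self, path: str) -> None:
        with open(path, "w", encoding="utf-8") as fh:
            json.dump(self.to_dict(), fh, indent=2)


def prf(
    gold: Sequence[str],
    predicted: Sequence[str],
    labels: Optional[Sequence[str]] = None,
    averaging: str = "micro",
) -> EvalReport:
    """Precision/recall/F1 from the confusion matrix.

    Zero-denominator cells (a class never predicted or never present) are
    reported as 0 and flagged on the class.
    """
    if len(gold) != len(predicted):
        raise ValueError(
            f"gold and predicted lengths differ: {len(gold)} != {len(predicted)}"
        )
    if averaging not in ("micro", "macro", "per_class"):
        raise ValueError(f"unknown averaging {averaging!r}")
    if labels is None:
        labels = sorted(set(gold) | set(predicted))
    labels = list(labels)
    gold = list(gold)
    predicted = list(predicted)

    p, r, f, s = precision_recall_fscore_support(
        gold, predicted, labels=labels, zero_division=0
    )
    per_class = {}
    for i, lab in enumerate(labels):
        predicted_count = sum(1 for x in predicted if x == lab)
        per_class[lab] = ClassMetrics(
            precision=float(p[i]),
            recall=float(r[i]),
            f1=float(f[i]),
            support=int(s[i]),
            zero_division=(predicted_count == 0 or s[i] == 0),
        )
    mp, mr, mf, _ = precision_recall_fscore_support(
        gold, predicted, labels=labels, average="micro", zero_division=0
    )
    Mp, Mr, Mf, _ = precision_recall_fscore_support(
        gold, predicted, labels=labels, average="macro", zero_division=0
    )
    return EvalReport(
        labels=labels,
        per_class=per_class,
        micro=ClassMetrics(float(mp), float(mr), float(mf), len(gold)),
        macro=ClassMetrics(float(Mp), float(Mr), float(Mf), len(gold)),
        confusion=confusion_matrix(gold, predicted, labels=labels),
        n=len(gold),
        averaging="micro" if averaging == "per_class" else averaging,
    )


def micro_f1(gold: Sequence[str], predicted: Sequence[str]) -> float:
    """Micro-averaged F1 (equals accuracy for single-label tasks)."""
    gold = np.asarray(gold)
    predicted = np.asarray(predicted)
    if gold.shape != predicted.shape:
        raise ValueError("length mismatch")
    if gold.size == 0:
        return 0.0
    return float(np.mean(gold == predicted))


@dataclass
class SignificanceResult:
    """Paired-bootstrap F1 comparison of two systems on one test set."""

    system_a: str
    system_b: str
    f1_a: float
    f1_b: float
    t_statistic: float
    p_value: float
    n_boot: int
    seed: int
    mean_difference: float
    degenerate: bool = False
    note: str = ""

    @property
    def significant(self) -> bool:
        return (not self.degenerate) and self.p_value < 0.05

    def to_dict(self) -> Dict[str, object]:
        return {
            "system_a": self.system_a,
            "system_b": self.system_b,
            "f1_a": self.f1_a,
            "f1_b": self.f1_b,
            "mean_difference": self.mean_difference,
            "t_statistic": self.t_statistic,
            "p_value": self.p_value,
            "n_boot": self.n_boot,
            "seed": self.seed,
            "degenerate": self.degenerate,
            "note": self.note,
        }


def significance_test(
    gold: Sequence[str],
    preds_a: Sequence[str],
    preds_b: Sequence[str],
    n_boot: int = 1000,
    seed: int = 0,
    system_a: str = "A",
    system_b: str = "B",
) -> SignificanceResult:
    """Paired bootstrap t-test of the micro-F1 difference A − B.

    The test set is resampled with replacement ``n_boot`` times; on each
    resample the F1 difference is recorded.  The statistic is the mean
    difference divided by the bootstrap standard deviation (the bootstrap
    SE of the difference), referred to a t distribution with n_boot − 1
    degrees of freedom.  Seeded and reproducible.
    """
    gold = np.asarray(gold)
    a = np.asarray(preds_a)
    b = np.asarray(preds_b)
    if not (gold.shape == a.shape == b.shape):
        raise ValueError("gold, preds_a and preds_b must have equal lengths")
    if n_boot < 100:
        raise ValueError("n_boot must be at least 100")
    n = gold.size
    f1_a = micro_f1(gold, a)
    f1_b = micro_f1(gold, b)

    if np.array_equal(a, b):
        return SignificanceResult(
            system_a, system_b, f1_a, f1_b, 0.0, 1.0, n_boot, seed, 0.0,
            degenerate=True, note="identical predictions; no evidence of difference",
        )
    if len(set(gold.tolist())) < 2:
        return SignificanceResult(
            system_a, system_b, f1_a, f1_b, float("nan"), float("nan"),
            n_boot, seed, f1_a - f1_b,
            degenerate=True, note="all gold labels identical; p-value undefined",
        )

    rng = np.random.default_rng(seed)
    correct_a = (a == gold).astype(float)
    correct_b = (b == gold).astype(float)
    idx = rng.integers(0, n, size=(n_boot, n))
    diffs = correct_a[idx].mean(axis=1) - correct_b[idx].mean(axis=1)
    sd = diffs.std(ddof=1)
    if sd == 0:
        return SignificanceResult(
            system_a, system_b, f1_a, f1_b, float("nan"), float("nan"),
            n_boot, seed, float(diffs.mean()),
            degenerate=True, note="zero bootstrap variance; p-value undefined",
        )
    t = float(diffs.mean() / sd)
    p = float(2.0 * stats.t.sf(abs(t), df=n_boot - 1))
    return SignificanceResult(
        system_a, system_b, f1_a, f1_b, t, p, n_boot, seed, float(diffs.mean())
    )


# ---------------------------------------------------------------------------
# Disagreement (error-analysis) reports
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class DisagreementCase:
    """A document where rule labeler and model disagree."""

    document_id: str
    text: str
    gold: str
    rule_label: str
    model_label: str
    winner: str  # "model" | "rules" | "neither"


@dataclass
class DisagreementReport:
    cases: List[DisagreementCase]
    model_right: int
    rules_right: int
    both_wrong: int

    def __len__(self) -> int:
        return len(self.cases)

    def to_tsv(self, path: str) -> None:
        with open(path, "w", encoding="utf-8") as fh:
            fh.write("id\ttext\tgold\trule\tmodel\twinner\n")
            for c in self.cases:
                text = c.text.replace("\t", " ").replace("\n", " ")
                fh.write(
                    f"{c.document_id}\t{text}\t{c.gold}\t{c.rule_label}\t"
                    f"{c.model_label}\t{c.winner}\n"
                )


def disagreement_report(
    corpus: Corpus,
    rule_labels: Dict[str, str],
    model_labels: Dict[str, str],
) -> DisagreementReport:
    """List documents where rules and model disagree; tally who was right.

    ``rule_labels`` and ``model_labels`` map document id -> label and must
    cover every document carrying a gold label.
    """
    cases: List[DisagreementCase] = []
    model_right = rules_right = both_wrong = 0
    for doc in corpus:
        if doc.gold_label is None:
            continue
        if doc.id not in rule_labels or doc.id not in model_labels:
            raise ValueError(f"labels missing for document id {doc.id!r}")
        rl = rule_labels[doc.id]
        ml = model_labels[doc.id]
        if rl == ml:
            continue
        if ml == doc.gold_label:
            winner = "model"
            model_right += 1
        elif rl == doc.gold_label:
            winner = "rules"
            rules_right += 1
        else:
            winner = "neither"
            both_wrong += 1
        cases.append(
            DisagreementCase(doc.id, doc.text, doc.gold_label, rl, ml, winner)
        )
    return DisagreementReport(cases, model_right, rules_right, both_wrong)
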