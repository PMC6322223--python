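"""Rule-based labeling functions for clinical snippets.

A *rule set* is a deterministic labeling function: an ordered collection of
regular-expression rules, a label set, and a precedence order over
categories.  Applied to a document it produces a *weak label* — the category
of the first category (in precedence order) with any matching rule, or the
task's default category when nothing fires.  These weak labels are what the
downstream classifiers are trained on.

Three built-in rule sets ship with the package:

``mayo_smoking``
    Binary smoker / non-smoker extraction from social-history sections.
    Negation patterns ("no smoking", "denies smoking", ...) take precedence
    over affirmative smoking keywords, and the default (nothing extracted)
    is non-smoker.

``hip_fracture``
    Binary proximal-femur (hip) fracture detection in radiology reports.
    This is a sentence-scoped co-occurrence labeler: a positive label
    requires an anatomical keyword ("femoral neck", "intertrochanteric",
    ...) and a fracture modifier ("fx", "fracture", "displaced", ...) to
    match within the same sentence.

``i2b2_smoking``
    Multiclass smoking status (current smoker / past smoker / non-smoker /
    unknown) for discharge records, combining temporal smoking patterns
    with the mayo negation rules; the default is unknown.

Matching is case-insensitive and every top-level pattern alternative is
anchored with word boundaries, so ``smokers?`` does not fire inside
``nonsmoker``.  Sentences are segmented on ``. ! ? ;`` and newline.
"""

from __future__ import annotations

import json
import re
from bisect import bisect_right
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

from .corpus_io import Corpus, Document, LabelSet

__all__ = [
    "Rule",
    "RuleSet",
    "WeakLabel",
    "Evidence",
    "WeakLabeledCorpus",
    "split_sentences",
    "compile_rule_pattern",
    "load_builtin",
    "load_ruleset_config",
    "apply_ruleset",
    "label_corpus",
    "BUILTIN_RULESETS",
]

SENTENCE_DELIMITERS = ".!?;\n"


def split_sentences(text: str) -> List[Tuple[int, int]]:
    """Split ``text`` into sentence spans on ``. ! ? ;`` and newline.

    Returns ordered, non-overlapping ``(start, end)`` character spans that
    together cover every non-delimiter character; zero-length segments
    (adjacent delimiters) are dropped.
    """
    spans: List[Tuple[int, int]] = []
    start = 0
    for i, ch in enumerate(text):
        if ch in SENTENCE_DELIMITERS:
            if i > start:
                spans.append((start, i))
            start = i + 1
    if len(text) > start:
        spans.append((start, len(text)))
    return spans


def _split_top_level(pattern: str) -> List[str]:
    """Split a regex on top-level ``|`` (outside any group, escapes kept)."""
    parts: List[str] = []
    cur: List[str] = []
    depth = 0
    i = 0
    while i < len(pattern):
        ch = pattern[i]
        if ch == "\\" and i + 1 < len(pattern):
            cur.append(pattern[i : i + 2])
            i += 2
            continue
        if ch == "(":
            depth += 1
        elif ch == ")":
            depth -= 1
        elif ch == "|" and depth == 0:
            parts.append("".join(cur))
            cur = []
            i += 1
            continue
        cur.append(ch)
        i += 1
    parts.append("".join(cur))
    return parts


def compile_rule_pattern(pattern: str) -> "re.Pattern[str]":
    """Compile a printed rule pattern: case-insensitive, each top-level
    alternative wrapped in word-boundary anchors."""
    alts = [r"\b(?:%s)\b" % alt for alt in _split_top_level(pattern)]
    return re.compile("|".join(alts), re.IGNORECASE)


@dataclass
class Rule:
    """One pattern rule: a regex mapped to a category (or co-occurrence role).

    ``assumed_accuracy`` is the per-rule correctness probability used only
    by the weak-supervision theory simulator, never by matching.
    """

    category: str
    pattern: str
    role: str = "pattern"  # one of {pattern, keyword, modifier}
    assumed_accuracy: Optional[float] = None
    compiled: "re.Pattern[str]" = field(init=False, repr=False)

    def __post_init__(self) -> None:
        if self.role not in ("pattern", "keyword", "modifier"):
            raise ValueError(f"unknown rule role {self.role!r}")
        if self.assumed_accuracy is not None and not (
            0.5 < self.assumed_accuracy <= 1.0
        ):
            raise ValueError("assumed_accuracy must lie in (0.5, 1]")
        self.compiled = compile_rule_pattern(self.pattern)


@dataclass
class RuleSet:
    """A named labeling function: rules + label set + precedence + scope."""

    name: str
    label_set: LabelSet
    rules: List[Rule]
    precedence: List[str]
    scope: str = "document"  # or "sentence"
    cooccurrence: bool = False

    def __post_init__(self) -> None:
        if not self.rules:
            raise ValueError("a rule set needs at least one rule")
        if self.scope not in ("document", "sentence"):
            raise ValueError(f"unknown scope {self.scope!r}")
        if self.cooccurrence and self.scope != "sentence":
            raise ValueError("co-occurrence rule sets must be sentence-scoped")
        for cat in self.precedence:
            if cat not in self.label_set:
                raise ValueError(f"precedence category {cat!r} not in label set")
        for rule in self.rules:
            if rule.category not in self.label_set:
                raise ValueError(f"rule category {rule.category!r} not in label set")

    @property
    def m(self) -> int:
        """Number of rules (the m of an m-rule labeling function)."""
        return len(self.rules)

    def accuracy_profile(self) -> Optional[List[float]]:
        """Per-rule assumed accuracies, if every rule declares one."""
        accs = [r.assumed_accuracy for r in self.rules]
        if any(a is None for a in accs):
            return None
        return [float(a) for a in accs]  # type: ignore[arg-type]


@dataclass(frozen=True)
class Evidence:
    """Where a rule fired: rule index, sentence index, character span."""

    rule_index: int
    sentence_index: int
    span: Tuple[int, int]


@dataclass
class WeakLabel:
    """The category a rule set assigned, with its supporting matches.

    ``evidence`` is empty exactly when the category is the default assigned
    because nothing fired.
    """

    category: str
    evidence: List[Evidence] = field(default_factory=list)


@dataclass
class WeakLabeledCorpus:
    """A corpus together with one weak label per document (order aligned)."""

    corpus: Corpus
    labels: List[WeakLabel]

    def __post_init__(self) -> None:
        if len(self.labels) != len(self.corpus):
            raise ValueError("one weak label per document required")

    def __len__(self) -> int:
        return len(self.corpus)

    def weak_labels(self) -> List[str]:
        return [wl.category for wl in self.labels]


# ---------------------------------------------------------------------------
# Built-in rule sets
# ---------------------------------------------------------------------------

_MAYO_SMOKER_PATTERNS = [
    "smokes?",
    "smoked",
    "smoking",
    "smokers?",
    "tobaccos?",
    "cigarettes?",
    "cigs?",
    "pipes?",
    "nicotine",
    "cigars?",
    "tob",
]

_MAYO_NONSMOKER_PATTERNS = [
    r"(no|non|not|never|negative)\W*(smoker|smoking|smoked|tobacco)",
    "nonsmoker",
    r"denies\W*smoking",
    r"(tobacco|smoke|smoking|nicotine)\W*(never|no)",
    r"doesn\'t smoke",
    r"0|zero smokers?",
]

_HIP_KEYWORD_PATTERNS = [
    "cervical|femoral head|neck",
    "(trans)?cervical",
    "(sub)?capital",
    "intracapsular",
    "trans(|-)?epiphyseal",
    "base of neck",
    "basilar femoral neck",
    "cervicotrochanteric",
    "(greater|lesser) trochanter",
    "(inter|per|intra) trochanteric",
]

# reading of the printed "(inter|per|intra) trochanteric" that also accepts
# the fused/hyphenated surface forms (intertrochanteric, inter-trochanteric)
_HIP_TROCHANTERIC_FLEXIBLE = "(inter|per|intra)[ -]?trochanteric"

_HIP_MODIFIER_PATTERNS = [
    "(micro-?)?fracture(s|d)?",
    "(epi|meta)physis",
    "separation",
    "fxs?",
    "broken",
    "cracked",
    "displace(d)?",
    "fragment",
]

_I2B2_CURRENT_PATTERNS = [
    "(does|has|continues to) smoked?",
    "uses tobacco",
    "active smoker",
    "(current|currently) (smoker|smoking)",
    "current smoker",
    r"tobacco use\W*(yes|still using|still smoking|smokes)",
]

_I2B2_PAST_PATTERNS = [
    "(stop|stopped|quit|quitted|discontinued) (tobacco|smoking)",
    "(previous|prior|remote|distant|former|ex-|ex) (tobacco|smoker)",
    "stop(ped)? smoking",
    r"tobacco use\W*(smoked|quit)",
    r"smoking\W*(used|former)",
]

BUILTIN_RULESETS = ("mayo_smoking", "hip_fracture", "i2b2_smoking")


def load_builtin(name: str, strict_trochanteric_space: bool = False) -> RuleSet:
    """Return one of the built-in rule sets by name.

    ``strict_trochanteric_space`` keeps the hip-fracture keyword
    ``(inter|per|intra) trochanteric`` with a mandatory space instead of the
    default reading that also accepts the fused and hyphenated forms.
    """
    if name == "mayo_smoking":
        label_set = LabelSet(("smoker", "non-smoker"), default_category="non-smoker")
        rules = [Rule("smoker", p) for p in _MAYO_SMOKER_PATTERNS] + [
            Rule("non-smoker", p) for p in _MAYO_NONSMOKER_PATTERNS
        ]
        return RuleSet(
            name=name,
            label_set=label_set,
            rules=rules,
            precedence=["non-smoker", "smoker"],
            scope="document",
        )
    if name == "hip_fracture":
        label_set = LabelSet(
            ("fracture", "no-fracture"), default_category="no-fracture"
        )
        keywords = list(_HIP_KEYWORD_PATTERNS)
        if not strict_trochanteric_space:
            keywords[-1] = _HIP_TROCHANTERIC_FLEXIBLE
        rules = [Rule("fracture", p, role="keyword") for p in keywords] + [
            Rule("fracture", p, role="modifier") for p in _HIP_MODIFIER_PATTERNS
        ]
        return RuleSet(
            name=name,
            label_set=label_set,
            rules=rules,
            precedence=["fracture"],
            scope="sentence",
            cooccurrence=True,
        )
    if name == "i2b2_smoking":
        label_set = LabelSet(
            ("current smoker", "past smoker", "non-smoker", "unknown"),
            default_category="unknown",
        )
        rules = (
            [Rule("current smoker", p) for p in _I2B2_CURRENT_PATTERNS]
            + [Rule("past smoker", p) for p in _I2B2_PAST_PATTERNS]
            + [Rule("non-smoker", p) for p in _MAYO_NONSMOKER_PATTERNS]
        )
        return RuleSet(
            name=name,
            label_set=label_set,
            rules=rules,
            precedence=["past smoker", "current smoker", "non-smoker"],
            scope="document",
        )
    raise ValueError(
        f"unknown built-in rule set {name!r}; valid names: {', '.join(BUILTIN_RULESETS)}"
    )


def load_ruleset_config(path: str) -> RuleSet:
    """Load a rule set from its JSON config representation."""
    with open(path, "r", encoding="utf-8") as fh:
        cfg = json.load(fh)
    return ruleset_from_config(cfg)


def ruleset_from_config(cfg: Dict[str, object]) -> RuleSet:
    label_set = LabelSet(tuple(cfg["labels"]), default_category=cfg["default"])
    rules = []
    for entry in cfg["rules"]:
        rules.append(
            Rule(
                category=entry.get("category", cfg.get("positive_category", "")),
                pattern=entry["pattern"],
                role=entry.get("role", "pattern"),
                assumed_accuracy=entry.get("accuracy"),
            )
        )
    return RuleSet(
        name=cfg.get("name", "custom"),
        label_set=label_set,
        rules=rules,
        precedence=list(cfg["precedence"]),
        scope=cfg.get("scope", "document"),
        cooccurrence=bool(cfg.get("cooccurrence", False)),
    )


def ruleset_to_config(rs: RuleSet) -> Dict[str, object]:
    return {
        "name": rs.name,
        "labels": list(rs.label_set.categories),
        "default": rs.label_set.default_category,
        "precedence": list(rs.precedence),
        "scope": rs.scope,
        "cooccurrence": rs.cooccurrence,
        "rules": [
            {
                "category": r.category,
                "role": r.role,
                "pattern": r.pattern,
                **({"accuracy": r.assumed_accuracy} if r.assumed_accuracy else {}),
            }
            for r in rs.rules
        ],
    }


# ---------------------------------------------------------------------------
# Application
# ---------------------------------------------------------------------------

def _sentence_index(spans: Sequence[Tuple[int, int]], pos: int) -> int:
    """Index of the sentence whose span contains (or most recently precedes)
    character position ``pos``; 0 for degenerate texts."""
    if not spans:
        return 0
    starts = [s for s, _ in spans]
    return max(bisect_right(starts, pos) - 1, 0)


def apply_ruleset(doc: Document, rs: RuleSet) -> WeakLabel:
    """Label one document with a rule set.

    Categories are tested in precedence order and the first with any match
    wins.  Co-occurrence rule sets instead require at least one keyword-role
    and one modifier-role match within a single sentence for the positive
    category.  If nothing fires the default category is returned with empty
    evidence.
    """
    text = doc.text
    spans = split_sentences(text)

    if rs.cooccurrence:
        return _apply_cooccurrence(text, spans, rs)

    for cat in rs.precedence:
        evidence: List[Evidence] = []
        for idx, rule in enumerate(rs.rules):
            if rule.category != cat:
                continue
            if rs.scope == "document":
                for m in rule.compiled.finditer(text):
                    evidence.append(
                        Evidence(idx, _sentence_index(spans, m.start()), m.span())
                    )
            else:
                for si, (s, e) in enumerate(spans):
                    for m in rule.compiled.finditer(text[s:e]):
                        evidence.append(
                            Evidence(idx, si, (s + m.start(), s + m.end()))
                        )
        if evidence:
            return WeakLabel(category=cat, evidence=evidence)
    return WeakLabel(category=rs.label_set.default_category, evidence=[])


def _apply_cooccurrence(
    text: str, spans: Sequence[Tuple[int, int]], rs: RuleSet
) -> WeakLabel:
    for cat in rs.precedence:
        evidence: List[Evidence] = []
        for si, (s, e) in enumerate(spans):
            sentence = text[s:e]
            kw_hits: List[Evidence] = []
            mod_hits: List[Evidence] = []
            for idx, rule in enumerate(rs.rules):
                if rule.category != cat:
                    continue
                bucket = kw_hits if rule.role == "keyword" else mod_hits
                for m in rule.compiled.finditer(sentence):
                    bucket.append(Evidence(idx, si, (s + m.start(), s + m.end())))
            if kw_hits and mod_hits:
                evidence.extend(kw_hits + mod_hits)
        if evidence:
            return WeakLabel(category=cat, evidence=evidence)
    return WeakLabel(category=rs.label_set.default_category, evidence=[])


def label_corpus(corpus: Corpus, rs: RuleSet) -> WeakLabeledCorpus:
    """Apply a rule set to every document; pure and order-preserving."""
    return WeakLabeledCorpus(
        corpus=corpus, labels=[apply_ruleset(doc, rs) for doc in corpus]
    )
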