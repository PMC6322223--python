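"""Seeded synthetic clinical-note generator.

Real social-history sections and radiology reports are protected data, so
this module fabricates corpora that reproduce the *mechanics* the
weak-supervision paradigm relies on, with gold labels assigned by
construction (before and independent of any rule set):

* smoker documents carry affirmative cue phrases ("smokes 2 packs per
  day", "current smoker", semi-structured "tobacco use: yes");
* non-smoker documents carry negated cues ("no smoking", "denies
  smoking", "tobacco: no") or no cue at all;
* fracture documents pair an anatomical keyword with a fracture modifier,
  either within one sentence or — with probability ``p_cross`` — split
  across two sentences, which the sentence-scoped rule labeler must miss;
* a misspelling operator perturbs cue words at rate ``p_miss`` by a
  single-character deletion or adjacent swap that never touches the first
  character (tobacco → tobaco), chosen so the perturbed word no longer
  matches any rule pattern on its own;
* filler words are pronounceable nonsense, screened so they can never
  trigger a rule.

``generate_embeddings`` builds a synthetic word-vector table mirroring the
geometry pre-trained clinical embeddings exhibit: each cue word is a
cluster center and every surface form (including misspelled variants)
lies near it, while filler words get independent random vectors.  That
geometry is exactly what lets an embedding-based classifier recover
documents the rules miss.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np

from .corpus_io import Corpus, Document, EmbeddingTable
from .representation import tokenize
from .rule_labeler import RuleSet, compile_rule_pattern, load_builtin
from . import theory_sim

__all__ = [
    "GeneratorConfig",
    "SyntheticCorpusBundle",
    "generate_corpus",
    "generate_embeddings",
    "corrupt_labels",
    "TASKS",
]

TASKS = ("smoking_binary", "fracture_binary", "smoking_multiclass")

# Templates: (cue phrase, words that are task cue words within it).
# {num} is filled with a random small integer at generation time.

_SMOKER_FREE = [
    ("smokes {num} packs per day", ("smokes",)),
    ("current smoker", ("smoker",)),
    ("smoking {num} per day", ("smoking",)),
    ("smoked for {num} years", ("smoked",)),
    ("heavy cigar use", ("cigar",)),
    ("nicotine dependence", ("nicotine",)),
    ("quit smoking {num} years ago", ("smoking",)),
]
_SMOKER_SEMI = [("tobacco use: yes", ("tobacco",))]

_NONSMOKER_FREE = [
    ("no smoking", ("smoking",)),
    ("denies smoking", ("denies", "smoking")),
    ("nonsmoker", ("nonsmoker",)),
    ("never smoked", ("never", "smoked")),
]
_NONSMOKER_SEMI = [("tobacco: no", ("tobacco",)), ("smoking: never", ("smoking", "never"))]

_FRACTURE_MODS = [
    ("fracture", ("fracture",)),
    ("fx", ("fx",)),
    ("displaced fracture", ("displaced", "fracture")),
]
_FRACTURE_KWS = [
    ("femoral neck", ("femoral", "neck")),
    ("intertrochanteric region", ("intertrochanteric",)),
    ("greater trochanter", ("trochanter",)),
    ("subcapital region", ("subcapital",)),
    ("basilar femoral neck", ("basilar", "femoral", "neck")),
]

_I2B2_CURRENT = [
    ("current smoker", ("current", "smoker")),
    ("active smoker", ("active", "smoker")),
    ("currently smoking", ("currently", "smoking")),
    ("continues to smoke", ("continues", "smoke")),
    ("tobacco use: yes", ("tobacco",)),
]
_I2B2_PAST = [
    ("quit smoking {num} years ago", ("quit", "smoking")),
    ("stopped smoking", ("stopped", "smoking")),
    ("former smoker", ("former", "smoker")),
    ("remote smoker history", ("remote", "smoker")),
    ("tobacco use: quit", ("tobacco", "quit")),
]
_I2B2_NONSMOKER = [
    ("no smoking", ("smoking",)),
    ("denies smoking", ("denies", "smoking")),
    ("nonsmoker", ("nonsmoker",)),
    ("never smoked", ("never", "smoked")),
    ("tobacco: no", ("tobacco",)),
]

# i2b2 2006 printed class mix (current, past, non-smoker, unknown) = 35/36/66/252
_I2B2_PROPORTIONS = {
    "current smoker": 35 / 389,
    "past smoker": 36 / 389,
    "non-smoker": 66 / 389,
    "unknown": 252 / 389,
}

_CONSONANTS = "bdfglmnprstvz"
_VOWELS = "aeiou"


@dataclass
class GeneratorConfig:
    """Study conditions for one synthetic corpus."""

    task: str
    n: int
    seed: int
    class_proportions: Optional[Dict[str, float]] = None
    p_miss: float = 0.0
    p_cross: float = 0.0
    semi_structured_rate: float = 0.2
    cue_free_negative_rate: float = 0.3
    filler_vocab_size: int = 50

    def __post_init__(self) -> None:
        if self.task not in TASKS:
            raise ValueError(f"unknown task {self.task!r}; valid: {TASKS}")
        if self.n < 0:
            raise ValueError("n must be non-negative")
        for name in ("p_miss", "p_cross", "semi_structured_rate", "cue_free_negative_rate"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must lie in [0, 1]")
        if self.class_proportions is not None:
            total = sum(self.class_proportions.values())
            if abs(total - 1.0) > 1e-9:
                raise ValueError("class proportions must sum to 1")


@dataclass
class SyntheticCorpusBundle:
    """A generated corpus plus the cue lexicon and per-document provenance.

    ``lexicon`` maps each base cue word to all surface forms generated for
    it (the base itself plus misspelled variants).  ``provenance`` records,
    per document, the gold label, template, cue sentences and corruptions —
    gold labels are recoverable from it alone.
    """

    corpus: Corpus
    lexicon: Dict[str, List[str]]
    provenance: List[Dict[str, object]]
    config: Optional[GeneratorConfig] = None


def _ruleset_for_task(task: str) -> RuleSet:
    return load_builtin(
        {
            "smoking_binary": "mayo_smoking",
            "fracture_binary": "hip_fracture",
            "smoking_multiclass": "i2b2_smoking",
        }[task]
    )


def _matches_any_rule(word: str, rs: RuleSet) -> bool:
    return any(r.compiled.search(word) for r in rs.rules)


def _make_filler_vocab(rng: np.random.Generator, size: int) -> List[str]:
    """Pronounceable nonsense words, screened against all built-in rules."""
    rulesets = [load_builtin(n) for n in ("mayo_smoking", "hip_fracture", "i2b2_smoking")]
    vocab: List[str] = []
    seen = set()
    while len(vocab) < size:
        n_syll = int(rng.integers(2, 4))
        word = "".join(
            _CONSONANTS[rng.integers(len(_CONSONANTS))]
            + _VOWELS[rng.integers(len(_VOWELS))]
            for _ in range(n_syll)
        )
        if word in seen:
            continue
        seen.add(word)
        if any(_matches_any_rule(word, rs) for rs in rulesets):
            continue
        vocab.append(word)
    return vocab


def _misspell(word: str, rng: np.random.Generator, rs: RuleSet) -> Optional[str]:
    """A single-character deletion or adjacent swap, never at position 0,
    such that the perturbed word alone no longer matches any rule."""
    if len(word) < 4:
        return None
    candidates: List[str] = []
    for i in range(1, len(word)):
        candidates.append(word[:i] + word[i + 1 :])
    for i in range(1, len(word) - 1):
        candidates.append(word[:i] + word[i + 1] + word[i] + word[i + 2 :])
    seen = []
    for c in candidates:
        if c != word and c not in seen and not _matches_any_rule(c, rs):
            seen.append(c)
    if not seen:
        return None
    return seen[int(rng.integers(len(seen)))]


def _filler_sentence(rng: np.random.Generator, fillers: Sequence[str]) -> str:
    k = int(rng.integers(3, 7))
    idx = rng.integers(0, len(fillers), size=k)
    return " ".join(fillers[i] for i in idx)


def _assemble(
    rng: np.random.Generator, cue_sentences: Sequence[str], fillers: Sequence[str]
) -> str:
    # snippets are short, section-like texts: one or two filler sentences
    sents = [_filler_sentence(rng, fillers) for _ in range(int(rng.integers(1, 3)))]
    for cs in cue_sentences:
        pos = int(rng.integers(0, len(sents) + 1))
        sents.insert(pos, cs)
    return ". ".join(sents) + "."


def _fill_num(phrase: str, rng: np.random.Generator) -> str:
    while "{num}" in phrase:
        phrase = phrase.replace("{num}", str(int(rng.integers(1, 41))), 1)
    return phrase


def _apply_misspelling(
    sentences: List[str],
    cue_words: Sequence[str],
    rng: np.random.Generator,
    rs: RuleSet,
    lexicon: Dict[str, set],
) -> Dict[str, str]:
    """Misspell one eligible cue word in-place; returns {base: variant}."""
    eligible = [w for w in dict.fromkeys(cue_words) if len(w) >= 4]
    if not eligible:
        return {}
    base = eligible[int(rng.integers(len(eligible)))]
    variant = _misspell(base, rng, rs)
    if variant is None:
        return {}
    pat = compile_rule_pattern(base)
    for i, s in enumerate(sentences):
        new, n_sub = pat.subn(variant, s, count=1)
        if n_sub:
            sentences[i] = new
            lexicon.setdefault(base, set()).add(variant)
            return {base: variant}
    return {}


def generate_corpus(config: GeneratorConfig) -> SyntheticCorpusBundle:
    """Generate a seeded synthetic corpus for one task.

    Gold labels are assigned by construction before any corruption is
    applied, so rule-labeler accuracy on the output is controlled entirely
    by ``p_miss`` (and ``p_cross`` for the fracture task).
    """
    rng = np.random.default_rng(config.seed)
    fillers = _make_filler_vocab(rng, config.filler_vocab_size)
    rs = _ruleset_for_task(config.task)

    # seed the lexicon with every base cue word of the task
    lexicon: Dict[str, set] = {}
    for templates in _task_templates(config.task).values():
        for _, cues in templates:
            for w in cues:
                lexicon.setdefault(w, set()).add(w)

    labels = _draw_labels(config, rng)
    docs: List[Document] = []
    provenance: List[Dict[str, object]] = []
    for i, gold in enumerate(labels):
        doc_id = f"{config.task}-{i:05d}"
        text, prov = _generate_document(config, gold, rng, rs, fillers, lexicon)
        prov.update({"id": doc_id, "gold": gold})
        docs.append(
            Document(id=doc_id, text=text, gold_label=gold, meta={"synthetic": True})
        )
        provenance.append(prov)
    corpus = Corpus(docs, task_name=config.task)
    return SyntheticCorpusBundle(
        corpus=corpus,
        lexicon={b: sorted(v) for b, v in sorted(lexicon.items())},
        provenance=provenance,
        config=config,
    )


def _task_templates(task: str) -> Dict[str, List[Tuple[str, Tuple[str, ...]]]]:
    if task == "smoking_binary":
        return {
            "smoker": _SMOKER_FREE + _SMOKER_SEMI,
            "non-smoker": _NONSMOKER_FREE + _NONSMOKER_SEMI,
        }
    if task == "fracture_binary":
        return {
            "fracture": [(m, mc) for m, mc in _FRACTURE_MODS]
            + [(k, kc) for k, kc in _FRACTURE_KWS],
            "no-fracture": [],
        }
    return {
        "current smoker": _I2B2_CURRENT,
        "past smoker": _I2B2_PAST,
        "non-smoker": _I2B2_NONSMOKER,
        "unknown": [],
    }


def _default_proportions(task: str) -> Dict[str, float]:
    if task == "smoking_binary":
        return {"smoker": 0.5, "non-smoker": 0.5}
    if task == "fracture_binary":
        return {"fracture": 0.5, "no-fracture": 0.5}
    return dict(_I2B2_PROPORTIONS)


def _draw_labels(config: GeneratorConfig, rng: np.random.Generator) -> List[str]:
    props = config.class_proportions or _default_proportions(config.task)
    cats = sorted(props)
    p = np.array([props[c] for c in cats])
    p = p / p.sum()
    idx = rng.choice(len(cats), size=config.n, p=p)
    return [cats[j] for j in idx]


def _pick(rng: np.random.Generator, options: Sequence) -> object:
    return options[int(rng.integers(len(options)))]


def _generate_document(
    config: GeneratorConfig,
    gold: str,
    rng: np.random.Generator,
    rs: RuleSet,
    fillers: Sequence[str],
    lexicon: Dict[str, set],
) -> Tuple[str, Dict[str, object]]:
    prov: Dict[str, object] = {"cross_split": False, "misspelled": {}, "template": ""}
    cue_sentences: List[str] = []
    cue_words: Tuple[str, ...] = ()

    if config.task == "fracture_binary":
        cue_sentences, cue_words, prov = _fracture_cues(config, gold, rng, prov)
    elif gold in ("unknown",) or (
        config.task == "smoking_binary"
        and gold == "non-smoker"
        and rng.random() < config.cue_free_negative_rate
    ):
        prov["template"] = "cue-free"
    else:
        templates = _task_templates(config.task)[gold]
        free = [t for t in templates if ":" not in t[0]]
        semi = [t for t in templates if ":" in t[0]]
        pool = semi if (semi and rng.random() < config.semi_structured_rate) else free
        phrase, cue_words = _pick(rng, pool)
        phrase = _fill_num(phrase, rng)
        cue_sentences = [phrase]
        prov["template"] = phrase

    if cue_sentences and rng.random() < config.p_miss:
        prov["misspelled"] = _apply_misspelling(
            cue_sentences, cue_words, rng, rs, lexicon
        )

    text = _assemble(rng, cue_sentences, fillers)
    prov["cue_sentences"] = list(cue_sentences)
    return text, prov


def _fracture_cues(
    config: GeneratorConfig,
    gold: str,
    rng: np.random.Generator,
    prov: Dict[str, object],
) -> Tuple[List[str], Tuple[str, ...], Dict[str, object]]:
    if gold == "fracture":
        mod, mod_cues = _pick(rng, _FRACTURE_MODS)
        kw, kw_cues = _pick(rng, _FRACTURE_KWS)
        cue_words = tuple(mod_cues) + tuple(kw_cues)
        if rng.random() < config.p_cross:
            prov["cross_split"] = True
            prov["template"] = f"cross: {mod} / {kw}"
            return (
                [f"indications: femur {mod}", f"pain in the {kw}"],
                cue_words,
                prov,
            )
        form = _pick(rng, ["{mod} of the {kw}", "{kw} {mod}"])
        sentence = form.format(mod=mod, kw=kw)
        prov["template"] = sentence
        return [sentence], cue_words, prov
    # no-fracture: cue-free, keyword-only, or a non-hip fracture mention
    choice = rng.random()
    if choice < 0.4:
        prov["template"] = "cue-free"
        return [], (), prov
    if choice < 0.7:
        kw, kw_cues = _pick(rng, _FRACTURE_KWS)
        sentence = f"{kw} appears intact"
        prov["template"] = sentence
        return [sentence], tuple(kw_cues), prov
    mod, mod_cues = _pick(rng, _FRACTURE_MODS)
    sentence = f"wrist {mod} noted"
    prov["template"] = sentence
    return [sentence], tuple(mod_cues), prov


# ---------------------------------------------------------------------------
# Synthetic embeddings
# ---------------------------------------------------------------------------

def generate_embeddings(
    bundle: SyntheticCorpusBundle,
    k: int = 100,
    cluster_sd: float = 0.2,
    seed: int = 0,
) -> EmbeddingTable:
    """Clustered synthetic word vectors covering the bundle's vocabulary.

    Each base cue word receives a random unit-scale cluster center; every
    surface form of it (base and misspelled variants) gets center plus
    Gaussian noise of scale ``cluster_sd``, so misspellings are close to
    their correct forms in cosine space.  All remaining corpus tokens get
    independent random vectors.
    """
    if k < 2:
        raise ValueError("embedding dimension k must be at least 2")
    if not bundle.lexicon:
        raise ValueError("bundle lexicon is empty")
    rng = np.random.default_rng(seed)
    scale = 1.0 / math.sqrt(k)
    vectors: Dict[str, np.ndarray] = {}
    for base in sorted(bundle.lexicon):
        center = rng.normal(size=k) * scale
        for form in sorted(set(bundle.lexicon[base]) | {base}):
            vectors[form.lower()] = center + rng.normal(size=k) * cluster_sd * scale
    # numerals cluster together in distributional spaces; mirror that
    number_center = rng.normal(size=k) * scale
    for doc in bundle.corpus:
        for tok in tokenize(doc.text):
            if tok in vectors:
                continue
            if tok.isdigit():
                vectors[tok] = number_center + rng.normal(size=k) * cluster_sd * scale
            else:
                vectors[tok] = rng.normal(size=k) * scale
    return EmbeddingTable(vectors)


def corrupt_labels(gold_labels: Sequence[str], phi, seed: int) -> List[str]:
    """Flip binary category labels through the rule-accuracy channel.

    Convenience wrapper over the weak-label sampler: categories are mapped
    to ±1 (sorted order), flipped with probability 1 − q, and mapped back.
    """
    cats = sorted(set(gold_labels))
    if len(cats) > 2:
        raise ValueError("corrupt_labels requires a binary task")
    if len(cats) < 2:
        # degenerate but legal: a single observed category still flips
        cats = cats + ["__other__"]
    to_sign = {cats[0]: 1, cats[1]: -1}
    signs = np.array([to_sign[g] for g in gold_labels])
    weak = theory_sim.sample_weak_labels(signs, phi, seed)
    back = {1: cats[0], -1: cats[1]}
    return [back[int(s)] for s in weak]
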