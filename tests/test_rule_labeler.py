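import itertools

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from weaktext import Corpus, Document, apply_ruleset, label_corpus, load_builtin, split_sentences
from weaktext.rule_labeler import (
    SENTENCE_DELIMITERS,
    compile_rule_pattern,
    ruleset_from_config,
    ruleset_to_config,
)

# The printed keyword tables, as comma-separated rows; the transcription in
# the package must match them pattern-for-pattern.
MAYO_SMOKER_ROW = (
    "smokes?, smoked, smoking, smokers?, tobaccos?, cigarettes?, cigs?, "
    "pipes?, nicotine, cigars?, tob"
)
MAYO_NONSMOKER_ROW = (
    r"(no|non|not|never|negative)\W*(smoker|smoking|smoked|tobacco), "
    r"nonsmoker, denies\W*smoking, (tobacco|smoke|smoking|nicotine)\W*(never|no), "
    r"doesn\'t smoke, 0|zero smokers?"
)


def doc(text):
    return Document(id="d", text=text)


class TestSentenceSplitting:
    @pytest.mark.parametrize(
        "text,n",
        [
            ("Indications: femur fx. Cannulated screw fixation.", 2),
            ("No smoking after age 40", 1),
            ("a; b. c", 3),
            ("", 0),
            ("one\ntwo!three?", 3),
        ],
    )
    def test_sentence_counts(self, text, n):
        assert len(split_sentences(text)) == n

    @settings(max_examples=200, deadline=None, derandomize=True)
    @given(st.text(alphabet="ab .;!?\n:x", max_size=60))
    def test_spans_tile_non_delimiter_text(self, text):
        spans = split_sentences(text)
        covered = set()
        last_end = -1
        for s, e in spans:
            assert s < e and s > last_end  # ordered, non-overlapping, non-empty
            last_end = e
            covered.update(range(s, e))
        for i, ch in enumerate(text):
            if i in covered:
                assert ch not in SENTENCE_DELIMITERS  # spans hold no delimiters
            else:
                assert ch in SENTENCE_DELIMITERS


class TestPatternCompilation:
    def test_word_boundaries_per_alternative(self):
        pat = compile_rule_pattern("smokers?")
        assert pat.search("smoker and smokers") is not None
        assert pat.search("nonsmoker") is None

    def test_top_level_alternation_is_split(self):
        pat = compile_rule_pattern("cervical|femoral head|neck")
        assert pat.search("the femoral head here") is not None
        assert pat.search("redneck") is None
        assert pat.search("Neck pain") is not None

    def test_case_insensitive(self):
        assert compile_rule_pattern("fxs?").search("Fx Vertebra") is not None


class TestBuiltinRuleSets:
    def test_mayo_rule_count_matches_printed_table(self, mayo):
        # independent oracle: count the comma-separated patterns per row
        smoker = [p.strip() for p in MAYO_SMOKER_ROW.split(", ")]
        nonsmoker = [p.strip() for p in MAYO_NONSMOKER_ROW.split(", ")]
        assert len(smoker) == 11 and len(nonsmoker) == 6
        assert mayo.m == len(smoker) + len(nonsmoker)
        assert [r.pattern for r in mayo.rules if r.category == "smoker"] == smoker
        assert [r.pattern for r in mayo.rules if r.category == "non-smoker"] == nonsmoker

    def test_hip_fracture_is_sentence_scoped_cooccurrence(self, hip):
        assert hip.cooccurrence and hip.scope == "sentence"
        roles = {r.role for r in hip.rules}
        assert roles == {"keyword", "modifier"}

    def test_i2b2_default_and_precedence(self, i2b2):
        assert i2b2.label_set.default_category == "unknown"
        assert i2b2.precedence == ["past smoker", "current smoker", "non-smoker"]

    def test_unknown_name_lists_valid_ones(self):
        with pytest.raises(ValueError, match="mayo_smoking"):
            load_builtin("nope")

    def test_config_round_trip(self, mayo):
        rs = ruleset_from_config(ruleset_to_config(mayo))
        assert rs.m == mayo.m
        assert apply_ruleset(doc("He smokes."), rs).category == "smoker"


CASES = [
    ("mayo", "No smoking after age XXX", "non-smoker"),
    ("mayo", "He smokes two packs daily.", "smoker"),
    ("mayo", "Patient enjoys gardening.", "non-smoker"),
    ("hip", "Exam: Sp Cerv*2vw Flex/Ext only Indications: Fx Vertebra Cervical Closed", "fracture"),
    ("hip", "Exam: R Major Jnt Asp and/or Inj Indications: R hip inj/marc/steroid; fx femur neck nos closed, pain hip", "fracture"),
    ("hip", "Indications: femur fx. Cannulated screw fixation of the right femoral neck.", "no-fracture"),
    ("i2b2", "She quit smoking in 1990.", "past smoker"),
    ("i2b2", "He is a current smoker.", "current smoker"),
    ("i2b2", "Vitals stable.", "unknown"),
]


class TestApplyRuleset:
    @pytest.mark.parametrize("rs_name,text,expected", CASES)
    def test_reference_snippets(self, rs_name, text, expected, mayo, hip, i2b2):
        rs = {"mayo": mayo, "hip": hip, "i2b2": i2b2}[rs_name]
        assert apply_ruleset(doc(text), rs).category == expected

    def test_default_has_empty_evidence(self, mayo):
        wl = apply_ruleset(doc("Patient enjoys gardening."), mayo)
        assert wl.category == "non-smoker" and wl.evidence == []

    def test_match_carries_evidence_span(self, mayo):
        wl = apply_ruleset(doc("He smokes daily."), mayo)
        assert wl.evidence
        s, e = wl.evidence[0].span
        assert "He smokes daily."[s:e].lower() == "smokes"

    def test_precedence_negation_wins(self, mayo):
        # matches both a smoker keyword and a negation pattern
        for text in ["No smoking.", "never smoked cigars", "denies smoking but smokes"]:
            assert apply_ruleset(doc(text), mayo).category == "non-smoker"

    def test_word_boundary_nonsmoker(self, mayo):
        wl = apply_ruleset(doc("nonsmoker"), mayo)
        assert wl.category == "non-smoker"
        assert wl.evidence  # matched, not defaulted

    def test_cooccurrence_order_invariance(self, hip):
        sentences = ["displaced fracture of the femoral neck", "no acute findings", "soft tissue normal"]
        labels = {
            apply_ruleset(doc(". ".join(p) + "."), hip).category
            for p in itertools.permutations(sentences)
        }
        assert labels == {"fracture"}

    def test_cooccurrence_monotonicity(self, hip):
        split = "Indications: femur fx. Pain in the femoral neck."
        joined = "Indications: femur fx of the femoral neck."
        assert apply_ruleset(doc(split), hip).category == "no-fracture"
        assert apply_ruleset(doc(joined), hip).category == "fracture"


def brute_force_label(text, rs):
    """Independent checker: enumerate every (rule, unit) pair, no short-circuiting."""
    spans = split_sentences(text)
    hits = []  # (rule_idx, sentence_idx or None)
    for idx, rule in enumerate(rs.rules):
        if rs.scope == "document" and not rs.cooccurrence:
            if rule.compiled.search(text):
                hits.append((idx, None))
        else:
            for si, (s, e) in enumerate(spans):
                if rule.compiled.search(text[s:e]):
                    hits.append((idx, si))
    if rs.cooccurrence:
        for cat in rs.precedence:
            for si in range(len(spans)):
                kw = any(
                    rs.rules[i].role == "keyword" and rs.rules[i].category == cat
                    for i, sj in hits if sj == si
                )
                mod = any(
                    rs.rules[i].role == "modifier" and rs.rules[i].category == cat
                    for i, sj in hits if sj == si
                )
                if kw and mod:
                    return cat
        return rs.label_set.default_category
    matched_cats = {rs.rules[i].category for i, _ in hits}
    for cat in rs.precedence:
        if cat in matched_cats:
            return cat
    return rs.label_set.default_category


class TestOracleEquivalence:
    def test_engine_agrees_with_brute_force(self, mayo, hip, i2b2, smoking_bundle):
        from weaktext import GeneratorConfig, generate_corpus

        corpora = {
            "mayo": Corpus(smoking_bundle.corpus.documents[:50]),
            "hip": generate_corpus(
                GeneratorConfig(task="fracture_binary", n=50, seed=21, p_miss=0.2, p_cross=0.4)
            ).corpus,
            "i2b2": generate_corpus(
                GeneratorConfig(task="smoking_multiclass", n=50, seed=22, p_miss=0.2)
            ).corpus,
        }
        for name, rs in [("mayo", mayo), ("hip", hip), ("i2b2", i2b2)]:
            for d in corpora[name]:
                assert apply_ruleset(d, rs).category == brute_force_label(d.text, rs), d.text


class TestLabelCorpus:
    def test_composition_and_determinism(self, mayo):
        c = Corpus([doc_ for doc_ in [
            Document("1", "He smokes."),
            Document("2", "No smoking."),
            Document("3", "Weather fine."),
        ]])
        out1 = label_corpus(c, mayo)
        out2 = label_corpus(c, mayo)
        assert out1.weak_labels() == ["smoker", "non-smoker", "non-smoker"]
        assert out1.weak_labels() == out2.weak_labels()
        assert len(out1) == 3

    def test_empty_corpus(self, mayo):
        assert len(label_corpus(Corpus([]), mayo)) == 0
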