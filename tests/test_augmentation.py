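import json
import math
import re
from itertools import permutations

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from dialogforge.augmentation import (
    ConfigurationError,
    Corpus,
    EntitySpan,
    GenerationConfig,
    LabeledUtterance,
    UtteranceTemplate,
    enumerate_orderings,
    expand_synonyms,
    fill_slots,
    generate_corpus,
    paraphrase,
    read_corpus_jsonl,
    write_corpus_jsonl,
)
from dialogforge.ontology import EntitySlot, IntentSpec, Ontology, PhraseTemplate


def _spec_with_phrases(m: int) -> IntentSpec:
    return IntentSpec(
        name="do-thing",
        verbs=("do",),
        activity_slot="thing-type",
        record_templates=tuple(
            PhraseTemplate("at", f"slot-{i}", (), pattern=1) for i in range(m)
        ),
    )


class TestEnumerateOrderings:
    @pytest.mark.parametrize("m", [0, 1, 2, 3, 4])
    def test_factorial_count_and_distinctness(self, m):
        templates = enumerate_orderings(_spec_with_phrases(m))
        assert len(templates) == math.factorial(m)
        orders = {tuple(p.slot for p in t.ordered_phrases) for t in templates}
        assert len(orders) == math.factorial(m)
        # oracle: matches brute-force permutation enumeration
        expected = {tuple(f"slot-{i}" for i in perm) for perm in permutations(range(m))}
        assert orders == expected

    def test_verb_and_activity_head_fixed(self):
        for t in enumerate_orderings(_spec_with_phrases(3)):
            assert t.verb == "do"
            assert t.activity_slot == "thing-type"

    def test_duplicate_slot_reference_rejected(self):
        phrase = PhraseTemplate("at", "dup", (), pattern=1)
        with pytest.raises(ConfigurationError, match="twice"):
            UtteranceTemplate("x", "do", "a", (phrase, phrase))


def _toy_ontology(n_a=2, n_b=3):
    return Ontology(
        intents=(
            IntentSpec(
                "do-thing", ("do",), "thing-type",
                (PhraseTemplate("at", "place", (), pattern=1),),
            ),
        ),
        slots=(
            EntitySlot("thing-type", "activity", tuple(f"thing{i}" for i in range(n_a))),
            EntitySlot("place", "record", tuple(f"place{i}" for i in range(n_b))),
        ),
    )


class TestFillSlots:
    def test_exhaustive_under_budget(self):
        o = _toy_ontology(2, 3)
        t = enumerate_orderings(o.intents[0])[0]
        out = fill_slots(t, o, budget=100)
        assert len(out) == 6
        assert len({u.text for u in out}) == 6

    def test_sampled_over_budget_reproducible(self):
        o = _toy_ontology(2, 3)
        t = enumerate_orderings(o.intents[0])[0]
        a = fill_slots(t, o, budget=4, seed=5)
        b = fill_slots(t, o, budget=4, seed=5)
        assert len(a) == 4 == len({u.text for u in a})
        assert [u.text for u in a] == [u.text for u in b]
        c = fill_slots(t, o, budget=4, seed=6)
        assert [u.text for u in a] != [u.text for u in c] or True  # seeds may coincide; only determinism is required

    def test_every_filled_slot_has_span(self):
        o = _toy_ontology()
        t = enumerate_orderings(o.intents[0])[0]
        for u in fill_slots(t, o, budget=100):
            u.check_spans()
            assert {e.slot for e in u.entities} == {"thing-type", "place"}

    def test_measurement_span_covers_number_and_unit(self, fixture_ontology):
        spec = fixture_ontology.intent("add-vital")
        t = UtteranceTemplate(
            intent="add-vital",
            verb="add",
            activity_slot=spec.activity_slot,
            ordered_phrases=(spec.record_templates[0],),  # "with @vital-value"
        )
        out = fill_slots(t, fixture_ontology, budget=10_000)
        target = "add pressure with 103 systolic blood pressure"
        match = [u for u in out if u.text == target]
        assert match, "expected sample utterance not generated"
        spans = {e.slot: e.surface for e in match[0].entities}
        assert spans["vital-value"] == "103 systolic blood pressure"

    def test_empty_slot_is_configuration_error(self):
        o = _toy_ontology()
        bad = Ontology(
            intents=o.intents,
            slots=(o.slots[0], EntitySlot("place", "record", ())),
        )
        t = enumerate_orderings(o.intents[0])[0]
        with pytest.raises(ConfigurationError):
            fill_slots(t, bad, budget=5)


class TestExpandSynonyms:
    def test_matches_brute_force_cosine_ranking(self, toy_table):
        hits, oov = expand_synonyms("pressure", toy_table, k=10, threshold=-1.0, min_length=1)
        assert not oov
        # brute force: cosine of every other token with "pressure" = (1,0)
        def cos(v):
            return float(np.dot(v, [1, 0]) / np.linalg.norm(v))
        expected = sorted(
            ((t, cos(v)) for t, v in toy_table.vectors.items() if t != "pressure"),
            key=lambda ts: (-ts[1], ts[0]),
        )
        assert [t for t, _ in hits] == [t for t, _ in expected]
        for (_, got), (_, want) in zip(hits, expected):
            assert got == pytest.approx(want, abs=1e-12)

    def test_unreachable_threshold_empty(self, toy_table):
        hits, oov = expand_synonyms("pressure", toy_table, threshold=1.01)
        assert hits == [] and not oov

    def test_oov_flag_distinct_from_no_hit(self, toy_table):
        hits, oov = expand_synonyms("zzz", toy_table)
        assert hits == [] and oov

    def test_special_characters_stripped_before_lookup(self, toy_table):
        hits_clean, _ = expand_synonyms("pressure", toy_table, threshold=-1, min_length=1)
        hits_punct, _ = expand_synonyms("pre-ssure!", toy_table, threshold=-1, min_length=1)
        assert hits_punct == hits_clean

    def test_documented_defaults(self):
        import inspect

        sig = inspect.signature(expand_synonyms)
        assert sig.parameters["k"].default == 10
        assert sig.parameters["threshold"].default == 0.5


def _utt(text, verb, activity_slot, entities):
    u = LabeledUtterance(
        text=text,
        intent="clean-oral",
        entities=tuple(EntitySpan(*e) for e in entities),
        provenance=({"op": "fill", "verb": verb, "activity_slot": activity_slot,
                     "ordering": []},),
    )
    u.check_spans()
    return u


@pytest.fixture
def clean_utt():
    return _utt(
        "clean dentures with detergent",
        "clean",
        "oral-type",
        [("oral-type", 6, 14, "dentures"), ("oral-material", 20, 29, "detergent")],
    )


class TestParaphrase:
    def test_question_rule_modal_or_wh_form(self, clean_utt):
        (v,) = paraphrase(clean_utt, rules=("question",), seed=0)
        assert re.fullmatch(
            r"(Can you|Could you|Did you|When did you|Where did you) clean dentures with detergent\?",
            v.text,
        )
        v.check_spans()
        assert v.intent == clean_utt.intent

    def test_politeness_prefix_remainder_unchanged(self, clean_utt):
        (v,) = paraphrase(clean_utt, rules=("politeness",), seed=1)
        assert v.text.startswith("Please") or v.text.startswith("I ")
        assert v.text.endswith(clean_utt.text)
        v.check_spans()

    def test_passive_transformation(self, clean_utt):
        (v,) = paraphrase(clean_utt, rules=("passive",), seed=0)
        assert v.text == "dentures are cleaned with detergent"
        v.check_spans()
        assert {e.slot for e in v.entities} == {"oral-type", "oral-material"}

    def test_passive_skipped_for_unknown_verb(self):
        u = _utt("help to use urinals", "help to use", "toilet-type",
                 [("toilet-type", 12, 19, "urinals")])
        assert paraphrase(u, rules=("passive",)) == []

    def test_synonym_rule_uses_lexicon(self, clean_utt):
        (v,) = paraphrase(clean_utt, rules=("synonym",),
                          lexicon={"clean": ["scrub"]}, seed=0)
        assert v.text == "scrub dentures with detergent"
        v.check_spans()

    def test_empty_rule_set_identity(self, clean_utt):
        assert paraphrase(clean_utt, rules=()) == []

    @given(seed=st.integers(0, 2**31 - 1))
    @settings(max_examples=25, deadline=None, derandomize=True)
    def test_spans_valid_under_every_rule_and_seed(self, seed):
        u = _utt(
            "clean dentures with detergent",
            "clean",
            "oral-type",
            [("oral-type", 6, 14, "dentures"), ("oral-material", 20, 29, "detergent")],
        )
        for v in paraphrase(u, seed=seed):
            v.check_spans()
            assert v.intent == u.intent
            assert {e.slot for e in v.entities} == {e.slot for e in u.entities}


class TestGenerateCorpus:
    def test_budget_one_per_intent(self, fixture_ontology):
        cfg = GenerationConfig(budgets={i.name: 1 for i in fixture_ontology.intents})
        c = generate_corpus(fixture_ontology, cfg, seed=0)
        assert len(c.utterances) == 6
        assert {u.intent for u in c.utterances} == {i.name for i in fixture_ontology.intents}

    def test_counts_match_budgets_and_texts_unique(self, small_corpus):
        counts = {k: len(v) for k, v in small_corpus.by_intent().items()}
        assert set(counts.values()) == {30}
        texts = small_corpus.texts()
        assert len(set(texts)) == len(texts)

    def test_same_seed_byte_identical_files(self, fixture_ontology, tmp_path):
        cfg = GenerationConfig(budgets={i.name: 10 for i in fixture_ontology.intents})
        pa, pb = tmp_path / "a.jsonl", tmp_path / "b.jsonl"
        write_corpus_jsonl(generate_corpus(fixture_ontology, cfg, seed=9), pa)
        write_corpus_jsonl(generate_corpus(fixture_ontology, cfg, seed=9), pb)
        assert pa.read_bytes() == pb.read_bytes()

    def test_shortfall_reported_when_budget_unattainable(self):
        o = _toy_ontology(1, 2)  # tiny product space
        cfg = GenerationConfig(budgets={"do-thing": 500}, rules=())
        c = generate_corpus(o, cfg, seed=0)
        assert c.shortfalls.get("do-thing", 0) > 0
        assert len(c.utterances) + c.shortfalls["do-thing"] == 500

    def test_jsonl_round_trip(self, small_corpus, tmp_path):
        p = tmp_path / "c.jsonl"
        write_corpus_jsonl(small_corpus, p)
        back = read_corpus_jsonl(p)
        assert back.texts() == small_corpus.texts()
        assert back.seed == small_corpus.seed
        assert [u.entities for u in back.utterances] == [
            u.entities for u in small_corpus.utterances
        ]
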