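"""Bigram language model and the new/redundant sentence decision."""

from __future__ import annotations

import random

import pytest

from notediff.concepts import (
    ConceptLexicon,
    SimilarityBackend,
    Taxonomy,
    compute_ic,
)
from notediff.corpus import NoteGroup, Sentence
from notediff.novelty import (
    UNK,
    BigramModel,
    DetectorParams,
    PipelineConfig,
    bigram_is_new,
    bigram_probability,
    build_bigram_model,
    classify_sentence,
    process_note_sequence,
)
from notediff.preprocess import Token, TokenSequence

from conftest import make_note, seq


def sent_seq(tokens, concepts=None, note_id="n", index=0):
    s = Sentence(note_id=note_id, index=index, span=(0, 5), text="x" * 5)
    ts = seq(tokens, concepts)
    ts.sentence = s
    return ts


def oracle_probability(sentences, w1, w2):
    """Independent count-and-divide Laplace oracle.

    Counts occurrences and within-sentence pairs (plus the documented
    end-of-sentence continuation to UNK) with plain loops.
    """
    unigrams: dict[str, int] = {}
    bigrams: dict[tuple[str, str], int] = {}
    vocab = {UNK}
    for tokens in sentences:
        if not tokens:
            continue
        vocab.update(tokens)
        for t in tokens:
            unigrams[t] = unigrams.get(t, 0) + 1
        pairs = list(zip(tokens, tokens[1:])) + [(tokens[-1], UNK)]
        for p in pairs:
            bigrams[p] = bigrams.get(p, 0) + 1
    if w1 not in vocab:
        w1 = UNK
    if w2 not in vocab:
        w2 = UNK
    return (bigrams.get((w1, w2), 0) + 1) / (unigrams.get(w1, 0) + len(vocab))


class TestBigramModel:
    def test_hand_counts(self):
        model = build_bigram_model([seq("a b c"), seq("a b")])
        assert model.bigram_counts[("a", "b")] == 2
        assert model.bigram_counts[("b", "c")] == 1
        assert dict(model.unigram_counts) == {"a": 2, "b": 2, "c": 1}
        assert model.vocab == {"a", "b", "c", UNK}

    def test_hand_probabilities(self):
        model = build_bigram_model([seq("a b c"), seq("a b")])
        assert bigram_probability(model, "a", "b") == pytest.approx(3 / 6)
        assert bigram_probability(model, "c", "a") == pytest.approx(1 / 5)

    def test_empty_history(self):
        model = build_bigram_model([])
        assert model.vocab == {UNK}
        assert bigram_probability(model, "x", "y") == 1.0

    def test_order_invariance(self):
        sentences = [seq("a b c"), seq("c a"), seq("b b a")]
        m1 = build_bigram_model(list(sentences))
        m2 = build_bigram_model(list(reversed(sentences)))
        assert m1.bigram_counts == m2.bigram_counts
        assert m1.unigram_counts == m2.unigram_counts

    @pytest.mark.parametrize("trial", range(20))
    def test_matches_count_and_divide_oracle(self, trial):
        rng = random.Random(42 + trial)
        alphabet = "abcdefgh"
        sentences = [
            [rng.choice(alphabet) for _ in range(rng.randrange(1, 8))]
            for _ in range(rng.randrange(1, 20))
        ]
        model = build_bigram_model([seq(s) for s in sentences])
        queries = [(rng.choice(alphabet + "zq"), rng.choice(alphabet + "zq")) for _ in range(30)]
        for w1, w2 in queries:
            assert bigram_probability(model, w1, w2) == oracle_probability(
                sentences, w1, w2
            )

    @pytest.mark.parametrize("trial", range(10))
    def test_laplace_conditionals_sum_to_one(self, trial):
        rng = random.Random(900 + trial)
        sentences = [
            [rng.choice("abcde") for _ in range(rng.randrange(1, 6))]
            for _ in range(rng.randrange(0, 12))
        ]
        model = build_bigram_model([seq(s) for s in sentences])
        for w1 in model.vocab:
            total = sum(bigram_probability(model, w1, w2) for w2 in model.vocab)
            assert total == pytest.approx(1.0, abs=1e-9)

    def test_incremental_update_equals_rebuild(self):
        notes = [[seq("a b c")], [seq("b c d")], [seq("a d")]]
        incremental = BigramModel()
        for i, sentences in enumerate(notes):
            incremental.update(sentences, note_id=f"n{i}")
        rebuilt = build_bigram_model(notes, note_ids=["n0", "n1", "n2"])
        assert incremental.bigram_counts == rebuilt.bigram_counts
        assert incremental.unigram_counts == rebuilt.unigram_counts
        assert incremental.history_note_ids == rebuilt.history_note_ids


@pytest.fixture
def heart_fixture():
    """Taxonomy with 'heart' and 'cardiac' concepts close under lin."""
    tax = Taxonomy(
        [
            ("Cheart", "Cheartgrp"),
            ("Ccardiac", "Cheartgrp"),
            ("Cheartgrp", "Corgan"),
            ("Clung", "Corgan"),
            ("Corgan", "R"),
        ]
    )
    ic = compute_ic(tax, {"Cheart": 1, "Ccardiac": 1, "Clung": 20})
    backend = SimilarityBackend(tax, ic, "lin")
    return tax, ic, backend


class TestBigramIsNew:
    def test_seen_bigram_is_not_new(self):
        model = build_bigram_model([seq("pain is better")])
        params = DetectorParams(prob_threshold=0.2)
        assert not bigram_is_new(model, "pain", "is", params=params)

    def test_unseen_bigram_is_new_without_similarity(self):
        model = build_bigram_model([seq("pain is better")])
        params = DetectorParams(prob_threshold=0.3)
        assert bigram_is_new(model, "cardiac", "pain", params=params)

    def test_semantic_substitution_recovers_paraphrase(self, heart_fixture):
        _, _, backend = heart_fixture
        history = [seq("heart arrest noted", {"heart": "Cheart"})]
        model = build_bigram_model(history)
        sim = backend.score("Cheart", "Ccardiac")
        assert sim >= 0.5
        params = DetectorParams(
            prob_threshold=0.3, sim_measure="lin", sim_threshold=sim
        )
        assert not bigram_is_new(
            model, "cardiac", "arrest", ("Ccardiac", None), backend, params
        )

    def test_strict_threshold_reduces_to_baseline(self, heart_fixture):
        tax, ic, backend = heart_fixture
        history = [seq("heart arrest noted", {"heart": "Cheart"})]
        model = build_bigram_model(history)
        theta = backend.max_distinct_similarity()
        assert theta < 1.0
        params_sim = DetectorParams(
            prob_threshold=0.3, sim_measure="lin", sim_threshold=min(1.0, theta + 1e-9)
        )
        params_none = DetectorParams(prob_threshold=0.3)
        for w1, w2, c in [
            ("cardiac", "arrest", ("Ccardiac", None)),
            ("lung", "arrest", ("Clung", None)),
            ("heart", "arrest", ("Cheart", None)),
        ]:
            assert bigram_is_new(model, w1, w2, c, backend, params_sim) == bigram_is_new(
                model, w1, w2, c, None, params_none
            )


class TestClassifySentence:
    def test_all_seen_is_redundant(self):
        model = build_bigram_model([seq("a b c d e")] * 3)
        verdict = classify_sentence(model, sent_seq("a b c d e"))
        assert not verdict.new

    def test_all_unseen_is_new(self):
        model = build_bigram_model([seq("a b c")])
        verdict = classify_sentence(model, sent_seq("x y z"))
        assert verdict.new

    def test_fraction_thresholds(self):
        # history "a b c d e"; target "a b x c d": 2 of 4 bigrams new
        model = build_bigram_model([seq("a b c d e")])
        target = sent_seq("a b x c d")
        v_50 = classify_sentence(
            model, target, params=DetectorParams(sentence_fraction=0.5)
        )
        v_60 = classify_sentence(
            model, target, params=DetectorParams(sentence_fraction=0.6)
        )
        assert v_50.new_fraction == pytest.approx(0.5)
        assert v_50.new
        assert not v_60.new

    def test_short_sentence_rule(self):
        model = build_bigram_model([seq("a b c")])
        assert not classify_sentence(model, sent_seq("a")).new
        assert classify_sentence(model, sent_seq("z")).new
        assert not classify_sentence(model, sent_seq([])).new

    def test_final_label_consistency(self):
        model = build_bigram_model([seq("a b c")])
        v = classify_sentence(model, sent_seq("x y"), relevance="irrelevant")
        assert v.new and v.final_label == "irrelevant_new"
        v2 = classify_sentence(model, sent_seq("a b"))
        assert not v2.new and v2.final_label == "redundant"


class TestProcessNoteSequence:
    def _group(self, texts, setting="inpatient"):
        notes = [
            make_note(f"n{i}", text=t, day=i + 1, setting=setting)
            for i, t in enumerate(texts)
        ]
        return NoteGroup(group_id="g", notes=notes, grouping="inpatient_encounter")

    def test_single_note_group_has_no_verdicts(self):
        group = self._group(["Pt stable today."])
        verdicts = process_note_sequence(group)
        assert verdicts == {"n0": []}

    def test_duplicate_note_fully_redundant(self):
        text = "Pt stable today.\nContinue current meds."
        group = self._group([text, text])
        verdicts = process_note_sequence(group)
        assert verdicts["n0"] == []
        assert all(not v.new for v in verdicts["n1"])

    def test_model_uses_all_prior_notes(self):
        # note 3 copies note 1: still redundant (history pools all priors)
        a = "Alpha bravo charlie delta."
        b = "Echo foxtrot golf hotel."
        group = self._group([a, b, a])
        verdicts = process_note_sequence(group)
        assert all(not v.new for v in verdicts["n2"])

    def test_disjoint_vocabulary_all_new(self):
        group = self._group(
            ["Alpha bravo charlie delta.", "Echo foxtrot golf hotel."]
        )
        verdicts = process_note_sequence(group)
        assert all(v.new for v in verdicts["n1"])
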