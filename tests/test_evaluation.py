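"""Detection metrics, agreement statistics, and threshold tuning."""

from __future__ import annotations

import random
from math import comb

import numpy as np
import pytest

from notediff.concepts import SimilarityBackend, compute_ic
from notediff.corpus import AnnotationSet, Sentence
from notediff.evaluation import (
    DEFAULT_SIM_GRID,
    EvalResult,
    fleiss_kappa,
    panel_table,
    percent_agreement,
    sentence_prf,
    tune_similarity_threshold,
)
from notediff.novelty import DetectorParams, PipelineConfig, SentenceVerdict, process_note_sequence
from notediff.synthetic import (
    GeneratorParams,
    generate_note_sequence,
    generate_rater_panel,
    generate_taxonomy_and_lexicon,
)


def verdict(note_id, start, end, new=True, relevance="relevant"):
    s = Sentence(note_id=note_id, index=0, span=(start, end), text="x" * (end - start))
    return SentenceVerdict(sentence=s, bigram_probs=[], new=new, relevance=relevance)


def gold_set(labels):
    gold = AnnotationSet("gold")
    for note_id, span, label in labels:
        gold.add(note_id, span, label)
    return gold


class TestSentencePRF:
    def test_exact_match_is_perfect(self):
        predicted = {"n1": [verdict("n1", 0, 10), verdict("n1", 11, 20, new=False)]}
        gold = gold_set([("n1", (0, 10), "new"), ("n1", (11, 20), "redundant")])
        r = sentence_prf(predicted, gold)
        assert (r.precision, r.recall, r.f1) == (1.0, 1.0, 1.0)

    def test_no_predictions_gives_zero_by_convention(self):
        predicted = {"n1": [verdict("n1", 0, 10, new=False)]}
        gold = gold_set([("n1", (0, 10), "new")])
        r = sentence_prf(predicted, gold)
        assert (r.precision, r.recall, r.f1) == (0.0, 0.0, 0.0)

    def test_counts_follow_definitions(self):
        predicted = {"n1": []}
        gold_labels = []
        # 7 true positives, 3 false positives, 3 false negatives
        for i in range(7):
            predicted["n1"].append(verdict("n1", i * 30, i * 30 + 10))
            gold_labels.append(("n1", (i * 30, i * 30 + 10), "new"))
        for i in range(7, 10):
            predicted["n1"].append(verdict("n1", i * 30, i * 30 + 10))
        for i in range(10, 13):
            gold_labels.append(("n1", (i * 30, i * 30 + 10), "new"))
        r = sentence_prf(predicted, gold_set(gold_labels))
        assert (r.true_positives, r.false_positives, r.false_negatives) == (7, 3, 3)
        assert r.precision == pytest.approx(0.7)
        assert r.recall == pytest.approx(0.7)
        assert r.f1 == pytest.approx(0.7)

    def test_overlap_rule_majority_of_shorter_span(self):
        # predicted [0,10) vs gold [4,20): overlap 6 > 10/2 -> match
        predicted = {"n1": [verdict("n1", 0, 10)]}
        assert sentence_prf(predicted, gold_set([("n1", (4, 20), "new")])).f1 == 1.0
        # predicted [0,10) vs gold [5,25): overlap 5, not > 5 -> no match
        r = sentence_prf(predicted, gold_set([("n1", (5, 25), "new")]))
        assert r.true_positives == 0

    def test_exact_span_mode(self):
        predicted = {"n1": [verdict("n1", 0, 10)]}
        gold = gold_set([("n1", (0, 11), "new")])
        assert sentence_prf(predicted, gold).true_positives == 1
        assert sentence_prf(predicted, gold, exact_spans=True).true_positives == 0

    def test_irrelevant_new_not_a_positive_in_relevant_mode(self):
        predicted = {"n1": [verdict("n1", 0, 10, relevance="irrelevant")]}
        gold = gold_set([("n1", (0, 10), "new")])
        assert sentence_prf(predicted, gold, relevant_only=True).true_positives == 0
        assert sentence_prf(predicted, gold, relevant_only=False).true_positives == 1

    def test_unknown_note_in_gold_is_an_error(self):
        predicted = {"n1": [verdict("n1", 0, 10)]}
        gold = gold_set([("n2", (0, 10), "new")])
        with pytest.raises(ValueError, match="n2"):
            sentence_prf(predicted, gold, known_notes=["n1"])


def oracle_fleiss(table):
    """Textbook P-bar / P-bar-e computation."""
    table = np.asarray(table, dtype=float)
    n_items, _ = table.shape
    n_raters = table[0].sum()
    p_i = (np.sum(table * (table - 1), axis=1)) / (n_raters * (n_raters - 1))
    p_bar = p_i.mean()
    p_j = table.sum(axis=0) / (n_items * n_raters)
    p_bar_e = np.sum(p_j**2)
    if p_bar_e == 1.0:
        return 1.0
    return (p_bar - p_bar_e) / (1 - p_bar_e)


class TestFleissKappa:
    def test_perfect_agreement(self):
        table = [[4, 0], [0, 4], [4, 0]]
        assert fleiss_kappa(table, 4) == 1.0

    def test_balanced_perfect_disagreement(self):
        # 2 items, 2 raters, always split
        table = [[1, 1], [1, 1]]
        assert fleiss_kappa(table, 2) == pytest.approx(oracle_fleiss(table))
        assert fleiss_kappa(table, 2) == pytest.approx(-1.0)

    @pytest.mark.parametrize("trial", range(20))
    def test_matches_brute_force_oracle(self, trial):
        rng = random.Random(1000 + trial)
        n_raters = rng.randrange(2, 6)
        table = []
        for _ in range(20):
            a = rng.randrange(0, n_raters + 1)
            table.append([a, n_raters - a])
        assert fleiss_kappa(table, n_raters) == pytest.approx(
            oracle_fleiss(table), abs=1e-12
        )

    def test_invariant_to_category_relabeling(self):
        rng = random.Random(7)
        table = [[a, 4 - a] for a in (rng.randrange(5) for _ in range(15))]
        swapped = [[b, a] for a, b in table]
        assert fleiss_kappa(table, 4) == pytest.approx(fleiss_kappa(swapped, 4))

    def test_row_sum_mismatch_is_an_error(self):
        with pytest.raises(ValueError, match="sum"):
            fleiss_kappa([[2, 1], [2, 2]], 4)


class TestPercentAgreement:
    def test_perfect(self):
        assert percent_agreement([[3, 0], [0, 3]], 3) == 1.0

    def test_two_raters_always_disagreeing(self):
        assert percent_agreement([[1, 1], [1, 1]], 2) == 0.0

    def test_three_one_split(self):
        # pairs agreeing: C(3,2) + C(1,2) = 3 of C(4,2) = 6
        assert percent_agreement([[3, 1]], 4) == pytest.approx(0.5)
        assert (comb(3, 2) + comb(1, 2)) / comb(4, 2) == 0.5


class TestPanelTable:
    def test_counts_by_unit(self):
        params = GeneratorParams(seed=5, n_notes=4, sentences_per_note=5)
        _, gold, _ = generate_note_sequence(params)
        panel = generate_rater_panel(gold, n_raters=3, flip_prob=0.2, seed=9)
        table = panel_table(panel)
        assert table.shape == (len(gold.labels), 2)
        assert (table.sum(axis=1) == 3).all()

    def test_incomplete_panel_rejected(self):
        a = AnnotationSet("r1")
        a.add("n1", (0, 5), "new")
        b = AnnotationSet("r2")
        b.add("n1", (0, 5), "new")
        b.add("n1", (6, 9), "new")
        with pytest.raises(ValueError, match="r2"):
            panel_table([a, b])


class TestTuneSimilarityThreshold:
    def test_default_grid_has_six_values(self):
        assert DEFAULT_SIM_GRID == (0.5, 0.6, 0.7, 0.8, 0.9, 1.0)

    def _setup(self, mode="synonym"):
        params = GeneratorParams(
            seed=11,
            n_notes=8,
            sentences_per_note=8,
            copy_rate=0.2,
            paraphrase_rate=0.4,
            synonym_fraction=1.0,
            taxonomy_size=12,
            paraphrase_mode=mode,
        )
        tax, lex, counts = generate_taxonomy_and_lexicon(params)
        group, gold, _ = generate_note_sequence(params, (tax, lex, counts))
        ic = compute_ic(tax, counts)
        cfg = PipelineConfig(
            lexicon=lex, sim_backend=SimilarityBackend(tax, ic, "lin")
        )
        return group, gold, cfg

    def test_equals_exhaustive_argmax(self):
        group, gold, cfg = self._setup(mode="sibling")
        best, results = tune_similarity_threshold([group], gold, "lin", cfg)
        # independent exhaustive loop over the grid
        from dataclasses import replace

        exhaustive = {}
        for theta in DEFAULT_SIM_GRID:
            params = replace(cfg.params, sim_measure="lin", sim_threshold=theta)
            predicted = process_note_sequence([g for g in [group]][0], replace(cfg, params=params))
            exhaustive[theta] = sentence_prf(predicted, gold)
        expected = max(exhaustive, key=lambda t: (exhaustive[t].f1, t))
        assert best == expected
        for theta in DEFAULT_SIM_GRID:
            assert results[theta].f1 == pytest.approx(exhaustive[theta].f1)

    def test_all_tie_returns_largest(self):
        # one non-root concept with two synonym terms: the only concept
        # pair has similarity exactly 1, so every grid threshold behaves
        # identically and the tie rule must pick 1.0
        params = GeneratorParams(
            seed=13,
            n_notes=6,
            sentences_per_note=6,
            copy_rate=0.2,
            paraphrase_rate=0.4,
            synonym_fraction=1.0,
            taxonomy_size=2,
        )
        tax, lex, counts = generate_taxonomy_and_lexicon(params)
        group, gold, _ = generate_note_sequence(params, (tax, lex, counts))
        ic = compute_ic(tax, counts)
        cfg = PipelineConfig(lexicon=lex, sim_backend=SimilarityBackend(tax, ic, "lin"))
        best, results = tune_similarity_threshold([group], gold, "lin", cfg)
        assert len({(r.true_positives, r.false_positives, r.false_negatives) for r in results.values()}) == 1
        assert best == 1.0

    def test_empty_training_set_is_an_error(self):
        _, gold, cfg = self._setup()
        with pytest.raises(ValueError):
            tune_similarity_threshold([], gold, "lin", cfg)
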