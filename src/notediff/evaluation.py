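"""Sentence-level evaluation, inter-rater agreement, and threshold tuning.

Detection metrics compare the detector's per-sentence verdicts with a
gold annotation set in standoff form.  A predicted sentence and a gold
span "match" when they belong to the same note and overlap by more than
half of the shorter span (exact-span mode is available), absorbing
small disagreements between automatic segmentation and annotated
statements.

Agreement statistics operate on an items x categories count table (one
row per annotated unit, columns new/redundant, entries summing to the
number of raters).  Fleiss' kappa is delegated to statsmodels with the
perfect-agreement corner (chance agreement 1) pinned to 1.0.
"""

from __future__ import annotations

from dataclasses import dataclass
from math import comb
from typing import Iterable, Mapping, Sequence

import numpy as np
from statsmodels.stats.inter_rater import fleiss_kappa as _sm_fleiss_kappa

from .corpus import AnnotationSet, NoteGroup
from .novelty import PipelineConfig, SentenceVerdict, process_note_sequence

__all__ = [
    "EvalResult",
    "sentence_prf",
    "fleiss_kappa",
    "percent_agreement",
    "panel_table",
    "tune_similarity_threshold",
    "DEFAULT_SIM_GRID",
]

DEFAULT_SIM_GRID = (0.5, 0.6, 0.7, 0.8, 0.9, 1.0)


@dataclass(frozen=True)
class EvalResult:
    true_positives: int
    false_positives: int
    false_negatives: int
    threshold_used: float | None = None

    @property
    def precision(self) -> float:
        denom = self.true_positives + self.false_positives
        return self.true_positives / denom if denom else 0.0

    @property
    def recall(self) -> float:
        denom = self.true_positives + self.false_negatives
        return self.true_positives / denom if denom else 0.0

    @property
    def f1(self) -> float:
        p, r = self.precision, self.recall
        return 2 * p * r / (p + r) if (p + r) else 0.0


def _spans_overlap(
    a: tuple[int, int], b: tuple[int, int], exact: bool
) -> bool:
    if exact:
        return a == b
    overlap = min(a[1], b[1]) - max(a[0], b[0])
    shorter = min(a[1] - a[0], b[1] - b[0])
    return overlap * 2 > shorter  # > 50% of the shorter span


def sentence_prf(
    predicted: Mapping[str, Sequence[SentenceVerdict]],
    gold: AnnotationSet,
    positive_class: str = "new",
    relevant_only: bool = True,
    exact_spans: bool = False,
    known_notes: Iterable[str] | None = None,
) -> EvalResult:
    """Sentence-level precision/recall/F1 against one gold set.

    ``positive_class`` selects which label counts as a positive: "new"
    scores new-information detection (a predicted-new sentence is a true
    positive when it matches a gold "new" span); "redundant" scores
    redundancy detection symmetrically.  With ``relevant_only`` (and
    positive class "new") only sentences the relevance rules deem
    relevant count as predicted positives, matching gold standards that
    capture *clinically relevant* new information.
    """
    if positive_class not in ("new", "redundant"):
        raise ValueError("positive_class must be 'new' or 'redundant'")
    if known_notes is not None:
        known = set(known_notes)
        unknown = {nid for nid, _ in gold.labels} - known
        if unknown:
            raise ValueError(f"gold references unknown notes: {sorted(unknown)}")

    gold_positive: dict[str, list[tuple[int, int]]] = {}
    for (note_id, span), label in gold.labels.items():
        if label == positive_class:
            gold_positive.setdefault(note_id, []).append(span)

    tp = fp = 0
    matched: set[tuple[str, tuple[int, int]]] = set()
    for note_id, verdicts in predicted.items():
        for verdict in verdicts:
            if positive_class == "new":
                is_positive = verdict.new and (
                    not relevant_only or verdict.relevance == "relevant"
                )
            else:
                is_positive = not verdict.new
            if not is_positive:
                continue
            hit = None
            for span in gold_positive.get(note_id, ()):
                if _spans_overlap(verdict.sentence.span, span, exact_spans):
                    hit = span
                    break
            if hit is None:
                fp += 1
            else:
                tp += 1
                matched.add((note_id, hit))
    fn = sum(
        1
        for note_id, spans in gold_positive.items()
        for span in spans
        if (note_id, span) not in matched
    )
    return EvalResult(true_positives=tp, false_positives=fp, false_negatives=fn)


def _validate_table(table: np.ndarray, n_raters: int) -> np.ndarray:
    table = np.asarray(table, dtype=float)
    if table.ndim != 2 or table.shape[1] < 2:
        raise ValueError("table must be items x categories with >= 2 categories")
    if not np.all(table.sum(axis=1) == n_raters):
        raise ValueError(f"every row must sum to n_raters={n_raters}")
    return table


def fleiss_kappa(table: Sequence[Sequence[int]], n_raters: int) -> float:
    """Fleiss' kappa for a fixed rater panel; in [-1, 1].

    Exactly 1.0 under perfect agreement (where the chance-corrected
    ratio is otherwise indeterminate).
    """
    table = _validate_table(np.asarray(table), n_raters)
    p_bar = float(
        np.mean(
            (np.sum(table * (table - 1), axis=1))
            / (n_raters * (n_raters - 1))
        )
    )
    if p_bar == 1.0:
        return 1.0
    return float(_sm_fleiss_kappa(table, method="fleiss"))


def percent_agreement(table: Sequence[Sequence[int]], n_raters: int) -> float:
    """Mean over items of the proportion of agreeing rater pairs."""
    table = _validate_table(np.asarray(table), n_raters)
    pair_total = comb(n_raters, 2)
    agree = [
        sum(comb(int(c), 2) for c in row) / pair_total for row in table
    ]
    return float(np.mean(agree))


def panel_table(
    sets: Sequence[AnnotationSet], categories: Sequence[str] = ("new", "redundant")
) -> np.ndarray:
    """Items x categories count table for a complete rater panel.

    Every rater must label the identical set of (note, span) units.
    """
    if not sets:
        raise ValueError("empty rater panel")
    units = sorted(sets[0].labels.keys())
    for aset in sets[1:]:
        if sorted(aset.labels.keys()) != units:
            raise ValueError(
                f"rater {aset.rater_id!r} labels a different unit set"
            )
    index = {cat: j for j, cat in enumerate(categories)}
    table = np.zeros((len(units), len(categories)), dtype=int)
    for aset in sets:
        for i, unit in enumerate(units):
            table[i, index[aset.labels[unit]]] += 1
    return table


def tune_similarity_threshold(
    train_groups: Sequence[NoteGroup],
    gold: AnnotationSet,
    measure: str,
    config: PipelineConfig,
    grid: Sequence[float] = DEFAULT_SIM_GRID,
    positive_class: str = "new",
    relevant_only: bool = True,
) -> tuple[float, dict[float, EvalResult]]:
    """Grid-search the similarity threshold maximizing F1 on a training set.

    Runs the full detection pipeline per candidate threshold and
    returns the argmax-F1 threshold (ties resolved toward the larger
    threshold, i.e. closer to baseline behavior) plus every
    per-threshold result.
    """
    if not grid:
        raise ValueError("empty threshold grid")
    if not train_groups:
        raise ValueError("empty training set")
    from dataclasses import replace

    results: dict[float, EvalResult] = {}
    for theta in grid:
        params = replace(config.params, sim_measure=measure, sim_threshold=theta)
        cfg = replace(config, params=params)
        predicted: dict[str, list[SentenceVerdict]] = {}
        for group in train_groups:
            predicted.update(process_note_sequence(group, cfg))
        res = sentence_prf(
            predicted,
            gold,
            positive_class=positive_class,
            relevant_only=relevant_only,
        )
        results[theta] = EvalResult(
            res.true_positives,
            res.false_positives,
            res.false_negatives,
            threshold_used=theta,
        )
    best = max(results, key=lambda t: (results[t].f1, t))
    return best, results
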