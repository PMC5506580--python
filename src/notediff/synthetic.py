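"""Synthetic taxonomies, lexicons, and longitudinal note sequences.

The generator emulates the structure that makes longitudinal clinical
notes hard to read: each new note mixes verbatim copy/paste of earlier
sentences, paraphrases in which one clinical term is swapped for a
synonym or taxonomy sibling, and genuinely fresh content, under
controlled rates with exact per-sentence ground-truth labels.  Notes
carry a header line, body sentences (including occasional vital-sign
statements, so relevance rules are exercised), and a signature line.

All randomness flows through one numpy PCG64 generator seeded from
``GeneratorParams.seed``, so outputs are bit-reproducible per seed.
The generator writes the same JSON-lines/TSV formats the readers
consume.  It produces token shapes (``c012ax``, ``w00042x``) that are
stable under the package normalizer — synthetic vocabulary, not
clinical language.
"""

from __future__ import annotations

from dataclasses import dataclass
from datetime import datetime, timedelta
from typing import Mapping, Sequence

import numpy as np

from .concepts import ConceptLexicon, Taxonomy
from .corpus import AnnotationSet, ClinicalNote, NoteGroup

__all__ = [
    "GeneratorParams",
    "generate_taxonomy_and_lexicon",
    "generate_note_sequence",
    "generate_rater_panel",
]


@dataclass
class GeneratorParams:
    """Knobs for the synthetic corpus.

    ``copy_rate`` (rho) and ``paraphrase_rate`` (pi) are per-sentence
    probabilities for notes after the first; their sum may not exceed 1.
    ``paraphrase_mode`` picks the swapped-in term: "synonym" (another
    term of the same concept, similarity 1) or "sibling" (a term of a
    sister concept, similarity set by the taxonomy).  The gold label of
    a paraphrased sentence is ``paraphrase_label``; the default
    "redundant" encodes that a synonym swap carries no new clinical
    information.
    """

    seed: int = 0
    n_notes: int = 10
    sentences_per_note: int = 20
    copy_rate: float = 0.5
    paraphrase_rate: float = 0.0
    vocab_size: int = 5000
    taxonomy_size: int = 50
    synonym_fraction: float = 0.5
    tokens_per_sentence: int = 5
    vitals_rate: float = 0.1
    paraphrase_mode: str = "synonym"
    paraphrase_label: str = "redundant"
    dag_edge_prob: float = 0.0
    setting: str = "inpatient"
    specialty: str = "General Medicine"
    patient_id: str = "P0001"
    encounter_id: str = "E0001"

    def __post_init__(self) -> None:
        if self.n_notes < 2:
            raise ValueError("n_notes must be >= 2")
        if self.copy_rate + self.paraphrase_rate > 1.0 + 1e-12:
            raise ValueError("copy_rate + paraphrase_rate must be <= 1")
        if self.taxonomy_size < 2:
            raise ValueError("taxonomy_size must be >= 2")
        if self.paraphrase_mode not in ("synonym", "sibling"):
            raise ValueError("paraphrase_mode must be 'synonym' or 'sibling'")
        if self.paraphrase_label not in ("redundant", "new"):
            raise ValueError("paraphrase_label must be 'redundant' or 'new'")


def generate_taxonomy_and_lexicon(
    params: GeneratorParams,
) -> tuple[Taxonomy, ConceptLexicon, dict[str, int]]:
    """Random rooted taxonomy with synonym-bearing lexicon and Zipf counts.

    Concept i attaches to a uniformly chosen earlier concept (a random
    recursive tree); with ``dag_edge_prob`` extra is-a edges make it a
    DAG.  Every non-root concept gets one term, and a
    ``synonym_fraction`` share get a second synonym term, enabling
    paraphrase tests.  Counts follow a truncated Zipf profile.
    """
    rng = np.random.default_rng(params.seed)
    n = params.taxonomy_size
    cids = [f"C{i:04d}" for i in range(n)]
    edges: list[tuple[str, str]] = []
    for i in range(1, n):
        parent = int(rng.integers(0, i))
        edges.append((cids[i], cids[parent]))
        if params.dag_edge_prob > 0 and i > 1 and rng.random() < params.dag_edge_prob:
            extra = int(rng.integers(0, i))
            if extra != parent:
                edges.append((cids[i], cids[extra]))
    tax = Taxonomy(edges)

    lexicon = ConceptLexicon()
    for i in range(1, n):
        lexicon.add((f"c{i:04d}ax",), cids[i])
        if rng.random() < params.synonym_fraction:
            lexicon.add((f"c{i:04d}bx",), cids[i])

    counts = {
        cid: int(min(rng.zipf(2.0), 1000)) for cid in cids[1:]
    }
    return tax, lexicon, counts


@dataclass
class _BodySentence:
    text: str
    tokens: list[str]
    concept_slots: list[int]  # token positions holding a lexicon term


class _SentenceFactory:
    """Fresh-sentence supply with globally unique filler tokens."""

    def __init__(self, params: GeneratorParams, lexicon: ConceptLexicon, rng):
        self.params = params
        self.rng = rng
        self._filler_counter = 0
        self._vital_counter = 0
        terms = sorted(phrase[0] for phrase in lexicon.entries)
        order = rng.permutation(len(terms))
        self._unused_terms = [terms[i] for i in order]
        self.term_concept = {p[0]: c for p, c in lexicon.entries.items()}

    def _filler(self) -> str:
        # fillers stay globally unique so fresh content is genuinely
        # unseen; vocab_size is the nominal budget, not a hard cap
        self._filler_counter += 1
        return f"w{self._filler_counter:05d}x"

    def vitals(self) -> _BodySentence:
        # unique values so a fresh vitals line never collides with history
        self._vital_counter += 1
        base = 100 + self._vital_counter * 3
        text = f"BP {base}/{base + 1} HR {base + 2}"
        return _BodySentence(
            text=text,
            tokens=["bp", str(base), str(base + 1), "hr", str(base + 2)],
            concept_slots=[],
        )

    def fresh(self) -> _BodySentence:
        if self.rng.random() < self.params.vitals_rate:
            return self.vitals()
        k = self.params.tokens_per_sentence
        tokens: list[str] = []
        slots: list[int] = []
        for pos in range(k):
            # put lexicon terms at interior positions while supply lasts
            if 0 < pos < k - 1 and len(slots) < 2 and self._unused_terms:
                tokens.append(self._unused_terms.pop())
                slots.append(pos)
            else:
                tokens.append(self._filler())
        return _BodySentence(
            text=" ".join(tokens) + ".", tokens=tokens, concept_slots=slots
        )


def _sibling_terms(
    tax: Taxonomy, lexicon: ConceptLexicon, concept: str
) -> list[tuple[str, str]]:
    """Terms of sister concepts (same parent), as (term, concept) pairs."""
    parents = set(tax.graph.successors(concept))
    siblings = {
        child
        for parent in parents
        for child in tax.graph.predecessors(parent)
        if child != concept
    }
    return sorted(
        (phrase[0], cid)
        for phrase, cid in lexicon.entries.items()
        if cid in siblings
    )


def generate_note_sequence(
    params: GeneratorParams,
    resources: tuple[Taxonomy, ConceptLexicon, Mapping[str, int]] | None = None,
) -> tuple[NoteGroup, AnnotationSet, dict[tuple[str, tuple[int, int]], str]]:
    """One longitudinal note group with exact per-sentence gold labels.

    Note 1 is entirely fresh (and excluded from scoring downstream).
    Each body sentence of a later note is, independently: a verbatim
    copy of a uniformly chosen body sentence from an *earlier* note
    (label redundant); a paraphrase of such a sentence with one concept
    term swapped (label ``paraphrase_label``); or fresh content built
    from never-before-used tokens (label new).  Labels are returned both
    as a gold :class:`AnnotationSet` (rater id "gold") and as a plain
    span->label mapping over body sentences of notes 2..n.
    """
    if resources is None:
        resources = generate_taxonomy_and_lexicon(params)
    tax, lexicon, _counts = resources
    rng = np.random.default_rng(params.seed + 1)
    factory = _SentenceFactory(params, lexicon, rng)

    notes: list[ClinicalNote] = []
    gold = AnnotationSet(rater_id="gold")
    labels: dict[tuple[str, tuple[int, int]], str] = {}
    pool: list[_BodySentence] = []  # body sentences of earlier notes
    t0 = datetime(2015, 4, 1, 8, 0)

    for k in range(params.n_notes):
        note_id = f"N{k + 1:04d}"
        body: list[tuple[_BodySentence, str]] = []  # (sentence, label)
        for _ in range(params.sentences_per_note):
            u = rng.random()
            if k > 0 and u < params.copy_rate:
                src = pool[int(rng.integers(0, len(pool)))]
                body.append((src, "redundant"))
            elif k > 0 and u < params.copy_rate + params.paraphrase_rate:
                para = _paraphrase(params, tax, lexicon, factory, pool, rng)
                if para is None:
                    body.append((factory.fresh(), "new"))
                else:
                    body.append((para, params.paraphrase_label))
            else:
                body.append((factory.fresh(), "new"))

        lines = ["PROGRESS NOTE:"] + [s.text for s, _ in body] + [
            "Electronically signed by Alex Morgan MD"
        ]
        text = "\n".join(lines)
        note = ClinicalNote(
            note_id=note_id,
            patient_id=params.patient_id,
            encounter_id=(
                params.encounter_id if params.setting == "inpatient" else ""
            ),
            timestamp=t0 + timedelta(days=k),
            setting=params.setting,
            specialty=params.specialty,
            text=text,
        )
        notes.append(note)

        if k > 0:
            offset = len(lines[0]) + 1
            for sent, label in body:
                span = (offset, offset + len(sent.text))
                labels[(note_id, span)] = label
                gold.add(note_id, span, label)
                offset += len(sent.text) + 1
        pool.extend(s for s, _ in body)

    grouping = (
        "inpatient_encounter" if params.setting == "inpatient" else "outpatient_patient"
    )
    group_id = (
        f"{params.patient_id}:{params.encounter_id}"
        if params.setting == "inpatient"
        else params.patient_id
    )
    return NoteGroup(group_id=group_id, notes=notes, grouping=grouping), gold, labels


def _paraphrase(
    params: GeneratorParams,
    tax: Taxonomy,
    lexicon: ConceptLexicon,
    factory: _SentenceFactory,
    pool: Sequence[_BodySentence],
    rng,
) -> _BodySentence | None:
    """Copy a prior sentence with one concept term swapped; None if no
    prior sentence admits a valid swap."""
    candidates = [s for s in pool if s.concept_slots]
    if not candidates:
        return None
    order = rng.permutation(len(candidates))
    for idx in order:
        src = candidates[int(idx)]
        slot = src.concept_slots[int(rng.integers(0, len(src.concept_slots)))]
        term = src.tokens[slot]
        concept = factory.term_concept[term]
        if params.paraphrase_mode == "synonym":
            synonyms = sorted(
                p[0]
                for p, c in lexicon.entries.items()
                if c == concept and p[0] != term
            )
            if not synonyms:
                continue
            replacement = synonyms[int(rng.integers(0, len(synonyms)))]
        else:
            options = _sibling_terms(tax, lexicon, concept)
            if not options:
                continue
            replacement = options[int(rng.integers(0, len(options)))][0]
        tokens = list(src.tokens)
        tokens[slot] = replacement
        return _BodySentence(
            text=" ".join(tokens) + ".",
            tokens=tokens,
            concept_slots=list(src.concept_slots),
        )
    return None


def generate_rater_panel(
    gold: AnnotationSet,
    n_raters: int,
    flip_prob: float,
    seed: int,
) -> list[AnnotationSet]:
    """Simulated rater panel: each rater independently flips each gold
    label with probability ``flip_prob`` (which must be <= 0.5)."""
    if not 0.0 <= flip_prob <= 0.5:
        raise ValueError("flip_prob must lie in [0, 0.5]")
    rng = np.random.default_rng(seed)
    flip = {"new": "redundant", "redundant": "new"}
    panel: list[AnnotationSet] = []
    for r in range(n_raters):
        aset = AnnotationSet(rater_id=f"rater{r + 1}")
        for (note_id, span), label in sorted(gold.labels.items()):
            if rng.random() < flip_prob:
                label = flip[label]
            aset.add(note_id, span, label)
        panel.append(aset)
    return panel
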