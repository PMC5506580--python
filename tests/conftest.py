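from __future__ import annotations

import random
from datetime import datetime

import pytest

from notediff.concepts import ICTable, Taxonomy, compute_ic
from notediff.corpus import ClinicalNote
from notediff.preprocess import Token, TokenSequence


def make_note(
    note_id: str = "n1",
    text: str = "Pt stable.",
    patient_id: str = "p1",
    encounter_id: str = "e1",
    setting: str = "inpatient",
    specialty: str = "General Medicine",
    day: int = 1,
) -> ClinicalNote:
    return ClinicalNote(
        note_id=note_id,
        patient_id=patient_id,
        encounter_id=encounter_id,
        timestamp=datetime(2015, 4, day, 9, 0),
        setting=setting,
        specialty=specialty,
        text=text,
    )


def seq(tokens: str | list[str], concepts: dict[str, str] | None = None) -> TokenSequence:
    """Token sequence from space-separated pre-normalized tokens."""
    if isinstance(tokens, str):
        tokens = tokens.split()
    concepts = concepts or {}
    return TokenSequence(
        [Token(t, t, concepts.get(t)) for t in tokens]
    )


def random_dag_edges(
    n_nodes: int, rng: random.Random, extra_edge_prob: float = 0.3
) -> list[tuple[str, str]]:
    """Random rooted DAG: node i attaches to >= 1 earlier node."""
    names = [f"C{i:02d}" for i in range(n_nodes)]
    edges = []
    for i in range(1, n_nodes):
        edges.append((names[i], names[rng.randrange(i)]))
        if i > 1 and rng.random() < extra_edge_prob:
            other = names[rng.randrange(i)]
            if (names[i], other) not in edges:
                edges.append((names[i], other))
    return edges


@pytest.fixture
def six_node_taxonomy() -> tuple[Taxonomy, ICTable, dict[str, int]]:
    """Small fixed taxonomy: R -> {A, B}; A -> {C, D}; B -> {E}."""
    tax = Taxonomy([("A", "R"), ("B", "R"), ("C", "A"), ("D", "A"), ("E", "B")])
    counts = {"C": 2, "D": 1, "E": 3, "B": 1}
    return tax, compute_ic(tax, counts), counts
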