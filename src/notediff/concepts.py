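"""Concept mapping and information-content semantic similarity.

This layer stands in for MetaMap + UMLS::Similarity with the same
contracts: a dictionary lexicon maps normalized token phrases to concept
ids by greedy longest match, and an is-a taxonomy with corpus-derived
concept frequencies backs the three information-content similarity
measures (Resnik, Lin, Jiang-Conrath).

The information content of a concept is IC(c) = -ln P(c), where P(c) is
the probability mass of the concept and everything below it in the
taxonomy.  By construction IC(root) = 0 and IC never decreases when
moving from a parent to a child.  Resnik and Jiang-Conrath scores are
not naturally bounded, so they are normalized into [0, 1]: Resnik by the
maximum IC in the table, and Jiang-Conrath as 1/(1 + distance) so that
distance 0 maps to 1.  Lin's score is already in [0, 1].
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping

import networkx as nx

from .preprocess import Token, TokenSequence

__all__ = [
    "ConceptLexicon",
    "Taxonomy",
    "ICTable",
    "SimilarityBackend",
    "TaxonomyError",
    "map_concepts",
    "compute_ic",
    "least_common_subsumer",
    "similarity",
    "SIMILARITY_MEASURES",
]

SIMILARITY_MEASURES = ("resnik", "lin", "jcn")


class TaxonomyError(ValueError):
    """Raised for malformed taxonomies or unknown concepts."""


class ConceptLexicon:
    """Normalized term phrases (1..k tokens) -> concept id.

    Duplicate phrases are resolved to the lexicographically smallest
    concept id so lookup is deterministic.
    """

    def __init__(self, entries: Mapping[tuple[str, ...], str] | None = None):
        self.entries: dict[tuple[str, ...], str] = {}
        self.max_len = 0
        for phrase, cid in (entries or {}).items():
            self.add(phrase, cid)

    def add(self, phrase: tuple[str, ...] | Iterable[str], concept_id: str) -> None:
        phrase = tuple(phrase)
        if not phrase or any(not t for t in phrase):
            raise ValueError("lexicon phrases must be non-empty token tuples")
        existing = self.entries.get(phrase)
        if existing is None or concept_id < existing:
            self.entries[phrase] = concept_id
        self.max_len = max(self.max_len, len(phrase))

    def __len__(self) -> int:
        return len(self.entries)

    @classmethod
    def from_tsv(cls, path: str | Path) -> "ConceptLexicon":
        """Load a TSV of space-joined normalized phrase, concept_id."""
        lex = cls()
        with open(path, encoding="utf-8") as fh:
            for line in fh:
                line = line.rstrip("\n")
                if not line or line.startswith("#"):
                    continue
                phrase, cid = line.split("\t")
                lex.add(tuple(phrase.split(" ")), cid)
        return lex

    def to_tsv(self, path: str | Path) -> None:
        with open(path, "w", encoding="utf-8") as fh:
            for phrase, cid in sorted(self.entries.items()):
                fh.write(" ".join(phrase) + "\t" + cid + "\n")


def map_concepts(seq: TokenSequence, lexicon: ConceptLexicon) -> TokenSequence:
    """Tag tokens with concept ids by greedy left-to-right longest match.

    Every token covered by a matched phrase receives that phrase's
    concept id; unmatched tokens keep ``concept_id=None``.
    """
    norm = seq.normalized()
    tagged: list[Token] = list(seq.tokens)
    i = 0
    while i < len(norm):
        match_cid = None
        match_len = 0
        for k in range(min(lexicon.max_len, len(norm) - i), 0, -1):
            cid = lexicon.entries.get(tuple(norm[i : i + k]))
            if cid is not None:
                match_cid, match_len = cid, k
                break
        if match_cid is None:
            i += 1
            continue
        for j in range(i, i + match_len):
            t = tagged[j]
            tagged[j] = Token(t.surface, t.normalized, match_cid)
        i += match_len
    return TokenSequence(tokens=tagged, sentence=seq.sentence)


class Taxonomy:
    """A rooted is-a DAG over concept ids.

    Edges run child -> parent.  The graph must be acyclic, have exactly
    one root (a concept with no parent), and every concept must reach
    the root.
    """

    def __init__(self, edges: Iterable[tuple[str, str]]):
        g = nx.DiGraph()
        for child, parent in edges:
            g.add_edge(child, parent)
        if g.number_of_nodes() == 0:
            raise TaxonomyError("taxonomy has no concepts")
        if not nx.is_directed_acyclic_graph(g):
            raise TaxonomyError("is-a relation contains a cycle")
        roots = [n for n in g.nodes if g.out_degree(n) == 0]
        if len(roots) != 1:
            raise TaxonomyError(f"expected exactly one root, found {sorted(roots)}")
        self.graph = g
        self.root: str = roots[0]
        for node in g.nodes:
            if node != self.root and not nx.has_path(g, node, self.root):
                raise TaxonomyError(f"concept {node!r} does not reach the root")

    @classmethod
    def single_root(cls, root: str) -> "Taxonomy":
        tax = cls.__new__(cls)
        g = nx.DiGraph()
        g.add_node(root)
        tax.graph = g
        tax.root = root
        return tax

    @property
    def concepts(self) -> set[str]:
        return set(self.graph.nodes)

    def __contains__(self, concept: str) -> bool:
        return concept in self.graph

    def ancestors(self, concept: str) -> set[str]:
        """All concepts reachable via is-a edges, including ``concept``."""
        if concept not in self.graph:
            raise TaxonomyError(f"unknown concept {concept!r}")
        return nx.descendants(self.graph, concept) | {concept}

    def descendants(self, concept: str) -> set[str]:
        """All concepts that subsume to ``concept``, including itself."""
        if concept not in self.graph:
            raise TaxonomyError(f"unknown concept {concept!r}")
        return nx.ancestors(self.graph, concept) | {concept}

    @classmethod
    def from_tsv(cls, path: str | Path) -> "Taxonomy":
        """Load child_id<TAB>parent_id edges."""
        edges = []
        with open(path, encoding="utf-8") as fh:
            for line in fh:
                line = line.rstrip("\n")
                if not line or line.startswith("#"):
                    continue
                child, parent = line.split("\t")
                edges.append((child, parent))
        return cls(edges)

    def to_tsv(self, path: str | Path) -> None:
        with open(path, "w", encoding="utf-8") as fh:
            for child, parent in sorted(self.graph.edges):
                fh.write(f"{child}\t{parent}\n")


@dataclass
class ICTable:
    """Per-concept probabilities and information content."""

    counts: dict[str, int]
    prob: dict[str, float]
    ic: dict[str, float]
    max_ic: float

    def __getitem__(self, concept: str) -> float:
        try:
            return self.ic[concept]
        except KeyError:
            raise TaxonomyError(f"unknown concept {concept!r}") from None


def compute_ic(
    tax: Taxonomy,
    counts: Mapping[str, int] | None = None,
    add_one: bool = True,
) -> ICTable:
    """Derive the IC table from raw concept counts.

    The effective count of a concept pools its own raw count and those
    of every descendant; with ``add_one`` each concept additionally
    contributes a pseudo-count of one, keeping every IC finite even on
    sparse count tables.  P(c) = effective(c) / effective(root) and
    IC(c) = -ln P(c) (natural log; the base only rescales the Resnik
    normalization uniformly).
    """
    counts = dict(counts or {})
    for cid, cnt in counts.items():
        if cid not in tax:
            raise TaxonomyError(f"count given for unknown concept {cid!r}")
        if cnt < 0:
            raise ValueError(f"negative count for concept {cid!r}")
    floor = 1 if add_one else 0
    node_mass = {c: floor + counts.get(c, 0) for c in tax.concepts}

    # Pool each concept's own mass over its descendant set (set-based, so
    # diamond paths in a DAG are not double-counted).
    effective = {
        c: sum(node_mass[d] for d in tax.descendants(c)) for c in tax.concepts
    }

    total = effective[tax.root]
    if total <= 0:
        raise ValueError("total effective count must be positive")
    prob = {c: effective[c] / total for c in tax.concepts}
    ic = {c: -math.log(prob[c]) if prob[c] < 1.0 else 0.0 for c in tax.concepts}
    ic[tax.root] = 0.0
    return ICTable(counts=counts, prob=prob, ic=ic, max_ic=max(ic.values()))


def least_common_subsumer(
    tax: Taxonomy, ic: ICTable, c1: str, c2: str
) -> str:
    """The common ancestor of ``c1`` and ``c2`` with maximal IC.

    Ancestor sets include the concepts themselves, so lcs(c, c) = c.
    Ties between equally informative ancestors (possible in a DAG) are
    broken by the lexicographically smallest concept id.
    """
    common = tax.ancestors(c1) & tax.ancestors(c2)
    if not common:
        raise TaxonomyError(f"no common subsumer for {c1!r} and {c2!r}")
    return min(common, key=lambda c: (-ic[c], c))


def similarity(
    measure: str, ic: ICTable, tax: Taxonomy, c1: str, c2: str
) -> float:
    """Normalized IC similarity of two concepts, in [0, 1].

    lin  = 2*IC(lcs) / (IC(c1) + IC(c2)); 1 when c1 == c2, 0 when both
           concepts carry zero IC.
    resnik = IC(lcs) / max_ic.
    jcn  = 1 / (1 + IC(c1) + IC(c2) - 2*IC(lcs)).
    """
    if measure not in SIMILARITY_MEASURES:
        raise ValueError(f"unknown measure {measure!r}")
    if c1 not in tax:
        raise TaxonomyError(f"unknown concept {c1!r}")
    if c2 not in tax:
        raise TaxonomyError(f"unknown concept {c2!r}")
    lcs = least_common_subsumer(tax, ic, c1, c2)
    ic1, ic2, ic_lcs = ic[c1], ic[c2], ic[lcs]
    if measure == "lin":
        if c1 == c2:
            return 1.0
        denom = ic1 + ic2
        if denom == 0.0:
            return 0.0
        return min(1.0, 2.0 * ic_lcs / denom)
    if measure == "resnik":
        if ic.max_ic <= 0.0:
            return 0.0
        return min(1.0, ic_lcs / ic.max_ic)
    distance = max(0.0, ic1 + ic2 - 2.0 * ic_lcs)
    return 1.0 / (1.0 + distance)


class SimilarityBackend:
    """Caching facade bundling a taxonomy and IC table.

    Used by the novelty detector to score concept pairs repeatedly
    without recomputing LCS searches.
    """

    def __init__(self, tax: Taxonomy, ic: ICTable, measure: str):
        if measure not in SIMILARITY_MEASURES:
            raise ValueError(f"unknown measure {measure!r}")
        self.tax = tax
        self.ic = ic
        self.measure = measure
        self._cache: dict[tuple[str, str], float] = {}

    def score(self, c1: str, c2: str) -> float:
        key = (c1, c2) if c1 <= c2 else (c2, c1)
        if key not in self._cache:
            self._cache[key] = similarity(self.measure, self.ic, self.tax, *key)
        return self._cache[key]

    def max_distinct_similarity(self) -> float:
        """Max similarity over all pairs of distinct concepts (brute force)."""
        concepts = sorted(self.tax.concepts)
        best = 0.0
        for i, a in enumerate(concepts):
            for b in concepts[i + 1 :]:
                best = max(best, self.score(a, b))
        return best


def load_counts(path: str | Path) -> dict[str, int]:
    """Load a concept_id<TAB>count TSV."""
    counts: dict[str, int] = {}
    with open(path, encoding="utf-8") as fh:
        for line in fh:
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            cid, cnt = line.split("\t")
            counts[cid] = int(cnt)
    return counts


def write_counts(counts: Mapping[str, int], path: str | Path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        for cid, cnt in sorted(counts.items()):
            fh.write(f"{cid}\t{cnt}\n")
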