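"""Tokenization, lexical normalization, and stopword handling.

Tokens are maximal runs of letters and digits.  Normalization lowercases
and strips common inflectional suffixes with a small ordered rule table
(a lightweight stand-in for a full lexical-variant generator): the goal
is that inflectional variants of one clinical term collapse to a single
form, not linguistically perfect lemmas.  A user-supplied equivalence
table (e.g. ``haemoglobin -> hemoglobin``) is applied first and wins.

Corpus-specific stopwords are derived from the TF-IDF distribution over
the whole note corpus: terms whose mean TF-IDF (over the documents that
contain them) falls at or below a threshold are dropped alongside the
classic stopword list.
"""

from __future__ import annotations

import math
import re
from collections import Counter
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Mapping, Sequence

from .corpus import ClinicalNote, Sentence

__all__ = [
    "Token",
    "TokenSequence",
    "StopwordPolicy",
    "Normalizer",
    "tokenize_and_normalize",
    "derive_tfidf_stopwords",
    "filter_tokens",
    "load_stopwords",
    "classic_stopwords",
]

_TOKEN_RE = re.compile(r"[A-Za-z0-9]+")


@dataclass(frozen=True)
class Token:
    surface: str
    normalized: str
    concept_id: str | None = None


@dataclass
class TokenSequence:
    """Ordered tokens of one sentence (or any text unit)."""

    tokens: list[Token]
    sentence: Sentence | None = None

    def normalized(self) -> list[str]:
        return [t.normalized for t in self.tokens]

    def __len__(self) -> int:
        return len(self.tokens)


# Tokens kept verbatim: stripping a suffix would corrupt them.
_SUFFIX_EXCEPTIONS = frozenset(
    {
        "morning", "evening", "during", "nothing", "anything", "everything",
        "something", "nursing", "diabetes", "herpes", "scabies", "feces",
        "series", "species", "bias", "bleed", "need", "news", "lens",
        "pancreas", "atlas", "canvas", "gas", "yes", "this", "his", "has",
        "was", "does", "goes", "its", "as", "is", "us",
    }
)

_VOWELS = "aeiou"


class Normalizer:
    """Lowercase + ordered suffix rules + equivalence table.

    The rules, in order: equivalence lookup; exception list; ``-ies``->
    ``-y``; ``-ing``/``-ed`` stripped with doubled-consonant reduction
    (``stopped``->``stop``) and ``e``-restoration after stems ending in
    c/g/s/u/v/z (``improving``->``improve``); plural ``-s`` stripped
    except after ``ss``/``us``/``is``.  Tokens containing digits are
    lowercased only.
    """

    def __init__(self, equivalences: Mapping[str, str] | None = None):
        self.equivalences = {
            k.lower(): v.lower() for k, v in (equivalences or {}).items()
        }

    def __call__(self, surface: str) -> str:
        word = surface.lower()
        if word in self.equivalences:
            return self.equivalences[word]
        if any(ch.isdigit() for ch in word):
            return word
        return self._strip_suffixes(word)

    def _strip_suffixes(self, word: str) -> str:
        if word in _SUFFIX_EXCEPTIONS:
            return word
        if word.endswith("ies") and len(word) > 4:
            return word[:-3] + "y"
        for suffix in ("ing", "ed"):
            if word.endswith(suffix) and len(word) - len(suffix) >= 3:
                stem = word[: -len(suffix)]
                if len(stem) >= 2 and stem[-1] == stem[-2] and stem[-1] not in _VOWELS:
                    return stem[:-1]
                if stem[-1] in "cgsuvz":
                    return stem + "e"
                return stem
        if word.endswith("es") and len(word) > 3 and word[-3:-2] in ("x", "z") :
            return word[:-2]
        if (
            word.endswith("s")
            and len(word) > 3
            and not word.endswith(("ss", "us", "is"))
        ):
            return word[:-1]
        return word


DEFAULT_NORMALIZER = Normalizer()


def tokenize_and_normalize(
    text: str,
    normalizer: Normalizer | None = None,
    sentence: Sentence | None = None,
) -> TokenSequence:
    """Tokenize ``text`` and attach normalized forms.

    Empty text yields an empty sequence; normalization is deterministic
    and case-insensitive.
    """
    normalizer = normalizer or DEFAULT_NORMALIZER
    tokens = [
        Token(surface=m.group(0), normalized=normalizer(m.group(0)))
        for m in _TOKEN_RE.finditer(text)
    ]
    return TokenSequence(tokens=tokens, sentence=sentence)


@dataclass
class StopwordPolicy:
    """Classic plus corpus-derived (TF-IDF) stopword sets."""

    classic: set[str] = field(default_factory=set)
    tfidf_derived: set[str] = field(default_factory=set)
    tfidf_threshold: float = 0.0

    def __post_init__(self) -> None:
        if self.tfidf_threshold < 0:
            raise ValueError("tfidf_threshold must be >= 0")
        self.classic.discard("")
        self.tfidf_derived.discard("")

    @property
    def all(self) -> set[str]:
        return self.classic | self.tfidf_derived


def derive_tfidf_stopwords(
    corpus: Sequence[ClinicalNote],
    threshold: float = 0.0,
    normalizer: Normalizer | None = None,
) -> set[str]:
    """Terms whose mean TF-IDF over containing documents is <= threshold.

    TF is the term's relative frequency within a document, IDF is
    ln(N/df).  A term present in every document has IDF 0 and is always
    returned; with threshold 0 only such zero-IDF terms qualify.
    TF-IDF is computed on unfiltered tokens.
    """
    if not corpus:
        raise ValueError("cannot derive TF-IDF stopwords from an empty corpus")
    if threshold < 0:
        raise ValueError("threshold must be >= 0")
    doc_counts: list[Counter[str]] = []
    for note in corpus:
        seq = tokenize_and_normalize(note.text, normalizer)
        doc_counts.append(Counter(seq.normalized()))
    n_docs = len(doc_counts)
    df: Counter[str] = Counter()
    for counts in doc_counts:
        df.update(counts.keys())
    score_sum: dict[str, float] = {}
    for counts in doc_counts:
        total = sum(counts.values())
        if total == 0:
            continue
        for term, count in counts.items():
            tf = count / total
            idf = math.log(n_docs / df[term])
            score_sum[term] = score_sum.get(term, 0.0) + tf * idf
    return {
        term
        for term, total_score in score_sum.items()
        if total_score / df[term] <= threshold
    }


def filter_tokens(seq: TokenSequence, policy: StopwordPolicy) -> TokenSequence:
    """Drop stopworded tokens, preserving the order of survivors.

    Idempotent: filtering a filtered sequence is a no-op.
    """
    stop = policy.all
    return TokenSequence(
        tokens=[t for t in seq.tokens if t.normalized not in stop],
        sentence=seq.sentence,
    )


def load_stopwords(path: str | Path) -> set[str]:
    """Load a one-term-per-line stopword file (UTF-8, '#' comments)."""
    words: set[str] = set()
    with open(path, encoding="utf-8") as fh:
        for line in fh:
            term = line.strip()
            if term and not term.startswith("#"):
                words.add(term.lower())
    return words


def classic_stopwords() -> set[str]:
    """The bundled classic English stopword list."""
    data = resources.files("notediff.data").joinpath("stopwords.txt")
    return {
        term.lower()
        for term in data.read_text(encoding="utf-8").splitlines()
        if term.strip() and not term.startswith("#")
    }


def load_equivalences(path: str | Path) -> dict[str, str]:
    """Load a surface->normalized equivalence TSV."""
    table: dict[str, str] = {}
    with open(path, encoding="utf-8") as fh:
        for line in fh:
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            surface, normalized = line.split("\t")
            table[surface.lower()] = normalized.lower()
    return table
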