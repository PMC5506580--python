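"""Per-patient bigram language models and new-information detection.

For each target note in a chronologically ordered group, a bigram model
is estimated from *all* prior notes of that group.  A bigram of the
target note is "new" when its Laplace-smoothed conditional probability
falls below a threshold and (optionally) no semantically equivalent
bigram — one position identical, the other position substituted by a
concept whose taxonomy similarity clears a second threshold — is known
to the model.  A sentence is new when the fraction of new bigrams among
its retained-token bigrams reaches the sentence threshold.

Smoothing detail: each sentence contributes, besides its within-sentence
token pairs, one end-of-sentence continuation count (last token -> UNK).
With that convention the Laplace conditionals P(.|w) sum to exactly one
for every context w, and the probability of a real token pair equals
(count(w1,w2) + 1) / (count(w1) + |V|) with count(w1) the plain
occurrence count of w1.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field
from typing import Iterable, Sequence

from .concepts import ConceptLexicon, SimilarityBackend, map_concepts
from .corpus import ClinicalNote, NoteGroup, Sentence, SegmentationRules, segment_note
from .preprocess import (
    Normalizer,
    StopwordPolicy,
    TokenSequence,
    filter_tokens,
    tokenize_and_normalize,
)
from .relevance import RelevanceRuleSet, classify_relevance

__all__ = [
    "UNK",
    "BigramModel",
    "DetectorParams",
    "SentenceVerdict",
    "PipelineConfig",
    "build_bigram_model",
    "bigram_probability",
    "bigram_is_new",
    "classify_sentence",
    "process_note_sequence",
    "prepare_note",
]

UNK = "<UNK>"

SIM_CHOICES = ("none", "resnik", "lin", "jcn")
FINAL_LABELS = ("relevant_new", "irrelevant_new", "redundant")


@dataclass
class BigramModel:
    """Token-pair counts over a patient's prior notes.

    ``unigram_counts`` are plain occurrence counts; ``bigram_counts``
    include the per-sentence end-of-sentence continuation (w, UNK).
    ``token_concepts`` caches the concept id each vocabulary token
    carried in the history (first tag wins), for semantic bigram search.
    """

    vocab: set[str] = field(default_factory=lambda: {UNK})
    unigram_counts: Counter = field(default_factory=Counter)
    bigram_counts: Counter = field(default_factory=Counter)
    history_note_ids: list[str] = field(default_factory=list)
    token_concepts: dict[str, str] = field(default_factory=dict)
    # bigram adjacency indexes for the semantic candidate search
    _by_first: dict[str, set[str]] = field(default_factory=dict)
    _by_second: dict[str, set[str]] = field(default_factory=dict)

    def update(self, sequences: Iterable[TokenSequence], note_id: str | None = None) -> None:
        """Fold one note's (filtered, normalized) sentences into the counts."""
        for seq in sequences:
            tokens = seq.normalized()
            for tok in seq.tokens:
                if tok.concept_id is not None:
                    self.token_concepts.setdefault(tok.normalized, tok.concept_id)
            if not tokens:
                continue
            self.vocab.update(tokens)
            self.unigram_counts.update(tokens)
            pairs = list(zip(tokens, tokens[1:])) + [(tokens[-1], UNK)]
            self.bigram_counts.update(pairs)
            for w1, w2 in pairs:
                self._by_first.setdefault(w1, set()).add(w2)
                self._by_second.setdefault(w2, set()).add(w1)
        if note_id is not None:
            self.history_note_ids.append(note_id)

    def probability(self, w1: str, w2: str) -> float:
        return bigram_probability(self, w1, w2)


def build_bigram_model(
    history: Sequence[Sequence[TokenSequence]] | Sequence[TokenSequence],
    note_ids: Sequence[str] | None = None,
) -> BigramModel:
    """Build a model from prior notes' sentence token sequences.

    ``history`` may be a flat list of sentences or a list of per-note
    sentence lists.  Counting is order-invariant; an empty history gives
    vocab {UNK} and all probabilities at the Laplace floor.
    """
    model = BigramModel()
    if history and isinstance(history[0], TokenSequence):
        history = [history]  # type: ignore[list-item]
    for i, note_seqs in enumerate(history):
        nid = note_ids[i] if note_ids is not None else None
        model.update(note_seqs, note_id=nid)
    return model


def bigram_probability(model: BigramModel, w1: str, w2: str) -> float:
    """Laplace add-one conditional P(w2 | w1); tokens outside the vocab
    are mapped to UNK.  Always in (0, 1]."""
    if w1 not in model.vocab:
        w1 = UNK
    if w2 not in model.vocab:
        w2 = UNK
    v = len(model.vocab)
    return (model.bigram_counts[(w1, w2)] + 1) / (model.unigram_counts[w1] + v)


@dataclass
class DetectorParams:
    """Thresholds governing the new/redundant decision.

    ``prob_threshold`` may be a float in (0, 1) or the string "auto",
    which resolves per model to 1.5/|V| — midway between the Laplace
    floor 1/|V| of an unseen pair and the minimum once-seen probability
    of roughly 2/|V| — so that "seen before" and "never seen" separate
    cleanly regardless of vocabulary size.
    """

    prob_threshold: float | str = "auto"
    sentence_fraction: float = 0.5
    sim_measure: str = "none"
    sim_threshold: float = 0.9

    def __post_init__(self) -> None:
        if isinstance(self.prob_threshold, str):
            if self.prob_threshold != "auto":
                raise ValueError("prob_threshold must be a float or 'auto'")
        elif not 0.0 < self.prob_threshold < 1.0:
            raise ValueError("prob_threshold must lie in (0, 1)")
        if not 0.0 <= self.sentence_fraction <= 1.0:
            raise ValueError("sentence_fraction must lie in [0, 1]")
        if self.sim_measure not in SIM_CHOICES:
            raise ValueError(f"sim_measure must be one of {SIM_CHOICES}")
        if not 0.0 <= self.sim_threshold <= 1.0:
            raise ValueError("sim_threshold must lie in [0, 1]")

    def resolve_prob_threshold(self, model: BigramModel) -> float:
        if self.prob_threshold == "auto":
            return 1.5 / len(model.vocab)
        return float(self.prob_threshold)


@dataclass
class SentenceVerdict:
    """Per-sentence decision: new vs. redundant, and clinical relevance."""

    sentence: Sentence
    bigram_probs: list[float]
    new: bool
    relevance: str = "relevant"
    new_fraction: float = 0.0  # fraction of new bigrams (1.0/0.0 for short sentences)

    @property
    def final_label(self) -> str:
        if not self.new:
            return "redundant"
        return "relevant_new" if self.relevance == "relevant" else "irrelevant_new"


def bigram_is_new(
    model: BigramModel,
    w1: str,
    w2: str,
    concepts: tuple[str | None, str | None] = (None, None),
    sim_backend: SimilarityBackend | None = None,
    params: DetectorParams | None = None,
) -> bool:
    """Is the ordered pair (w1, w2) new given the history model?

    Not new when its own Laplace probability clears the threshold, or —
    with a similarity backend — when some counted history bigram matches
    one position exactly and substitutes the other with a concept whose
    similarity to the query token's concept clears the similarity
    threshold, that bigram itself clearing the probability threshold.
    """
    params = params or DetectorParams()
    theta_b = params.resolve_prob_threshold(model)
    if bigram_probability(model, w1, w2) >= theta_b:
        return False
    if params.sim_measure == "none" or sim_backend is None:
        return True
    c1, c2 = concepts
    # substitute position 2: history bigrams (w1, v2)
    if c2 is not None:
        for v2 in model._by_first.get(w1, ()):
            if v2 == w2 or v2 == UNK:
                continue
            vc = model.token_concepts.get(v2)
            if vc is None:
                continue
            if sim_backend.score(c2, vc) >= params.sim_threshold and (
                bigram_probability(model, w1, v2) >= theta_b
            ):
                return False
    # substitute position 1: history bigrams (v1, w2)
    if c1 is not None:
        for v1 in model._by_second.get(w2, ()):
            if v1 == w1 or v1 == UNK:
                continue
            vc = model.token_concepts.get(v1)
            if vc is None:
                continue
            if sim_backend.score(c1, vc) >= params.sim_threshold and (
                bigram_probability(model, v1, w2) >= theta_b
            ):
                return False
    return True


def classify_sentence(
    model: BigramModel,
    seq: TokenSequence,
    sim_backend: SimilarityBackend | None = None,
    params: DetectorParams | None = None,
    relevance: str = "relevant",
) -> SentenceVerdict:
    """Aggregate bigram decisions into a sentence verdict.

    The sentence is new when the fraction of new bigrams among its
    adjacent retained-token pairs reaches ``sentence_fraction``.  With
    fewer than two retained tokens the sentence is new iff any retained
    token is absent from the model vocabulary.
    """
    params = params or DetectorParams()
    if seq.sentence is None:
        raise ValueError("classify_sentence requires a sequence with a sentence ref")
    tokens = seq.normalized()
    concept_ids = [t.concept_id for t in seq.tokens]
    probs: list[float] = []
    if len(tokens) < 2:
        new = any(t not in model.vocab for t in tokens)
        return SentenceVerdict(
            seq.sentence, probs, new, relevance, new_fraction=1.0 if new else 0.0
        )
    n_new = 0
    pairs = list(zip(tokens, tokens[1:]))
    for i, (w1, w2) in enumerate(pairs):
        probs.append(bigram_probability(model, w1, w2))
        if bigram_is_new(
            model, w1, w2, (concept_ids[i], concept_ids[i + 1]), sim_backend, params
        ):
            n_new += 1
    fraction = n_new / len(pairs)
    new = fraction >= params.sentence_fraction
    return SentenceVerdict(seq.sentence, probs, new, relevance, new_fraction=fraction)


@dataclass
class PipelineConfig:
    """Everything the end-to-end detector needs besides the notes."""

    params: DetectorParams = field(default_factory=DetectorParams)
    normalizer: Normalizer = field(default_factory=Normalizer)
    stopword_policy: StopwordPolicy = field(default_factory=StopwordPolicy)
    lexicon: ConceptLexicon | None = None
    sim_backend: SimilarityBackend | None = None
    relevance_rules: RelevanceRuleSet | None = None
    segmentation: SegmentationRules = field(default_factory=SegmentationRules)


def prepare_note(
    note: ClinicalNote, config: PipelineConfig
) -> list[tuple[Sentence, TokenSequence]]:
    """Segment, tokenize, concept-tag, and stopword-filter one note."""
    prepared: list[tuple[Sentence, TokenSequence]] = []
    for sentence in segment_note(note, config.segmentation):
        seq = tokenize_and_normalize(sentence.text, config.normalizer, sentence)
        if config.lexicon is not None:
            seq = map_concepts(seq, config.lexicon)
        seq = filter_tokens(seq, config.stopword_policy)
        prepared.append((sentence, seq))
    return prepared


def process_note_sequence(
    group: NoteGroup, config: PipelineConfig | None = None
) -> dict[str, list[SentenceVerdict]]:
    """Score every note of a group against its predecessors.

    The first note of a group receives no verdicts (there is no history
    to compare against, matching the annotation protocol that starts
    from the second document).  For note k the model pools notes
    1..k-1; the model is extended incrementally, which is count-
    identical to a full rebuild.
    """
    config = config or PipelineConfig()
    rules = config.relevance_rules or RelevanceRuleSet.default()
    sim_backend = config.sim_backend if config.params.sim_measure != "none" else None

    verdicts: dict[str, list[SentenceVerdict]] = {}
    model = BigramModel()
    for k, note in enumerate(group.notes):
        prepared = prepare_note(note, config)
        if k == 0:
            verdicts[note.note_id] = []
        else:
            note_verdicts = []
            for sentence, seq in prepared:
                verdict = classify_sentence(
                    model,
                    seq,
                    sim_backend=sim_backend,
                    params=config.params,
                    relevance=classify_relevance(sentence, rules),
                )
                note_verdicts.append(verdict)
            verdicts[note.note_id] = note_verdicts
        model.update((seq for _, seq in prepared), note_id=note.note_id)
    return verdicts
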