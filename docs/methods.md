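# Methods

This note documents the models and procedures implemented in
`notediff`, the choices made where the design was genuinely open, and
what the synthetic experiments do and do not demonstrate.

## Detection model

**Unit of analysis.** Notes are segmented into sentences (one
convention throughout: 0-based half-open character offsets). Lines are
the primary unit; within a line, breaks occur after `". "`, `"! "`,
`"? "` unless the period closes a configured abbreviation. A line of
the form `ALL CAPS:` is a header; trailing e-signature lines and
configurable footer patterns are tagged accordingly. Segmentation is a
partition: every non-whitespace character belongs to exactly one
sentence.

**History scope.** Inpatient notes are grouped per (patient,
encounter); outpatient notes are pooled per patient. For the k-th note
of a group the model pools notes 1..k−1 — *all* prior notes, not just
the most recent. The first note of each group receives no verdicts,
matching an annotation protocol that starts from the second document.
The model is extended incrementally per note, which is count-identical
to a rebuild.

**Language model.** After stopword filtering and normalization, each
sentence contributes its adjacent ordered token pairs, plus one
end-of-sentence continuation pair (last token → UNK). The continuation
count is a deliberate convention: with it, the occurrence count of a
token equals its context count, so the Laplace conditional

    P(w2 | w1) = (c(w1,w2) + 1) / (c(w1) + |V|)

sums to exactly 1 over the vocabulary (UNK included) for *every*
context — including sentence-final and unknown tokens — while the
probability of any real token pair is the plain count-and-divide value.
Unknown tokens map to UNK on lookup; the empty model (vocab = {UNK})
returns probability 1, so empty-history notes must be scored via a
threshold below 1 (they are: the first note of a group is never
scored).

**Thresholds.**

- `prob_threshold` (θ_b): a bigram with probability ≥ θ_b is not new.
  Besides a fixed value in (0,1), the detector accepts `"auto"`
  (default), which resolves per model to 1.5/|V| — midway between the
  Laplace floor 1/|V| of a never-seen pair and the ≈2/|V| minimum of a
  once-seen pair. This makes the operating point "seen before at least
  once" independent of vocabulary size, which is the regime in which a
  copy/paste detector is meaningful. A tuned fixed value is appropriate
  when training annotations exist.
- `sentence_fraction` (θ_s, default 0.5): a sentence is new when the
  fraction of new bigrams among its retained-token pairs is ≥ θ_s. The
  aggregation rule is a package design choice (sentence-level labels
  need a sentence-level rule); the fraction rule is monotone and
  tunable. Sentences with fewer than two retained tokens are new iff
  any retained token is out of vocabulary (an empty sentence is
  redundant).
- `sim_threshold` (θ_sim, default 0.9, grid 0.5..1.0 in steps of 0.1):
  minimum concept similarity for a semantic bigram match.

**Semantic augmentation.** A low-probability bigram is rescued when a
counted history bigram matches one position exactly (token identity)
and the other position's token carries a concept whose similarity to
the query token's concept is ≥ θ_sim, with the candidate bigram itself
clearing θ_b. Substitution is limited to exactly one position, both
substituted tokens must carry concept ids, and the candidate search is
exact (adjacency index over counted bigrams). Raising θ_sim can only
shrink the match set, so the set of new bigrams is non-decreasing in
θ_sim, and a θ_sim above the maximum similarity of distinct concepts
reduces the augmented detector to the baseline exactly.

## Concept layer

The taxonomy is a rooted is-a DAG (child → parent edges, validated
acyclic with a unique root). Concept probability pools each concept's
count over its descendant *set* (no double counting across diamond
paths); by default every concept also contributes a pseudo-count of 1
(`add_one`), keeping every IC finite on sparse count tables — a
documented knob that can be disabled. IC uses the natural log; the base
only rescales the Resnik normalization uniformly.

Resnik and Jiang–Conrath scores are not naturally bounded, so they are
normalized into [0,1]: Resnik by the table's maximum IC, and
Jiang–Conrath as 1/(1+distance) so zero distance maps to 1 instead of
diverging. These normalizations are declared choices of this package.
LCS ties in a DAG (several common ancestors at maximal IC) break to the
lexicographically smallest concept id for determinism. Lin is defined
as 1 for identical concepts and 0 when both concepts have zero IC.

Token→concept mapping is greedy left-to-right longest match against a
normalized-phrase lexicon; duplicate phrases resolve to the smallest
concept id. The lexical normalizer is a small ordered suffix-rule table
(plural/`-ing`/`-ed` stripping with doubled-consonant reduction and
e-restoration, an exception list, and a user equivalence table). It is
intentionally lightweight: the contract is that inflectional variants
of one term collapse to one form, not that the output is a dictionary
lemma.

## Stopwords

TF–IDF stopwords are derived on the whole corpus before filtering:
TF = within-document relative frequency, IDF = ln(N/df), score = mean
TF–IDF over the documents containing the term; terms with score ≤
threshold (default 0, i.e. only zero-IDF terms present in every
document) are removed together with the classic list (~170 bundled
English stopwords, overridable). The score is monotone in the
threshold, so stopword sets are nested.

## Relevance, redundancy, evaluation

Relevance is an ordered first-match-wins rule list: headers, footers
and signature lines → irrelevant; vital-sign patterns → relevant;
default relevant. Ambiguous statements like "No acute events
overnight" therefore default to relevant. Note redundancy counts *all*
scored sentences by default; a `body_only` flag excludes non-body
lines. Aggregation reports n, mean, and sample (n−1) standard
deviation per (SMD group, setting) with marginals; a single record has
SD 0 by definition; empty cells are absent. The "Overall" row pools
every record, including unmapped and non-physician specialties.

Sentence-level precision/recall/F1 match predicted sentences to gold
standoff spans by >50% overlap of the shorter span (exact-span mode
available), absorbing small segmentation/annotation disagreements. The
positive class is "new" (optionally restricted to relevant-new);
a "redundant" positive class is provided for redundancy-recovery
experiments, where semantic augmentation shows its effect — augmenting
the detector can only shrink the predicted-new set, so its benefit
appears as strictly better recall of redundant (paraphrased) content
and better precision on new content. Fleiss' κ is computed via
statsmodels with the perfect-agreement corner pinned to 1.0; percent
agreement is the pairwise definition (mean proportion of agreeing
rater pairs per item). The similarity-threshold grid search runs the
full pipeline per candidate and breaks F1 ties toward the larger
threshold (closer to baseline behavior).

## Synthetic generator

The generator emulates the *structure* of longitudinal clinical
documentation: per-sentence verbatim copy (rate ρ), single-term
paraphrase by synonym or taxonomy sibling (rate π), and fresh content
built from never-reused tokens, with headers, signature lines, and
occasional vital-sign statements (unique values, so fresh vitals never
collide with history). Gold labels are recorded exactly as constructed;
a synonym paraphrase is labeled redundant by default because it carries
no new clinical information — precisely what the semantic augmentation
should recover and the lexical baseline should miss. All randomness
flows through one numpy PCG64 generator per seed.

It does **not** model realistic clinical language: no discourse
structure, no section reorganization, no summarized restatements
("added drug X" vs. an updated medication list), no negation, no
misspellings. Passing the synthetic experiments demonstrates that the
machinery is correct and that the paraphrase-recovery mechanism works
as designed; it does not certify performance on real notes, where
rephrasing is richer than single-term substitution and the measured
benefit of semantic similarity is correspondingly smaller.

## Problem sizes and tolerances

The synthetic experiments use 50 notes × 20 sentences for copy-rate
recovery (tolerance ±0.05, the binomial scale of ~1000 Bernoulli
draws), 25 × 15 for the paraphrase comparison, and ~500 annotation
units for agreement statistics — sizes at which the measured quantities
are stable to well within the asserted tolerances while the whole suite
runs in seconds. Exact-agreement checks (probability oracle, IC/LCS
enumeration) assert equality or 1e-12; accumulation-order checks
(Laplace normalization, aggregation marginals) assert 1e-9.

## Known limitations

- Sentence segmentation is rule-based; clinical formats with unusual
  layout need custom rules.
- The normalizer is not a full lexical-variant generator; derivational
  variants ("renal"/"kidney") must come from the concept layer.
- Relevance rules ship only the stable conventions; institution-
  specific lists must be supplied.
- Section-level (rather than sentence-level) scoring is not
  implemented.
- Trigram and higher-order models are out of scope (bigrams are the
  design point of this detector).
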