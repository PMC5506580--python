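# notediff

Detect clinically relevant **new** versus **redundant** information in
longitudinal clinical notes.

Clinical notes in electronic health records are heavily copy/pasted:
each new progress note tends to be a recombination of earlier notes with
a little genuinely new content mixed in. `notediff` scores every
sentence of a note against the patient's *prior* notes and labels it
`relevant_new`, `irrelevant_new`, or `redundant`, then rolls per-note
redundancy up by author specialty (SMD group) and care setting
(inpatient/outpatient).

## Method

For each target note in a chronologically ordered group (inpatient
notes grouped per admission encounter, outpatient notes pooled per
patient), a **bigram language model** is estimated from all prior notes
of the group after stopword removal (a classic list plus corpus-derived
TF–IDF stopwords) and rule-based lexical normalization. Bigram
probabilities use Laplace (add-one) smoothing,

    P(w2 | w1) = (c(w1, w2) + 1) / (c(w1) + |V|),

and a bigram of the target note counts as *new* when its probability
falls below a threshold θ_b. A sentence is new when the fraction of new
bigrams among its retained-token pairs reaches θ_s (default 0.5).

Optionally, the model is augmented with **information-content semantic
similarity** over an is-a concept taxonomy. Tokens are mapped to
concepts by dictionary longest match; with IC(c) = −ln P(c) and
lcs(c₁,c₂) the least common subsumer, three measures are supported:

    score_res(c1, c2) = IC(lcs(c1, c2)) / max IC
    score_lin(c1, c2) = 2·IC(lcs(c1, c2)) / (IC(c1) + IC(c2))
    score_jcn(c1, c2) = 1 / (1 + IC(c1) + IC(c2) − 2·IC(lcs(c1, c2)))

(all normalized into [0, 1]). A low-probability bigram is rescued as
"not new" when the history contains a bigram identical in one position
whose other-position concept is similar to the query concept at or
above a threshold θ_sim — so "cardiac arrest" is recognized as a
paraphrase of a previously documented "heart arrest".

Heuristic rules classify new sentences as clinically relevant or not
(headers/footers/signatures are irrelevant; vital-sign statements are
always relevant; the rule list is a user-editable file). Note
redundancy is (# sentences without new information) / (# sentences),
aggregated as mean ± SD per specialty group and setting.

Because real clinical corpora are protected health data, the package
ships a synthetic generator that produces longitudinal note groups with
controlled copy/paste, synonym- or sibling-concept paraphrase, and
fresh-content rates — with exact per-sentence gold labels — plus random
taxonomies/lexicons and simulated annotator panels for the agreement
statistics (Fleiss κ, pairwise percent agreement).

## Worked example

```python
from notediff import (
    GeneratorParams, generate_taxonomy_and_lexicon, generate_note_sequence,
    PipelineConfig, DetectorParams, process_note_sequence,
    SimilarityBackend, compute_ic, sentence_prf, note_redundancy,
)

params = GeneratorParams(seed=1, n_notes=8, sentences_per_note=10,
                         copy_rate=0.4, paraphrase_rate=0.3,
                         synonym_fraction=1.0)
tax, lexicon, counts = generate_taxonomy_and_lexicon(params)
group, gold, _ = generate_note_sequence(params, (tax, lexicon, counts))

baseline = process_note_sequence(group, PipelineConfig(lexicon=lexicon))
ic = compute_ic(tax, counts)
lin = process_note_sequence(group, PipelineConfig(
    params=DetectorParams(sim_measure="lin", sim_threshold=0.9),
    lexicon=lexicon,
    sim_backend=SimilarityBackend(tax, ic, "lin"),
))

for name, verdicts in [("baseline", baseline), ("baseline+lin", lin)]:
    new = sentence_prf(verdicts, gold, positive_class="new")
    red = sentence_prf(verdicts, gold, positive_class="redundant")
    mean_red = sum(note_redundancy(v, body_only=True)
                   for v in verdicts.values() if v) / (len(group.notes) - 1)
    print(f"{name:12s}  new P={new.precision:.2f} R={new.recall:.2f} "
          f"F1={new.f1:.2f}  redundant recall={red.recall:.2f}  "
          f"mean note redundancy={mean_red:.2f}")
```

prints

```
baseline      new P=0.64 R=1.00 F1=0.78  redundant recall=0.72  mean note redundancy=0.49
baseline+lin  new P=1.00 R=1.00 F1=1.00  redundant recall=1.00  mean note redundancy=0.67
```

The corpus mixes 40% verbatim copies and 30% synonym paraphrases per
sentence. The baseline model catches the verbatim copies but flags the
paraphrases as new (redundant recall 0.72, diluted precision on the new
class); adding Lin similarity recognizes the synonym swaps as redundant
and recovers them all. On real notes the gap is smaller — clinicians
rarely paraphrase by swapping single terms — but the direction is the
same: semantic similarity helps recall of redundant content.

## Command line

```bash
notediff simulate --out-dir data --seed 1 --n-notes 20 --copy-rate 0.5
notediff detect   --corpus data/notes.jsonl --out-dir out
notediff redundancy --corpus data/notes.jsonl --out-dir out
notediff evaluate --corpus data/notes.jsonl --annotations data/gold.tsv --out-dir out
notediff tune     --corpus data/notes.jsonl --annotations data/gold.tsv \
                  --taxonomy data/taxonomy.tsv --lexicon data/lexicon.tsv \
                  --counts data/counts.tsv --sim-measure lin --out-dir out
```

Options may also come from a JSON config file (`--config cfg.json`);
flags override the file, which overrides defaults. All inputs and
outputs are plain UTF-8 JSON-lines/TSV.

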