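# trialscope

Automated evidence surveillance for randomized controlled trials (RCTs).

Evidence-based medicine depends on finding RCT reports quickly, but trials
are a small, slowly hand-indexed fraction of the biomedical literature, and
their key facts — who was studied, what was compared, what was measured, how
many people were randomized, how trustworthy the methods look — sit in
unstructured abstracts. `trialscope` implements the full machine-reading
pipeline for this problem, aimed at informaticians and evidence-synthesis
researchers:

1. **Screening.** An ensemble of a calibrated linear SVM and several
   independently initialized convolutional text classifiers scores each
   record as RCT vs non-RCT (mean of member probabilities); a second linear
   model screens human vs non-human studies. The operating point is the
   *balanced* threshold t\* = argmax over cuts of (sensitivity +
   specificity), the outer-left extreme of the ROC curve, with bootstrap
   evaluation of threshold stability (threshold set on each resample,
   precision/recall measured out-of-bag).
2. **Sample size.** English number words are normalized to numerals
   ("one hundred and twelve" → "112"); every integer in the abstract becomes
   a candidate described by context features (adjacent-token word vectors,
   part-of-speech one-hots, "patients"/randomization-verb proximity,
   percent- and year-context indicators); a small feed-forward network
   scores candidates and the winner is returned if it clears a decision
   threshold. The target is the number randomized, not the number completing
   the trial.
3. **PICO extraction.** A BIO sequence labeler tags population,
   intervention (interventions and comparators share one label), and
   outcome spans; abbreviations are expanded from definitions found anywhere
   in the abstract; spans are linked to a controlled vocabulary by
   longest-match-first dictionary lookup over minimally normalized synonyms
   (bracket tags such as "[NOS]" stripped, lowercased). Concept-level
   evaluation is *strict* (exact id) or *relaxed* (immediate parent/child
   also counts).
4. **Risk of bias.** Per-domain ratings collapse to an overall label by the
   all-low rule (low overall ⇔ every domain low); a ridge-penalized
   logistic regression over unigram/bigram/trigram bag-of-words of
   title + abstract predicts P(low risk of bias overall), evaluated by
   Brier score, C-statistic, and reliability bins — it is used to *rank*
   results, not to classify.
5. **Retrieval.** An annotated store answers conjunctive structured PICO
   queries, suggests terms with their modal facet, exports RIS, and ranks by
   `1.0 · P(low bias) + 0.5 · log10(n)`.

Registry records (trial registrations) pass their structured fields through
directly — study design and target sample size are taken as-is, PICO
snippets are concept-linked, and no bias probability is ever predicted for
them.

Every component trains and is tested on a packaged synthetic corpus
generator (`trialscope.synth`) that plants all of the above signals with
exact gold annotations, so the pipeline is fully reproducible without any
external or licensed data.

## Worked example

```python
from trialscope import synth
from trialscope.screening import train_rct_ensemble, train_human_model, predict_rct, RctTrainConfig
from trialscope.sizeextract import train_size_model, extract_sample_size, SizeTrainConfig
from trialscope.pico import train_span_tagger, tag_spans, build_synonym_index, link_concepts, TaggerTrainConfig
from trialscope.bias import train_bias_model, predict_low_rob
from trialscope.store import PipelineModels, build_store, Query

vocab = synth.make_vocabulary(seed=0, n_concepts=60)
corpus = synth.generate_corpus(synth.GeneratorConfig(n_records=600, seed=0), vocab)
rcts = [(r, g) for r, g in corpus if g.is_rct]

models = PipelineModels(
    rct=train_rct_ensemble(corpus[:500], RctTrainConfig(n_cnn=2, seed=0)),
    human=train_human_model(corpus[:500], seed=0),
    size=train_size_model(rcts[:250], SizeTrainConfig(seed=0)),
    tagger=train_span_tagger(corpus[:500], TaggerTrainConfig(seed=0)),
    bias=train_bias_model(rcts[:250], seed=0),
    vocab=vocab,
)

record, gold = next((r, g) for r, g in corpus[500:] if g.is_rct and g.is_human)
print("P(RCT):", round(predict_rct(models.rct, record), 3))
print("n randomized:", extract_sample_size(models.size, record))
index = build_synonym_index(vocab)
for s in tag_spans(models.tagger, record.abstract):
    ids = sorted({c.concept_id for c in link_concepts(index, s, record.abstract)})
    print(f"  {s.label:<12} {s.text!r} -> {ids}")
print("P(low bias):", round(predict_low_rob(models.bias, record), 3))

store = build_store([r for r, _ in corpus[500:]], models)
pop = next(iter(gold.pico_concepts["population"]))
res = store.run_query(Query(terms=[(pop, "population")], rank_by_quality=True))
print(f"{len(res)} trials, top {res[0].record.record_id} (n={res[0].annotation.sample_size})")
```

Output:

```
P(RCT): 0.923
n randomized: 138
  population   'patients with psoriasis' -> ['P0012']
  intervention 'low-dose carimab' -> ['I0012c']
  intervention 'Intensive Lorapril' -> ['I0011c']
  outcome      'Fatigue score' -> ['O0002']
  outcome      'relapse rate' -> ['O0004']
  intervention 'Low-dose carimab' -> ['I0012c']
  outcome      'Fatigue score' -> ['O0002']
3 trials, top SYN000588 (n=248)
```

Reading: the screener is confident this abstract reports an RCT (0.923,
above its balanced threshold), the extractor recovered the planted number
randomized (138), each tagged span was linked to its vocabulary concept
(`P0012` = psoriasis; `I0012c` = the child concept "low-dose carimab"), and
a population query over the annotated store returns the matching trials
with the largest/lowest-bias one first.

The same flow is available from the shell:

```bash
trialscope make-corpus --n 600 --seed 1 --out corpus/
trialscope train --n 800 --seed 1 --models models.joblib
trialscope annotate --models models.joblib --medline corpus/medline.xml \
    --registry corpus/registry.csv --out store.jsonl
trialscope query --store store.jsonl --vocab corpus/vocab.tsv --population P0012 --ranked
trialscope export --store store.jsonl --ris results.ris
```

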