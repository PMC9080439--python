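# amrtriage

Weakly supervised literature triage for antimicrobial-resistance (AMR)
biocuration.

Curation pipelines for AMR resources need to find the small fraction of
newly published articles that actually describe resistance determinants,
without hand-labeling training data for every query. `amrtriage`
implements a label-free triage strategy: score each full-text article by
its similarity to a *context document* built from a domain lexicon, convert
the scores into weak relevance labels by mean thresholding, and train a
conventional SVM classifier on those weak labels. Expert labels are used
only for final evaluation, never for training.

Two document representations are implemented and compared:

- **`pvdm`** — a hand-implemented Paragraph Vector (PV-DM, doc2vec) model
  with negative sampling; the score is the cosine between a document's
  paragraph vector and the inferred vector of the lexicon context document
  (after subtracting the corpus-mean vector; see
  [docs/methods.md](docs/methods.md)).
- **`bow`** — the mean of the document's non-zero TF-IDF weights over the
  lexicon vocabulary.

The package also includes a PubMed Central retrieval client (ESearch /
EFetch with injectable transport), a synthetic-corpus generator so the
whole pipeline can be exercised and validated offline, an evaluation module
(per-class precision/recall/F1, accuracy, labeling agreement), and a
`click` command-line interface with resumable, manifest-tracked stages.

## Quick start

Run the full synthetic experiment (generate → score → label → train →
evaluate) from the command line:

```bash
amrtriage run --output-dir scratch/demo --seed 1
cat scratch/demo/evaluation_pvdm.json
```

or drive it from Python:

```python
from amrtriage.benchmark import run_replicate

print(run_replicate(seed=1))
```

which on one replicate at the default problem size (100 documents, 50-term
lexicon, 62-document gold subset) prints outcomes like:

```python
{'pvdm_agreement_corpus': 99.0, 'pvdm_agreement_gold': 100.0, 'svm_pvdm_accuracy': 100.0,
 'bow_agreement_corpus': 93.0, 'bow_agreement_gold': 93.54838709677419, 'svm_bow_accuracy': 100.0}
```

To triage real articles, point the pipeline at PubMed Central instead of
the simulator:

```bash
amrtriage fetch --output-dir scratch/pmc --retmax 500   # needs network access
amrtriage run --output-dir scratch/pmc --stages score,label,train,evaluate \
    --lexicon my_terms.txt --gold expert_labels.csv
```

Stages are resumable: a completed stage with an unchanged configuration is
skipped on re-run (`--force` recomputes). Exit codes: 0 success, 2
configuration error, 3 stage failure.

## Conventions

- Label **0 = relevant**, **1 = irrelevant**; class 0 is the positive class
  in all metrics.
- Weak labeling: relevant iff score ≥ the corpus-wide arithmetic mean of
  the scores (ties are relevant).
- The SVM never sees gold-labeled documents during fitting
  (`exclude_ids`); hyperparameters come from 5-fold stratified
  cross-validation over a small C/γ grid.
- Everything is deterministic from a single seed (single-threaded
  training); identical configurations reproduce artifacts byte-for-byte.

## Testing

```bash
python -m pytest -q tests/
```

The suite (~115 tests, about 5 minutes on one CPU) covers unit oracles
(TF-IDF against a brute-force recount, metrics against direct recounting,
cosine against hand-computed values), property-based checks via
`hypothesis` (labeling translation-invariance, normalization idempotence),
multi-seed statistical properties of the PV-DM representation, and full
pipeline/CLI runs including bit-reproducibility.

## Package layout

| module | contents |
|---|---|
| `amrtriage.corpus_io` | E-utilities client, JATS flattening, corpus/score/label file formats |
| `amrtriage.preprocess` | normalization, lexicon, phrase-aware tokenization, context document |
| `amrtriage.scoring` | PV-DM training/inference, cosine scoring, TF-IDF weights, bag-of-words scoring |
| `amrtriage.labeling` | mean-threshold weak labeling |
| `amrtriage.classification` | TF-IDF featurization, SVM grid search, model persistence |
| `amrtriage.evaluation` | confusion matrix, per-class metrics, agreement, report formatting |
| `amrtriage.synthetic_data` | two-class corpus generator, stratified gold subsets |
| `amrtriage.benchmark` | one-call end-to-end synthetic replicate |
| `amrtriage.cli` | configuration, staged pipeline, `amrtriage` command |
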