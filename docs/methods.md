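# Methods

## Problem and overall design

`amrtriage` addresses literature triage for antimicrobial-resistance (AMR)
biocuration: given a large set of full-text articles retrieved from PubMed
Central, rank and label each article by its relevance to the AMR domain
without any manually labeled training data, then use those automatic
("weak") labels to train a conventional supervised classifier. The pipeline
has five stages:

1. **Retrieval** — ESearch against the PMC full-text index with a MeSH-based
   query for microbial drug resistance (open-access filter, `retmax` 10000),
   then EFetch of the full-text XML in batches. Title, abstract, and body
   paragraphs are flattened to plain text in document order.
2. **Context scoring** — every document receives a similarity score against
   a *context document*: a pseudo-document consisting of the domain lexicon
   (AMR terms of the kind curated in CARD and the Gene Ontology), each term
   once, in sorted order. Two representations are implemented:
   - `pvdm_cosine`: a Paragraph Vector–Distributed Memory (PV-DM) model is
     trained on the corpus; the score is the cosine similarity between a
     document's paragraph vector and the inferred vector of the context
     document.
   - `bow_tfidf_mean`: the score is the arithmetic mean of the document's
     non-zero TF-IDF weights over the lexicon vocabulary.
3. **Weak labeling** — the corpus-wide arithmetic mean of the scores is the
   threshold: label 0 ("relevant") iff score ≥ mean, else label 1
   ("irrelevant"). Ties at the mean are relevant.
4. **Classification** — an RBF-kernel SVM is trained on the weak labels
   with TF-IDF lexicon features, with the expert-labeled test set excluded
   from all fitting, and hyperparameters (C, γ) chosen by mean 5-fold
   stratified cross-validation accuracy over a log grid
   (C ∈ {0.1, 1, 10, 100}, γ ∈ {10⁻³, 10⁻², 10⁻¹, 1, 1/n_features}); ties
   break toward smaller C, then smaller γ.
5. **Evaluation** — confusion matrix with class 0 as the positive class,
   per-class precision/recall/F1, accuracy, and labeling-agreement
   percentages against the gold labels.

## The PV-DM implementation

The paragraph-vector trainer is implemented in numpy rather than wrapping an
external embedding library. It is distributed-memory doc2vec with negative
sampling:

- For each corpus position, the model predicts the center word from the
  average of the window context word vectors (window 5 on each side) plus
  the document's paragraph vector.
- The output layer is trained by negative sampling (5 negatives per
  position) from the unigram distribution raised to the 0.75 power.
- Learning rate decays linearly from `alpha` = 0.025 to `min_alpha` =
  0.00025 over `epochs` = 30 epochs. Vocabulary is pruned below
  `min_count` = 3 occurrences. Vectors are 300-dimensional by default.
- Updates are applied in shuffled mini-batches with duplicate-index
  gradients accumulated exactly (sort + segmented reduction), so training is
  single-threaded and bit-reproducible from the seed. `workers` is kept at
  1 for that reason; the parameter exists for interface compatibility but
  multi-threaded training is intentionally not implemented, since it would
  sacrifice reproducibility.
- Inference for an unseen document freezes the word and output matrices and
  fits only a fresh paragraph vector with the same procedure (same epoch
  count by default).

A document whose tokens are all out-of-vocabulary still receives a vector
(its random initialization) with a warning, so downstream bookkeeping never
loses a document silently.

### Mean-centered cosine scoring

Negative-sampling SGD gives *every* paragraph vector a large displacement in
a shared direction that carries no topical information (the net pull of the
output layer integrated over training). In this implementation that shared
component is several times larger than the topical component, and the
context vector — fitted by inference rather than joint training —
accumulates a different displacement. Left uncorrected, all raw cosines
collapse into a narrow band near ±1 and the relevance signal is compressed
into the third decimal place.

`score_corpus_pvdm` therefore subtracts the corpus-mean paragraph vector
from the document vectors *and* the context vector before taking the
cosine (`center=True`, the default; `center=False` recovers the raw
cosine). Centering removes exactly the shared component, leaves scores in
[−1, 1], and on synthetic corpora raises gold agreement of the weak labels
from the high-80s to 96–99%. Because mean thresholding is
translation-sensitive only through the score geometry, not the score scale,
this choice affects ranking quality, not the labeling rule.

Corpus documents are scored with their trained vectors; only the context
document (and any unseen document) is scored through inference. Re-inferring
corpus documents was measured to give the same labeling quality at ~30%
extra cost.

## TF-IDF variant

`tfidf_weights` computes raw term frequency times smoothed inverse document
frequency, idf(t) = ln((1 + N)/(1 + df(t))) + 1, with no length
normalization, over exactly the lexicon vocabulary in lexicographic order
(scikit-learn's `TfidfVectorizer` with `norm=None`). Tokens outside the
lexicon never influence a row. The bag-of-words score averages over the
lexicon terms *present* in the document rather than the full lexicon width:
dividing by all terms would make scores shrink with lexicon size rather
than reflect document content. The alternative is available as
`mean_over="all"`.

## Text normalization

Terms and text are NFKC-normalized, lowercased, and punctuation-stripped
(removed, not blanked, so "beta-lactamase" matches the lexicon form
"betalactamase"). Multiword lexicon terms are collapsed to single
underscore-joined tokens, and in-text occurrences are rewritten by maximal
left-to-right phrase matching, so each lexicon term survives as one
feature in both representations. No stemming and no stop-word removal are
applied.

The context document presents each lexicon term exactly once, sorted:
sorting makes the representation independent of lexicon file order, and
single occurrence avoids weighting the context by how often a term happens
to be listed in the source resources.

## Synthetic corpora

The generator emulates the one property the scoring methods exploit:
relevant documents are enriched for lexicon terms. Each document is a bag
of independent token draws — from the lexicon with probability
`enrichment` (class 0, default 0.3) or `background_rate` (class 1, default
0.05), otherwise uniformly from a background vocabulary. Defaults: 50
relevant + 50 irrelevant documents, 50 lexicon terms, 500 background words,
Poisson document lengths with mean 120 truncated at 20 tokens (short
documents make paragraph-vector inference degenerate). These sizes keep a
full end-to-end replicate (train + score + label + SVM) in the tens of
seconds on one CPU while leaving the class structure statistically
unambiguous.

What the generator deliberately does **not** model: word order and
discourse structure, topical correlation between background words, citation
and section text, near-duplicate articles, and vocabulary burstiness.
Passing tests on these corpora therefore demonstrate that the pipeline
recovers lexicon-enrichment structure, not that it reaches any particular
accuracy on real PMC text, where relevance is only partially mediated by
lexicon frequency.

A stratified `generate_gold_subset` emulates the expert-labeled test set: a
62-document draw preserving the class ratio (15/47 when the corpus ratio is
15:47), held out from all SVM fitting.

## Evaluation conventions

Class 0 (relevant) is the positive class. Metrics are reported at full
precision together with a rounded view: half-up to two decimals for ratios,
half-up to the nearest integer for percentages. (Reference tables for this
kind of experiment occasionally truncate rather than round — e.g. printing
10/15 = 66.7% as 66 — and this package does not reproduce truncation.)
Division by zero in precision/recall/F1 yields 0 with a `zero_division`
flag rather than an error. Identical document-id sets are required; any
mismatch is reported as the symmetric difference.

## Representation-quality regimes

A practical caveat established while testing: the relative geometry of
trained paragraph vectors and inferred vectors is only stable once the word
vectors are adequately trained. On very small corpora (tens of documents of
a few dozen tokens, few epochs) the inferred context vector can
systematically *anti*-align with the relevant class, because paragraph
vectors learn the residual left over by context-word averages, and the size
of that residual depends on how far word-vector training has progressed.
Multi-seed representation properties are therefore tested at a reduced but
adequately trained scale (50 documents × 120 tokens, 100 dimensions, 30
epochs) rather than at toy scale.

## Numerical and procedural choices

- Tie at the labeling threshold → relevant, for both methods.
- The labeling mean is computed over the entire scored corpus, including
  documents later held out as gold test items; only SVM training excludes
  them.
- Grid-search ties break toward smaller C then smaller γ, making model
  selection independent of grid enumeration order.
- E-Fetch batches default to 200 ids per request with a politeness delay;
  all transports are injectable so tests run on recorded fixtures.
- Corpus files are JSON-lines (streamable at 10⁵-document scale); scores
  and labels are plain CSV; the SVM artifact stores the fitted estimator,
  chosen hyperparameters, feature-term list, and a format-version tag.
- Pipeline stages write atomically (temp file + rename) and record a config
  hash in a run manifest; an unchanged completed stage is skipped unless
  forced.

## Known limitations

- The PV-DM trainer is optimized for clarity and reproducibility, not
  throughput; corpora of 10⁵ documents are feasible but take hours, and
  multi-threading is deliberately absent.
- The shipped lexicon handling assumes one term per line; no ontology
  traversal or synonym expansion is performed.
- JATS handling extracts title/abstract/body paragraphs only; tables,
  figure captions, and references are ignored.
- Mean-threshold labeling always splits the corpus near its score mean; on
  a corpus that is almost entirely relevant (or irrelevant) the weak labels
  are necessarily poor, whatever the scorer does.
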