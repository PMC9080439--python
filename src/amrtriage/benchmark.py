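"""End-to-end replicates of the weak-labeling experiment on synthetic corpora.

One replicate mirrors the full study design at desk scale: generate a
two-class corpus, score it against the lexicon context under both
representations, weak-label each by mean thresholding, train an SVM on each
set of weak labels with a stratified gold subset held out, and measure
weak-label agreement and SVM accuracy against the gold labels.
"""

from __future__ import annotations

from dataclasses import replace

from .classification import SvmConfig, featurize, predict, train_svm
from .evaluation import confusion, label_agreement, metrics
from .labeling import mean_threshold_label
from .preprocess import build_context_document, tokenize_corpus
from .scoring import EmbeddingParams, score_corpus_bow, score_corpus_pvdm, tfidf_weights, train_pvdm
from .synthetic_data import SyntheticSpec, generate_corpus, generate_gold_subset

__all__ = ["run_replicate"]


def run_replicate(
    seed: int,
    spec: SyntheticSpec = SyntheticSpec(),
    embedding: EmbeddingParams = EmbeddingParams(),
    svm: SvmConfig = SvmConfig(),
    n_gold: int = 62,
) -> dict[str, float]:
    """Run one full synthetic experiment; returns percentage-scale outcomes.

    Keys: ``{pvdm,bow}_agreement_corpus`` (weak labels vs gold over the whole
    corpus), ``{pvdm,bow}_agreement_gold`` (same, on the held-out gold
    subset), ``svm_pvdm_accuracy`` / ``svm_bow_accuracy`` (SVM trained on
    each weak labeling, evaluated on the gold subset), all in percent.
    """
    spec = replace(spec, seed=seed)
    embedding = replace(embedding, seed=seed)
    svm = replace(svm, seed=seed)

    documents, gold, lexicon = generate_corpus(spec)
    tokenized = tokenize_corpus(documents, lexicon)
    context = build_context_document(lexicon)

    model = train_pvdm(tokenized, embedding)
    pvdm_scores = score_corpus_pvdm(model, tokenized, context, seed=seed)
    weights = tfidf_weights(tokenized, lexicon)
    bow_scores = score_corpus_bow(weights)

    _, pvdm_labels = mean_threshold_label(pvdm_scores)
    _, bow_labels = mean_threshold_label(bow_scores)

    gold_subset = generate_gold_subset(gold, n_gold, seed=seed)
    gold_ids = {r.doc_id for r in gold_subset}
    features = featurize(tokenized, lexicon)
    held_out = features.loc[[i for i in features.index if i in gold_ids]]

    out: dict[str, float] = {}
    for name, weak_labels in (("pvdm", pvdm_labels), ("bow", bow_labels)):
        out[f"{name}_agreement_corpus"] = label_agreement(weak_labels, gold).pct_overall
        on_gold = [r for r in weak_labels if r.doc_id in gold_ids]
        out[f"{name}_agreement_gold"] = label_agreement(on_gold, gold_subset).pct_overall
        classifier = train_svm(features, weak_labels, svm, exclude_ids=gold_ids)
        predictions = predict(classifier, held_out)
        report = metrics(confusion(predictions, gold_subset))
        out[f"svm_{name}_accuracy"] = 100.0 * report.accuracy
    return out
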