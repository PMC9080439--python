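"""Synthetic two-class corpora with controllable lexicon enrichment.

Stands in for a retrieved literature corpus: each document is a bag of
tokens drawn from a unigram mixture.  In relevant documents (class 0) each
token comes from the domain lexicon with probability ``enrichment``,
otherwise from a background vocabulary; irrelevant documents (class 1) use
the lower ``background_rate``.  Relevance therefore *is* lexicon-term
enrichment by construction, which is exactly the assumption the scoring
methods exploit — so parameter-recovery tests on these corpora probe the
pipeline, not incidental text structure.

Documents are emitted as plain :class:`~amrtriage.corpus_io.RawDocument`
bodies (space-joined tokens), so synthetic and fetched corpora are
interchangeable everywhere downstream.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .corpus_io import RawDocument
from .labeling import IRRELEVANT, RELEVANT, LabelRecord
from .preprocess import Lexicon

__all__ = ["SyntheticSpec", "generate_corpus", "generate_gold_subset"]

#: shortest admissible document; keeps paragraph-vector inference non-degenerate
MIN_DOC_LENGTH = 20


@dataclass(frozen=True)
class SyntheticSpec:
    """Generator settings for a two-class corpus.

    Defaults give a well-separated desk-scale corpus: 50 relevant and 50
    irrelevant documents of ~120 tokens, a 50-term lexicon against a
    500-word background vocabulary, with 30% of relevant-document tokens
    drawn from the lexicon versus 5% for irrelevant documents.
    """

    n_relevant: int = 50
    n_irrelevant: int = 50
    lexicon_size: int = 50
    background_vocab_size: int = 500
    enrichment: float = 0.3
    background_rate: float = 0.05
    doc_length_mean: int = 120
    seed: int = 0

    def __post_init__(self) -> None:
        if min(self.n_relevant, self.n_irrelevant, self.lexicon_size,
               self.background_vocab_size, self.doc_length_mean) < 1:
            raise ValueError("all counts must be >= 1")
        if self.n_relevant + self.n_irrelevant < 4:
            raise ValueError("corpus must have at least 4 documents")
        if not (0.0 <= self.background_rate < self.enrichment <= 1.0):
            raise ValueError(
                "need 0 <= background_rate < enrichment <= 1, got "
                f"background_rate={self.background_rate}, enrichment={self.enrichment}"
            )


def _vocabularies(spec: SyntheticSpec) -> tuple[list[str], list[str]]:
    width = len(str(spec.lexicon_size))
    lexicon = [f"amrterm{i:0{width}d}" for i in range(spec.lexicon_size)]
    width = len(str(spec.background_vocab_size))
    background = [f"bgword{i:0{width}d}" for i in range(spec.background_vocab_size)]
    return lexicon, background


def generate_corpus(
    spec: SyntheticSpec = SyntheticSpec(),
) -> tuple[list[RawDocument], list[LabelRecord], Lexicon]:
    """Draw a corpus, its gold labels, and the generating lexicon.

    Document lengths are Poisson(``doc_length_mean``) truncated below at 20
    tokens.  Every token is an independent two-stage draw: lexicon vs
    background by the class's rate, then uniform within the chosen
    vocabulary.  Fully reproducible from ``spec.seed``.
    """
    rng = np.random.default_rng(spec.seed)
    lex_terms, bg_terms = _vocabularies(spec)

    documents: list[RawDocument] = []
    gold: list[LabelRecord] = []
    n_total = spec.n_relevant + spec.n_irrelevant
    width = len(str(n_total))
    for i in range(n_total):
        label = RELEVANT if i < spec.n_relevant else IRRELEVANT
        rate = spec.enrichment if label == RELEVANT else spec.background_rate
        length = max(MIN_DOC_LENGTH, int(rng.poisson(spec.doc_length_mean)))
        from_lexicon = rng.random(length) < rate
        lex_draws = rng.integers(0, spec.lexicon_size, size=length)
        bg_draws = rng.integers(0, spec.background_vocab_size, size=length)
        tokens = [
            lex_terms[l] if use_lex else bg_terms[b]
            for use_lex, l, b in zip(from_lexicon, lex_draws, bg_draws)
        ]
        doc_id = f"SYN{i:0{width}d}"
        documents.append(RawDocument(doc_id=doc_id, title="", body=" ".join(tokens)))
        gold.append(LabelRecord(doc_id=doc_id, label=label, method="gold"))

    lexicon = Lexicon.from_terms(lex_terms, source_tag=f"synthetic(seed={spec.seed})")
    return documents, gold, lexicon


def generate_gold_subset(
    gold: list[LabelRecord], n: int, seed: int = 0
) -> list[LabelRecord]:
    """Stratified sample of *n* gold records preserving the class ratio.

    Per-class quotas are proportional with largest-remainder rounding, so a
    62-item draw from a 15:47-ratio corpus contains exactly 15 relevant and
    47 irrelevant documents.  Reproducible from ``seed``.
    """
    if not 1 <= n <= len(gold):
        raise ValueError(f"n must be in [1, {len(gold)}], got {n}")
    by_class = {
        cls: [r for r in gold if r.label == cls] for cls in (RELEVANT, IRRELEVANT)
    }
    total = len(gold)
    exact = {cls: n * len(rs) / total for cls, rs in by_class.items()}
    quota = {cls: int(x) for cls, x in exact.items()}
    leftover = n - sum(quota.values())
    for cls, _ in sorted(exact.items(), key=lambda kv: kv[1] - int(kv[1]), reverse=True):
        if leftover == 0:
            break
        quota[cls] += 1
        leftover -= 1
    for cls, q in quota.items():
        if q > len(by_class[cls]):
            raise ValueError(
                f"class {cls} has only {len(by_class[cls])} documents, need {q}"
            )

    rng = np.random.default_rng(seed)
    subset: list[LabelRecord] = []
    for cls in (RELEVANT, IRRELEVANT):
        records = by_class[cls]
        picked = rng.choice(len(records), size=quota[cls], replace=False)
        subset.extend(records[i] for i in sorted(picked))
    return subset
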