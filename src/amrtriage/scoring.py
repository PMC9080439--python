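"""Context-similarity scoring under two document representations.

Two scoring routes produce a per-document relevance score against the
lexicon context document:

``pvdm_cosine``
    A Paragraph Vector–Distributed Memory (PV-DM) model is trained on the
    corpus; each document's trained paragraph vector is compared by cosine
    similarity with the *inferred* vector of the context document.  Scores
    lie in [-1, 1].

``bow_tfidf_mean``
    Documents are represented as TF-IDF weights over the lexicon vocabulary
    only (raw term frequency, smoothed idf ``ln((1+N)/(1+df)) + 1``, no
    length normalization); the score is the arithmetic mean of the
    document's non-zero lexicon weights.  Scores are >= 0.

The PV-DM trainer here is a from-scratch implementation: distributed-memory
paragraph vectors with negative sampling, mean-combined context, linearly
decaying learning rate, single-threaded and fully reproducible from a seed.
Each training step predicts a center word from the average of its window
context word vectors and the document's paragraph vector; inference freezes
the word and output matrices and fits only a new paragraph vector.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy.special import expit
from sklearn.feature_extraction.text import TfidfVectorizer

from .corpus_io import ArticleId
from .preprocess import Lexicon, TokenizedDocument

__all__ = [
    "PVDM_COSINE",
    "BOW_TFIDF_MEAN",
    "EmbeddingParams",
    "EmbeddingModel",
    "DocVector",
    "ScoreRecord",
    "train_pvdm",
    "infer_vector",
    "cosine_similarity",
    "score_corpus_pvdm",
    "tfidf_weights",
    "score_corpus_bow",
]

PVDM_COSINE = "pvdm_cosine"
BOW_TFIDF_MEAN = "bow_tfidf_mean"

_NOISE_EXPONENT = 0.75  # unigram distribution damping for negative sampling


@dataclass(frozen=True)
class EmbeddingParams:
    """PV-DM hyperparameters.

    Defaults are the published configuration of this pipeline: 300-dimensional
    vectors, initial learning rate 0.025 decaying linearly to 0.00025,
    vocabulary pruned below 3 occurrences, 30 epochs, distributed-memory
    architecture (``dm = 1``).  ``workers`` defaults to 1 because
    single-threaded training is bit-reproducible; ``window`` and ``negative``
    follow the customary defaults of paragraph-vector implementations.
    """

    vector_size: int = 300
    alpha: float = 0.025
    min_alpha: float = 0.00025
    min_count: int = 3
    epochs: int = 30
    dm: int = 1
    workers: int = 1
    seed: int = 1
    window: int = 5
    negative: int = 5

    def __post_init__(self) -> None:
        if self.vector_size < 1:
            raise ValueError("vector_size must be positive")
        if not (0 < self.min_alpha <= self.alpha):
            raise ValueError("need 0 < min_alpha <= alpha")
        if self.epochs < 1:
            raise ValueError("epochs must be >= 1")
        if self.dm != 1:
            raise ValueError("only the distributed-memory architecture (dm=1) is supported")
        if self.window < 1 or self.negative < 1:
            raise ValueError("window and negative must be >= 1")


@dataclass(frozen=True)
class DocVector:
    doc_id: ArticleId
    values: np.ndarray

    def __post_init__(self) -> None:
        if not np.all(np.isfinite(self.values)):
            raise ValueError(f"non-finite entries in vector for {self.doc_id!r}")


@dataclass(frozen=True)
class ScoreRecord:
    doc_id: ArticleId
    score: float
    method: str


@dataclass
class EmbeddingModel:
    """A trained PV-DM model: vocabulary, word/output matrices, doc vectors."""

    params: EmbeddingParams
    vocab: dict[str, int]
    word_vectors: np.ndarray       # (V, D) input word embeddings
    output_weights: np.ndarray     # (V, D) negative-sampling output layer
    doc_vectors: np.ndarray        # (N, D) trained paragraph vectors
    doc_ids: tuple[ArticleId, ...]
    noise_cdf: np.ndarray = field(repr=False, default=None)

    _doc_index: dict[ArticleId, int] = field(init=False, repr=False, default=None)

    def __post_init__(self) -> None:
        self._doc_index = {d: i for i, d in enumerate(self.doc_ids)}

    def docvec(self, doc_id: ArticleId) -> DocVector:
        try:
            idx = self._doc_index[doc_id]
        except KeyError:
            raise KeyError(f"{doc_id!r} was not part of the training corpus") from None
        return DocVector(doc_id=doc_id, values=self.doc_vectors[idx].copy())

    def __contains__(self, doc_id: ArticleId) -> bool:
        return doc_id in self._doc_index


def _build_positions(token_ids: list[np.ndarray], window: int):
    """Flatten (center, padded context, mask, doc index) over all documents."""
    centers, ctxs, masks, docidx = [], [], [], []
    width = 2 * window
    for d, ids in enumerate(token_ids):
        n = len(ids)
        if n < 2:
            continue  # a lone in-vocabulary token has no context to learn from
        for t in range(n):
            lo, hi = max(0, t - window), min(n, t + window + 1)
            ctx = np.concatenate([ids[lo:t], ids[t + 1 : hi]])
            pad = width - len(ctx)
            centers.append(ids[t])
            ctxs.append(np.pad(ctx, (0, pad)))
            masks.append(np.pad(np.ones(len(ctx)), (0, pad)))
            docidx.append(d)
    if not centers:
        return None
    return (
        np.asarray(centers, dtype=np.int64),
        np.stack(ctxs).astype(np.int64),
        np.stack(masks).astype(np.float32),
        np.asarray(docidx, dtype=np.int64),
    )


def _scatter_add(target: np.ndarray, idx: np.ndarray, grads: np.ndarray) -> None:
    """``target[idx] += grads`` with repeated indices accumulated.

    Sorting + ``reduceat`` collapses duplicate rows first so the final update
    is a plain fancy-index add; much faster than ``np.add.at`` here.
    """
    order = np.argsort(idx, kind="stable")
    idx_sorted = idx[order]
    uniq, starts = np.unique(idx_sorted, return_index=True)
    target[uniq] += np.add.reduceat(grads[order], starts, axis=0)


def _sgd_epochs(
    positions,
    word_vectors,
    output_weights,
    doc_vectors,
    noise_cdf,
    params: EmbeddingParams,
    rng: np.random.Generator,
    update_words: bool,
    batch_size: int = 512,
):
    """Run negative-sampling SGD epochs over precomputed training positions.

    With ``update_words=False`` only the paragraph vectors move — this is
    the inference mode for unseen documents.
    """
    centers, ctxs, masks, docidx = positions
    n_pos = len(centers)
    k = params.negative
    for epoch in range(params.epochs):
        frac = epoch / max(1, params.epochs - 1) if params.epochs > 1 else 1.0
        lr = np.float32(params.alpha + (params.min_alpha - params.alpha) * frac)
        order = rng.permutation(n_pos)
        for start in range(0, n_pos, batch_size):
            b = order[start : start + batch_size]
            c, cx, m, d = centers[b], ctxs[b], masks[b], docidx[b]
            n_in = m.sum(axis=1) + 1.0  # context words + the doc vector

            h = (word_vectors[cx] * m[..., None]).sum(axis=1)
            h = (h + doc_vectors[d]) / n_in[:, None]

            neg = np.searchsorted(noise_cdf, rng.random((len(b), k))).astype(np.int64)
            tgt = np.concatenate([c[:, None], neg], axis=1)  # (B, 1+k)
            out = output_weights[tgt]                         # (B, 1+k, D)

            f = expit(np.einsum("bd,bkd->bk", h, out))
            g = -f
            g[:, 0] += 1.0  # first target is the observed center word
            g *= lr

            g_h = np.einsum("bk,bkd->bd", g, out) / n_in[:, None]
            _scatter_add(doc_vectors, d, g_h)
            if update_words:
                _scatter_add(
                    output_weights,
                    tgt.ravel(),
                    (g[..., None] * h[:, None, :]).reshape(-1, h.shape[1]),
                )
                _scatter_add(
                    word_vectors,
                    cx.ravel(),
                    (g_h[:, None, :] * m[..., None]).reshape(-1, h.shape[1]),
                )


def train_pvdm(corpus: list[TokenizedDocument], params: EmbeddingParams) -> EmbeddingModel:
    """Train a PV-DM model on a tokenized corpus.

    Builds the vocabulary with ``min_count`` pruning, then runs
    negative-sampling SGD jointly over word vectors, the output layer, and
    one paragraph vector per document.  Training with a fixed ``seed`` and
    ``workers = 1`` is bit-reproducible.
    """
    docs = [d for d in corpus if not d.is_empty]
    if len(docs) < 2:
        raise ValueError("PV-DM training needs at least 2 non-empty documents")

    counts: dict[str, int] = {}
    for doc in docs:
        for tok in doc.tokens:
            counts[tok] = counts.get(tok, 0) + 1
    vocab_tokens = sorted(t for t, c in counts.items() if c >= params.min_count)
    if not vocab_tokens:
        raise ValueError(
            f"vocabulary is empty after pruning words with count < {params.min_count}"
        )
    vocab = {t: i for i, t in enumerate(vocab_tokens)}

    freq = np.array([counts[t] for t in vocab_tokens], dtype=np.float64)
    noise = freq ** _NOISE_EXPONENT
    noise_cdf = np.cumsum(noise / noise.sum())
    noise_cdf[-1] = 1.0

    token_ids = [
        np.array([vocab[t] for t in doc.tokens if t in vocab], dtype=np.int64)
        for doc in docs
    ]

    rng = np.random.default_rng(params.seed)
    D, V, N = params.vector_size, len(vocab), len(docs)
    word_vectors = ((rng.random((V, D)) - 0.5) / D).astype(np.float32)
    doc_vectors = ((rng.random((N, D)) - 0.5) / D).astype(np.float32)
    output_weights = np.zeros((V, D), dtype=np.float32)

    positions = _build_positions(token_ids, params.window)
    if positions is not None:
        _sgd_epochs(
            positions, word_vectors, output_weights, doc_vectors,
            noise_cdf, params, rng, update_words=True,
        )

    return EmbeddingModel(
        params=params,
        vocab=vocab,
        word_vectors=word_vectors,
        output_weights=output_weights,
        doc_vectors=doc_vectors,
        doc_ids=tuple(d.doc_id for d in docs),
        noise_cdf=noise_cdf,
    )


def infer_vector(
    model: EmbeddingModel,
    doc: TokenizedDocument,
    infer_epochs: int | None = None,
    seed: int = 0,
) -> DocVector:
    """Infer a paragraph vector for a document not seen in training.

    Word and output matrices stay frozen; a fresh paragraph vector is fitted
    by the same SGD procedure for ``infer_epochs`` epochs (defaults to the
    training epoch count).  Deterministic for a fixed seed.  A document with
    no in-vocabulary tokens yields its random initialization, with a warning.
    """
    if model.doc_vectors is None or not len(model.doc_ids):
        raise RuntimeError("model has not been trained")
    if doc.is_empty:
        raise ValueError(f"cannot infer a vector for empty document {doc.doc_id!r}")

    params = model.params if infer_epochs is None else replace(model.params, epochs=infer_epochs)
    rng = np.random.default_rng(seed)
    D = model.params.vector_size
    vec = ((rng.random((1, D)) - 0.5) / D).astype(np.float32)

    ids = np.array([model.vocab[t] for t in doc.tokens if t in model.vocab], dtype=np.int64)
    positions = _build_positions([ids], model.params.window)
    if positions is None:
        warnings.warn(
            f"document {doc.doc_id!r} has no in-vocabulary context; "
            "returning an uninformed vector"
        )
        return DocVector(doc_id=doc.doc_id, values=vec[0].astype(np.float32))

    _sgd_epochs(
        positions, model.word_vectors, model.output_weights, vec,
        model.noise_cdf, params, rng, update_words=False,
    )
    return DocVector(doc_id=doc.doc_id, values=vec[0])


def cosine_similarity(u: np.ndarray, v: np.ndarray) -> float:
    """Cosine of the angle between two vectors: u.v / (|u||v|), in [-1, 1]."""
    u = np.asarray(u, dtype=np.float64)
    v = np.asarray(v, dtype=np.float64)
    if u.shape != v.shape:
        raise ValueError(f"length mismatch: {u.shape} vs {v.shape}")
    nu, nv = np.linalg.norm(u), np.linalg.norm(v)
    if nu == 0.0 or nv == 0.0:
        raise ValueError("cosine similarity is undefined for a zero vector")
    return float(np.clip(u @ v / (nu * nv), -1.0, 1.0))


def score_corpus_pvdm(
    model: EmbeddingModel,
    corpus: list[TokenizedDocument],
    context: TokenizedDocument,
    infer_epochs: int | None = None,
    seed: int = 0,
    center: bool = True,
) -> list[ScoreRecord]:
    """Score every corpus document against the context document.

    Corpus documents use their trained paragraph vectors; the context
    document's vector is inferred from the frozen model.

    By default (``center=True``) the corpus-mean paragraph vector is
    subtracted from every vector — documents and context alike — before the
    cosine is taken.  Negative-sampling SGD gives all paragraph vectors a
    large shared displacement that carries no topical information; left in
    place it compresses every cosine toward a common constant and buries the
    relevance signal.  Centering removes exactly that component and leaves
    scores in [-1, 1].
    """
    missing = [d.doc_id for d in corpus if d.doc_id not in model]
    if missing:
        raise ValueError(f"documents not in the trained model: {missing[:5]}")
    ctx = infer_vector(model, context, infer_epochs=infer_epochs, seed=seed)
    doc_vecs = np.stack([model.docvec(d.doc_id).values for d in corpus])
    ctx_vec = ctx.values.astype(np.float64)
    if center:
        mu = doc_vecs.mean(axis=0)
        doc_vecs = doc_vecs - mu
        ctx_vec = ctx_vec - mu
    return [
        ScoreRecord(
            doc_id=d.doc_id,
            score=cosine_similarity(vec, ctx_vec),
            method=PVDM_COSINE,
        )
        for d, vec in zip(corpus, doc_vecs)
    ]


def _identity_analyzer(tokens):
    return tokens


def tfidf_weights(corpus: list[TokenizedDocument], lexicon: Lexicon) -> pd.DataFrame:
    """TF-IDF weight table restricted to the lexicon vocabulary.

    Rows are documents (corpus order), columns the lexicon terms in
    lexicographic order.  Entries are raw term frequency times the smoothed
    inverse document frequency ``ln((1 + N)/(1 + df)) + 1``; document
    frequencies count over the whole corpus.  No length normalization is
    applied — the downstream mean-threshold consumes score order, and raw
    weights keep the table interpretable.  Tokens outside the lexicon never
    influence a row.
    """
    if not corpus:
        raise ValueError("corpus must be non-empty")
    terms = list(lexicon.sorted_terms())
    vectorizer = TfidfVectorizer(
        analyzer=_identity_analyzer,
        vocabulary=terms,
        norm=None,
        smooth_idf=True,
        sublinear_tf=False,
    )
    matrix = vectorizer.fit_transform([list(d.tokens) for d in corpus])
    return pd.DataFrame(
        matrix.toarray(),
        index=[d.doc_id for d in corpus],
        columns=terms,
    )


def score_corpus_bow(weights: pd.DataFrame, mean_over: str = "present") -> list[ScoreRecord]:
    """Mean TF-IDF weight per document over its lexicon terms.

    ``mean_over="present"`` (default) averages over the terms that actually
    occur in the document, so the score reflects how heavily the document
    uses the vocabulary it shares with the lexicon rather than scaling with
    lexicon size; ``"all"`` divides by the full lexicon width instead.
    Documents containing no lexicon term score 0.
    """
    if mean_over not in ("present", "all"):
        raise ValueError(f"mean_over must be 'present' or 'all', got {mean_over!r}")
    values = weights.to_numpy()
    if mean_over == "all":
        scores = values.mean(axis=1)
    else:
        nonzero = (values > 0).sum(axis=1)
        scores = np.where(nonzero > 0, values.sum(axis=1) / np.maximum(nonzero, 1), 0.0)
    return [
        ScoreRecord(doc_id=doc_id, score=float(s), method=BOW_TFIDF_MEAN)
        for doc_id, s in zip(weights.index, scores)
    ]
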