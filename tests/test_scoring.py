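"""Embedding training, cosine scoring, and TF-IDF mean-weight scoring."""

import math
import warnings

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.stats import binomtest

from amrtriage.preprocess import Lexicon, TokenizedDocument, build_context_document, tokenize_corpus
from amrtriage.scoring import (
    BOW_TFIDF_MEAN,
    PVDM_COSINE,
    EmbeddingParams,
    cosine_similarity,
    infer_vector,
    score_corpus_bow,
    score_corpus_pvdm,
    tfidf_weights,
    train_pvdm,
)
from amrtriage.synthetic_data import SyntheticSpec, generate_corpus

#: fast settings for determinism checks, where representation quality is moot
FAST = dict(vector_size=32, epochs=8, min_count=1, window=5, negative=5)
FAST_SPEC = dict(n_relevant=8, n_irrelevant=8, lexicon_size=10,
                 background_vocab_size=50, doc_length_mean=40)

#: reduced-scale settings for multi-seed representation properties; sized so
#: the word vectors are trained well enough for paragraph-vector geometry to
#: behave as it does at full corpus scale
SWEEP_PARAMS = dict(vector_size=100, epochs=30, min_count=3)
SWEEP_SPEC = dict(n_relevant=25, n_irrelevant=25, lexicon_size=30,
                  background_vocab_size=250, doc_length_mean=120)
N_SWEEP_SEEDS = 20


def _fast_pipeline(seed: int):
    documents, gold, lexicon = generate_corpus(SyntheticSpec(seed=seed, **FAST_SPEC))
    tokenized = tokenize_corpus(documents, lexicon)
    model = train_pvdm(tokenized, EmbeddingParams(seed=seed, **FAST))
    return tokenized, gold, lexicon, model


@pytest.fixture(scope="module")
def seed_sweep():
    """Twenty independently seeded corpora with trained PV-DM models."""
    runs = []
    for seed in range(N_SWEEP_SEEDS):
        documents, gold, lexicon = generate_corpus(SyntheticSpec(seed=seed, **SWEEP_SPEC))
        tokenized = tokenize_corpus(documents, lexicon)
        model = train_pvdm(tokenized, EmbeddingParams(seed=seed, **SWEEP_PARAMS))
        runs.append({"tokenized": tokenized, "gold": gold, "lexicon": lexicon,
                     "model": model, "seed": seed})
    return runs


class TestCosine:
    @pytest.mark.parametrize(
        "u, v, expected",
        [
            ([1, 0], [1, 0], 1.0),
            ([1, 0], [0, 1], 0.0),
            ([1, 2, 3], [4, 5, 6], 32 / math.sqrt(1078)),
            ([1, 1], [-1, -1], -1.0),
        ],
    )
    def test_known_values(self, u, v, expected):
        assert cosine_similarity(np.array(u), np.array(v)) == pytest.approx(
            expected, abs=1e-4
        )

    def test_zero_vector_undefined(self):
        with pytest.raises(ValueError, match="zero vector"):
            cosine_similarity(np.zeros(3), np.ones(3))

    def test_length_mismatch(self):
        with pytest.raises(ValueError, match="mismatch"):
            cosine_similarity(np.ones(2), np.ones(3))


def tfidf_oracle(token_lists, terms):
    """Brute-force tf * idf with smoothed idf ln((1+N)/(1+df)) + 1."""
    n = len(token_lists)
    table = []
    for tokens in token_lists:
        row = []
        for term in sorted(terms):
            df = sum(term in toks for toks in token_lists)
            idf = math.log((1 + n) / (1 + df)) + 1
            row.append(tokens.count(term) * idf)
        table.append(row)
    return np.array(table)


class TestTfidf:
    def test_everywhere_term_has_unit_idf(self):
        docs = [TokenizedDocument(f"d{i}", ("plasmid",) * (i + 1)) for i in range(3)]
        lex = Lexicon(terms=("plasmid",))
        weights = tfidf_weights(docs, lex)
        # idf = ln(4/4) + 1 = 1, so the weight is the raw count
        assert list(weights["plasmid"]) == [1.0, 2.0, 3.0]

    def test_absent_term_weighs_zero(self):
        docs = [TokenizedDocument("d1", ("plasmid",)), TokenizedDocument("d2", ("other",))]
        lex = Lexicon(terms=("plasmid",))
        assert tfidf_weights(docs, lex).loc["d2", "plasmid"] == 0.0

    def test_hand_computed_three_document_corpus(self):
        token_lists = [
            ["efflux", "efflux", "pump"],
            ["efflux", "plasmid"],
            ["unrelated", "words", "only"],
        ]
        terms = ["efflux", "plasmid", "pump"]
        docs = [TokenizedDocument(f"d{i}", tuple(t)) for i, t in enumerate(token_lists)]
        weights = tfidf_weights(docs, Lexicon(terms=tuple(terms)))
        np.testing.assert_allclose(
            weights.to_numpy(), tfidf_oracle(token_lists, terms), atol=1e-12
        )

    @given(
        st.lists(
            st.lists(st.sampled_from(["t0", "t1", "t2", "x", "y", "z"]),
                     min_size=1, max_size=12),
            min_size=1, max_size=5,
        )
    )
    @settings(max_examples=60, deadline=None)
    def test_matches_brute_force_oracle(self, token_lists):
        terms = ["t0", "t1", "t2"]
        docs = [TokenizedDocument(f"d{i}", tuple(t)) for i, t in enumerate(token_lists)]
        weights = tfidf_weights(docs, Lexicon(terms=tuple(terms)))
        np.testing.assert_allclose(
            weights.to_numpy(), tfidf_oracle(token_lists, terms), atol=1e-10
        )

    def test_non_lexicon_tokens_never_affect_rows(self):
        base = [TokenizedDocument("d1", ("plasmid", "efflux")),
                TokenizedDocument("d2", ("plasmid",))]
        noisy = [TokenizedDocument("d1", ("plasmid", "noise", "efflux", "more")),
                 TokenizedDocument("d2", ("plasmid", "junk"))]
        lex = Lexicon(terms=("efflux", "plasmid"))
        pd.testing.assert_frame_equal(tfidf_weights(base, lex), tfidf_weights(noisy, lex))


class TestBowScores:
    def _weights(self, rows, terms=("a", "b", "c")):
        return pd.DataFrame(rows, index=[f"d{i}" for i in range(len(rows))],
                            columns=list(terms))

    def test_mean_over_present_terms(self):
        records = score_corpus_bow(self._weights([[0.2, 0.4, 0.0]]))
        assert records[0].score == pytest.approx(0.3)
        assert records[0].method == BOW_TFIDF_MEAN

    def test_no_lexicon_terms_scores_zero(self):
        assert score_corpus_bow(self._weights([[0.0, 0.0, 0.0]]))[0].score == 0.0

    def test_identical_profiles_score_equally(self):
        records = score_corpus_bow(self._weights([[0.5, 0.0, 0.1], [0.5, 0.0, 0.1]]))
        assert records[0].score == records[1].score

    def test_mean_over_all_divides_by_lexicon_width(self):
        records = score_corpus_bow(self._weights([[0.2, 0.4, 0.0]]), mean_over="all")
        assert records[0].score == pytest.approx(0.2)

    def test_scores_non_negative_property(self):
        rng = np.random.default_rng(0)
        weights = self._weights(rng.random((10, 3)) * 5)
        assert all(r.score >= 0 for r in score_corpus_bow(weights))


class TestTrainPvdm:
    def test_vector_dimensionality_matches_params(self):
        documents, _, lexicon = generate_corpus(
            SyntheticSpec(n_relevant=20, n_irrelevant=20, lexicon_size=20,
                          background_vocab_size=100, doc_length_mean=60, seed=3)
        )
        tokenized = tokenize_corpus(documents, lexicon)
        model = train_pvdm(tokenized, EmbeddingParams(seed=3, epochs=5))
        assert model.doc_vectors.shape == (40, 300)
        assert model.docvec(tokenized[0].doc_id).values.shape == (300,)

    def test_fixed_seed_single_worker_is_reproducible(self):
        tok, _, _, model1 = _fast_pipeline(seed=11)
        model2 = train_pvdm(tok, EmbeddingParams(seed=11, **FAST))
        np.testing.assert_array_equal(model1.doc_vectors, model2.doc_vectors)
        np.testing.assert_array_equal(model1.word_vectors, model2.word_vectors)

    def test_single_document_corpus_rejected(self):
        doc = TokenizedDocument("d1", ("a", "b", "c"))
        with pytest.raises(ValueError, match="at least 2"):
            train_pvdm([doc], EmbeddingParams(**FAST))

    def test_empty_vocabulary_after_pruning_rejected(self):
        docs = [TokenizedDocument("d1", ("a", "b")), TokenizedDocument("d2", ("c", "d"))]
        with pytest.raises(ValueError, match="min_count|vocabulary"):
            train_pvdm(docs, EmbeddingParams(vector_size=8, min_count=3))

    def test_invalid_params_rejected(self):
        with pytest.raises(ValueError):
            EmbeddingParams(vector_size=0)
        with pytest.raises(ValueError):
            EmbeddingParams(min_alpha=0.5, alpha=0.1)
        with pytest.raises(ValueError):
            EmbeddingParams(dm=0)


class TestInferVector:
    def test_deterministic_for_fixed_seed(self, small_trained):
        model = small_trained["model"]
        ctx = build_context_document(small_trained["lexicon"])
        v1 = infer_vector(model, ctx, seed=5)
        v2 = infer_vector(model, ctx, seed=5)
        np.testing.assert_array_equal(v1.values, v2.values)

    def test_out_of_vocabulary_document_warns_but_returns(self, small_trained):
        doc = TokenizedDocument("oov", ("zzz_never_seen", "also_unseen"))
        with pytest.warns(UserWarning, match="no in-vocabulary"):
            vec = infer_vector(small_trained["model"], doc, seed=1)
        assert vec.values.shape == (small_trained["model"].params.vector_size,)

    def test_training_document_reinfers_near_its_own_vector(self, seed_sweep):
        """Over many seeds, an inferred training document usually lands closer
        to its own trained vector than to an opposite-class document's
        (majority vote by one-sided sign test)."""
        wins = 0
        for run in seed_sweep:
            model, tokenized = run["model"], run["tokenized"]
            probe, other = tokenized[0], tokenized[-1]
            # compare in the centered geometry the scorer uses: the corpus-mean
            # paragraph vector is shared drift, not topical signal
            mu = model.doc_vectors.mean(axis=0)
            inferred = infer_vector(model, probe, seed=run["seed"]).values - mu
            own = cosine_similarity(inferred, model.docvec(probe.doc_id).values - mu)
            cross = cosine_similarity(inferred, model.docvec(other.doc_id).values - mu)
            wins += own > cross
        assert binomtest(wins, len(seed_sweep), 0.5, alternative="greater").pvalue < 0.05


class TestScoreCorpusPvdm:
    def test_lexicon_rich_documents_outscore_lexicon_poor(self, seed_sweep):
        """Mean score of the enriched class exceeds the background class in
        significantly more than half of the seeds (one-sided sign test)."""
        wins = 0
        for run in seed_sweep:
            scores = score_corpus_pvdm(
                run["model"], run["tokenized"],
                build_context_document(run["lexicon"]), seed=run["seed"],
            )
            by_id = {r.doc_id: r.score for r in scores}
            labels = {r.doc_id: r.label for r in run["gold"]}
            rich = np.mean([s for i, s in by_id.items() if labels[i] == 0])
            poor = np.mean([s for i, s in by_id.items() if labels[i] == 1])
            wins += rich > poor
        assert binomtest(wins, len(seed_sweep), 0.5, alternative="greater").pvalue < 0.05

    def test_scores_within_cosine_range(self, small_trained):
        scores = score_corpus_pvdm(
            small_trained["model"], small_trained["tokenized"],
            build_context_document(small_trained["lexicon"]), seed=0,
        )
        assert all(-1.0 <= r.score <= 1.0 for r in scores)
        assert all(r.method == PVDM_COSINE for r in scores)
        assert len(scores) == len(small_trained["tokenized"])

    def test_near_identical_documents_score_nearly_equally(self):
        ctx_tokens = tuple(f"term{i:02d}" for i in range(20))
        docs = [TokenizedDocument(f"d{i}", ctx_tokens) for i in range(6)]
        model = train_pvdm(docs, EmbeddingParams(vector_size=16, epochs=40,
                                                 min_count=1, seed=0))
        lex = Lexicon(terms=ctx_tokens)
        scores = score_corpus_pvdm(model, docs, build_context_document(lex),
                                   seed=0, center=False)
        values = [r.score for r in scores]
        assert max(values) - min(values) < 0.2

    def test_unseen_document_rejected(self, small_trained):
        stranger = TokenizedDocument("stranger", ("some", "tokens"))
        with pytest.raises(ValueError, match="not in the trained model"):
            score_corpus_pvdm(
                small_trained["model"], [stranger],
                build_context_document(small_trained["lexicon"]),
            )
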