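"""RBF-kernel SVM on weak labels with cross-validated grid search.

Documents are featurized as TF-IDF weights over the lexicon vocabulary (the
same table the bag-of-words scorer uses).  An expert-labeled test set is
excluded from training; hyperparameters C and gamma are selected by mean
5-fold stratified cross-validation accuracy over a log grid, with ties
broken toward the smaller C and then the smaller gamma, and the winning
configuration is refit on all training data.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import joblib
import numpy as np
import pandas as pd
from sklearn.model_selection import StratifiedKFold, cross_val_score
from sklearn.svm import SVC

from .corpus_io import ArticleId
from .labeling import LabelRecord
from .preprocess import Lexicon, TokenizedDocument
from .scoring import tfidf_weights

__all__ = [
    "MODEL_FORMAT_VERSION",
    "SvmConfig",
    "TrainedClassifier",
    "featurize",
    "train_svm",
    "predict",
    "save_model",
    "load_model",
]

MODEL_FORMAT_VERSION = 1

#: log grid bracketing the usual RBF operating regimes; "auto" = 1/n_features
DEFAULT_C_GRID = (0.1, 1.0, 10.0, 100.0)
DEFAULT_GAMMA_GRID = (1e-3, 1e-2, 1e-1, 1.0, "auto")


@dataclass(frozen=True)
class SvmConfig:
    kernel: str = "rbf"
    C_grid: tuple = DEFAULT_C_GRID
    gamma_grid: tuple = DEFAULT_GAMMA_GRID
    folds: int = 5
    seed: int = 0

    def __post_init__(self) -> None:
        if self.kernel != "rbf":
            raise ValueError("only the RBF kernel is supported")
        if self.folds < 2:
            raise ValueError("folds must be >= 2")
        if not self.C_grid or not self.gamma_grid:
            raise ValueError("hyperparameter grids must be non-empty")
        if any(c <= 0 for c in self.C_grid):
            raise ValueError("C values must be positive")


@dataclass
class TrainedClassifier:
    estimator: SVC
    C: float
    gamma: float
    cv_score: float
    feature_terms: tuple[str, ...]
    config: SvmConfig
    training_ids: tuple[ArticleId, ...] = field(default=(), repr=False)


def featurize(corpus: list[TokenizedDocument], lexicon: Lexicon) -> pd.DataFrame:
    """TF-IDF feature table over the lexicon vocabulary (lexicographic columns).

    Rows with no lexicon term are all-zero but retained: the classifier must
    see off-topic documents too.
    """
    return tfidf_weights(corpus, lexicon)


def _resolve_gamma(gamma, n_features: int) -> float:
    if gamma == "auto":
        return 1.0 / n_features
    g = float(gamma)
    if g <= 0:
        raise ValueError("gamma values must be positive")
    return g


def train_svm(
    features: pd.DataFrame,
    labels: list[LabelRecord],
    config: SvmConfig = SvmConfig(),
    exclude_ids: set[ArticleId] = frozenset(),
) -> TrainedClassifier:
    """Grid-search and fit an RBF SVM on weak labels.

    Rows whose ids are in ``exclude_ids`` (the expert test set) are removed
    before anything is fit, so no held-out document leaks into model
    selection or the final refit.  Each (C, gamma) cell is scored by mean
    stratified k-fold accuracy with a fixed shuffle seed; the best cell wins,
    ties going to the smaller C, then the smaller gamma.
    """
    label_by_id = {r.doc_id: r.label for r in labels}
    missing = [i for i in features.index if i not in label_by_id]
    if missing:
        raise ValueError(f"no label for documents: {missing[:5]}")
    keep = [i for i in features.index if i not in exclude_ids]
    if not keep:
        raise ValueError("every document was excluded; nothing to train on")

    X = features.loc[keep].to_numpy()
    y = np.array([label_by_id[i] for i in keep])

    class_counts = np.bincount(y, minlength=2)
    if class_counts.min() == 0:
        raise ValueError(
            "training set is single-class after exclusions "
            f"(counts: relevant={class_counts[0]}, irrelevant={class_counts[1]})"
        )
    if config.folds > class_counts.min():
        raise ValueError(
            f"{config.folds}-fold CV impossible: minority class has "
            f"only {class_counts.min()} training documents"
        )

    cv = StratifiedKFold(n_splits=config.folds, shuffle=True, random_state=config.seed)
    n_features = X.shape[1]

    best = None  # (score, C, resolved_gamma)
    for C in sorted(float(c) for c in config.C_grid):
        for gamma in sorted(_resolve_gamma(g, n_features) for g in config.gamma_grid):
            clf = SVC(kernel="rbf", C=C, gamma=gamma)
            score = float(np.mean(cross_val_score(clf, X, y, cv=cv, scoring="accuracy")))
            if best is None or score > best[0] + 1e-12:
                best = (score, C, gamma)

    cv_score, C, gamma = best
    estimator = SVC(kernel="rbf", C=C, gamma=gamma).fit(X, y)
    return TrainedClassifier(
        estimator=estimator,
        C=C,
        gamma=gamma,
        cv_score=cv_score,
        feature_terms=tuple(features.columns),
        config=config,
        training_ids=tuple(keep),
    )


def predict(model: TrainedClassifier, features: pd.DataFrame) -> list[LabelRecord]:
    """Predict relevance labels for a feature table.

    The table's columns must match the model's feature terms exactly
    (same terms, same order).  The decision-function value is carried in the
    record's ``score`` field.
    """
    if tuple(features.columns) != model.feature_terms:
        raise ValueError(
            f"feature columns ({len(features.columns)}) do not match the model's "
            f"training features ({len(model.feature_terms)})"
        )
    X = features.to_numpy()
    y = model.estimator.predict(X)
    margins = model.estimator.decision_function(X)
    return [
        LabelRecord(doc_id=i, label=int(lab), score=float(m), method="svm")
        for i, lab, m in zip(features.index, y, margins)
    ]


def save_model(model: TrainedClassifier, path: str | Path) -> None:
    """Persist a trained classifier to a single artifact file."""
    joblib.dump(
        {
            "format_version": MODEL_FORMAT_VERSION,
            "estimator": model.estimator,
            "C": model.C,
            "gamma": model.gamma,
            "cv_score": model.cv_score,
            "feature_terms": list(model.feature_terms),
            "config": {
                "kernel": model.config.kernel,
                "C_grid": list(model.config.C_grid),
                "gamma_grid": list(model.config.gamma_grid),
                "folds": model.config.folds,
                "seed": model.config.seed,
            },
            "training_ids": list(model.training_ids),
        },
        path,
    )


def load_model(path: str | Path) -> TrainedClassifier:
    payload = joblib.load(path)
    if payload.get("format_version") != MODEL_FORMAT_VERSION:
        raise ValueError(f"unsupported model format: {payload.get('format_version')!r}")
    cfg = dict(payload["config"])
    cfg["C_grid"] = tuple(cfg["C_grid"])
    cfg["gamma_grid"] = tuple(cfg["gamma_grid"])
    return TrainedClassifier(
        estimator=payload["estimator"],
        C=payload["C"],
        gamma=payload["gamma"],
        cv_score=payload["cv_score"],
        feature_terms=tuple(payload["feature_terms"]),
        config=SvmConfig(**cfg),
        training_ids=tuple(payload["training_ids"]),
    )
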