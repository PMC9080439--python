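"""Weak labeling of scored documents by arithmetic-mean thresholding.

The corpus-wide arithmetic mean of the context-similarity scores is the
decision boundary: a document scoring at or above the mean is labeled
relevant (class 0), below it irrelevant (class 1).  The same rule applies to
both scoring methods; ties at the mean go to relevant.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

from .corpus_io import ArticleId
from .scoring import ScoreRecord

__all__ = ["RELEVANT", "IRRELEVANT", "LabelRecord", "ThresholdSummary", "mean_threshold_label"]

RELEVANT = 0
IRRELEVANT = 1


@dataclass(frozen=True)
class LabelRecord:
    """A binary relevance label (0 = relevant, 1 = irrelevant) for a document."""

    doc_id: ArticleId
    label: int
    score: float = math.nan
    method: str = "gold"

    def __post_init__(self) -> None:
        if self.label not in (RELEVANT, IRRELEVANT):
            raise ValueError(f"label must be 0 or 1, got {self.label!r}")


@dataclass(frozen=True)
class ThresholdSummary:
    mean_score: float
    n_relevant: int
    n_irrelevant: int
    method: str


def mean_threshold_label(
    scores: list[ScoreRecord],
) -> tuple[ThresholdSummary, list[LabelRecord]]:
    """Label every scored document against the corpus-mean threshold.

    All records must carry the same scoring method.  The threshold is the
    arithmetic mean of all scores; class 0 (relevant) is assigned iff
    ``score >= mean``.  The labeling depends only on scores relative to
    their mean, so adding a constant to every score changes nothing.
    """
    if not scores:
        raise ValueError("cannot threshold an empty score list")
    methods = {s.method for s in scores}
    if len(methods) > 1:
        raise ValueError(f"mixed scoring methods in one labeling call: {sorted(methods)}")
    method = scores[0].method

    mean = math.fsum(s.score for s in scores) / len(scores)
    # The rounded quotient can exceed the true mean by one ulp and land above
    # the maximum score; clamp so the mathematical guarantee max >= mean (and
    # hence at least one relevant document) survives floating point.
    mean = min(mean, max(s.score for s in scores))
    labels = [
        LabelRecord(
            doc_id=s.doc_id,
            label=RELEVANT if s.score >= mean else IRRELEVANT,
            score=s.score,
            method=method,
        )
        for s in scores
    ]
    n_rel = sum(1 for r in labels if r.label == RELEVANT)
    summary = ThresholdSummary(
        mean_score=mean,
        n_relevant=n_rel,
        n_irrelevant=len(labels) - n_rel,
        method=method,
    )
    return summary, labels
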