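"""Rocchio relevance feedback: the classic two-level comparator.

Rocchio moves a query vector toward the centroid of judged-relevant
documents and away from the centroid of judged-non-relevant ones,

    q' = a*q + b*centroid(relevant) - c*centroid(nonrelevant),

then ranks documents by cosine similarity to q'. Negative components of
q' are clipped to zero (standard practice in the vector-space model).
Being a two-class method, it consumes multi-level judgments only after
collapsing them to relevant/non-relevant: every level above the bottom
one counts as relevant.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np

from .ranklearn import TrainRecord, to_dense, vectors_dim

__all__ = [
    "RocchioModel",
    "rocchio_fit",
    "rocchio_score",
    "collapse_levels",
    "RocchioRanker",
]

# classic SMART weights
DEFAULT_A, DEFAULT_B, DEFAULT_C = 1.0, 0.75, 0.15


@dataclass
class RocchioModel:
    vector: np.ndarray
    a: float
    b: float
    c: float


def rocchio_fit(
    query_vector: Mapping[int, float] | None,
    relevant: Sequence[Mapping[int, float]],
    nonrelevant: Sequence[Mapping[int, float]],
    a: float = DEFAULT_A,
    b: float = DEFAULT_B,
    c: float = DEFAULT_C,
) -> RocchioModel:
    """Build the modified query vector; empty feedback sets contribute zero."""
    if min(a, b, c) < 0:
        raise ValueError("Rocchio weights must be non-negative")
    if not relevant and not nonrelevant:
        raise ValueError("Rocchio needs at least one judged document")
    dims = [vectors_dim(relevant), vectors_dim(nonrelevant)]
    if query_vector:
        dims.append(max(query_vector) + 1)
    dim = max(dims)
    vec = np.zeros(dim)
    if query_vector:
        for i, v in query_vector.items():
            vec[i] += a * v
    if relevant:
        vec += b * to_dense(list(relevant), dim).mean(axis=0)
    if nonrelevant:
        vec -= c * to_dense(list(nonrelevant), dim).mean(axis=0)
    np.maximum(vec, 0.0, out=vec)
    return RocchioModel(vector=vec, a=a, b=b, c=c)


def rocchio_score(
    model: RocchioModel, vectors: Sequence[Mapping[int, float]]
) -> np.ndarray:
    """Cosine similarity of each document to the modified query (0 for zero vectors)."""
    qnorm = float(np.linalg.norm(model.vector))
    scores = np.zeros(len(vectors))
    if qnorm == 0.0:
        return scores
    for k, vec in enumerate(vectors):
        dot = sum(v * model.vector[i] for i, v in vec.items() if i < len(model.vector))
        norm = np.sqrt(sum(v * v for v in vec.values()))
        scores[k] = dot / (qnorm * norm) if norm > 0 else 0.0
    return scores


def collapse_levels(rank: int, min_rank: int = 1) -> int:
    """Two-level collapse: the bottom level stays 1, everything above becomes 2."""
    return 1 if rank <= min_rank else 2


class RocchioRanker:
    """Adapter giving Rocchio the same fit/score surface as the RankSVM ranker.

    Judged records are collapsed to two levels; in feedback-only mode there
    is no explicit query vector, so the query weight a defaults to 0.
    """

    def __init__(self, a: float = 0.0, b: float = DEFAULT_B, c: float = DEFAULT_C,
                 query_vector: Mapping[int, float] | None = None):
        self.a, self.b, self.c = a, b, c
        self.query_vector = query_vector
        self.model: RocchioModel | None = None

    def fit(self, records: Sequence[TrainRecord]) -> "RocchioRanker":
        min_rank = min(r.rank for r in records)
        relevant = [dict(r.fvector) for r in records
                    if collapse_levels(r.rank, min_rank) == 2]
        nonrelevant = [dict(r.fvector) for r in records
                       if collapse_levels(r.rank, min_rank) == 1]
        self.model = rocchio_fit(
            self.query_vector, relevant, nonrelevant, self.a, self.b, self.c
        )
        return self

    def score(self, vectors: Sequence[Mapping[int, float]]) -> np.ndarray:
        if self.model is None:
            raise ValueError("ranker is not fitted")
        return rocchio_score(self.model, vectors)
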