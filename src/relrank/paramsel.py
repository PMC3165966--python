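"""Soft-margin parameter selection for RankSVM without a validation set.

A relevance-feedback session has no held-out data to tune C on, so the
rank-selection rule derives a per-record lower bound on C from the dual
box constraint instead: the learned scorer satisfies
|F(x)| <= C * sum_z |K(z, x)| pointwise (all dual coefficients are capped
at C), so asking F to reach each record's relevance level r(x) forces

    C >= C_x = r(x) / sum_z |K(z, x)|,

the sum running over every training record z. The bounds are collected and
the 90th-percentile value is chosen (nearest-rank, counting from the
bottom: 90% of the bounds lie at or below the selected C), giving the
model capacity to satisfy most — not all — of the per-record bounds.
This is a reconstruction of the published selection rule from the dual
box constraint; it is pinned by the comparison harness rather than by a
closed-form reference.

Comparators: the SVM-Light-style default C = 1 / mean K(x, x), the LIBSVM
default C = 1, and grid-search cross-validation over whole rank groups.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable, Sequence

import numpy as np

from .metrics import kendall_tau_paper, ndcg, order_by_score
from .ranklearn import (
    KernelSpec,
    TrainRecord,
    _record_gram,
    ranksvm_learn,
    ranksvm_predict,
    to_dense,
)

__all__ = [
    "CandidateBounds",
    "rank_select_C",
    "default_C_svmlight",
    "default_C_libsvm",
    "cv_select_C",
    "DEFAULT_CV_GRID",
]

DEFAULT_CV_GRID = tuple(10.0 ** k for k in range(-4, 5))

#: A C selector: (records, kernel spec) -> chosen C. All built-ins and any
#: user-supplied strategy (e.g. an external C-selection method) fit this.
Selector = Callable[[Sequence[TrainRecord], KernelSpec], float]


@dataclass
class CandidateBounds:
    """Per-record lower bounds C_x and the percentile-selected value."""

    bounds: np.ndarray
    selected: float
    percentile: float


def rank_select_C(
    records: Sequence[TrainRecord],
    spec: KernelSpec = KernelSpec(),
    percentile: float = 90.0,
) -> CandidateBounds:
    """Validation-free C selection from per-record dual-box lower bounds.

    Requires every kernel value among training records to be strictly
    positive: always true for the RBF kernel, and true for the linear
    kernel on overlapping non-negative feature vectors (TFIDF weights).
    """
    if not records:
        raise ValueError("rank_select_C needs at least one training record")
    if not 0.0 < percentile < 100.0:
        raise ValueError("percentile must lie strictly between 0 and 100")
    X = to_dense([r.fvector for r in records])
    if X.size == 0:
        raise ValueError("all training records are empty vectors")
    G = _record_gram(X, spec)
    if spec.ktype == "linear" and np.any(G <= 0.0):
        raise ValueError(
            "linear-kernel C selection requires K(z, x) > 0 for all record "
            "pairs; ensure non-negative overlapping features or use the RBF kernel"
        )
    denom = np.abs(G).sum(axis=0)
    if np.any(denom <= 0.0):
        raise ValueError("zero kernel-sum denominator for some record")
    levels = np.array([r.rank for r in records], dtype=float)
    bounds = levels / denom
    selected = _nearest_rank(np.sort(bounds), percentile)
    return CandidateBounds(bounds=bounds, selected=float(selected), percentile=percentile)


def _nearest_rank(ascending: np.ndarray, percentile: float) -> float:
    """Value at position ceil(p/100 * m) of the ascending list (1-based)."""
    m = len(ascending)
    k = int(np.ceil(percentile / 100.0 * m))
    k = min(max(k, 1), m)
    return float(ascending[k - 1])


def default_C_svmlight(
    records: Sequence[TrainRecord], spec: KernelSpec = KernelSpec()
) -> float:
    """The SVM-Light-style default: C = 1 / mean self-kernel over records."""
    if not records:
        raise ValueError("need at least one training record")
    X = to_dense([r.fvector for r in records])
    if X.size == 0:
        raise ValueError("all training records are empty vectors")
    if spec.ktype == "linear":
        self_k = np.einsum("ij,ij->i", X, X)
    else:
        self_k = np.ones(len(records))
    mean = float(self_k.mean())
    if mean <= 0.0:
        raise ValueError("zero-norm corpus: mean self-kernel is 0")
    return 1.0 / mean


def default_C_libsvm(*_args, **_kwargs) -> float:
    """The LIBSVM default parameter, C = 1, regardless of the data."""
    return 1.0


def cv_select_C(
    records: Sequence[TrainRecord],
    spec: KernelSpec = KernelSpec(),
    grid: Sequence[float] = DEFAULT_CV_GRID,
    folds: int = 3,
    metric: str = "ndcg",
    seed: int = 0,
) -> float:
    """Grid-search C by group-aware k-fold cross-validation.

    Whole rank groups are assigned to folds (a group's ordering is never
    split), the held-out metric ('ndcg' at n=10 against the records' own
    levels, or 'tau' against the level-induced ordering) is averaged over
    folds, and the best grid value is returned with ties broken toward
    smaller C.
    """
    if folds < 2:
        raise ValueError("folds must be >= 2")
    if not grid:
        raise ValueError("grid must be non-empty")
    if metric not in ("ndcg", "tau"):
        raise ValueError(f"unknown metric {metric!r}")
    groups = sorted({r.rank_group for r in records})
    if len(groups) < folds:
        raise ValueError(
            f"{len(groups)} rank groups cannot be split into {folds} folds"
        )
    rng = np.random.default_rng(seed)
    order = list(rng.permutation(len(groups)))
    assignment = {groups[gi]: f % folds for f, gi in enumerate(order)}

    best_c = None
    best_score = -np.inf
    for c in sorted(grid):
        scores = []
        for fold in range(folds):
            train = [r for r in records if assignment[r.rank_group] != fold]
            held = [r for r in records if assignment[r.rank_group] == fold]
            if not held:
                continue
            try:
                model, _ = ranksvm_learn(train, c, spec)
            except ValueError:
                continue  # fold with no preference pairs
            scores.append(_heldout_score(model, held, metric))
        if scores and float(np.mean(scores)) > best_score:
            best_score = float(np.mean(scores))
            best_c = c
    if best_c is None:
        raise ValueError("no fold produced a usable train/validation split")
    return best_c


def _heldout_score(model, held: Sequence[TrainRecord], metric: str) -> float:
    by_group: dict[str, list[TrainRecord]] = {}
    for r in held:
        by_group.setdefault(r.rank_group, []).append(r)
    vals = []
    for group_records in by_group.values():
        preds = ranksvm_predict(model, [r.fvector for r in group_records])
        scores = {r.id: float(s) for r, s in zip(group_records, preds)}
        predicted, _ = order_by_score(scores)
        if metric == "ndcg":
            level = {r.id: r.rank for r in group_records}
            vals.append(ndcg([(i, level[i]) for i in predicted], n=10))
        else:
            ref_scores = {r.id: float(r.rank) for r in group_records}
            reference, _ = order_by_score(ref_scores)
            if len(reference) < 2:
                continue
            vals.append(kendall_tau_paper(reference, predicted))
    return float(np.mean(vals)) if vals else 0.0
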