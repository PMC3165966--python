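"""Synthetic multi-level ranking data and the desk-scale experiment harness.

The generator emulates feedback data with a known ground truth: n instances
(default 150) of d uniform-[0, 1) features (default 50), a hidden weight
vector w* with entries uniform on [-1, 1], true utilities F*(x) = w*.x, and
ordinal relevance levels obtained by equal-frequency quantile binning of F*
into L levels (level 1 = least relevant; remainders go to the lower bins,
so every level is populated). Labels are exactly monotone in F* by
construction — there is no label noise, only the information loss of
quantization.

Three experiments run on this data, all fully determined by their seed:

* ``run_levels_experiment`` — ranking accuracy as the number of relevance
  levels in the feedback grows (more levels = more pairwise constraints).
* ``run_size_experiment`` — 3-level RankSVM vs 2-level RankSVM vs 2-level
  Rocchio as the amount of feedback grows.
* ``run_paramsel_experiment`` — soft-margin selection strategies compared
  on multi-group data (fixed defaults vs rank-selection vs cross-validation).

Accuracy is always measured against the hidden ground truth on held-out
instances: Kendall's tau (concordant fraction) against the F* ordering,
and NDCG@10 with fixed 3-quantile ratings of F*, so arms trained with
different label granularities are scored on one common scale.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Callable, Mapping, Sequence

import numpy as np
import pandas as pd

from .baselines import RocchioRanker, collapse_levels
from .metrics import kendall_tau_classical, kendall_tau_paper, ndcg, order_by_score
from .paramsel import (
    cv_select_C,
    default_C_libsvm,
    default_C_svmlight,
    rank_select_C,
)
from .ranklearn import KernelSpec, TrainRecord, ranksvm_learn, ranksvm_predict

__all__ = [
    "SyntheticSpec",
    "SyntheticDataset",
    "generate",
    "run_levels_experiment",
    "run_size_experiment",
    "run_paramsel_experiment",
    "summarize",
    "write_results_tsv",
    "RESULT_COLUMNS",
]

RESULT_COLUMNS = [
    "experiment", "L", "train_size", "ranker", "run", "seed", "C",
    "tau_paper", "tau_classical", "ndcg@10", "status",
]

#: ratings used for NDCG evaluation: fixed 3-quantile labels of F*
_EVAL_LEVELS = 3


@dataclass(frozen=True)
class SyntheticSpec:
    """Generation parameters: instance count, feature count, levels, split, seed."""

    n: int = 150
    d: int = 50
    levels: int = 3
    train_size: int = 20
    seed: int = 0

    def __post_init__(self) -> None:
        if self.d < 1:
            raise ValueError("d must be >= 1")
        if self.levels < 2:
            raise ValueError("at least two relevance levels are required")
        if self.n < self.levels:
            raise ValueError("need at least one instance per relevance level")


@dataclass
class SyntheticDataset:
    """Feature matrix, hidden utility, and quantile-binned relevance levels."""

    X: np.ndarray
    w_star: np.ndarray
    true_scores: np.ndarray
    labels: np.ndarray
    ids: list[str]
    group: str
    levels: int

    def labels_for(self, levels: int) -> np.ndarray:
        """Relabel the same instances into a different number of levels."""
        return _quantile_labels(self.true_scores, levels)

    def fvector(self, i: int) -> dict[int, float]:
        return {j: float(v) for j, v in enumerate(self.X[i])}

    def records(
        self,
        indices: Sequence[int],
        labels: np.ndarray | None = None,
        group: str | None = None,
    ) -> list[TrainRecord]:
        """Materialize TrainRecords for a subset of instances."""
        lab = self.labels if labels is None else labels
        grp = self.group if group is None else group
        return [
            TrainRecord(self.ids[i], self.fvector(i), grp, int(lab[i]))
            for i in indices
        ]


def _quantile_labels(scores: np.ndarray, levels: int) -> np.ndarray:
    """Equal-frequency binning, remainder instances going to the lower bins."""
    n = len(scores)
    if n < levels:
        raise ValueError("need at least one instance per relevance level")
    order = np.argsort(scores, kind="stable")
    base, rem = divmod(n, levels)
    labels = np.empty(n, dtype=int)
    start = 0
    for level in range(1, levels + 1):
        size = base + (1 if level <= rem else 0)
        labels[order[start : start + size]] = level
        start += size
    return labels


def generate(spec: SyntheticSpec, group: str = "g0") -> SyntheticDataset:
    """Draw a dataset per the spec; bit-identical for identical seeds."""
    rng = np.random.default_rng(spec.seed)
    X = rng.random((spec.n, spec.d))
    w_star = rng.uniform(-1.0, 1.0, spec.d)
    true_scores = X @ w_star
    labels = _quantile_labels(true_scores, spec.levels)
    ids = [f"x{k:04d}" for k in range(spec.n)]
    return SyntheticDataset(X, w_star, true_scores, labels, ids, group, spec.levels)


# ---------------------------------------------------------------------------
# shared harness plumbing

def _run_seeds(seed: int, runs: int) -> list[int]:
    """Per-run child seeds, each below 2**31, derived from one base seed."""
    return [int(s) % (2**31) for s in np.random.SeedSequence(seed).generate_state(runs)]


def _evaluate(ds: SyntheticDataset, test_idx: np.ndarray, scores: np.ndarray) -> dict:
    """Score a ranking of the test instances against the hidden ground truth."""
    score_map = {ds.ids[i]: float(s) for i, s in zip(test_idx, scores)}
    predicted, _ = order_by_score(score_map)
    truth = {ds.ids[i]: float(ds.true_scores[i]) for i in test_idx}
    reference, _ = order_by_score(truth)
    ratings_all = ds.labels_for(_EVAL_LEVELS)
    ratings = {ds.ids[i]: int(ratings_all[i]) for i in test_idx}
    return {
        "tau_paper": kendall_tau_paper(reference, predicted),
        "tau_classical": kendall_tau_classical(reference, predicted),
        "ndcg@10": ndcg([(i, ratings[i]) for i in predicted], n=10),
    }


def _choose_C(records, spec: KernelSpec, c_strategy) -> float:
    if isinstance(c_strategy, (int, float)):
        return float(c_strategy)
    if c_strategy == "rank-select":
        return rank_select_C(records, spec).selected
    if callable(c_strategy):
        return float(c_strategy(records, spec))
    raise ValueError(f"unknown C strategy {c_strategy!r}")


def _row(**kw) -> dict:
    row = {c: np.nan for c in RESULT_COLUMNS}
    row["status"] = "ok"
    row.update(kw)
    return row


# ---------------------------------------------------------------------------
# experiments

def run_levels_experiment(
    levels_grid: Sequence[int] = (2, 3, 4, 5, 6),
    runs: int = 30,
    base: SyntheticSpec = SyntheticSpec(),
    c_strategy="rank-select",
    kernel: KernelSpec = KernelSpec(),
    seed: int = 0,
) -> pd.DataFrame:
    """Accuracy as a function of the number of relevance levels in the feedback.

    Each run draws one dataset and one train/test split, then relabels the
    same training instances at every level count in the grid, so the arms
    differ only in label granularity.
    """
    if runs < 1:
        raise ValueError("runs must be >= 1")
    rows = []
    for run, run_seed in enumerate(_run_seeds(seed, runs)):
        ds = generate(replace(base, seed=run_seed, levels=max(levels_grid)))
        split_rng = np.random.default_rng(run_seed + 1)
        perm = split_rng.permutation(base.n)
        train_idx, test_idx = perm[: base.train_size], perm[base.train_size :]
        for L in levels_grid:
            labels = ds.labels_for(L)
            row = _row(
                experiment="levels", L=L, train_size=base.train_size,
                ranker="ranksvm", run=run, seed=run_seed,
            )
            train = ds.records(train_idx, labels)
            if len({r.rank for r in train}) < 2:
                row["status"] = "failed: single relevance level in training split"
                rows.append(row)
                continue
            c = _choose_C(train, kernel, c_strategy)
            model, _ = ranksvm_learn(train, c, kernel)
            scores = ranksvm_predict(model, [ds.fvector(i) for i in test_idx])
            row.update(C=c, **_evaluate(ds, test_idx, scores))
            rows.append(row)
    return pd.DataFrame(rows, columns=RESULT_COLUMNS)


def run_size_experiment(
    sizes: Sequence[int] = (10, 20, 40),
    runs: int = 30,
    base: SyntheticSpec = SyntheticSpec(levels=3),
    c_strategy="rank-select",
    kernel: KernelSpec = KernelSpec(),
    queries_per_run: int = 5,
    seed: int = 0,
) -> pd.DataFrame:
    """RankSVM (3- and 2-level labels) vs two-level Rocchio vs feedback size.

    Each run evaluates ``queries_per_run`` independent query datasets (the
    comparison this emulates averaged each training size over a pool of
    queries as well as over repeated runs) and every (run, query) pair
    contributes one row per size and ranker. Training sets are nested
    across sizes within a query; the test set is the complement of the
    largest training size, shared by all arms. Two-level arms collapse
    labels by merging every level above the bottom into 'relevant'.
    """
    if runs < 1:
        raise ValueError("runs must be >= 1")
    max_size = max(sizes)
    rows = []
    draws = [
        (run, qseed)
        for run, run_seed in enumerate(_run_seeds(seed, runs))
        for qseed in _run_seeds(run_seed, queries_per_run)
    ]
    for run, run_seed in draws:
        ds = generate(replace(base, seed=run_seed, levels=3))
        split_rng = np.random.default_rng(run_seed + 1)
        perm = split_rng.permutation(base.n)
        test_idx = perm[max_size:]
        labels3 = ds.labels
        labels2 = np.array([collapse_levels(int(l)) for l in labels3])
        test_vectors = [ds.fvector(i) for i in test_idx]
        for size in sizes:
            train_idx = perm[:size]
            for ranker, labels in (
                ("ranksvm-3level", labels3),
                ("ranksvm-2level", labels2),
                ("rocchio-2level", labels2),
            ):
                row = _row(
                    experiment="size", L=int(labels.max()), train_size=size,
                    ranker=ranker, run=run, seed=run_seed,
                )
                train = ds.records(train_idx, labels)
                if len({r.rank for r in train}) < 2:
                    row["status"] = "failed: single relevance level in training split"
                    rows.append(row)
                    continue
                if ranker == "rocchio-2level":
                    scores = RocchioRanker().fit(train).score(test_vectors)
                else:
                    c = _choose_C(train, kernel, c_strategy)
                    model, _ = ranksvm_learn(train, c, kernel)
                    scores = ranksvm_predict(model, test_vectors)
                    row["C"] = c
                row.update(_evaluate(ds, test_idx, scores))
                rows.append(row)
    return pd.DataFrame(rows, columns=RESULT_COLUMNS)


def default_selectors(cv_seed: int = 0) -> dict[str, Callable]:
    """The comparison slate: fixed defaults, rank-selection, and 3-fold CV.

    Any extra strategy with the (records, kernel_spec) -> C signature can be
    added to the returned mapping before passing it to the harness.
    """
    return {
        "svmlight-default": default_C_svmlight,
        "libsvm-default": lambda recs, spec: default_C_libsvm(),
        "rank-selection": lambda recs, spec: rank_select_C(recs, spec).selected,
        "cv": lambda recs, spec: cv_select_C(recs, spec, seed=cv_seed),
    }


def run_paramsel_experiment(
    selectors: Mapping[str, Callable] | None = None,
    runs: int = 30,
    base: SyntheticSpec = SyntheticSpec(levels=3),
    groups_per_run: int = 6,
    kernel: KernelSpec = KernelSpec(),
    seed: int = 0,
) -> pd.DataFrame:
    """Compare C-selection strategies on multi-group synthetic data.

    Each run draws ``groups_per_run`` independent datasets (one rank group
    each; six by default, mirroring the six-query evaluation blocks of the
    comparison this emulates), pools their training splits into one
    training set, lets each strategy choose C on it, and scores the fitted
    model on each group's held-out instances.
    """
    if runs < 1:
        raise ValueError("runs must be >= 1")
    if selectors is None:
        selectors = default_selectors(cv_seed=seed)
    rows = []
    for run, run_seed in enumerate(_run_seeds(seed, runs)):
        group_seeds = _run_seeds(run_seed, groups_per_run)
        datasets, train, holdout = [], [], []
        for gi, gseed in enumerate(group_seeds):
            ds = generate(replace(base, seed=gseed), group=f"g{gi}")
            split_rng = np.random.default_rng(gseed + 1)
            perm = split_rng.permutation(base.n)
            tr, te = perm[: base.train_size], perm[base.train_size :]
            datasets.append((ds, te))
            train.extend(ds.records(tr))
        if len({r.rank for r in train}) < 2:
            for name in selectors:
                rows.append(_row(
                    experiment="paramsel", L=base.levels,
                    train_size=base.train_size * groups_per_run, ranker=name,
                    run=run, seed=run_seed,
                    status="failed: single relevance level in training split",
                ))
            continue
        for name, select in selectors.items():
            c = float(select(train, kernel))
            model, _ = ranksvm_learn(train, c, kernel)
            per_group = []
            for ds, te in datasets:
                scores = ranksvm_predict(model, [ds.fvector(i) for i in te])
                per_group.append(_evaluate(ds, te, scores))
            mean = {k: float(np.mean([m[k] for m in per_group])) for k in per_group[0]}
            rows.append(_row(
                experiment="paramsel", L=base.levels,
                train_size=base.train_size * groups_per_run, ranker=name,
                run=run, seed=run_seed, C=c, **mean,
            ))
    return pd.DataFrame(rows, columns=RESULT_COLUMNS)


# ---------------------------------------------------------------------------
# reporting

def summarize(results: pd.DataFrame) -> pd.DataFrame:
    """Mean and sd per (experiment, L, train_size, ranker) cell, ok runs only."""
    ok = results[results["status"] == "ok"]
    grouped = ok.groupby(["experiment", "L", "train_size", "ranker"], dropna=False)
    out = grouped[["tau_paper", "tau_classical", "ndcg@10"]].agg(["mean", "std"])
    out.columns = [f"{m}_{s}" for m, s in out.columns]
    return out.reset_index()


def write_results_tsv(results: pd.DataFrame, path) -> None:
    results.to_csv(path, sep="\t", index=False)
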