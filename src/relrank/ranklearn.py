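"""RankSVM: max-margin learning of a rank scoring function from pairwise preferences.

Multi-level ordered training data (records with a rank group and an integer
relevance level, larger = more preferred) is turned into pairwise preference
constraints within each group. The soft-margin primal

    minimize   (1/2)||w||^2 + C * sum_ij xi_ij
    subject to w.(x_i - x_j) >= 1 - xi_ij   for every preferred pair (i over j)
               xi_ij >= 0

is solved through its dual: maximize sum a - (1/2) a'Qa subject to the box
0 <= a_ij <= C, where Q is the Gram matrix of the pairwise difference
vectors under the chosen kernel. There is no intercept: ranking functions
are translation invariant. The learned scorer is

    F(x) = sum_{support pairs} a_ij (K(x_i, x) - K(x_j, x)),

which for the linear kernel collapses to F(x) = w.x with the materialized
weight vector w = sum a_ij (x_i - x_j).

The dual is solved by deterministic cyclic coordinate ascent with closed-form
box-clipped updates, initialized at a = 0, sweeping pairs in a fixed order
(group, preferred id, other id), so learning is bit-reproducible.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np

from .textfeat import FeatureVector, format_sparse, parse_sparse

__all__ = [
    "KernelSpec",
    "TrainRecord",
    "PreferencePair",
    "SupportPair",
    "RankModel",
    "TrainingReport",
    "kernel_eval",
    "make_pairs",
    "ranksvm_learn",
    "ranksvm_predict",
    "read_letor",
    "write_letor",
    "read_model",
    "write_model",
]

DEFAULT_PAIR_CAP = 250_000
_RBF_PAIR_CAP = 10_000  # dense m x m Gram of difference vectors


@dataclass(frozen=True)
class KernelSpec:
    """Kernel choice: 'linear' (a.b) or 'rbf' (exp(-g ||a-b||^2))."""

    ktype: str = "linear"
    g: float = 1.0

    def __post_init__(self) -> None:
        if self.ktype not in ("linear", "rbf"):
            raise ValueError(f"unknown kernel type {self.ktype!r}")
        if self.ktype == "rbf" and not self.g > 0:
            raise ValueError("RBF kernel requires g > 0")


@dataclass(frozen=True)
class TrainRecord:
    """One training instance: id, sparse features, rank group, relevance level."""

    id: str
    fvector: Mapping[int, float]
    rank_group: str
    rank: int


@dataclass(frozen=True)
class PreferencePair:
    """An ordered preference: *preferred* outranks *other* within one group."""

    preferred: TrainRecord
    other: TrainRecord

    def __post_init__(self) -> None:
        if self.preferred.rank_group != self.other.rank_group:
            raise ValueError("preference pairs may not cross rank groups")
        if not self.preferred.rank > self.other.rank:
            raise ValueError("preferred record must have the strictly larger rank")


@dataclass(frozen=True)
class SupportPair:
    """A preference pair retained in the model with its dual coefficient."""

    alpha: float
    preferred: FeatureVector
    other: FeatureVector
    preferred_id: str = ""
    other_id: str = ""


@dataclass
class RankModel:
    kernel: KernelSpec
    C: float
    support_pairs: list[SupportPair]
    weight: FeatureVector | None = None  # materialized for the linear kernel

    def __post_init__(self) -> None:
        for sp in self.support_pairs:
            if not (0.0 < sp.alpha <= self.C * (1 + 1e-9)):
                raise ValueError(
                    f"support coefficient {sp.alpha} outside (0, C={self.C}]"
                )


@dataclass
class TrainingReport:
    """Solver diagnostics: dual objective, per-pair slacks, passes, training tau."""

    dual_objective: float
    slacks: np.ndarray
    iterations: int
    training_tau: float
    converged: bool
    n_pairs: int


# ---------------------------------------------------------------------------
# kernels and vector plumbing

def kernel_eval(a: Mapping[int, float], b: Mapping[int, float], spec: KernelSpec) -> float:
    """Evaluate K(a, b) for sparse vectors."""
    if spec.ktype == "linear":
        if len(b) < len(a):
            a, b = b, a
        return sum(v * b[i] for i, v in a.items() if i in b)
    # rbf
    sq = 0.0
    for i in set(a) | set(b):
        d = a.get(i, 0.0) - b.get(i, 0.0)
        sq += d * d
    return math.exp(-spec.g * sq)


def vectors_dim(vectors: Iterable[Mapping[int, float]]) -> int:
    dim = 0
    for v in vectors:
        if v:
            dim = max(dim, max(v) + 1)
    return dim


def to_dense(vectors: Sequence[Mapping[int, float]], dim: int | None = None) -> np.ndarray:
    """Stack sparse vectors into a dense (n, dim) array."""
    if dim is None:
        dim = vectors_dim(vectors)
    X = np.zeros((len(vectors), dim))
    for r, vec in enumerate(vectors):
        for i, v in vec.items():
            if i >= dim:
                raise ValueError(f"feature index {i} exceeds dimension {dim}")
            X[r, i] = v
    return X


# ---------------------------------------------------------------------------
# pair construction

def make_pairs(records: Sequence[TrainRecord]) -> list[PreferencePair]:
    """All within-group strict-preference pairs, in deterministic order.

    One pair per (i, j) sharing a rank_group with rank(i) > rank(j); equal
    ranks contribute nothing. Order: group, then preferred id, then other id.
    """
    by_group: dict[str, list[TrainRecord]] = {}
    for rec in records:
        by_group.setdefault(rec.rank_group, []).append(rec)
    pairs = []
    for group in sorted(by_group):
        recs = sorted(by_group[group], key=lambda r: r.id)
        for a in recs:
            for b in recs:
                if a.rank > b.rank:
                    pairs.append(PreferencePair(a, b))
    return pairs


# ---------------------------------------------------------------------------
# learning

def ranksvm_learn(
    records: Sequence[TrainRecord],
    C: float,
    spec: KernelSpec = KernelSpec(),
    tol: float = 1e-6,
    max_passes: int = 10_000,
    pair_cap: int = DEFAULT_PAIR_CAP,
) -> tuple[RankModel, TrainingReport]:
    """Fit a RankSVM by coordinate ascent on the boxed dual.

    Parameters
    ----------
    records : training instances with rank groups and integer levels.
    C : soft-margin parameter (> 0); upper box bound on dual coefficients.
    spec : kernel specification.
    tol : maximum KKT violation at which the solver stops.
    max_passes : cap on full sweeps; exceeding it emits a warning.
    pair_cap : hard limit on the number of preference pairs.

    Returns the fitted :class:`RankModel` (support pairs only, i.e. a > 0)
    and a :class:`TrainingReport` with the dual objective, slack variables,
    sweep count and the fraction of training pairs scored concordantly.
    """
    if not C > 0:
        raise ValueError("C must be positive")
    pairs = make_pairs(records)
    if not pairs:
        raise ValueError("no preference information: records yield no preference pairs")
    if len(pairs) > pair_cap:
        raise ValueError(
            f"{len(pairs)} preference pairs exceed the cap of {pair_cap}; "
            "reduce the training set or raise pair_cap explicitly"
        )
    ids = {id(r): k for k, r in enumerate(records)}
    dim = vectors_dim([r.fvector for r in records])
    X = to_dense([r.fvector for r in records], dim)
    if not np.all(np.isfinite(X)):
        raise ValueError("non-finite feature values in training records")
    pi = np.array([ids[id(p.preferred)] for p in pairs])
    oi = np.array([ids[id(p.other)] for p in pairs])

    if spec.ktype == "linear":
        alpha, w, passes, converged = _solve_linear(X, pi, oi, C, tol, max_passes)
        margins = (X[pi] - X[oi]) @ w
        dual_obj = float(alpha.sum() - 0.5 * w @ w)
        weight = {i: float(v) for i, v in enumerate(w) if v != 0.0}
    else:
        if len(pairs) > _RBF_PAIR_CAP:
            raise ValueError(
                f"{len(pairs)} pairs exceed the RBF pair limit of {_RBF_PAIR_CAP}"
            )
        Q = _difference_gram(X, pi, oi, spec)
        alpha, grad, passes, converged = _solve_boxed(Q, C, tol, max_passes)
        margins = grad + 1.0  # Qa
        dual_obj = float(alpha.sum() - 0.5 * alpha @ (margins))
        weight = None

    if not converged:
        warnings.warn(
            f"RankSVM solver did not reach tol={tol} within {max_passes} passes",
            RuntimeWarning,
        )
    slacks = np.maximum(0.0, 1.0 - margins)
    training_tau = float(np.mean(margins > 0.0))
    support = [
        SupportPair(
            alpha=float(min(a, C)),
            preferred=dict(pairs[k].preferred.fvector),
            other=dict(pairs[k].other.fvector),
            preferred_id=pairs[k].preferred.id,
            other_id=pairs[k].other.id,
        )
        for k, a in enumerate(alpha)
        if a > 1e-12 * max(C, 1.0)
    ]
    model = RankModel(kernel=spec, C=C, support_pairs=support, weight=weight)
    report = TrainingReport(
        dual_objective=dual_obj,
        slacks=slacks,
        iterations=passes,
        training_tau=training_tau,
        converged=converged,
        n_pairs=len(pairs),
    )
    return model, report


def _solve_linear_py(D, qdiag, C, tol, max_passes):
    """Coordinate ascent keeping the explicit weight vector w = D'a."""
    m, dim = D.shape
    alpha = np.zeros(m)
    w = np.zeros(dim)
    passes = 0
    converged = False
    while passes < max_passes:
        passes += 1
        max_viol = 0.0
        for p in range(m):
            g = D[p] @ w - 1.0  # gradient of (1/2)a'Qa - sum a
            a_old = alpha[p]
            if a_old <= 0.0:
                viol = max(0.0, -g)
            elif a_old >= C:
                viol = max(0.0, g)
            else:
                viol = abs(g)
            if viol > max_viol:
                max_viol = viol
            if qdiag[p] > 0.0:
                a_new = min(max(a_old - g / qdiag[p], 0.0), C)
            else:
                # zero difference vector: dual is linear in this coordinate
                a_new = C if g < 0.0 else 0.0
            if a_new != a_old:
                w += (a_new - a_old) * D[p]
                alpha[p] = a_new
        if max_viol <= tol:
            converged = True
            break
    return alpha, w, passes, converged


def _solve_boxed_py(Q, qdiag, C, tol, max_passes):
    """Coordinate ascent maintaining the full gradient (kernel path)."""
    m = Q.shape[0]
    alpha = np.zeros(m)
    grad = -np.ones(m)  # Qa - 1
    passes = 0
    converged = False
    while passes < max_passes:
        passes += 1
        max_viol = 0.0
        for p in range(m):
            g = grad[p]
            a_old = alpha[p]
            if a_old <= 0.0:
                viol = max(0.0, -g)
            elif a_old >= C:
                viol = max(0.0, g)
            else:
                viol = abs(g)
            if viol > max_viol:
                max_viol = viol
            if qdiag[p] > 0.0:
                a_new = min(max(a_old - g / qdiag[p], 0.0), C)
            else:
                a_new = C if g < 0.0 else 0.0
            delta = a_new - a_old
            if delta != 0.0:
                grad += delta * Q[:, p]
                alpha[p] = a_new
        if max_viol <= tol:
            converged = True
            break
    return alpha, grad, passes, converged


try:  # JIT the sweep loops; the pure-Python bodies are the reference semantics
    from numba import njit as _njit

    _solve_linear_jit = _njit(cache=False)(_solve_linear_py)
    _solve_boxed_jit = _njit(cache=False)(_solve_boxed_py)
except ImportError:  # pragma: no cover - numba is a declared dependency
    _solve_linear_jit = _solve_linear_py
    _solve_boxed_jit = _solve_boxed_py


def _solve_linear(X, pi, oi, C, tol, max_passes):
    D = np.ascontiguousarray(X[pi] - X[oi])
    qdiag = np.einsum("ij,ij->i", D, D)
    return _solve_linear_jit(D, qdiag, float(C), float(tol), max_passes)


def _solve_boxed(Q, C, tol, max_passes):
    Q = np.ascontiguousarray(Q)
    qdiag = np.ascontiguousarray(np.diag(Q))
    return _solve_boxed_jit(Q, qdiag, float(C), float(tol), max_passes)


def _difference_gram(X, pi, oi, spec: KernelSpec) -> np.ndarray:
    """Gram matrix of pairwise difference vectors in kernel space."""
    G = _record_gram(X, spec)
    return (
        G[np.ix_(pi, pi)] - G[np.ix_(pi, oi)] - G[np.ix_(oi, pi)] + G[np.ix_(oi, oi)]
    )


def _record_gram(X: np.ndarray, spec: KernelSpec) -> np.ndarray:
    if spec.ktype == "linear":
        return X @ X.T
    sq = np.sum(X * X, axis=1)
    d2 = sq[:, None] + sq[None, :] - 2.0 * (X @ X.T)
    np.maximum(d2, 0.0, out=d2)
    return np.exp(-spec.g * d2)


# ---------------------------------------------------------------------------
# prediction

def ranksvm_predict(
    model: RankModel,
    vectors: Sequence[Mapping[int, float]],
    method: str = "auto",
) -> np.ndarray:
    """Score vectors with a fitted model (higher score = more relevant).

    method='auto' uses the materialized weight vector when available
    (linear kernel) and the support-pair kernel expansion otherwise;
    'weight' and 'expansion' force one path (used for cross-checking).
    """
    if method not in ("auto", "weight", "expansion"):
        raise ValueError(f"unknown prediction method {method!r}")
    if method == "weight" and model.weight is None:
        raise ValueError("model has no materialized weight vector")
    if not model.support_pairs and (model.weight is None or method == "expansion"):
        return np.zeros(len(vectors))

    if model.weight is not None and method != "expansion":
        return np.array(
            [
                sum(v * model.weight.get(i, 0.0) for i, v in x.items())
                for x in vectors
            ]
        )

    dim = max(
        vectors_dim(vectors),
        vectors_dim(sp.preferred for sp in model.support_pairs),
        vectors_dim(sp.other for sp in model.support_pairs),
    )
    Xnew = to_dense(list(vectors), dim)
    P = to_dense([sp.preferred for sp in model.support_pairs], dim)
    O = to_dense([sp.other for sp in model.support_pairs], dim)
    a = np.array([sp.alpha for sp in model.support_pairs])
    if model.kernel.ktype == "linear":
        return Xnew @ ((P - O).T @ a)
    Kp = _cross_rbf(P, Xnew, model.kernel.g)
    Ko = _cross_rbf(O, Xnew, model.kernel.g)
    return (Kp - Ko).T @ a


def _cross_rbf(A: np.ndarray, B: np.ndarray, g: float) -> np.ndarray:
    d2 = (
        np.sum(A * A, axis=1)[:, None]
        + np.sum(B * B, axis=1)[None, :]
        - 2.0 * (A @ B.T)
    )
    np.maximum(d2, 0.0, out=d2)
    return np.exp(-g * d2)


# ---------------------------------------------------------------------------
# file formats

def write_letor(records: Sequence[TrainRecord], path: str | Path) -> None:
    """Write records in the sparse 'rank qid:group index:value ... # id' dialect.

    Feature indices are written 1-based as is conventional for this format;
    values use shortest round-tripping precision.
    """
    with open(path, "w", encoding="utf-8") as fh:
        for rec in records:
            feats = " ".join(
                f"{i + 1}:{float(v)!r}" for i, v in sorted(rec.fvector.items())
            )
            line = f"{rec.rank} qid:{rec.rank_group}"
            if feats:
                line += f" {feats}"
            fh.write(f"{line} # {rec.id}\n")


def read_letor(path: str | Path) -> list[TrainRecord]:
    records = []
    for lineno, raw in enumerate(Path(path).read_text(encoding="utf-8").splitlines(), 1):
        line = raw.strip()
        if not line:
            continue
        body, _, comment = line.partition("#")
        parts = body.split()
        if len(parts) < 2 or not parts[1].startswith("qid:"):
            raise ValueError(f"{path}:{lineno}: malformed record {raw!r}")
        rank = int(parts[0])
        group = parts[1][4:]
        vec: FeatureVector = {}
        for pair in parts[2:]:
            idx, _, val = pair.partition(":")
            vec[int(idx) - 1] = float(val)
        rec_id = comment.strip() or f"line{lineno}"
        records.append(TrainRecord(rec_id, vec, group, rank))
    return records


def write_model(model: RankModel, path: str | Path) -> None:
    """Plain-text model file: header, optional weight line, one support pair per line."""
    with open(path, "w", encoding="utf-8") as fh:
        fh.write(f"ktype\t{model.kernel.ktype}\n")
        fh.write(f"g\t{model.kernel.g!r}\n")
        fh.write(f"C\t{model.C!r}\n")
        fh.write(f"pairs\t{len(model.support_pairs)}\n")
        if model.weight is not None:
            fh.write(f"weight\t{format_sparse(model.weight)}\n")
        for sp in model.support_pairs:
            fh.write(
                f"{sp.alpha!r}\t{format_sparse(sp.preferred)}\t"
                f"{format_sparse(sp.other)}\t{sp.preferred_id}\t{sp.other_id}\n"
            )


def read_model(path: str | Path) -> RankModel:
    lines = Path(path).read_text(encoding="utf-8").splitlines()
    header: dict[str, str] = {}
    i = 0
    for key in ("ktype", "g", "C", "pairs"):
        name, _, value = lines[i].partition("\t")
        if name != key:
            raise ValueError(f"{path}: expected header line {key!r}, got {lines[i]!r}")
        header[key] = value
        i += 1
    weight = None
    if i < len(lines) and lines[i].startswith("weight\t"):
        weight = parse_sparse(lines[i].split("\t", 1)[1])
        i += 1
    n_pairs = int(header["pairs"])
    support = []
    for ln in lines[i : i + n_pairs]:
        fields = ln.split("\t")
        if len(fields) < 3:
            raise ValueError(f"{path}: malformed support-pair line {ln!r}")
        alpha = float(fields[0])
        pref = parse_sparse(fields[1])
        other = parse_sparse(fields[2])
        pid = fields[3] if len(fields) > 3 else ""
        oid = fields[4] if len(fields) > 4 else ""
        support.append(SupportPair(alpha, pref, other, pid, oid))
    if len(support) != n_pairs:
        raise ValueError(f"{path}: header promises {n_pairs} pairs, found {len(support)}")
    return RankModel(
        kernel=KernelSpec(header["ktype"], float(header["g"])),
        C=float(header["C"]),
        support_pairs=support,
        weight=weight,
    )
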