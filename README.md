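# relrank — multi-level relevance-feedback ranking

`relrank` is a toolkit for learning document-ranking functions from
*ordinal* relevance feedback, built for interactive literature search:
a user issues a keyword query, judges a handful of results on a graded
scale (e.g. 1 = not relevant, 2 = partially relevant, 3 = highly
relevant), pushes the feedback, and the system re-ranks all candidates
with a function learned from those few judgments — then repeats. Binary
feedback methods (Rocchio and classifier-based relevance feedback) throw
away the ordering information between grades; `relrank` learns from it.

It is aimed at people building or studying retrieval systems over
scientific abstracts: the feature layer is TFIDF over title+abstract text,
and the learn/predict cycle is exposed both as a Python API and as
commands over embedded relational tables, mirroring an in-database
deployment where learning runs directly on stored tables with no
intermediate file export.

## The model

**RankSVM.** Judged documents (x_i, y_i) within one query group induce a
pairwise preference x_i ⊳ x_j whenever y_i > y_j. A linear scoring
function F(x) = w·x is fitted by the soft-margin program

    minimize   ½‖w‖² + C Σ ξ_ij
    subject to w·(x_i − x_j) ≥ 1 − ξ_ij,   ξ_ij ≥ 0   for every preference pair,

solved through its dual — maximize Σα − ½ αᵀQα over the box 0 ≤ α ≤ C,
with Q the Gram matrix of the pairwise difference vectors under a linear
or RBF kernel. The scorer is F(x) = Σ α_ij (K(x_i,x) − K(x_j,x)); for the
linear kernel the weight vector w = Σ α_ij (x_i − x_j) is materialized.
The dual is solved by deterministic cyclic coordinate ascent (no
randomness; bit-reproducible models).

**Validation-free C selection.** A live feedback session has no held-out
data, so C is chosen from the dual box constraint: since every α is capped
at C and kernel values among training records are positive,
|F(x)| ≤ C·Σ_z K(z, x), and asking F to reach each record's relevance
level r(x) gives per-record lower bounds C_x = r(x) / Σ_z K(z, x). The
90th-percentile bound (nearest rank, counting from below) is selected, so
the model gets capacity to satisfy most — not all — of the bounds.
Comparators included: the SVM-Light-style default 1/mean K(x,x), the
LIBSVM default C = 1, and group-aware 3-fold cross-validation.

**Evaluation.** Rankings are scored by the concordant-pair fraction
τ = P/(P+Q) ∈ [0,1] (the classical Kendall statistic (P−Q)/(P+Q) is also
reported) and by NDCG@n with exponential gains, (2^R(j)−1)/log₂(j+1),
normalized so a rating-sorted list scores exactly 1.

**Synthetic ground truth.** The generator draws n = 150 instances of
d = 50 uniform [0,1) features, a hidden weight vector w* ∈ [−1,1]^d, and
relevance levels by equal-frequency quantile binning of F*(x) = w*·x, so
experiments can measure accuracy against a known optimal ordering.

## Worked example

```python
from relrank import KernelSpec, TrainRecord, ranksvm_learn, ranksvm_predict

records = [
    TrainRecord("a", {0: 4.0, 1: 0.0}, "q", 3),
    TrainRecord("b", {0: 3.5, 1: 0.5}, "q", 3),
    TrainRecord("c", {0: 2.0, 1: 1.0}, "q", 2),
    TrainRecord("d", {0: 1.5, 1: 1.5}, "q", 2),
    TrainRecord("e", {0: 0.0, 1: 2.0}, "q", 1),
    TrainRecord("f", {0: 0.5, 1: 3.0}, "q", 1),
]
model, report = ranksvm_learn(records, C=10.0, spec=KernelSpec("linear"))
print(report.training_tau)   # 1.0  — every training pair ordered correctly
print(model.weight)          # {0: 0.5714290796948228, 1: -0.28571394687011814}
print(ranksvm_predict(model, [{0: 3.0, 1: 0.2}, {0: 0.1, 1: 2.5}]))
# [ 1.65714445 -0.65714196]  — first item ranked far above the second
```

The six judgments induce 12 preference pairs; the solver keeps 2 support
pairs and recovers the direction of the hidden preference (high feature 0,
low feature 1). On the metric side:

```python
from relrank import kendall_tau_paper, ndcg
kendall_tau_paper(["x1","x2","x3","x4","x5"], ["x3","x2","x1","x4","x5"])
# 0.7   — 3 of the 10 item pairs are discordant
ndcg([("docA", 1), ("docB", 3), ("docC", 0), ("docD", 2)], n=4)
# 0.7142...  — burying the top-rated item at position 2 costs accuracy
```

The `examples/` directory holds one narrative script per capability
(featurization, learning, metrics, C selection, the feedback session, the
synthetic experiments); each prints the numbers above with a line on what
they mean. The same functionality is scriptable through the `relrank` CLI
(`featurize`, `learn`, `predict`, `rank`, `select-c`, `experiment`,
`feedback`), which reads and writes tab-separated tables with the
canonical `ID / FVector / RankGroup / Rank` headers or named tables in an
embedded database file.

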