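# Methods

This note records the models, numerical choices, and protocol decisions
behind `relrank`, and what the synthetic experiments do and do not show.

## Text featurization

Documents contribute only their title and abstract. Tokenization splits on
non-alphanumeric characters, lowercases, drops single-character and
pure-number tokens, removes words from a fixed English stopword list
frozen in the package, and applies the Porter suffix-stripping stemmer
(implemented in-repo and checked against the algorithm's published example
words, so featurization never depends on a runtime download).

TFIDF uses the plain textbook form w(t,d) = tf(t,d) · ln(N/df(t)): raw
term frequency, natural-log inverse document frequency, no smoothing, no
length normalization by default (cosine normalization is an option,
default off). Vocabulary columns are assigned in lexicographic term order
and pruned at `min_df` (default 1, i.e. no pruning). Consequences worth
knowing: weights are non-negative — which the linear-kernel capacity bound
below relies on — and a term present in every document receives weight 0
and disappears from the sparse vectors.

## RankSVM

Within a rank group, every pair of records with strictly different
relevance levels yields one preference constraint; equal levels yield
none, and pairs never cross groups. The convention throughout is
*larger rank value = more preferred*, and difference vectors are always
(preferred − other). The primal is the standard soft-margin program over
pairwise differences with no intercept (ranking is translation
invariant); the dual — maximize Σα − ½αᵀQα subject to 0 ≤ α ≤ C — is
solved directly.

Solver: cyclic coordinate ascent with the closed-form box-clipped update
α_p ← clip(α_p − (∇_p)/Q_pp, 0, C), initialized at α = 0, sweeping pairs
in the fixed deterministic order (group, preferred id, other id). For the
linear kernel the weight vector w = Σα_p d_p is maintained incrementally,
so a sweep costs O(pairs × dim) and no Q matrix is formed; for the RBF
kernel the full difference-vector Gram is materialized (capped at 10,000
pairs) and the gradient is maintained. The inner sweep is JIT-compiled
with numba; a pure-Python body with identical semantics is the fallback.
Convergence is declared when the largest KKT violation in a sweep is
≤ 1e-6 (default), with a hard cap of 10,000 sweeps and an explicit
warning on non-convergence — reachable only for near-hard-margin fits
(very large C), where the returned iterate is still feasible and close.
A coordinate with Q_pp = 0 (identical feature vectors with different
levels) has a linear dual restriction and is set directly to its bound.
A configurable pair-count cap (default 250,000) fails loudly rather than
subsampling. Support pairs with α below 1e-12·max(C,1) are dropped from
the stored model.

The training report exposes the dual objective, per-pair slacks
ξ = max(0, 1 − margin), sweep count, and the fraction of training pairs
ordered strictly correctly (training τ; 1.0 on separable data with ample
C). Equivalence of the solver with a generic box-constrained QP solve,
and of weight-based with kernel-expansion scoring, is part of the test
suite rather than assumed.

## Validation-free soft-margin selection

The selection rule derives per-record lower bounds on C from the dual box
constraint: |F(x)| ≤ Σ α_ij |K(x_i,x) − K(x_j,x)| ≤ C·Σ_z |K(z,x)| when
all kernel values are positive, so requiring F to reach each record's
relevance level r(x) gives C_x = r(x) / Σ_z |K(z,x)|, the denominator
summed over *all* training records. The selected value is the
nearest-rank 90th percentile counting from below (90% of the bounds lie
at or below it): large enough to satisfy most records' capacity
requirement, but not dragged to the extreme tail, so the model gets
capacity for good-but-not-perfect training performance. This algebraic
form is a **reconstruction** of the published selection rule from the
stated derivation sketch (the original equation is not recoverable from
the source text); it is pinned behaviorally by the comparison harness
(ordering against defaults and cross-validation), not by a closed-form
reference. Two consequences are tested as invariants: doubling all
relevance levels doubles every bound, and the selected C is
non-decreasing in the percentile.

The linear-kernel path refuses data with any K(z,x) ≤ 0 (the derivation
needs positive kernels; TFIDF features satisfy this whenever judged
documents share vocabulary, and the RBF kernel satisfies it always).

Comparators: `default_C_svmlight` = 1 / mean K(x,x); `default_C_libsvm`
= 1 exactly; `cv_select_C` grid-searches powers of ten from 1e-4 to 1e4
with group-aware 3-fold cross-validation (whole rank groups per fold,
NDCG@10 validation metric by default, ties toward smaller C). Any other
strategy with the `(records, kernel) -> C` signature can be slotted into
the comparison harness.

## Ranking metrics

τ is reported as the concordant-pair fraction P/(P+Q) ∈ [0,1] — on the
five-item example with three discordant pairs this gives 0.7 — together
with the classical statistic (P−Q)/(P+Q) = 2·τ − 1. Both require strict
orderings over the same item set; predicted-score ties are broken by item
identifier ascending, and the tie count is reported by the ordering
helper so ambiguity is visible rather than silent.

NDCG@n uses exponential gain and logarithmic discount,
DCG@n = Σ_{j≤n} (2^{R(j)}−1)/log₂(j+1), normalized by the DCG of the
same items sorted by rating, so any rating-sorted list scores exactly 1;
an all-zero-rated list scores 0 by convention. n defaults to 10. The
exact gain/discount interior is a documented choice of the standard form
(the source rendering is ambiguous); what is fixed independently of that
choice is the normalization to 1 and the logarithmic position discount.

## Rocchio baseline

The two-level comparator forms q' = a·q + b·centroid(relevant) −
c·centroid(non-relevant) with classic SMART weights a=1, b=0.75, c=0.15
(a=0 in feedback-only mode, where there is no explicit query vector),
clips negative components to zero, and ranks by cosine similarity.
Multi-level judgments are collapsed by mapping every level above the
bottom one to "relevant" — the assertion that 3→relevant, 2→relevant,
1→non-relevant is part of the baseline's tests. The exact Rocchio variant
behind the published comparison is unstated, so conclusions involving it
are qualitative orderings only.

## Synthetic data and experiments

`generate` draws n=150 instances of d=50 i.i.d. uniform [0,1) features,
a hidden weight vector w* with i.i.d. uniform [−1,1] entries, true
utilities F* = Xw*, and levels by equal-frequency quantile binning of F*
into L bins (level 1 lowest; remainder instances go to the lower bins so
every level is populated). Labels are exactly monotone in F* — there is
no label noise, only quantization. Everything is a pure function of the
seed; experiment harnesses derive per-run child seeds (< 2³¹) from one
base seed via a seed sequence.

Design choices that were genuinely open: quantile binning (the published
protocol does not say how levels are derived from the linear function;
equal frequencies keep every level populated and make L comparable across
arms), the signed w* range (needed for a non-trivial ranking direction),
and the default split of 20 training instances with the remainder as
test.

Evaluation is always against the hidden ground truth on held-out
instances: τ against the F* ordering, and NDCG@10 with ratings fixed to
the 3-quantile labels of F* regardless of the training label granularity,
so arms trained at different L are scored on one common scale.

Protocol sizes (chosen as the package's desk-scale defaults):

* **Levels experiment** — one dataset and one 20-instance training split
  per run, relabeled at each L in the grid (arms differ only in label
  granularity); 30 runs; C by rank-selection. Cross-validation is not a
  per-arm option here because a single-group dataset cannot be split
  group-wise.
* **Size experiment** — training sizes 10/20/40 nested within a query,
  test set shared across arms; 5 independent query datasets per run × 30
  runs (the comparison this emulates averaged over a pool of queries as
  well as runs; single-query cells have Monte-Carlo error of the same
  order as the 3-vs-2-level gap being measured).
* **C-selection experiment** — 6 independent single-group datasets per
  run (mirroring six-query evaluation blocks), pooled 120-record training
  sets, 30 runs; each strategy picks C on the pooled set and is scored on
  each group's held-out instances.

## What passing tests do and do not show

The generator emulates graded feedback with a perfectly linear utility,
noiseless monotone labels, dense uniform features, and a single judge.
Real abstracts have sparse heavy-tailed TFIDF features, inconsistent
judgments, and no linear ground truth. Passing trends therefore show that
the machinery extracts the ordinal information that is present — more
levels and more feedback help, pairwise learning beats a two-level
centroid method, the capacity-bound C lands in the well-performing
regime — not that the absolute accuracies transfer to any corpus. One
consequence of the noiseless design worth stating plainly: the test
accuracy is nearly flat in C across [1e-4, 1e-2], so cross-validation has
little genuine signal to exploit at this scale and its advantage over
rank-selection is within Monte-Carlo noise; the experiments assert
closeness and ordering with tolerances, not a strict CV win.

## Known limitations

* No intercept, no tie ("same level") constraints, no incremental
  updates between feedback rounds — each push re-learns from scratch.
* The RBF path materializes an m×m pair Gram and is intended for small
  feedback sets (the default kernel is linear, which is also the sensible
  choice for high-dimensional text).
* The rank-selection rule requires strictly positive kernels among
  training records under the linear kernel; judged documents sharing no
  vocabulary terms need the RBF kernel instead.
* The embedded table layer is single-process sqlite; it preserves the
  schema/command contract and the no-intermediate-files property, not
  DBMS concurrency semantics.
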