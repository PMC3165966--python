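"""Ranking accuracy measures: concordant-fraction Kendall's tau and NDCG@n.

Two orderings of the same items are compared pair by pair. With P
concordant and Q discordant pairs this module reports

    tau = P / (P + Q)            (the fraction of agreeing pairs, in [0, 1])

together with the classical statistic (P - Q)/(P + Q) = 2*tau - 1. The
fraction form is the similarity used throughout the experiment harness: two
identical orderings score 1, a full reversal scores 0, and for five items
with three discordant pairs it is 7/10 = 0.7.

NDCG@n uses exponential gains and a logarithmic position discount,

    DCG@n  = sum_{j=1..n} (2^R(j) - 1) / log2(j + 1),
    NDCG@n = DCG@n / Z_n,

where R(j) is the integer rating of the item retrieved at position j and
Z_n is the DCG of the same items sorted by rating descending, so a perfect
ranking scores exactly 1. If every rating is zero the score is 0 by
convention.
"""

from __future__ import annotations

import math
from typing import Hashable, Mapping, Sequence

__all__ = [
    "concordance_counts",
    "kendall_tau_paper",
    "kendall_tau_classical",
    "ndcg",
    "order_by_score",
    "write_metric_report",
]

Item = Hashable


def _positions(ordering: Sequence[Item]) -> dict[Item, int]:
    pos = {}
    for i, item in enumerate(ordering):
        if item in pos:
            raise ValueError(f"duplicate item {item!r} in ordering")
        pos[item] = i
    return pos


def concordance_counts(
    ref: Sequence[Item], test: Sequence[Item]
) -> tuple[int, int]:
    """Count (concordant, discordant) item pairs between two strict orderings.

    Both orderings must contain exactly the same items; every one of the
    n(n-1)/2 unordered pairs is either concordant (same relative order in
    both) or discordant.
    """
    rp = _positions(ref)
    tp = _positions(test)
    if set(rp) != set(tp):
        raise ValueError("orderings must contain the same item set")
    items = list(ref)
    n = len(items)
    concordant = discordant = 0
    for i in range(n):
        for j in range(i + 1, n):
            a, b = items[i], items[j]
            if (rp[a] < rp[b]) == (tp[a] < tp[b]):
                concordant += 1
            else:
                discordant += 1
    return concordant, discordant


def kendall_tau_paper(ref: Sequence[Item], test: Sequence[Item]) -> float:
    """Concordant-pair fraction P/(P+Q) between two strict orderings, in [0, 1]."""
    if len(ref) < 2:
        raise ValueError("tau needs at least two items (no pairs otherwise)")
    p, q = concordance_counts(ref, test)
    return p / (p + q)


def kendall_tau_classical(ref: Sequence[Item], test: Sequence[Item]) -> float:
    """Classical Kendall tau (P-Q)/(P+Q) in [-1, 1]; equals 2*tau_fraction - 1."""
    if len(ref) < 2:
        raise ValueError("tau needs at least two items (no pairs otherwise)")
    p, q = concordance_counts(ref, test)
    return (p - q) / (p + q)


def ndcg(rated: Sequence[tuple[Item, int]], n: int = 10) -> float:
    """NDCG@n of a retrieved list of (item, rating) in retrieved order.

    Ratings are non-negative integers; position 1 is the first element.
    n is truncated to the list length. Returns 0 when the ideal DCG is 0.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    if len(rated) == 0:
        raise ValueError("cannot score an empty list")
    ratings = [r for _, r in rated]
    if any(r < 0 for r in ratings):
        raise ValueError("ratings must be non-negative")
    n = min(n, len(rated))
    dcg = _dcg(ratings, n)
    ideal = _dcg(sorted(ratings, reverse=True), n)
    if ideal == 0.0:
        return 0.0
    return dcg / ideal


def _dcg(ratings: Sequence[int], n: int) -> float:
    return sum(
        (2.0 ** ratings[j] - 1.0) / math.log2(j + 2) for j in range(n)
    )


def order_by_score(
    scores: Mapping[Item, float]
) -> tuple[list[Item], int]:
    """Strict ordering from scores: descending score, ties broken by item id.

    Returns the ordering and the number of tied adjacent score pairs that
    required the deterministic tie-break, so callers can report ambiguity.
    """
    items = sorted(scores, key=lambda it: (-scores[it], str(it)))
    ties = sum(
        1
        for a, b in zip(items, items[1:])
        if scores[a] == scores[b]
    )
    return items, ties


def write_metric_report(rows, path) -> None:
    """Tab-separated metric report: group, tau_paper, tau_classical, ndcg@n."""
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("group\ttau_paper\ttau_classical\tndcg\n")
        for group, tau_p, tau_c, nd in rows:
            fh.write(f"{group}\t{tau_p!r}\t{tau_c!r}\t{nd!r}\n")
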