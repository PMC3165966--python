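"""Score rankings with the concordant-fraction Kendall tau and NDCG@n.

Reproduces the five-item worked example: exchanging the items at positions
1 and 3 discords exactly 3 of the 10 pairs, so tau = 7/10 = 0.7 (the
classical statistic would be 0.4). Also shows NDCG for a partially
shuffled rated list and for a perfectly sorted one.
"""

from relrank import (
    concordance_counts,
    kendall_tau_classical,
    kendall_tau_paper,
    ndcg,
)

reference = ["x1", "x2", "x3", "x4", "x5"]
predicted = ["x3", "x2", "x1", "x4", "x5"]

p, q = concordance_counts(reference, predicted)
print(f"concordant pairs P = {p}, discordant pairs Q = {q}")
print(f"tau (fraction form, in [0,1]):  {kendall_tau_paper(reference, predicted)}")
print(f"tau (classical, in [-1,1]):     {kendall_tau_classical(reference, predicted)}")

retrieved = [("docA", 1), ("docB", 3), ("docC", 0), ("docD", 2)]
print(f"\nretrieved list (item, rating): {retrieved}")
print(f"NDCG@4 of retrieved order:  {ndcg(retrieved, n=4):.4f}")
ideal = sorted(retrieved, key=lambda t: -t[1])
print(f"NDCG@4 of rating-sorted order: {ndcg(ideal, n=4):.4f}")
print("\nNDCG discounts gains logarithmically with position, so burying the")
print("top-rated docB at position 2 costs accuracy even though tau-style")
print("pair counting would treat all positions alike.")
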