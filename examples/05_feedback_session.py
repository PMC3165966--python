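"""An interactive multi-level feedback session over the embedded table layer.

Featurizes a corpus, filters candidates with a conjunctive keyword query,
judges a few of them on the default 3-level scale, and pushes the feedback:
the system learns a RankSVM (C chosen by rank-selection), scores every
candidate, and returns the re-ranked list. A second push with one more
judgment refines the ranking; judgments accumulate across rounds.
"""

from relrank import (
    Document,
    FeedbackSession,
    featurize_corpus,
    feedback_round,
    match_candidates,
)

corpus = [
    Document("d1", "Breast cancer gene study", "BRCA1 gene mutations in breast cancer."),
    Document("d2", "Swine flu outbreak", "Influenza virus surveillance and swine flu cases."),
    Document("d3", "Gene therapy advances", "Novel gene therapy vectors for cancer treatment."),
    Document("d4", "Cancer treatment review", "Chemotherapy and radiation therapy for cancer."),
    Document("d5", "Flu vaccine efficacy", "Seasonal influenza vaccine trial results."),
    Document("d6", "Breast cancer screening", "Mammography screening reduces cancer mortality."),
]

_, vectors = featurize_corpus(corpus)
candidates = match_candidates(corpus, vectors, "cancer")
print(f"query 'cancer' matches: {sorted(candidates)}")

session = FeedbackSession(query="cancer", candidates=candidates)

ranked = feedback_round(session, {"d1": 3, "d4": 1}, k=10)
print("\nround 1 (d1 judged highly relevant, d4 not relevant):")
for doc_id, score in ranked:
    note = f"  <- judged {session.judgments[doc_id]}" if doc_id in session.judgments else ""
    print(f"  {doc_id}: {score:+.4f}{note}")

ranked = feedback_round(session, {"d3": 2}, k=10)
print("\nround 2 (d3 added as partially relevant; earlier judgments kept):")
for doc_id, score in ranked:
    note = f"  <- judged {session.judgments[doc_id]}" if doc_id in session.judgments else ""
    print(f"  {doc_id}: {score:+.4f}{note}")

print("\nDocuments sharing terms with the highly-relevant judgment (d6 with")
print("d1: breast/cancer) rise above those resembling the non-relevant one.")
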