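"""Featurize a tiny article corpus into sparse TFIDF vectors.

Builds six short title+abstract documents, fits a vocabulary (stopwords
removed, Porter-stemmed, lexicographic column order) and prints each
document's sparse vector. Weights are tf * ln(N/df), so terms shared by
every document vanish and rarer terms weigh more.
"""

from relrank import Document, featurize_corpus, format_sparse

corpus = [
    Document("d1", "Breast cancer gene study", "BRCA1 gene mutations in breast cancer."),
    Document("d2", "Swine flu outbreak", "Influenza virus surveillance and swine flu cases."),
    Document("d3", "Gene therapy advances", "Novel gene therapy vectors for cancer treatment."),
    Document("d4", "Cancer treatment review", "Chemotherapy and radiation therapy for cancer."),
    Document("d5", "Flu vaccine efficacy", "Seasonal influenza vaccine trial results."),
    Document("d6", "Breast cancer screening", "Mammography screening reduces cancer mortality."),
]

vocab, vectors = featurize_corpus(corpus)

print(f"{len(corpus)} documents, {len(vocab)} vocabulary terms")
print("term -> (column, df):")
for term in sorted(vocab.index)[:8]:
    print(f"  {term:12s} -> ({vocab.index[term]}, df={vocab.df[term]})")
print()
for doc in corpus:
    print(f"{doc.doc_id}: {format_sparse(vectors[doc.doc_id])}")
print()
print("Each 'index:value' pair is a stemmed term's TFIDF weight; documents")
print("about the same topic (d1, d6) share heavy columns and so will score")
print("similarly under any linear ranking function.")
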