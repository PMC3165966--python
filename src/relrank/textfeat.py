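"""TFIDF featurization of documents (title + abstract).

Articles are represented by sparse TFIDF vectors over the words of their
title and abstract, after lowercasing, stopword removal and Porter
stemming. The weighting is the plain textbook form

    w(t, d) = tf(t, d) * ln(N / df(t))

with raw term frequency, natural-log idf, no smoothing and (by default)
no length normalization; cosine normalization is available as an option.
All weights are non-negative, which the downstream soft-margin
parameter-selection rule relies on for the linear kernel.
"""

from __future__ import annotations

import math
import re
from collections import Counter
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator, Mapping, Sequence

from ._stopwords import STOPWORDS
from .porter import stem

__all__ = [
    "Document",
    "Vocabulary",
    "tokenize",
    "fit_vocabulary",
    "tfidf_vector",
    "featurize_corpus",
    "read_corpus_tsv",
    "write_corpus_tsv",
    "read_corpus_dir",
    "format_sparse",
    "parse_sparse",
]

#: A sparse feature vector: column index -> positive TFIDF weight.
FeatureVector = dict[int, float]

_TOKEN_RE = re.compile(r"[^0-9a-z]+")


@dataclass(frozen=True)
class Document:
    """A raw corpus record; only title and abstract contribute features."""

    doc_id: str
    title: str
    abstract: str = ""

    @property
    def text(self) -> str:
        return f"{self.title} {self.abstract}"


@dataclass
class Vocabulary:
    """Term -> (column index, document frequency) map over a corpus of size n_docs.

    Column indices are 0-based, contiguous and assigned in lexicographic
    term order, so refitting the same corpus always yields the same map.
    """

    index: dict[str, int]
    df: dict[str, int]
    n_docs: int

    def __len__(self) -> int:
        return len(self.index)

    def __contains__(self, term: str) -> bool:
        return term in self.index

    def idf(self, term: str) -> float:
        return math.log(self.n_docs / self.df[term])


def tokenize(text: str) -> list[str]:
    """Split text into lowercased, stopword-filtered, Porter-stemmed terms.

    Tokens are maximal alphanumeric runs; pure-number tokens and
    single-character tokens are dropped. Order of appearance is kept.
    """
    out = []
    for tok in _TOKEN_RE.split(text.lower()):
        if len(tok) < 2 or tok.isdigit():
            continue
        if tok in STOPWORDS:
            continue
        out.append(stem(tok))
    return out


def fit_vocabulary(corpus: Sequence[Document], min_df: int = 1) -> Vocabulary:
    """Build a vocabulary over the corpus, keeping terms with df >= min_df."""
    if len(corpus) == 0:
        raise ValueError("cannot fit a vocabulary on an empty corpus")
    if min_df < 1:
        raise ValueError("min_df must be a positive integer")
    df: Counter[str] = Counter()
    for doc in corpus:
        df.update(set(tokenize(doc.text)))
    kept = sorted(t for t, c in df.items() if c >= min_df)
    return Vocabulary(
        index={t: i for i, t in enumerate(kept)},
        df={t: df[t] for t in kept},
        n_docs=len(corpus),
    )


def tfidf_vector(
    doc: Document, vocab: Vocabulary, normalize: bool = False
) -> FeatureVector:
    """TFIDF vector of one document under a fitted vocabulary.

    Terms outside the vocabulary are ignored; a term present in every
    document has idf 0 and is therefore absent from the sparse result.
    """
    counts = Counter(t for t in tokenize(doc.text) if t in vocab)
    vec = {}
    for term, tf in counts.items():
        w = tf * vocab.idf(term)
        if w > 0.0:
            vec[vocab.index[term]] = w
    if normalize and vec:
        norm = math.sqrt(sum(v * v for v in vec.values()))
        vec = {i: v / norm for i, v in vec.items()}
    return vec


def featurize_corpus(
    corpus: Sequence[Document], vocab: Vocabulary | None = None,
    min_df: int = 1, normalize: bool = False,
) -> tuple[Vocabulary, dict[str, FeatureVector]]:
    """Fit (or reuse) a vocabulary and vectorize every document."""
    if vocab is None:
        vocab = fit_vocabulary(corpus, min_df=min_df)
    return vocab, {d.doc_id: tfidf_vector(d, vocab, normalize) for d in corpus}


# ---------------------------------------------------------------------------
# corpus readers / writers

def read_corpus_tsv(path: str | Path) -> list[Document]:
    """Read a tab-separated corpus with header columns doc_id, title, abstract."""
    lines = Path(path).read_text(encoding="utf-8").splitlines()
    if not lines:
        raise ValueError(f"{path}: empty corpus file")
    header = lines[0].split("\t")
    if header[:3] != ["doc_id", "title", "abstract"]:
        raise ValueError(
            f"{path}: expected header 'doc_id\\ttitle\\tabstract', got {lines[0]!r}"
        )
    docs = []
    for ln in lines[1:]:
        if not ln:
            continue
        parts = ln.split("\t")
        if len(parts) < 2:
            raise ValueError(f"{path}: malformed row {ln!r}")
        doc_id, title = parts[0], parts[1]
        abstract = parts[2] if len(parts) > 2 else ""
        docs.append(Document(doc_id, title, abstract))
    _check_unique_ids(docs)
    return docs


def write_corpus_tsv(docs: Iterable[Document], path: str | Path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("doc_id\ttitle\tabstract\n")
        for d in docs:
            fh.write(f"{d.doc_id}\t{d.title}\t{d.abstract}\n")


def read_corpus_dir(path: str | Path) -> list[Document]:
    """Read a directory of text files: filename = doc_id, first line = title."""
    docs = []
    for fp in sorted(Path(path).iterdir()):
        if not fp.is_file():
            continue
        lines = fp.read_text(encoding="utf-8").splitlines()
        title = lines[0] if lines else ""
        abstract = " ".join(lines[1:])
        docs.append(Document(fp.name, title, abstract))
    if not docs:
        raise ValueError(f"{path}: no document files found")
    _check_unique_ids(docs)
    return docs


def _check_unique_ids(docs: Sequence[Document]) -> None:
    seen = set()
    for d in docs:
        if d.doc_id in seen:
            raise ValueError(f"duplicate doc_id {d.doc_id!r} in corpus")
        seen.add(d.doc_id)


# ---------------------------------------------------------------------------
# sparse "index:value" dialect (shared with the relational FVector column)

def format_sparse(vec: Mapping[int, float]) -> str:
    """Serialize a sparse vector as ascending 'index:value' pairs.

    Values are written with shortest round-tripping precision, so
    parse_sparse(format_sparse(v)) == v bit-for-bit.
    """
    return " ".join(f"{i}:{float(v)!r}" for i, v in sorted(vec.items()))


def parse_sparse(text: str) -> FeatureVector:
    vec: FeatureVector = {}
    for pair in text.split():
        try:
            idx, val = pair.split(":", 1)
            i = int(idx)
            v = float(val)
        except ValueError as exc:
            raise ValueError(f"malformed sparse pair {pair!r}") from exc
        if i < 0:
            raise ValueError(f"negative feature index in {pair!r}")
        vec[i] = v
    return vec
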