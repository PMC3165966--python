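"""Embedded relational layer: learn/predict commands operating on database tables.

Mirrors the in-database design of the ranking system: four table shapes —

* train_table  (ID, FVector, RankGroup, Rank)
* model_table  (one parameter row CVal/KType/KVal, a weight row for linear
  kernels, and one row per support pair with its coefficient)
* test_table   (ID, FVector)
* output_table (ID, RScore)

— plus two commands. ``learn_command`` reads a train table, fits a RankSVM
and writes a model table; ``predict_command`` scores a test table into an
output table. Both operate on stored tables directly, with no intermediate
file export/import (tight coupling). ``learn_command_loose`` is the
file-mediated comparator: export, learn on files, import — it must produce
the identical model, which is the correctness half of the tight-vs-loose
comparison (timing is hardware-bound and out of scope).

``ranked_retrieval`` chains learn -> predict -> join-on-ID -> sort by
RScore descending (ties by ID), the canonical retrieval query.
``FeedbackSession`` and ``feedback_round`` implement the interactive
multi-level feedback loop on top of it: judgments accumulate across
rounds, each push re-learns with C chosen by the validation-free
rank-selection rule and re-ranks all candidates.

The store is an embedded sqlite database (file or in-memory); FVector
columns hold the sparse "index:value" text dialect so tables are
inspectable and round-trip bit-exactly.
"""

from __future__ import annotations

import re
import sqlite3
import tempfile
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

from .paramsel import rank_select_C
from .ranklearn import (
    KernelSpec,
    RankModel,
    SupportPair,
    TrainRecord,
    ranksvm_learn,
    ranksvm_predict,
    read_letor,
    read_model,
    write_letor,
    write_model,
)
from .textfeat import Document, format_sparse, parse_sparse, tokenize

__all__ = [
    "RankStore",
    "LearnParams",
    "FeedbackSession",
    "feedback_round",
    "match_candidates",
]

_NAME_RE = re.compile(r"^[A-Za-z_][A-Za-z0-9_]*$")

TRAIN_COLUMNS = ("ID", "FVector", "RankGroup", "Rank")
TEST_COLUMNS = ("ID", "FVector")
OUTPUT_COLUMNS = ("ID", "RScore")


def _check_name(name: str) -> str:
    if not _NAME_RE.match(name):
        raise ValueError(f"invalid table name {name!r}")
    return name


@dataclass(frozen=True)
class LearnParams:
    """The learn command's parameter triple: CVal, KType, KVal.

    CVal may be a positive number or the sentinel "auto", which invokes the
    validation-free rank-selection rule on the training rows. KType is
    LINEAR or RBF (case-insensitive); KVal is the RBF width g.
    """

    cval: float | str = "auto"
    ktype: str = "LINEAR"
    kval: float = 1.0

    def kernel(self) -> KernelSpec:
        return KernelSpec(self.ktype.lower(), self.kval)

    def resolve_c(self, records: Sequence[TrainRecord]) -> float:
        if self.cval == "auto":
            return rank_select_C(records, self.kernel()).selected
        c = float(self.cval)
        if not c > 0:
            raise ValueError("CVal must be positive")
        return c


class RankStore:
    """An embedded database holding train/model/test/output tables."""

    def __init__(self, path: str | Path = ":memory:"):
        self.conn = sqlite3.connect(str(path))

    def close(self) -> None:
        self.conn.close()

    def __enter__(self) -> "RankStore":
        return self

    def __exit__(self, *exc) -> None:
        self.close()

    # -- table creation and IO -------------------------------------------

    def create_train_table(
        self, name: str, rows: Sequence[tuple[str, str, str, int]]
    ) -> None:
        """(Re)create a train table from (ID, FVector, RankGroup, Rank) rows."""
        _check_name(name)
        cur = self.conn.cursor()
        cur.execute(f"DROP TABLE IF EXISTS {name}")
        cur.execute(
            f"CREATE TABLE {name} (ID TEXT PRIMARY KEY, FVector TEXT, "
            "RankGroup TEXT, Rank INTEGER)"
        )
        cur.executemany(f"INSERT INTO {name} VALUES (?, ?, ?, ?)", rows)
        self.conn.commit()

    def create_test_table(self, name: str, rows: Sequence[tuple[str, str]]) -> None:
        _check_name(name)
        cur = self.conn.cursor()
        cur.execute(f"DROP TABLE IF EXISTS {name}")
        cur.execute(f"CREATE TABLE {name} (ID TEXT PRIMARY KEY, FVector TEXT)")
        cur.executemany(f"INSERT INTO {name} VALUES (?, ?)", rows)
        self.conn.commit()

    def read_train_records(self, name: str) -> list[TrainRecord]:
        _check_name(name)
        records = []
        for rid, fv, group, rank in self.conn.execute(
            f"SELECT ID, FVector, RankGroup, Rank FROM {name} ORDER BY ID"
        ):
            try:
                vec = parse_sparse(fv or "")
            except ValueError as exc:
                raise ValueError(f"{name}: malformed FVector in row ID={rid!r}") from exc
            records.append(TrainRecord(str(rid), vec, str(group), int(rank)))
        return records

    def read_test_rows(self, name: str) -> list[tuple[str, dict]]:
        _check_name(name)
        rows = []
        for rid, fv in self.conn.execute(
            f"SELECT ID, FVector FROM {name} ORDER BY ID"
        ):
            try:
                rows.append((str(rid), parse_sparse(fv or "")))
            except ValueError as exc:
                raise ValueError(f"{name}: malformed FVector in row ID={rid!r}") from exc
        return rows

    # -- model table <-> RankModel ---------------------------------------

    def write_model_table(self, name: str, model: RankModel) -> None:
        _check_name(name)
        cur = self.conn.cursor()
        cur.execute(f"DROP TABLE IF EXISTS {name}")
        cur.execute(
            f"CREATE TABLE {name} (RowKind TEXT, CVal REAL, KType TEXT, "
            "KVal REAL, Alpha REAL, Vector1 TEXT, Vector2 TEXT, "
            "PreferredID TEXT, OtherID TEXT)"
        )
        cur.execute(
            f"INSERT INTO {name} VALUES ('param', ?, ?, ?, NULL, NULL, NULL, NULL, NULL)",
            (model.C, model.kernel.ktype.upper(), model.kernel.g),
        )
        if model.weight is not None:
            cur.execute(
                f"INSERT INTO {name} (RowKind, Vector1) VALUES ('weight', ?)",
                (format_sparse(model.weight),),
            )
        cur.executemany(
            f"INSERT INTO {name} (RowKind, Alpha, Vector1, Vector2, PreferredID, OtherID) "
            "VALUES ('sv', ?, ?, ?, ?, ?)",
            [
                (sp.alpha, format_sparse(sp.preferred), format_sparse(sp.other),
                 sp.preferred_id, sp.other_id)
                for sp in model.support_pairs
            ],
        )
        self.conn.commit()

    def read_model_table(self, name: str) -> RankModel:
        _check_name(name)
        params = self.conn.execute(
            f"SELECT CVal, KType, KVal FROM {name} WHERE RowKind='param'"
        ).fetchall()
        if len(params) != 1:
            raise ValueError(
                f"{name}: expected exactly one parameter row, found {len(params)}"
            )
        cval, ktype, kval = params[0]
        weight_rows = self.conn.execute(
            f"SELECT Vector1 FROM {name} WHERE RowKind='weight'"
        ).fetchall()
        weight = parse_sparse(weight_rows[0][0]) if weight_rows else None
        support = [
            SupportPair(float(a), parse_sparse(v1), parse_sparse(v2),
                        str(pid or ""), str(oid or ""))
            for a, v1, v2, pid, oid in self.conn.execute(
                f"SELECT Alpha, Vector1, Vector2, PreferredID, OtherID "
                f"FROM {name} WHERE RowKind='sv' ORDER BY rowid"
            )
        ]
        return RankModel(
            kernel=KernelSpec(str(ktype).lower(), float(kval)),
            C=float(cval),
            support_pairs=support,
            weight=weight,
        )

    # -- commands ---------------------------------------------------------

    def learn_command(
        self, train_table: str, model_table: str, params: LearnParams
    ) -> RankModel:
        """RANKSVM_LEARN: fit on a train table, materialize a model table."""
        records = self.read_train_records(train_table)
        if not records:
            raise ValueError(f"{train_table}: empty train table")
        c = params.resolve_c(records)
        model, _ = ranksvm_learn(records, c, params.kernel())
        self.write_model_table(model_table, model)
        return model

    def learn_command_loose(
        self,
        train_table: str,
        model_table: str,
        params: LearnParams,
        workdir: str | Path | None = None,
    ) -> RankModel:
        """The loose-coupling comparator: same learn, mediated by files on disk."""
        with tempfile.TemporaryDirectory(dir=workdir) as tmp:
            train_path = Path(tmp) / "train.dat"
            model_path = Path(tmp) / "model.txt"
            write_letor(self.read_train_records(train_table), train_path)
            records = read_letor(train_path)
            if not records:
                raise ValueError(f"{train_table}: empty train table")
            c = params.resolve_c(records)
            model, _ = ranksvm_learn(records, c, params.kernel())
            write_model(model, model_path)
            model = read_model(model_path)
        self.write_model_table(model_table, model)
        return model

    def predict_command(
        self, model_table: str, test_table: str, output_table: str
    ) -> list[tuple[str, float]]:
        """RANKSVM_PREDICT: score every test row into an output table."""
        model = self.read_model_table(model_table)
        rows = self.read_test_rows(test_table)
        scores = ranksvm_predict(model, [vec for _, vec in rows])
        _check_name(output_table)
        cur = self.conn.cursor()
        cur.execute(f"DROP TABLE IF EXISTS {output_table}")
        cur.execute(f"CREATE TABLE {output_table} (ID TEXT PRIMARY KEY, RScore REAL)")
        out = [(rid, float(s)) for (rid, _), s in zip(rows, scores)]
        cur.executemany(f"INSERT INTO {output_table} VALUES (?, ?)", out)
        self.conn.commit()
        return out

    def ranked_retrieval(
        self,
        train_table: str,
        test_table: str,
        params: LearnParams,
        k: int,
        model_table: str = "model_table",
        output_table: str = "output_table",
    ) -> list[tuple[str, float]]:
        """Learn, predict, join output to test on ID, sort by RScore desc, top k."""
        if k < 1:
            raise ValueError("k must be >= 1")
        self.learn_command(train_table, model_table, params)
        self.predict_command(model_table, test_table, output_table)
        rows = self.conn.execute(
            f"SELECT t.ID, o.RScore FROM {_check_name(output_table)} o "
            f"JOIN {_check_name(test_table)} t ON t.ID = o.ID "
            "ORDER BY o.RScore DESC, t.ID ASC LIMIT ?",
            (k,),
        ).fetchall()
        return [(str(rid), float(s)) for rid, s in rows]

    # -- tab-separated import/export --------------------------------------

    def export_tsv(self, table: str, path: str | Path, kind: str) -> None:
        columns = _KIND_COLUMNS[kind]
        _check_name(table)
        with open(path, "w", encoding="utf-8") as fh:
            fh.write("\t".join(columns) + "\n")
            for row in self.conn.execute(
                f"SELECT {', '.join(columns)} FROM {table} ORDER BY ID"
            ):
                fh.write("\t".join(_cell(v) for v in row) + "\n")

    def import_tsv(self, table: str, path: str | Path, kind: str) -> None:
        columns = _KIND_COLUMNS[kind]
        lines = Path(path).read_text(encoding="utf-8").splitlines()
        header = "\t".join(columns)
        if not lines or tuple(lines[0].split("\t")) != columns:
            raise ValueError(f"{path}: expected header {header!r}")
        rows = [tuple(ln.split("\t")) for ln in lines[1:] if ln]
        for r in rows:
            if len(r) != len(columns):
                raise ValueError(f"{path}: malformed row {r!r}")
        if kind == "train":
            self.create_train_table(
                table, [(i, f, g, int(r)) for i, f, g, r in rows]
            )
        elif kind == "test":
            self.create_test_table(table, rows)
        else:
            raise ValueError(f"cannot import tables of kind {kind!r}")


_KIND_COLUMNS = {
    "train": TRAIN_COLUMNS,
    "test": TEST_COLUMNS,
    "output": OUTPUT_COLUMNS,
}


def _cell(v) -> str:
    if isinstance(v, float):
        return repr(v)
    return str(v)


# ---------------------------------------------------------------------------
# interactive multi-level feedback loop

@dataclass
class FeedbackSession:
    """State of one interactive search: query, candidates, accumulated judgments."""

    query: str
    candidates: dict[str, Mapping[int, float]]
    levels: int = 3
    judgments: dict[str, int] = field(default_factory=dict)

    def judge(self, doc_id: str, level: int) -> None:
        if doc_id not in self.candidates:
            raise ValueError(f"judged document {doc_id!r} is not a candidate")
        if not 1 <= level <= self.levels:
            raise ValueError(
                f"relevance level {level} outside 1..{self.levels}"
            )
        self.judgments[doc_id] = level


def feedback_round(
    session: FeedbackSession,
    new_judgments: Mapping[str, int] | None = None,
    k: int = 20,
    params: LearnParams | None = None,
    store: RankStore | None = None,
) -> list[tuple[str, float]]:
    """One push of feedback: absorb judgments, re-learn, return top-k candidates.

    Judgments accumulate across rounds with equal weight. Requires at least
    two distinct judged levels; C defaults to the validation-free
    rank-selection rule ("auto").
    """
    for doc_id, level in (new_judgments or {}).items():
        session.judge(doc_id, level)
    if len(set(session.judgments.values())) < 2:
        raise ValueError(
            "need at least two relevance levels among the judged documents"
        )
    params = params or LearnParams()
    own_store = store is None
    store = store or RankStore()
    try:
        store.create_train_table(
            "session_train",
            [
                (doc_id, format_sparse(session.candidates[doc_id]),
                 session.query, level)
                for doc_id, level in sorted(session.judgments.items())
            ],
        )
        store.create_test_table(
            "session_test",
            [
                (doc_id, format_sparse(vec))
                for doc_id, vec in sorted(session.candidates.items())
            ],
        )
        return store.ranked_retrieval("session_train", "session_test", params, k)
    finally:
        if own_store:
            store.close()


def match_candidates(
    docs: Sequence[Document],
    vectors: Mapping[str, Mapping[int, float]],
    query: str,
) -> dict[str, Mapping[int, float]]:
    """Conjunctive keyword filter: candidates containing every query term (stemmed)."""
    terms = set(tokenize(query))
    if not terms:
        raise ValueError("query contains no indexable terms")
    out = {}
    for doc in docs:
        if terms <= set(tokenize(doc.text)):
            out[doc.doc_id] = vectors[doc.doc_id]
    return out
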