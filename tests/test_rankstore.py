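import numpy as np
import pytest

from relrank import (
    FeedbackSession,
    KernelSpec,
    LearnParams,
    RankStore,
    TrainRecord,
    feedback_round,
    format_sparse,
    match_candidates,
    ranksvm_learn,
    ranksvm_predict,
)
from relrank.textfeat import Document


def train_rows_from_records(records):
    return [
        (r.id, format_sparse(r.fvector), r.rank_group, r.rank) for r in records
    ]


@pytest.fixture
def store():
    with RankStore() as s:
        yield s


@pytest.fixture
def separable_rows(separable_records):
    return train_rows_from_records(separable_records)


class TestTables:
    def test_train_table_round_trip(self, store, separable_records, separable_rows):
        store.create_train_table("train_table", separable_rows)
        assert store.read_train_records("train_table") == sorted(
            separable_records, key=lambda r: r.id
        )

    def test_malformed_fvector_names_the_row(self, store):
        store.create_train_table("t", [("bad1", "not-a-vector", "g", 1)])
        with pytest.raises(ValueError, match="bad1"):
            store.read_train_records("t")

    def test_invalid_table_name_rejected(self, store):
        with pytest.raises(ValueError, match="invalid table name"):
            store.create_train_table("bad name; drop", [])

    def test_tsv_export_import_round_trip(self, store, separable_rows, tmp_path):
        store.create_train_table("t1", separable_rows)
        path = tmp_path / "train.tsv"
        store.export_tsv("t1", path, "train")
        assert path.read_text().splitlines()[0] == "ID\tFVector\tRankGroup\tRank"
        store.import_tsv("t2", path, "train")
        assert store.read_train_records("t2") == store.read_train_records("t1")


class TestModelTable:
    @pytest.mark.parametrize("spec", [KernelSpec(), KernelSpec("rbf", 0.4)])
    def test_model_round_trip_lossless(self, store, separable_records, spec):
        model, _ = ranksvm_learn(separable_records, C=2.0, spec=spec)
        store.write_model_table("m", model)
        back = store.read_model_table("m")
        assert back.kernel == model.kernel
        assert back.C == model.C
        assert back.weight == model.weight
        assert back.support_pairs == model.support_pairs

    def test_missing_parameter_row_rejected(self, store):
        store.conn.execute(
            "CREATE TABLE broken (RowKind TEXT, CVal REAL, KType TEXT, KVal REAL,"
            " Alpha REAL, Vector1 TEXT, Vector2 TEXT, PreferredID TEXT, OtherID TEXT)"
        )
        with pytest.raises(ValueError, match="parameter row"):
            store.read_model_table("broken")


class TestCommands:
    def test_learn_then_predict_orders_separable_rows(self, store):
        rows = [
            ("hi", "0:1.0", "q", 2),
            ("lo", "", "q", 1),
        ]
        store.create_train_table("train_table", rows)
        store.create_test_table("test_table", [("hi", "0:1.0"), ("lo", "")])
        store.learn_command("train_table", "model_table", LearnParams(1.0))
        out = dict(store.predict_command("model_table", "test_table", "output_table"))
        assert out["hi"] > out["lo"]

    def test_predict_matches_in_memory_oracle(self, store, separable_records,
                                              separable_rows):
        store.create_train_table("train_table", separable_rows)
        test_rows = [(r.id, format_sparse(r.fvector)) for r in separable_records]
        store.create_test_table("test_table", test_rows)
        store.learn_command("train_table", "model_table", LearnParams(2.0))
        out = dict(store.predict_command("model_table", "test_table", "output_table"))

        model, _ = ranksvm_learn(separable_records, C=2.0)
        expected = ranksvm_predict(
            model, [r.fvector for r in sorted(separable_records, key=lambda r: r.id)]
        )
        ids = sorted(out)
        np.testing.assert_allclose([out[i] for i in ids], expected, atol=1e-12)

    def test_output_ids_match_test_ids(self, store, separable_rows):
        store.create_train_table("train_table", separable_rows)
        store.create_test_table("test_table", [("a", "0:0.2"), ("b", "1:0.4")])
        store.learn_command("train_table", "model_table", LearnParams(1.0))
        out = store.predict_command("model_table", "test_table", "output_table")
        assert [i for i, _ in out] == ["a", "b"]

    def test_empty_test_table_gives_empty_output(self, store, separable_rows):
        store.create_train_table("train_table", separable_rows)
        store.create_test_table("test_table", [])
        store.learn_command("train_table", "model_table", LearnParams(1.0))
        assert store.predict_command("model_table", "test_table", "out") == []

    def test_auto_c_uses_rank_selection(self, store):
        from relrank import rank_select_C

        # overlapping non-negative vectors so the linear K > 0 precondition holds
        rows = [
            ("a", "0:1.0 1:0.2", "q", 3),
            ("b", "0:0.8 1:0.3", "q", 2),
            ("c", "0:0.1 1:1.0", "q", 1),
        ]
        store.create_train_table("train_table", rows)
        model = store.learn_command("train_table", "m", LearnParams("auto"))
        records = store.read_train_records("train_table")
        assert model.C == pytest.approx(rank_select_C(records).selected)

    def test_learn_on_empty_table_rejected(self, store):
        store.create_train_table("train_table", [])
        with pytest.raises(ValueError, match="empty train table"):
            store.learn_command("train_table", "m", LearnParams(1.0))


class TestRankedRetrieval:
    def test_full_sorted_table_when_k_large(self, store, separable_rows):
        store.create_train_table("train_table", separable_rows)
        test_rows = [(rid, fv) for rid, fv, _, _ in separable_rows]
        store.create_test_table("test_table", test_rows)
        ranked = store.ranked_retrieval("train_table", "test_table",
                                        LearnParams(10.0), k=100)
        assert len(ranked) == len(test_rows)
        scores = [s for _, s in ranked]
        assert scores == sorted(scores, reverse=True)

    def test_judged_top_level_docs_outrank_bottom_level(self, store,
                                                        separable_records,
                                                        separable_rows):
        store.create_train_table("train_table", separable_rows)
        test_rows = [(rid, fv) for rid, fv, _, _ in separable_rows]
        store.create_test_table("test_table", test_rows)
        ranked = store.ranked_retrieval("train_table", "test_table",
                                        LearnParams(100.0), k=10)
        pos = {rid: i for i, (rid, _) in enumerate(ranked)}
        by_level = {r.id: r.rank for r in separable_records}
        for rid_hi in (r.id for r in separable_records if r.rank == 3):
            for rid_lo in (r.id for r in separable_records if r.rank == 1):
                assert pos[rid_hi] < pos[rid_lo]

    def test_k_below_one_rejected(self, store, separable_rows):
        store.create_train_table("train_table", separable_rows)
        store.create_test_table("test_table", [("a", "0:1.0")])
        with pytest.raises(ValueError, match="k must be"):
            store.ranked_retrieval("train_table", "test_table", LearnParams(1.0), 0)

    def test_rerun_is_stable(self, store, separable_rows):
        store.create_train_table("train_table", separable_rows)
        test_rows = [(rid, fv) for rid, fv, _, _ in separable_rows]
        store.create_test_table("test_table", test_rows)
        first = store.ranked_retrieval("train_table", "test_table", LearnParams(2.0), 6)
        second = store.ranked_retrieval("train_table", "test_table", LearnParams(2.0), 6)
        assert first == second


class TestTightLooseEquivalence:
    def test_identical_models_and_rankings(self, random_records, tmp_path):
        rng = np.random.default_rng(17)
        for trial in range(5):
            records = random_records(rng, 8, 4, groups=2, nonneg=True)
            rows = train_rows_from_records(records)
            with RankStore() as store:
                store.create_train_table("train_table", rows)
                store.create_test_table(
                    "test_table", [(r.id, format_sparse(r.fvector)) for r in records]
                )
                params = LearnParams(1.5)
                tight = store.learn_command("train_table", "m_tight", params)
                loose = store.learn_command_loose(
                    "train_table", "m_loose", params, workdir=tmp_path
                )
                assert tight.C == loose.C
                assert tight.kernel == loose.kernel
                assert tight.weight == loose.weight
                assert tight.support_pairs == loose.support_pairs
                out_t = store.predict_command("m_tight", "test_table", "o_t")
                out_l = store.predict_command("m_loose", "test_table", "o_l")
                assert out_t == out_l


class TestFeedbackLoop:
    def _session(self):
        candidates = {
            "d1": {0: 1.0, 2: 0.3},
            "d2": {0: 0.9, 2: 0.2},
            "d3": {1: 1.0, 2: 0.4},
            "d4": {1: 0.8, 2: 0.3},
            "d5": {0: 0.5, 1: 0.5, 2: 0.3},
        }
        return FeedbackSession(query="q", candidates=candidates)

    def test_round_ranks_all_candidates(self):
        session = self._session()
        ranked = feedback_round(session, {"d1": 3, "d3": 1}, k=10)
        assert len(ranked) == 5
        pos = {rid: i for i, (rid, _) in enumerate(ranked)}
        assert pos["d1"] < pos["d3"]
        assert pos["d2"] < pos["d3"]  # similar to the relevant doc

    def test_single_level_feedback_rejected(self):
        session = self._session()
        with pytest.raises(ValueError, match="two relevance levels"):
            feedback_round(session, {"d1": 2, "d2": 2})

    def test_judgments_accumulate_across_rounds(self):
        session = self._session()
        feedback_round(session, {"d1": 3, "d3": 1}, k=5)
        feedback_round(session, {"d4": 2}, k=5)
        assert session.judgments == {"d1": 3, "d3": 1, "d4": 2}

    def test_identical_repush_gives_identical_ranking(self):
        session = self._session()
        first = feedback_round(session, {"d1": 3, "d3": 1}, k=5)
        second = feedback_round(session, {}, k=5)
        assert first == second

    def test_out_of_range_level_rejected(self):
        session = self._session()
        with pytest.raises(ValueError, match="outside 1..3"):
            session.judge("d1", 4)

    def test_unknown_candidate_rejected(self):
        session = self._session()
        with pytest.raises(ValueError, match="not a candidate"):
            session.judge("nope", 2)


class TestMatchCandidates:
    def test_conjunctive_filter(self, toy_corpus):
        from relrank import featurize_corpus

        _, vectors = featurize_corpus(toy_corpus)
        hits = match_candidates(toy_corpus, vectors, "swine flu")
        assert set(hits) == {"d2"}
        hits = match_candidates(toy_corpus, vectors, "cancer")
        assert set(hits) == {"d1", "d3", "d4", "d6"}

    def test_stopword_only_query_rejected(self, toy_corpus):
        from relrank import featurize_corpus

        _, vectors = featurize_corpus(toy_corpus)
        with pytest.raises(ValueError, match="no indexable terms"):
            match_candidates(toy_corpus, vectors, "the and of")
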