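"""Knowledge store: build stages, co-occurrence accounting, retrieval,
and the primary/user tier split."""

import itertools

import numpy as np
import pytest

from kbdiffuse.encoding import TokenSettings, encode
from kbdiffuse.store import CooccurrenceStore, DataItem, KnowledgeBase

from conftest import random_items


class TestBuild:
    def test_self_queries(self, toy_kb):
        for item_id in ["i0", "i1", "i2"]:
            item = toy_kb.get_item(item_id)
            vec = toy_kb.encode_text(item.text, normalize=True)
            hits = toy_kb.nearest(vec, "main", n=1)
            assert hits[0].item_id == item_id
            assert hits[0].similarity == pytest.approx(1.0, abs=1e-9)

    def test_collection_scoping(self, settings):
        a = [DataItem(id="a1", body="alpha beta"), DataItem(id="a2", body="beta gamma")]
        b = [DataItem(id="b1", body="alpha delta")]
        kb = KnowledgeBase.build({"ca": a, "cb": b}, settings)
        vec = kb.encode_text("alpha", normalize=True)
        assert {h.item_id for h in kb.nearest(vec, "ca", n=5)} == {"a1", "a2"}
        assert {h.item_id for h in kb.nearest(vec, "cb", n=5)} == {"b1"}

    def test_duplicate_ids_rejected(self, settings):
        items = [DataItem(id="x", body="aaa"), DataItem(id="x", body="bbb")]
        with pytest.raises(ValueError, match="duplicate"):
            KnowledgeBase.build({"c": items}, settings)

    def test_empty_collection_named_in_error(self, settings):
        with pytest.raises(ValueError, match="bad_coll"):
            KnowledgeBase.build(
                {"ok": [DataItem(id="x", body="aaa")], "bad_coll": []}, settings
            )

    def test_cooccurrence_diagonal_positive_for_used_features(self, settings, rng):
        items = random_items(rng, 200)
        kb = KnowledgeBase.build({"c": items}, settings, c0=1.0, c1=0.0)
        coll = kb.collections["c"]
        used = sorted({int(i) for v in coll.vectors.values() for i in v.indices})
        diag = coll.cooccurrence.diagonal()
        assert all(diag[i] > 0 for i in used)


class TestCooccurrence:
    def test_pair_increment_inverse_length(self):
        store = CooccurrenceStore(4)
        store.increment(np.array([0, 2]))
        m = store.matrix
        assert m[0, 2] == pytest.approx(0.5)
        assert m[2, 0] == pytest.approx(0.5)
        assert m[0, 0] == pytest.approx(0.5)

    def test_single_feature_only_diagonal(self):
        store = CooccurrenceStore(4)
        store.increment(np.array([1]))
        m = store.matrix
        assert m[1, 1] == pytest.approx(1.0)
        assert m.nnz == 1

    def test_linearity_of_identical_items(self):
        one = CooccurrenceStore(5)
        two = CooccurrenceStore(5)
        idx = np.array([0, 1, 3])
        one.increment(idx)
        two.increment(idx)
        two.increment(idx)
        assert np.allclose(two.matrix.toarray(), 2 * one.matrix.toarray())

    def test_total_mass_matches_bruteforce_recount(self, rng):
        # sum over items of L^2 pairs each weighted 1/L = sum of L
        store = CooccurrenceStore(30)
        expected = np.zeros((30, 30))
        for _ in range(100):
            L = int(rng.integers(1, 8))
            idx = rng.choice(30, size=L, replace=False)
            store.increment(idx)
            for i, j in itertools.product(idx, idx):
                expected[i, j] += 1.0 / L
        assert np.allclose(store.matrix.toarray(), expected)

    def test_symmetry_and_insert_order_invariance(self, rng):
        idx_sets = [rng.choice(20, size=int(rng.integers(1, 6)), replace=False) for _ in range(30)]
        forward = CooccurrenceStore(20)
        backward = CooccurrenceStore(20)
        for idx in idx_sets:
            forward.increment(idx)
        for idx in reversed(idx_sets):
            backward.increment(idx)
        f = forward.matrix.toarray()
        assert np.allclose(f, f.T)
        assert np.allclose(f, backward.matrix.toarray())


class TestNearest:
    def test_bruteforce_cosine_agreement(self, settings, rng):
        items = random_items(rng, 50)
        kb = KnowledgeBase.build({"c": items}, settings, c0=0.0, c1=1.0)
        coll = kb.collections["c"]
        for _ in range(10):
            probe = random_items(rng, 1, prefix="q")[0]
            vec = kb.encode_text(probe.text, normalize=True)
            if vec.nnz == 0:
                continue
            hits = kb.nearest(vec, "c", n=10)
            dense_q = vec.to_dense(len(kb.catalog))
            sims = {
                iid: float(v.to_dense(len(kb.catalog)) @ dense_q)
                for iid, v in coll.vectors.items()
            }
            expected = sorted(sims, key=lambda i: (-sims[i], i))[:10]
            assert [h.item_id for h in hits] == expected

    def test_orthogonal_query_ties_in_id_order(self, settings):
        items = [DataItem(id=f"i{j}", body="shared") for j in range(3)]
        items = [
            DataItem(id="b", body="aaa"),
            DataItem(id="a", body="aaa"),
            DataItem(id="c", body="bbb"),
        ]
        kb = KnowledgeBase.build({"c": items}, settings, c0=1.0, c1=0.0)
        vec = kb.encode_text("bbb", normalize=True)
        hits = kb.nearest(vec, "c", n=3)
        assert [h.item_id for h in hits] == ["c", "a", "b"]
        assert hits[1].similarity == pytest.approx(0.0)

    def test_empty_query_warns_and_returns_nothing(self, toy_kb):
        from kbdiffuse.encoding import EncodedVector

        with pytest.warns(UserWarning):
            assert toy_kb.nearest(EncodedVector.empty(), "main") == []

    def test_ranks_consecutive_similarity_nonincreasing(self, toy_kb):
        vec = toy_kb.encode_text("skin lesion", normalize=True)
        hits = toy_kb.nearest(vec, "main", n=3)
        assert [h.rank for h in hits] == [1, 2, 3]
        sims = [h.similarity for h in hits]
        assert sims == sorted(sims, reverse=True)


class TestUserTier:
    def test_write_into_primary_rejected(self, toy_kb):
        with pytest.raises(ValueError, match="primary"):
            toy_kb.add_item(DataItem(id="u1", body="new text"), "main")

    def test_immediate_retrieval_and_no_primary_rebuild(self, toy_kb):
        primary_index = toy_kb.collections["main"].index
        primary_matrix = toy_kb.collections["main"].index.matrix
        toy_kb.add_item(DataItem(id="u1", body="lethargy skin"), "notes")
        vec = toy_kb.encode_text("lethargy skin", normalize=True)
        hits = toy_kb.nearest(vec, "notes", n=1)
        assert hits[0].item_id == "u1"
        assert toy_kb.collections["main"].index is primary_index
        assert toy_kb.collections["main"].index.matrix is primary_matrix

    def test_tier_separation_restores_primary_results(self, settings, rng):
        items = random_items(rng, 30)
        kb = KnowledgeBase.build({"c": items}, settings)
        vec = kb.encode_text(items[0].text, normalize=True)
        before = kb.nearest(vec, "c", n=5)
        for j in range(5):
            kb.add_item(DataItem(id=f"u{j}", body=f"annotation {j}"), "user")
        kb.drop_user_tier()
        after = kb.nearest(vec, "c", n=5)
        assert before == after
        assert "user" not in kb.collections

    def test_duplicate_user_id_rejected(self, toy_kb):
        with pytest.raises(ValueError, match="already"):
            toy_kb.add_item(DataItem(id="i0", body="x"), "notes")

    def test_user_cooccurrence_incremented(self, toy_kb):
        toy_kb.add_item(DataItem(id="u1", body="skin lesion"), "notes")
        cooc = toy_kb.collections["notes"].cooccurrence
        assert cooc.matrix.nnz > 0


def test_save_load_roundtrip(tmp_path, toy_kb):
    toy_kb.add_item(DataItem(id="u1", body="skin note"), "notes")
    toy_kb.save(tmp_path / "store")
    loaded = KnowledgeBase.load(tmp_path / "store")
    assert set(loaded.collections) == {"main", "notes"}
    assert loaded.collections["notes"].tier == "user"
    vec = loaded.encode_text("vascular lesion of the skin", normalize=True)
    orig = toy_kb.nearest(vec, "main", n=3)
    assert loaded.nearest(vec, "main", n=3) == orig
    assert np.allclose(
        loaded.collections["main"].cooccurrence.matrix.toarray(),
        toy_kb.collections["main"].cooccurrence.matrix.toarray(),
    )
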