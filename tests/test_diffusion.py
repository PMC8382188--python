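"""Diffusion transform: row construction, harmonic gating, 1-step
application, and equivalence with a dense linear-algebra oracle."""

import numpy as np
import pytest

from kbdiffuse.diffusion import (
    DiffusionSettings,
    apply,
    apply_to_kb,
    diffusion_row,
    explain_imputation,
)
from kbdiffuse.encoding import EncodedVector, FeatureCatalog, TokenSettings, scan_corpus
from kbdiffuse.store import CooccurrenceStore, DataItem, KnowledgeBase

from conftest import random_items


def uniform_catalog(features, weight=1.0):
    return FeatureCatalog(
        feature_index={f: i for i, f in enumerate(features)},
        doc_count=np.ones(len(features), dtype=np.int64),
        total_docs=1,
        c0=weight,
        c1=0.0,
    )


class TestDiffusionRow:
    def test_printed_formula(self):
        # c_ii = 4, c_ij = 2, w_i = w_j = 1 -> D_ij = (2/4) * (2*1*1/2) = 0.5
        store = CooccurrenceStore(2)
        for _ in range(4):
            store.increment(np.array([0, 1]))  # c_00 += .5, c_01 += .5
        for _ in range(2):
            store.increment(np.array([0]))  # c_00 += 1
        cat = uniform_catalog(["fa", "fb"])
        assert store.matrix[0, 0] == pytest.approx(4.0)
        assert store.matrix[0, 1] == pytest.approx(2.0)
        row = diffusion_row(0, store, cat)
        d = row.to_dict()
        assert d[1] == pytest.approx(0.5)

    def test_unit_diagonal_times_weight(self):
        # c^_ii = 1, harmonic of equal weights is the weight itself
        store = CooccurrenceStore(2)
        store.increment(np.array([0, 1]))
        cat = uniform_catalog(["fa", "fb"], weight=0.7)
        row = diffusion_row(0, store, cat)
        assert row.to_dict()[0] == pytest.approx(0.7)

    def test_zero_weight_feature_blocked(self):
        store = CooccurrenceStore(2)
        store.increment(np.array([0, 1]))
        cat = FeatureCatalog(
            feature_index={"fa": 0, "fb": 1},
            doc_count=np.array([1, 2]),
            total_docs=2,
            c0=0.0,
            c1=1.0,
        )
        assert cat.weights[1] == 0.0  # ubiquitous feature
        row = diffusion_row(0, store, cat)
        assert 1 not in row.to_dict()

    def test_unseen_feature_empty_row(self):
        store = CooccurrenceStore(3)
        store.increment(np.array([0]))
        cat = uniform_catalog(["fa", "fb", "fc"])
        assert diffusion_row(2, store, cat).nnz == 0


def dense_diffusion_oracle(q_dense, strengths_stores, weights):
    """q + sum_d s_d * D_d q with sources restricted to q's support,
    assembled densely from first principles."""
    out = q_dense.copy()
    support = np.nonzero(q_dense)[0]
    for s, store in strengths_stores:
        C = store.matrix.toarray()
        n = C.shape[0]
        D = np.zeros((n, n))
        for i in range(n):
            if C[i, i] == 0:
                continue
            for j in range(n):
                denom = weights[i] + weights[j]
                harm = 2 * weights[i] * weights[j] / denom if denom > 0 else 0.0
                D[i, j] = C[i, j] / C[i, i] * harm
        restricted = np.zeros_like(q_dense)
        restricted[support] = q_dense[support]
        out = out + s * (D @ restricted)
    return out


@pytest.fixture
def random_setup(rng):
    n_feat = 40
    features = [f"f{i:02d}" for i in range(n_feat)]
    cat = FeatureCatalog(
        feature_index={f: i for i, f in enumerate(features)},
        doc_count=rng.integers(1, 50, size=n_feat),
        total_docs=50,
        c0=0.2,
        c1=1.0,
    )
    stores = {}
    for name in ["d1", "d2"]:
        store = CooccurrenceStore(n_feat)
        for _ in range(60):
            idx = rng.choice(n_feat, size=int(rng.integers(1, 7)), replace=False)
            store.increment(idx)
        stores[name] = store
    return cat, stores


class TestApply:
    def test_zero_strength_identity(self, random_setup):
        cat, stores = random_setup
        q = EncodedVector(np.array([3, 7]), np.array([0.5, -0.2]))
        out = apply(q, DiffusionSettings({"d1": 0.0}), stores, cat)
        assert out.to_dict() == q.to_dict()

    def test_sparse_matches_dense_oracle(self, random_setup, rng):
        cat, stores = random_setup
        n_feat = len(cat)
        settings = DiffusionSettings({"d1": 0.8, "d2": 1.3})
        for _ in range(10):
            support = rng.choice(n_feat, size=int(rng.integers(1, 6)), replace=False)
            vals = rng.normal(size=support.size)
            q = EncodedVector(np.sort(support), vals[np.argsort(support)])
            out = apply(q, settings, stores, cat)
            expected = dense_diffusion_oracle(
                q.to_dense(n_feat),
                [(0.8, stores["d1"]), (1.3, stores["d2"])],
                cat.weights,
            )
            np.testing.assert_allclose(out.to_dense(n_feat), expected, atol=1e-10)

    def test_single_feature_matches_row(self, random_setup):
        cat, stores = random_setup
        i = 5
        s = 0.9
        q = EncodedVector(np.array([i]), np.array([1.0]))
        out = apply(q, DiffusionSettings({"d1": s}), stores, cat).to_dict()
        # contribution at target j is s * (c_ji / c_jj) * harm(w_j, w_i)
        C = stores["d1"].matrix
        w = cat.weights
        for j, v in out.items():
            denom = w[i] + w[j]
            harm = 2 * w[i] * w[j] / denom if denom > 0 else 0.0
            expected = s * C[j, i] / C[j, j] * harm if C[j, j] > 0 else 0.0
            if j == i:
                expected += 1.0
            assert v == pytest.approx(expected, abs=1e-12)

    def test_linearity(self, random_setup):
        cat, stores = random_setup
        settings = DiffusionSettings({"d1": 1.1})
        q = EncodedVector(np.array([2, 9, 11]), np.array([0.3, -0.7, 1.2]))
        out1 = apply(q, settings, stores, cat)
        out2 = apply(q.scaled(2.5), settings, stores, cat)
        np.testing.assert_allclose(out2.to_dense(len(cat)), 2.5 * out1.to_dense(len(cat)), atol=1e-12)

    def test_additivity_across_datasets(self, random_setup):
        cat, stores = random_setup
        q = EncodedVector(np.array([4, 8]), np.array([1.0, 0.5]))
        both = apply(q, DiffusionSettings({"d1": 0.6, "d2": 0.4}), stores, cat)
        only1 = apply(q, DiffusionSettings({"d1": 0.6}), stores, cat)
        only2 = apply(q, DiffusionSettings({"d2": 0.4}), stores, cat)
        n = len(cat)
        np.testing.assert_allclose(
            both.to_dense(n),
            only1.to_dense(n) + only2.to_dense(n) - q.to_dense(n),
            atol=1e-12,
        )

    def test_monotone_influence(self, random_setup):
        cat, stores = random_setup
        q = EncodedVector(np.array([5]), np.array([1.0]))
        weak = apply(q, DiffusionSettings({"d1": 0.5}), stores, cat).to_dict()
        strong = apply(q, DiffusionSettings({"d1": 1.5}), stores, cat).to_dict()
        for j, v in weak.items():
            if j == 5:
                continue
            assert abs(strong.get(j, 0.0)) >= abs(v) - 1e-12

    def test_unknown_collection_raises(self, random_setup):
        cat, stores = random_setup
        q = EncodedVector(np.array([0]), np.array([1.0]))
        with pytest.raises(KeyError, match="nope"):
            apply(q, DiffusionSettings({"nope": 1.0}), stores, cat)

    def test_negative_strength_rejected(self):
        with pytest.raises(ValueError):
            DiffusionSettings({"d": -1.0})

    def test_support_grows_only_to_cooccurring_features(self, random_setup):
        cat, stores = random_setup
        q = EncodedVector(np.array([5]), np.array([1.0]))
        out = apply(q, DiffusionSettings({"d1": 1.0}), stores, cat)
        C = stores["d1"].matrix
        allowed = set(C.getrow(5).indices) | {5}
        assert set(int(i) for i in out.indices) <= allowed


class TestExplain:
    def test_zero_strength_empty(self, random_setup):
        cat, stores = random_setup
        q = EncodedVector(np.array([1]), np.array([1.0]))
        assert explain_imputation(q, DiffusionSettings({}), stores, cat) == []

    def test_single_feature_lists_row_offdiagonal(self, random_setup):
        cat, stores = random_setup
        i = 5
        q = EncodedVector(np.array([i]), np.array([1.0]))
        out = explain_imputation(q, DiffusionSettings({"d1": 1.0}), stores, cat, top_m=100)
        applied = apply(q, DiffusionSettings({"d1": 1.0}), stores, cat).to_dict()
        expected = {cat.features[j]: v for j, v in applied.items() if j != i}
        got = {name: v for name, v, _ in out}
        assert got == pytest.approx(expected)
        mags = [abs(v) for _, v, _ in out]
        assert mags == sorted(mags, reverse=True)

    def test_negative_query_weights_impute_negative(self, random_setup):
        cat, stores = random_setup
        q = EncodedVector(np.array([5]), np.array([-1.0]))
        out = explain_imputation(q, DiffusionSettings({"d1": 1.0}), stores, cat, top_m=100)
        assert out, "expected some imputation"
        assert all(v < 0 for _, v, _ in out)


def test_apply_to_kb_uses_collection_stores(toy_kb):
    q = toy_kb.encode_text("vascular", normalize=False)
    out = apply_to_kb(q, DiffusionSettings({"main": 1.0}), toy_kb)
    assert out.nnz > q.nnz  # imputes co-occurring k-mers
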