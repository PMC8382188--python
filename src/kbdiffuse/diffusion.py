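"""Co-occurrence-driven feature imputation (data diffusion).

A query vector ``q`` over k-mer features is augmented by transferring weight
from its own features to features that co-occurred with them in reference
collections:

    q  ->  q + sum_d  s_d * D_d q

with a per-collection diffusion matrix

    D_ij = c^_ij * 2 w_i w_j / (w_i + w_j)

where ``c^_ij = c_ij / c_ii`` is the row-normalized co-occurrence (unit
diagonal) and the second factor is the harmonic mean of the two feature
weights.  The harmonic mean gates diffusion both ways: an uninformative
feature (w = 0) neither sources nor receives weight, so common k-mers cannot
inflate the imputation.

Diffusion is restricted to one step: only features present in the original
query act as sources, and features imputed from one collection never source
diffusion through another.  This keeps queries sparse and avoids the
over-smoothing of iterated diffusion.  Queries may carry negative values
(e.g. from user annotations marking dissimilarity); the transform is linear
and sign-preserving.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping

import numpy as np

from .encoding import EncodedVector, FeatureCatalog
from .store import CooccurrenceStore, KnowledgeBase

__all__ = [
    "DiffusionSettings",
    "diffusion_row",
    "apply",
    "apply_to_kb",
    "explain_imputation",
]


@dataclass(frozen=True)
class DiffusionSettings:
    """Per-collection diffusion strengths ``s_d >= 0``; all-zero strengths
    give the identity transform."""

    strengths: Mapping[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for name, s in self.strengths.items():
            if s < 0:
                raise ValueError(f"diffusion strength for {name!r} is negative")

    @property
    def active(self) -> dict[str, float]:
        return {k: v for k, v in self.strengths.items() if v != 0.0}


def diffusion_row(
    i: int, cooc: CooccurrenceStore, catalog: FeatureCatalog
) -> EncodedVector:
    """Row i of the diffusion matrix: D_ij = (c_ij / c_ii) * harm(w_i, w_j).

    A feature never seen in the collection (c_ii = 0) yields an empty row.
    """
    matrix = cooc.matrix
    c_ii = matrix[i, i]
    if c_ii == 0:
        return EncodedVector.empty()
    row = matrix.getrow(i)
    cols = row.indices.astype(np.int64)
    vals = row.data / c_ii
    w = catalog.weights
    wi = w[i]
    wj = w[cols]
    denom = wi + wj
    with np.errstate(invalid="ignore", divide="ignore"):
        harm = np.where(denom > 0, 2.0 * wi * wj / np.where(denom > 0, denom, 1.0), 0.0)
    values = vals * harm
    keep = values != 0
    return EncodedVector(cols[keep], values[keep])


def _single_dataset_imputation(
    query: EncodedVector, cooc: CooccurrenceStore, catalog: FeatureCatalog
) -> dict[int, float]:
    """D @ q with sources restricted to the query's own support.

    The imputed value at target j is sum_i (c_ji / c_jj) harm(w_j, w_i) q_i;
    by symmetry of C this is assembled from the source rows of C divided by
    the target diagonal.
    """
    matrix = cooc.matrix
    diag = matrix.diagonal()
    w = catalog.weights
    out: dict[int, float] = {}
    for i, qi in zip(query.indices, query.values):
        row = matrix.getrow(int(i))
        if row.nnz == 0:
            continue
        cols = row.indices.astype(np.int64)
        c_vals = row.data
        d_target = diag[cols]
        wi = w[int(i)]
        wj = w[cols]
        denom = wi + wj
        with np.errstate(invalid="ignore", divide="ignore"):
            harm = np.where(denom > 0, 2.0 * wi * wj / np.where(denom > 0, denom, 1.0), 0.0)
        contrib = np.where(d_target > 0, c_vals / np.where(d_target > 0, d_target, 1.0), 0.0)
        contrib = contrib * harm * qi
        for j, v in zip(cols, contrib):
            if v != 0.0:
                out[int(j)] = out.get(int(j), 0.0) + float(v)
    return out


def apply(
    query: EncodedVector,
    settings: DiffusionSettings,
    stores: Mapping[str, CooccurrenceStore],
    catalog: FeatureCatalog,
) -> EncodedVector:
    """Diffuse a query: q + sum over collections of s_d * D_d q.

    Sources are the original query's features only (1-step restriction), so
    the multi-collection result is the sum of the single-collection
    imputations added to q.  The result is not re-normalized here; callers
    that feed it into cosine search normalize afterwards.
    """
    active = settings.active
    for name in active:
        if name not in stores:
            raise KeyError(f"unknown diffusion collection {name!r}")
    if not active or query.nnz == 0:
        return EncodedVector(query.indices.copy(), query.values.copy())
    acc = query.to_dict()
    for name, s in active.items():
        imputed = _single_dataset_imputation(query, stores[name], catalog)
        for j, v in imputed.items():
            acc[j] = acc.get(j, 0.0) + s * v
    return EncodedVector.from_dict(acc)


def apply_to_kb(
    query: EncodedVector, settings: DiffusionSettings, kb: KnowledgeBase
) -> EncodedVector:
    """Diffuse against a knowledge base's per-collection co-occurrence."""
    stores = {name: coll.cooccurrence for name, coll in kb.collections.items()}
    return apply(query, settings, stores, kb.catalog)


def explain_imputation(
    query: EncodedVector,
    settings: DiffusionSettings,
    stores: Mapping[str, CooccurrenceStore],
    catalog: FeatureCatalog,
    top_m: int = 10,
) -> list[tuple[str, float, dict[str, float]]]:
    """Top newly-imputed features with per-collection breakdown.

    Returns (feature, total imputed value, {collection: contribution}) for
    the ``top_m`` features absent from the raw query, ranked by absolute
    imputed value.  Negative values (from negative query or annotation
    weights) rank by magnitude.
    """
    if top_m < 1:
        raise ValueError("top_m must be >= 1")
    active = settings.active
    original = set(int(i) for i in query.indices)
    totals: dict[int, float] = {}
    breakdown: dict[int, dict[str, float]] = {}
    for name, s in active.items():
        if name not in stores:
            raise KeyError(f"unknown diffusion collection {name!r}")
        imputed = _single_dataset_imputation(query, stores[name], catalog)
        for j, v in imputed.items():
            if j in original:
                continue
            totals[j] = totals.get(j, 0.0) + s * v
            breakdown.setdefault(j, {})[name] = breakdown.get(j, {}).get(name, 0.0) + s * v
    names = catalog.features
    ranked = sorted(totals.items(), key=lambda kv: (-abs(kv[1]), names[kv[0]]))
    return [(names[j], v, breakdown[j]) for j, v in ranked[:top_m]]
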