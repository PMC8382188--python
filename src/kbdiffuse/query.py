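"""Free-text querying: ranked search and greedy decomposition.

Search encodes a query into the weighted k-mer space, optionally diffuses
it, and ranks one collection's items by cosine similarity.

Decomposition returns a small set of items whose linear combination
approximately reconstructs the query.  It is a greedy matching-pursuit loop:
find the best match to the current residual, refit the coefficients of all
selected items to the original query by least squares, recompute the
residual, and repeat until the requested number of components, a
non-positive coefficient, or a negligible residual.  The solution is greedy
and not unique, but runs in time comparable to a handful of searches.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import scipy.sparse as sp

from .diffusion import DiffusionSettings, apply_to_kb
from .encoding import EncodedVector
from .store import KnowledgeBase, SearchHit

__all__ = ["Decomposition", "search", "decompose"]


@dataclass
class Decomposition:
    """Ordered (item_id, coefficient) components plus the residual norm of
    the final least-squares reconstruction."""

    components: list[tuple[str, float]]
    residual_norm: float
    residual_norms: list[float]  # after each accepted component

    @property
    def item_ids(self) -> list[str]:
        return [item_id for item_id, _ in self.components]


def _prepare_query(
    kb: KnowledgeBase,
    query_text: str | None,
    diffusion_settings: DiffusionSettings | None,
    query_vector: EncodedVector | None = None,
) -> EncodedVector:
    if query_vector is None:
        if query_text is None:
            raise ValueError("either query_text or query_vector is required")
        raw = kb.encode_text(query_text, normalize=False)
    else:
        raw = query_vector
    if diffusion_settings is not None and diffusion_settings.active:
        raw = apply_to_kb(raw, diffusion_settings, kb)
    return raw.normalized()


def search(
    kb: KnowledgeBase,
    query_text: str | None,
    collection: str,
    n: int = 5,
    diffusion_settings: DiffusionSettings | None = None,
    query_vector: EncodedVector | None = None,
) -> list[SearchHit]:
    """Encode, diffuse, and rank: top-n items of a collection by cosine.

    A pre-encoded ``query_vector`` may be given instead of text.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    vec = _prepare_query(kb, query_text, diffusion_settings, query_vector)
    if vec.nnz == 0:
        warnings.warn(f"query {query_text!r} encoded to an empty vector")
        return []
    return kb.nearest(vec, collection, n)


def decompose(
    kb: KnowledgeBase,
    query_text: str | None,
    collection: str,
    max_components: int = 5,
    diffusion_settings: DiffusionSettings | None = None,
    residual_tolerance: float = 1e-6,
    refit: bool = True,
    query_vector: EncodedVector | None = None,
) -> Decomposition:
    """Greedily decompose a query into explanatory items.

    With ``refit`` (default) all coefficients are re-estimated against the
    original query at every iteration by unconstrained least squares; with
    ``refit=False`` earlier coefficients are frozen and only the newest is
    fitted to the residual.  Iteration stops at ``max_components``, when a
    coefficient becomes non-positive (the offending component is discarded),
    or when the residual norm falls below ``residual_tolerance`` times the
    query norm.
    """
    if max_components < 1:
        raise ValueError("max_components must be >= 1")
    if collection not in kb.collections:
        raise KeyError(f"unknown collection {collection!r}")
    query = _prepare_query(kb, query_text, diffusion_settings, query_vector)
    if query.nnz == 0:
        warnings.warn(f"query {query_text!r} encoded to an empty vector")
        return Decomposition([], 0.0, [])
    coll = kb.collections[collection]
    index = coll.index
    n_features = index.n_features
    q = sp.csr_matrix(
        (query.values, query.indices, [0, query.nnz]), shape=(1, n_features)
    ).T.toarray().ravel()
    q_norm = float(np.linalg.norm(q))

    selected: list[str] = []
    basis: list[np.ndarray] = []
    coeffs: list[float] = []
    residual = q.copy()
    residual_history: list[float] = []
    matrix = index.matrix
    selected_set: set[str] = set()

    while len(selected) < max_components:
        sims = matrix @ residual
        order = sorted(
            range(len(index.ids)), key=lambda i: (-sims[i], index.ids[i])
        )
        pick = None
        for i in order:
            if index.ids[i] not in selected_set:
                if sims[i] <= 0:
                    break
                pick = i
                break
        if pick is None:
            break
        vec = np.asarray(matrix.getrow(pick).todense()).ravel()
        if refit:
            trial = basis + [vec]
            A = np.column_stack(trial)
            sol, *_ = np.linalg.lstsq(A, q, rcond=None)
            if np.any(sol <= 0):
                break
            basis = trial
            coeffs = [float(c) for c in sol]
        else:
            c = float(vec @ residual)
            if c <= 0:
                break
            basis = basis + [vec]
            coeffs = coeffs + [c]
        selected.append(index.ids[pick])
        selected_set.add(index.ids[pick])
        recon = np.column_stack(basis) @ np.array(coeffs)
        residual = q - recon
        residual_history.append(float(np.linalg.norm(residual)))
        if residual_history[-1] < residual_tolerance * q_norm:
            break

    final = residual_history[-1] if residual_history else q_norm
    return Decomposition(list(zip(selected, coeffs)), final, residual_history)
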