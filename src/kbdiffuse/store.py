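"""Document store with per-collection co-occurrence statistics and
nearest-neighbor retrieval.

A :class:`KnowledgeBase` holds named collections of :class:`DataItem`
records.  Collections are either *primary* (created once at build time) or
*user* tier (writable at run time).  The tier split is strict: user inserts
never touch primary indexes, so run-time learning is immediate and primary
results are reproducible byte-for-byte after user data are removed.

Each collection maintains a symmetric sparse co-occurrence matrix ``C`` over
catalog features: inserting an item with L distinct features increments
``c_ij`` by ``1/L`` for every feature pair of the item, so co-occurrence in
short items counts more than in long ones.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import scipy.sparse as sp

from .encoding import (
    EncodedVector,
    FeatureCatalog,
    TokenSettings,
    encode,
    scan_corpus,
)

__all__ = [
    "DataItem",
    "CooccurrenceStore",
    "NeighborIndex",
    "SearchHit",
    "KnowledgeBase",
    "build",
]

PRIMARY = "primary"
USER = "user"


@dataclass
class DataItem:
    """One stored text record."""

    id: str
    title: str = ""
    body: str = ""
    collection: str = ""
    tier: str = PRIMARY
    metadata: dict[str, str] = field(default_factory=dict)

    @property
    def text(self) -> str:
        return f"{self.title} {self.body}".strip()


@dataclass(frozen=True)
class SearchHit:
    item_id: str
    similarity: float
    rank: int


class CooccurrenceStore:
    """Incrementally updatable symmetric co-occurrence counts over features."""

    def __init__(self, n_features: int):
        self.n_features = n_features
        self._matrix = sp.csr_matrix((n_features, n_features))
        self._buf_rows: list[np.ndarray] = []
        self._buf_cols: list[np.ndarray] = []
        self._buf_vals: list[np.ndarray] = []

    def increment(self, feature_indices: np.ndarray) -> None:
        """Record one item: every ordered feature pair (i, j), including the
        diagonal, gains 1/L where L is the item's distinct-feature count."""
        idx = np.asarray(feature_indices, dtype=np.int64)
        L = idx.size
        if L == 0:
            return
        w = 1.0 / L
        rows = np.repeat(idx, L)
        cols = np.tile(idx, L)
        self._buf_rows.append(rows)
        self._buf_cols.append(cols)
        self._buf_vals.append(np.full(rows.size, w))
        if sum(r.size for r in self._buf_rows) > 2_000_000:
            self._flush()

    def _flush(self) -> None:
        if not self._buf_rows:
            return
        add = sp.coo_matrix(
            (
                np.concatenate(self._buf_vals),
                (np.concatenate(self._buf_rows), np.concatenate(self._buf_cols)),
            ),
            shape=(self.n_features, self.n_features),
        ).tocsr()
        self._matrix = (self._matrix + add).tocsr()
        self._buf_rows, self._buf_cols, self._buf_vals = [], [], []

    @property
    def matrix(self) -> sp.csr_matrix:
        self._flush()
        return self._matrix

    def diagonal(self) -> np.ndarray:
        return self.matrix.diagonal()

    def row(self, i: int) -> sp.csr_matrix:
        return self.matrix.getrow(i)


class NeighborIndex:
    """Exact nearest-neighbor index: stacked unit item vectors queried by
    cosine similarity, ties broken by item id."""

    backend = "exact"

    def __init__(self, n_features: int):
        self.n_features = n_features
        self.ids: list[str] = []
        self._rows: list[EncodedVector] = []
        self._matrix: sp.csr_matrix | None = None

    def add(self, item_id: str, vector: EncodedVector) -> None:
        self.ids.append(item_id)
        self._rows.append(vector)
        self._matrix = None

    @property
    def matrix(self) -> sp.csr_matrix:
        if self._matrix is None:
            indptr = np.zeros(len(self._rows) + 1, dtype=np.int64)
            for i, v in enumerate(self._rows):
                indptr[i + 1] = indptr[i] + v.nnz
            indices = (
                np.concatenate([v.indices for v in self._rows])
                if self._rows
                else np.empty(0, dtype=np.int64)
            )
            data = (
                np.concatenate([v.values for v in self._rows])
                if self._rows
                else np.empty(0)
            )
            self._matrix = sp.csr_matrix(
                (data, indices, indptr), shape=(len(self._rows), self.n_features)
            )
        return self._matrix

    def query(self, vector: EncodedVector, n: int) -> list[SearchHit]:
        if vector.nnz == 0 or not self.ids:
            return []
        q = vector.normalized()
        qv = sp.csr_matrix(
            (q.values, q.indices, [0, q.nnz]), shape=(1, self.n_features)
        )
        sims = np.asarray((self.matrix @ qv.T).todense()).ravel()
        order = sorted(range(len(self.ids)), key=lambda i: (-sims[i], self.ids[i]))
        hits = []
        for rank, i in enumerate(order[:n], start=1):
            hits.append(SearchHit(self.ids[i], float(sims[i]), rank))
        return hits


class Collection:
    """One named collection: items, vectors, NN index, co-occurrence."""

    def __init__(self, name: str, tier: str, n_features: int):
        self.name = name
        self.tier = tier
        self.items: dict[str, DataItem] = {}
        self.vectors: dict[str, EncodedVector] = {}
        self.index = NeighborIndex(n_features)
        self.cooccurrence = CooccurrenceStore(n_features)

    def insert(self, item: DataItem, vector: EncodedVector) -> None:
        self.items[item.id] = item
        self.vectors[item.id] = vector
        self.index.add(item.id, vector)
        self.cooccurrence.increment(vector.indices)


class KnowledgeBase:
    """Catalog + collections; the object the query engine operates on."""

    def __init__(self, catalog: FeatureCatalog, settings: TokenSettings):
        self.catalog = catalog
        self.settings = settings
        self.collections: dict[str, Collection] = {}

    # -- construction ------------------------------------------------------

    @classmethod
    def build(
        cls,
        collections: Mapping[str, Sequence[DataItem]],
        settings: TokenSettings | None = None,
        c0: float = 0.0,
        c1: float = 1.0,
        max_features: int = 200_000,
    ) -> "KnowledgeBase":
        """Three-stage build: scan all documents into a shared feature
        catalog; encode and store every item; construct the per-collection
        index and co-occurrence structures."""
        settings = settings or TokenSettings()
        if not collections:
            raise ValueError("at least one collection is required")
        for name, items in collections.items():
            if not items:
                raise ValueError(f"collection {name!r} is empty")
        seen: set[str] = set()
        for items in collections.values():
            for item in items:
                if item.id in seen:
                    raise ValueError(f"duplicate item id {item.id!r}")
                seen.add(item.id)
        corpus = (
            item.text for items in collections.values() for item in items
        )
        catalog = scan_corpus(corpus, settings, c0=c0, c1=c1, max_features=max_features)
        kb = cls(catalog, settings)
        for name, items in collections.items():
            coll = Collection(name, PRIMARY, len(catalog))
            for item in items:
                item.collection = name
                item.tier = PRIMARY
                vec = encode(item.text, catalog, settings, normalize=True)
                coll.insert(item, vec)
            kb.collections[name] = coll
        return kb

    # -- run-time learning -------------------------------------------------

    def add_item(self, item: DataItem, target_collection: str) -> None:
        """Insert a user-tier item at run time.

        The target collection is created on first use; writing into a
        primary collection is refused.  Primary indexes are never touched,
        so the insert cost does not grow with primary data size.
        """
        existing = self.collections.get(target_collection)
        if existing is not None and existing.tier == PRIMARY:
            raise ValueError(
                f"collection {target_collection!r} is primary tier; "
                "user items go into separate user collections"
            )
        if any(item.id in c.items for c in self.collections.values()):
            raise ValueError(f"item id {item.id!r} already in store")
        if existing is None:
            existing = Collection(target_collection, USER, len(self.catalog))
            self.collections[target_collection] = existing
        item.collection = target_collection
        item.tier = USER
        vec = encode(item.text, self.catalog, self.settings, normalize=True)
        existing.insert(item, vec)

    def drop_user_tier(self) -> None:
        """Remove every user collection, restoring pristine primary state."""
        self.collections = {
            name: c for name, c in self.collections.items() if c.tier == PRIMARY
        }

    # -- retrieval ---------------------------------------------------------

    def get_item(self, item_id: str) -> DataItem:
        for coll in self.collections.values():
            if item_id in coll.items:
                return coll.items[item_id]
        raise KeyError(item_id)

    def nearest(
        self, query_vector: EncodedVector, collection: str, n: int = 5
    ) -> list[SearchHit]:
        """Top-n items of one collection by cosine similarity."""
        if n < 1:
            raise ValueError("n must be >= 1")
        if collection not in self.collections:
            raise KeyError(f"unknown collection {collection!r}")
        if query_vector.nnz == 0:
            warnings.warn("empty query vector: no features matched the catalog")
            return []
        return self.collections[collection].index.query(query_vector, n)

    def encode_text(self, text: str, normalize: bool = False) -> EncodedVector:
        return encode(text, self.catalog, self.settings, normalize=normalize)

    # -- persistence -------------------------------------------------------

    def save(self, directory: str | Path) -> None:
        directory = Path(directory)
        directory.mkdir(parents=True, exist_ok=True)
        meta = {
            "settings": {"k": self.settings.k, "case_fold": self.settings.case_fold},
            "catalog": {
                "features": self.catalog.features,
                "doc_count": self.catalog.doc_count.tolist(),
                "total_docs": self.catalog.total_docs,
                "c0": self.catalog.c0,
                "c1": self.catalog.c1,
                "max_features": self.catalog.max_features,
            },
            "collections": {
                name: coll.tier for name, coll in self.collections.items()
            },
        }
        (directory / "store.json").write_text(json.dumps(meta))
        for name, coll in self.collections.items():
            with open(directory / f"{name}.items.jsonl", "w") as fh:
                for item in coll.items.values():
                    fh.write(
                        json.dumps(
                            {
                                "id": item.id,
                                "title": item.title,
                                "body": item.body,
                                "metadata": item.metadata,
                            }
                        )
                        + "\n"
                    )
            sp.save_npz(directory / f"{name}.vectors.npz", coll.index.matrix)
            sp.save_npz(directory / f"{name}.cooc.npz", coll.cooccurrence.matrix)
            (directory / f"{name}.ids.json").write_text(json.dumps(coll.index.ids))

    @classmethod
    def load(cls, directory: str | Path) -> "KnowledgeBase":
        directory = Path(directory)
        meta = json.loads((directory / "store.json").read_text())
        settings = TokenSettings(**meta["settings"])
        cat = meta["catalog"]
        catalog = FeatureCatalog(
            feature_index={f: i for i, f in enumerate(cat["features"])},
            doc_count=np.array(cat["doc_count"], dtype=np.int64),
            total_docs=cat["total_docs"],
            c0=cat["c0"],
            c1=cat["c1"],
            max_features=cat["max_features"],
        )
        kb = cls(catalog, settings)
        for name, tier in meta["collections"].items():
            coll = Collection(name, tier, len(catalog))
            ids = json.loads((directory / f"{name}.ids.json").read_text())
            vectors = sp.load_npz(directory / f"{name}.vectors.npz").tocsr()
            with open(directory / f"{name}.items.jsonl") as fh:
                records = [json.loads(line) for line in fh]
            for rec, item_id in zip(records, ids):
                row = vectors.getrow(ids.index(rec["id"]))
                vec = EncodedVector(row.indices.astype(np.int64), row.data)
                item = DataItem(
                    id=rec["id"],
                    title=rec["title"],
                    body=rec["body"],
                    collection=name,
                    tier=tier,
                    metadata=rec.get("metadata", {}),
                )
                coll.items[item.id] = item
                coll.vectors[item.id] = vec
                coll.index.add(item.id, vec)
            coll.cooccurrence._matrix = sp.load_npz(directory / f"{name}.cooc.npz").tocsr()
            kb.collections[name] = coll
        return kb


def build(
    collections: Mapping[str, Sequence[DataItem] | Iterable[DataItem]],
    settings: TokenSettings | None = None,
    **kwargs,
) -> KnowledgeBase:
    """Module-level convenience wrapper around :meth:`KnowledgeBase.build`."""
    materialized = {name: list(items) for name, items in collections.items()}
    return KnowledgeBase.build(materialized, settings=settings, **kwargs)
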