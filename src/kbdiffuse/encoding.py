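"""Tokenization, k-mer feature catalogs, and sparse vector encodings.

Text is split into words, words into overlapping k-mers, and documents are
represented as sparse vectors over a catalog of k-mer features.  Each feature
carries a weight

    w = c0 - c1 * log10(n / N)

where ``n`` is the number of documents containing the feature and ``N`` the
total number of documents.  ``c1 = 0`` gives uniform weighting (every feature
equally important, suited to unweighted gene sets); ``c0 = 0`` gives pure
information-content (inverse document frequency) weighting, suited to natural
language where frequent words carry little signal.  Negative weights are
clipped at zero.
"""

from __future__ import annotations

import math
import string
from collections import Counter
from dataclasses import dataclass, field
from typing import Iterable, Iterator

import numpy as np

__all__ = [
    "TokenSettings",
    "FeatureCatalog",
    "EncodedVector",
    "kmerize",
    "tokenize",
    "scan_corpus",
    "encode",
]

_PUNCT = string.punctuation + "‘’“”"


@dataclass(frozen=True)
class TokenSettings:
    """How text is reduced to a multiset of k-mers.

    Parameters
    ----------
    k:
        Maximum k-mer length; words shorter than ``k`` pass through whole.
    case_fold:
        Lowercase text before tokenization.
    """

    k: int = 6
    case_fold: bool = True

    def __post_init__(self) -> None:
        if self.k < 1:
            raise ValueError("k must be >= 1")


def tokenize(text: str, settings: TokenSettings) -> list[str]:
    """Split text into words: whitespace-separated, case-folded, with
    leading/trailing punctuation stripped so gene symbols and ontology ids
    survive intact."""
    if settings.case_fold:
        text = text.lower()
    words = []
    for raw in text.split():
        word = raw.strip(_PUNCT)
        if word:
            words.append(word)
    return words


def kmerize(word: str, settings: TokenSettings) -> list[str]:
    """Overlapping k-mers of a word, e.g. 'vascular' at k=6 gives
    ['vascul', 'ascula', 'scular'].  Words of length <= k pass through
    whole; an empty word yields an empty list."""
    if not word:
        return []
    k = settings.k
    if len(word) <= k:
        return [word]
    return [word[i : i + k] for i in range(len(word) - k + 1)]


def _iter_doc_features(text: str, settings: TokenSettings) -> Iterator[str]:
    for word in tokenize(text, settings):
        yield from kmerize(word, settings)


@dataclass
class FeatureCatalog:
    """Map from k-mer features to integer columns, with document frequencies
    and the two weighting constants."""

    feature_index: dict[str, int]
    doc_count: np.ndarray  # documents containing each feature, aligned to columns
    total_docs: int
    c0: float = 0.0
    c1: float = 1.0
    max_features: int = 200_000
    _weights: np.ndarray | None = field(default=None, repr=False, compare=False)

    def __len__(self) -> int:
        return len(self.feature_index)

    @property
    def features(self) -> list[str]:
        out = [""] * len(self.feature_index)
        for f, i in self.feature_index.items():
            out[i] = f
        return out

    @property
    def weights(self) -> np.ndarray:
        """Per-column weights, computed lazily and clipped at zero."""
        if self._weights is None:
            with np.errstate(divide="ignore"):
                w = self.c0 - self.c1 * np.log10(self.doc_count / self.total_docs)
            self._weights = np.clip(w, 0.0, None)
        return self._weights

    def weight(self, feature: str) -> float:
        idx = self.feature_index.get(feature)
        if idx is None:
            return 0.0
        return float(self.weights[idx])


def scan_corpus(
    items: Iterable[str],
    settings: TokenSettings,
    c0: float = 0.0,
    c1: float = 1.0,
    max_features: int = 200_000,
) -> FeatureCatalog:
    """First pass over a corpus: count, per k-mer, the number of documents
    containing it (presence, not occurrences).

    If distinct k-mers exceed ``max_features``, the most document-frequent
    features are retained, ties broken lexicographically.
    """
    doc_freq: Counter[str] = Counter()
    n_docs = 0
    for text in items:
        feats = set(_iter_doc_features(text, settings))
        n_docs += 1
        doc_freq.update(feats)
    if n_docs == 0 or not doc_freq:
        raise ValueError("corpus is empty: nothing to index")
    if len(doc_freq) > max_features:
        kept = sorted(doc_freq.items(), key=lambda kv: (-kv[1], kv[0]))[:max_features]
    else:
        kept = sorted(doc_freq.items())
    feature_index = {f: i for i, f in enumerate(sorted(f for f, _ in kept))}
    counts = np.zeros(len(feature_index), dtype=np.int64)
    for f, n in kept:
        counts[feature_index[f]] = n
    return FeatureCatalog(
        feature_index=feature_index,
        doc_count=counts,
        total_docs=n_docs,
        c0=c0,
        c1=c1,
        max_features=max_features,
    )


@dataclass
class EncodedVector:
    """Sparse vector over catalog columns.

    ``indices`` are strictly increasing; values may be negative (user
    annotations and diffusion allow signed weights).  Encoded *documents* are
    unit-norm; raw queries may have any norm.
    """

    indices: np.ndarray
    values: np.ndarray

    @classmethod
    def empty(cls) -> "EncodedVector":
        return cls(np.empty(0, dtype=np.int64), np.empty(0, dtype=np.float64))

    @classmethod
    def from_dict(cls, data: dict[int, float]) -> "EncodedVector":
        if not data:
            return cls.empty()
        idx = np.array(sorted(data), dtype=np.int64)
        vals = np.array([data[i] for i in idx], dtype=np.float64)
        return cls(idx, vals)

    def __post_init__(self) -> None:
        self.indices = np.asarray(self.indices, dtype=np.int64)
        self.values = np.asarray(self.values, dtype=np.float64)
        if self.indices.size > 1 and not np.all(np.diff(self.indices) > 0):
            order = np.argsort(self.indices)
            self.indices = self.indices[order]
            self.values = self.values[order]
            if np.any(np.diff(self.indices) == 0):
                raise ValueError("duplicate indices in EncodedVector")

    @property
    def nnz(self) -> int:
        return int(self.indices.size)

    def norm(self) -> float:
        return float(np.linalg.norm(self.values))

    def normalized(self) -> "EncodedVector":
        n = self.norm()
        if n == 0:
            return EncodedVector.empty()
        return EncodedVector(self.indices.copy(), self.values / n)

    def scaled(self, alpha: float) -> "EncodedVector":
        return EncodedVector(self.indices.copy(), self.values * alpha)

    def to_dict(self) -> dict[int, float]:
        return {int(i): float(v) for i, v in zip(self.indices, self.values)}

    def to_dense(self, n_features: int) -> np.ndarray:
        out = np.zeros(n_features)
        out[self.indices] = self.values
        return out

    def dot(self, other: "EncodedVector") -> float:
        d = other.to_dict()
        return float(sum(v * d.get(int(i), 0.0) for i, v in zip(self.indices, self.values)))


def encode(
    text: str,
    catalog: FeatureCatalog,
    settings: TokenSettings,
    normalize: bool = True,
) -> EncodedVector:
    """Encode text as a sparse weighted k-mer vector.

    Each word contributes, to every one of its k-mers, a value

        (1 + ln(word count in item)) * catalog weight * overlap adjustment

    where the overlap adjustment is ``k / len(word)`` for words longer than
    ``k`` (overlapping k-mers of one long word share content, so the word's
    total mass stays about one token) and 1 otherwise.  Features absent from
    the catalog are dropped; an all-unknown text encodes to the empty vector.
    """
    word_counts = Counter(tokenize(text, settings))
    weights = catalog.weights
    acc: dict[int, float] = {}
    k = settings.k
    for word, count in word_counts.items():
        tf = 1.0 + math.log(count)
        adjust = k / len(word) if len(word) > k else 1.0
        for kmer in kmerize(word, settings):
            col = catalog.feature_index.get(kmer)
            if col is None:
                continue
            w = weights[col]
            if w == 0.0:
                continue
            acc[col] = acc.get(col, 0.0) + tf * w * adjust
    vec = EncodedVector.from_dict(acc)
    if normalize:
        vec = vec.normalized()
    return vec
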