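"""Deterministic synthetic-data generators.

Three surfaces are generated, each seeded and byte-reproducible:

* GO-like gene-set collections over a synthetic gene universe, with optional
  parent/child redundancy (supersets) emulating ontology structure;
* a pair of toy phenotype ontologies with a known one-to-one translation
  table, where a configurable fraction of term pairs share no k-mers
  directly but are bridged by planted co-occurrence snippets, so diffusion
  demonstrably rescues them;
* random text corpora with planted word co-occurrence.

All fixtures are emitted through the same formats the package reads for real
data (GMT gene sets, OBO ontologies), so format round-trips are exercised by
construction.
"""

from __future__ import annotations

import string as _string
from dataclasses import dataclass, field
from typing import Iterator

import numpy as np

from .genesets import SetCollection
from .store import DataItem

__all__ = [
    "FixtureConfig",
    "OntologyPair",
    "make_set_collection",
    "make_toy_ontology_pair",
    "make_corpus",
]


@dataclass(frozen=True)
class FixtureConfig:
    seed: int = 0
    universe_size: int = 20_000
    n_sets: int = 500
    set_size_range: tuple[int, int] = (5, 100)
    nesting_fraction: float = 0.0
    corpus_size: int = 100
    vocabulary_size: int = 200
    n_terms: int = 30
    hard_fraction: float = 0.2

    def __post_init__(self) -> None:
        lo, hi = self.set_size_range
        if not 1 <= lo <= hi:
            raise ValueError("invalid set_size_range")
        if hi > self.universe_size:
            raise ValueError("universe smaller than maximum set size")
        if not 0 <= self.nesting_fraction <= 1:
            raise ValueError("nesting_fraction must be in [0, 1]")
        if self.n_terms < 5:
            raise ValueError("need at least 5 ontology terms")


def _gene_universe(size: int) -> list[str]:
    # 6-character symbols: each gene is a single feature at the default k=6
    return [f"g{i:05d}" for i in range(size)]


def make_set_collection(config: FixtureConfig) -> tuple[SetCollection, list[str]]:
    """Generate a GO-like gene-set collection and its gene universe.

    Base sets have sizes uniform within ``set_size_range`` and are sampled
    independently from the universe (pairwise near-disjoint for a large
    universe).  With ``nesting_fraction > 0``, that fraction of base sets
    each gains up to two strict supersets (~1.25x and ~1.5x the base size,
    clipped to the size bound), emulating parent terms whose redundancy
    crowds ranked hit lists.
    """
    rng = np.random.default_rng(config.seed)
    universe = _gene_universe(config.universe_size)
    arr = np.asarray(universe)
    lo, hi = config.set_size_range
    sets: dict[str, frozenset[str]] = {}
    parents: dict[str, str] = {}
    base_ids = []
    for i in range(config.n_sets):
        size = int(rng.integers(lo, hi + 1))
        members = frozenset(rng.choice(arr, size=size, replace=False).tolist())
        name = f"set{i:04d}"
        sets[name] = members
        base_ids.append(name)
    if config.nesting_fraction > 0:
        n_nested = int(round(config.nesting_fraction * config.n_sets))
        chosen = rng.choice(base_ids, size=n_nested, replace=False)
        for name in sorted(chosen):
            base = sets[name]
            for tag, factor in (("a", 1.25), ("b", 1.5)):
                target = min(hi, int(round(factor * len(base))))
                extra = target - len(base)
                if extra < 1:
                    continue
                pool = np.asarray([g for g in universe if g not in base])
                added = rng.choice(pool, size=extra, replace=False)
                pid = f"{name}.parent{tag}"
                sets[pid] = base | frozenset(added.tolist())
                parents[name] = pid
    return SetCollection(sets, parents), universe


# ---------------------------------------------------------------------------
# toy ontology pair


_LETTERS = _string.ascii_lowercase


def _word_stream(rng: np.random.Generator, k: int = 6) -> Iterator[str]:
    """Random words of length 7-9 whose k-mer sets are pairwise disjoint,
    so lexical overlap between fixture words is fully controlled."""
    used_kmers: set[str] = set()
    while True:
        length = int(rng.integers(7, 10))
        word = "".join(_LETTERS[i] for i in rng.integers(0, 26, size=length))
        kmers = {word[i : i + k] for i in range(len(word) - k + 1)}
        if kmers & used_kmers:
            continue
        used_kmers.update(kmers)
        yield word


@dataclass
class OntologyPair:
    """Two OBO ontologies with a known term-to-term translation."""

    obo_a: str
    obo_b: str
    expected: dict[str, str]  # A term id -> B term id
    hard_ids: list[str]  # A ids whose pair shares no k-mers with the query
    bridge_items: list[DataItem]  # snippets linking hard A-words to B-words
    dictionary_items: list[DataItem]  # one definition item per content word
    query_words: dict[str, list[str]] = field(default_factory=dict)


def _obo_text(prefix: str, terms: list[dict]) -> str:
    lines = ["format-version: 1.2", f"ontology: toy-{prefix.lower()}", ""]
    for t in terms:
        lines.append("[Term]")
        lines.append(f"id: {t['id']}")
        lines.append(f"name: {t['name']}")
        if t.get("def"):
            lines.append(f'def: "{t["def"]}" []')
        for syn in t.get("synonyms", []):
            lines.append(f'synonym: "{syn}" EXACT []')
        if t.get("comment"):
            lines.append(f"comment: {t['comment']}")
        for parent in t.get("is_a", []):
            lines.append(f"is_a: {parent}")
        if t.get("obsolete"):
            lines.append("is_obsolete: true")
        lines.append("")
    return "\n".join(lines)


def make_toy_ontology_pair(config: FixtureConfig) -> OntologyPair:
    """Build two parallel toy ontologies (A = query side, B = target side).

    Every A term maps to exactly one B term.  *Easy* pairs share their two
    distinctive content words, so plain lexical search recovers them.
    *Hard* pairs use disjoint vocabularies (word x on the A side, synonym y
    on the B side); each hard A term also carries a decoy word planted into
    several unrelated B terms, so without diffusion the expected term ranks
    below the decoys.  Bridge snippets pairing x with y supply the
    co-occurrence that diffusion needs to impute y from x.  Dictionary items
    define every content word separately (one word per item), giving the
    feature catalog full vocabulary coverage without linking x to y.
    """
    rng = np.random.default_rng(config.seed)
    words = _word_stream(rng)
    n = config.n_terms
    n_hard = max(1, int(round(config.hard_fraction * n)))
    n_easy = n - n_hard
    if n_easy < 6:
        raise ValueError("need at least 6 easy terms to host decoys")

    filler = [next(words) for _ in range(3)]  # appears everywhere; low IC weight
    terms_a: list[dict] = []
    terms_b: list[dict] = []
    expected: dict[str, str] = {}
    hard_ids: list[str] = []
    bridge_items: list[DataItem] = []
    dictionary_words: set[str] = set(filler)
    query_words: dict[str, list[str]] = {}
    decoy_targets: dict[int, list[str]] = {}

    root_a = {"id": "A:0000000", "name": "root condition a"}
    root_b = {"id": "B:0000000", "name": "root condition b"}
    terms_a.append(root_a)
    terms_b.append(root_b)

    # easy pairs first (small ids), hard pairs afterwards
    for i in range(n):
        aid = f"A:{i + 1:07d}"
        bid = f"B:{i + 1:07d}"
        hard = i >= n_easy
        if hard:
            x1, x2 = next(words), next(words)
            y1, y2 = next(words), next(words)
            decoy = next(words)
            a_words = [x1, x2, decoy]
            b_words = [y1, y2]
            hard_ids.append(aid)
            bridge_items.append(
                DataItem(
                    id=f"bridge{i:03d}",
                    title=f"bridge {i}",
                    body=f"{x1} {y1} {x2} {y2}",
                )
            )
            # plant the decoy into 6 easy B terms so the hard query has
            # positive similarity to unrelated targets
            hosts = rng.choice(n_easy, size=6, replace=False)
            for h in hosts:
                decoy_targets.setdefault(int(h), []).append(decoy)
            dictionary_words.update([x1, x2, y1, y2, decoy])
        else:
            d1, d2 = next(words), next(words)
            a_words = [d1, d2]
            b_words = [d1, d2]
            dictionary_words.update([d1, d2])
        syn = next(words)
        dictionary_words.add(syn)
        terms_a.append(
            {
                "id": aid,
                "name": f"{a_words[0]} {filler[0]}",
                "def": " ".join(a_words) + f" {filler[1]}",
                "synonyms": [f"{a_words[-1]} {filler[2]}"],
                "is_a": ["A:0000000"],
            }
        )
        terms_b.append(
            {
                "id": bid,
                "name": f"{b_words[0]} {filler[0]}",
                "def": " ".join(b_words) + f" {filler[1]}",
                "synonyms": [f"{syn} {filler[2]}"],
                "is_a": ["B:0000000"],
            }
        )
        expected[aid] = bid
        query_words[aid] = a_words
    for h, decoys in decoy_targets.items():
        terms_b[h + 1]["def"] += " " + " ".join(decoys)

    dictionary_items = [
        DataItem(id=f"dict-{w}", title=w, body=f"{w} definition entry")
        for w in sorted(dictionary_words)
    ]
    return OntologyPair(
        obo_a=_obo_text("A", terms_a),
        obo_b=_obo_text("B", terms_b),
        expected=expected,
        hard_ids=hard_ids,
        bridge_items=bridge_items,
        dictionary_items=dictionary_items,
        query_words=query_words,
    )


def make_corpus(config: FixtureConfig) -> tuple[list[DataItem], list[tuple[str, str]]]:
    """Random text corpus with planted co-occurring word pairs.

    Returns the documents and the list of planted (word_a, word_b) pairs;
    each planted pair appears together in several documents, all other
    word pairings are random.
    """
    rng = np.random.default_rng(config.seed)
    vocab = [
        "".join(_LETTERS[i] for i in rng.integers(0, 26, size=7))
        for _ in range(config.vocabulary_size)
    ]
    n_planted = max(1, config.vocabulary_size // 20)
    planted = [(vocab[2 * i], vocab[2 * i + 1]) for i in range(n_planted)]
    docs: list[DataItem] = []
    for d in range(config.corpus_size):
        n_words = int(rng.integers(5, 11))
        body_words = rng.choice(vocab, size=n_words, replace=False).tolist()
        if d % 2 == 0:
            pair = planted[(d // 2) % n_planted]
            body_words = [w for w in body_words if w not in pair]
            body_words.extend(pair)
        docs.append(DataItem(id=f"doc{d:04d}", title=f"doc {d}", body=" ".join(body_words)))
    return docs, planted
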