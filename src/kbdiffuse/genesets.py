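"""Synthetic gene-set benchmarks, the Fisher-exact baseline, and
sum-of-Jaccard scoring.

Benchmark sets are generated from a collection of reference gene sets by
three recipes: *components* (genes drawn from one to four source sets),
*coverage* (the fraction of each source's genes transferred), and *signal*
(the fraction of the benchmark that originates from sources, the rest being
random genes from the universe).  Each method under evaluation reports a
ranked list of collection sets; the score sums Jaccard indexes between
reported and true source sets and so counts the number of correctly
identified components, bounded above by the component count.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
from scipy.optimize import linear_sum_assignment
from scipy.stats import hypergeom

__all__ = [
    "SetCollection",
    "BenchmarkSpec",
    "BenchmarkSet",
    "ScoreReport",
    "generate_benchmarks",
    "benchmark_grid",
    "fisher_rank",
    "jaccard",
    "score_sum_jaccard",
    "genomic_window_sets",
]

FULL_GRID_COMPONENTS = (1, 2, 3, 4)
FULL_GRID_FRACTIONS = (0.25, 0.5, 0.75, 1.0)
FULL_GRID_REPLICATES = 1000


@dataclass
class SetCollection:
    """Named gene sets with optional parent links emulating ontology
    redundancy (a parent is a superset of its child)."""

    sets: dict[str, frozenset[str]]
    parents: dict[str, str] = field(default_factory=dict)

    def __len__(self) -> int:
        return len(self.sets)

    def __getitem__(self, name: str) -> frozenset[str]:
        return self.sets[name]

    def ids(self) -> list[str]:
        return sorted(self.sets)

    def size_bounds(self) -> tuple[int, int]:
        sizes = [len(s) for s in self.sets.values()]
        return min(sizes), max(sizes)


@dataclass(frozen=True)
class BenchmarkSpec:
    """One cell of the benchmark grid."""

    n_components: int = 1
    coverage: float = 0.5
    signal: float = 0.5
    replicates: int = 1000
    seed: int = 0

    def __post_init__(self) -> None:
        if not 1 <= self.n_components:
            raise ValueError("n_components must be >= 1")
        if not 0 < self.coverage <= 1:
            raise ValueError("coverage must be in (0, 1]")
        if not 0 < self.signal <= 1:
            raise ValueError("signal must be in (0, 1]")
        if self.replicates < 1:
            raise ValueError("replicates must be >= 1")


@dataclass
class BenchmarkSet:
    """One synthetic gene set with its ground-truth source components."""

    genes: frozenset[str]
    truth_components: list[str]
    spec: BenchmarkSpec


@dataclass
class ScoreReport:
    per_component_ji: list[float]

    @property
    def sum_jaccard(self) -> float:
        return float(sum(self.per_component_ji))


def generate_benchmarks(
    collection: SetCollection,
    spec: BenchmarkSpec,
    universe: Sequence[str],
    rng: np.random.Generator | None = None,
    source_ids: Sequence[str] | None = None,
    exact_fraction: bool = True,
) -> list[BenchmarkSet]:
    """Sample ``spec.replicates`` benchmark sets.

    For each replicate: pick ``n_components`` distinct source sets; transfer
    ``round(coverage * |set|)`` genes from each (or Bernoulli(coverage) per
    gene when ``exact_fraction`` is off); then add random universe genes
    until source genes make up the ``signal`` fraction of the benchmark.
    Reproducible given the spec seed (or an explicit generator).
    """
    if rng is None:
        rng = np.random.default_rng(spec.seed)
    ids = sorted(source_ids) if source_ids is not None else collection.ids()
    if spec.n_components > len(ids):
        raise ValueError("not enough sets to sample components from")
    universe = np.asarray(sorted(universe))
    out: list[BenchmarkSet] = []
    for _ in range(spec.replicates):
        chosen = list(rng.choice(ids, size=spec.n_components, replace=False))
        source_genes: set[str] = set()
        for name in chosen:
            members = np.asarray(sorted(collection[name]))
            if exact_fraction:
                n_take = max(1, round(spec.coverage * members.size))
                take = rng.choice(members, size=n_take, replace=False)
            else:
                mask = rng.random(members.size) < spec.coverage
                take = members[mask]
            source_genes.update(take.tolist())
        n_src = len(source_genes)
        total = max(n_src, round(n_src / spec.signal))
        n_noise = total - n_src
        genes = set(source_genes)
        if n_noise > 0:
            pool = np.asarray([g for g in universe if g not in source_genes])
            noise = rng.choice(pool, size=min(n_noise, pool.size), replace=False)
            genes.update(noise.tolist())
        out.append(BenchmarkSet(frozenset(genes), chosen, spec))
    return out


def benchmark_grid(
    collection: SetCollection,
    universe: Sequence[str],
    components: Iterable[int] = FULL_GRID_COMPONENTS,
    coverages: Iterable[float] = FULL_GRID_FRACTIONS,
    signals: Iterable[float] = FULL_GRID_FRACTIONS,
    replicates: int = FULL_GRID_REPLICATES,
    seed: int = 0,
    count_only: bool = False,
):
    """Enumerate the full benchmark grid.

    With ``count_only`` the sets themselves are not constructed and the
    total benchmark count is returned (the full default grid enumerates
    4 x 4 x 4 x 1000 = 64,000 sets).
    """
    if count_only:
        return (
            len(list(components)) * len(list(coverages)) * len(list(signals)) * replicates
        )
    out: list[BenchmarkSet] = []
    rng = np.random.default_rng(seed)
    for n_comp in components:
        for cov in coverages:
            for sig in signals:
                spec = BenchmarkSpec(n_comp, cov, sig, replicates, seed)
                out.extend(generate_benchmarks(collection, spec, universe, rng=rng))
    return out


def fisher_rank(
    query_genes: Iterable[str],
    collection: SetCollection,
    universe: Sequence[str],
    n: int = 5,
) -> list[tuple[str, float]]:
    """Rank collection sets by one-sided Fisher exact (hypergeometric
    enrichment) p-value of the overlap with the query over the universe.

    Returns the top-n (set id, p-value) pairs, ascending p, ties broken by
    set id.
    """
    query = set(query_genes)
    if not query:
        raise ValueError("empty query gene set")
    M = len(set(universe))
    N = len(query)
    scored = []
    for name in collection.ids():
        members = collection[name]
        a = len(query & members)
        # P(X >= a) for X ~ Hypergeom(M, |set|, |query|)
        p = float(hypergeom.sf(a - 1, M, len(members), N))
        scored.append((name, p))
    scored.sort(key=lambda t: (t[1], t[0]))
    return scored[:n]


def jaccard(a: Iterable[str], b: Iterable[str]) -> float:
    a, b = set(a), set(b)
    union = a | b
    if not union:
        return 0.0
    return len(a & b) / len(union)


def score_sum_jaccard(
    reported: Sequence[Iterable[str]],
    truth: Sequence[Iterable[str]],
    mode: str = "assignment",
    top_n: int | None = None,
) -> ScoreReport:
    """Sum of Jaccard indexes between reported and true component sets.

    ``mode='assignment'`` (default) pairs truth components to the top
    ``top_n`` hits (default: one hit per component) by the one-to-one
    assignment maximizing total Jaccard; ``mode='positional'`` compares the
    i-th ranked hit to the i-th component.  The score lies in
    [0, len(truth)] and equals len(truth) only for exact recovery.
    """
    if not truth:
        raise ValueError("truth components must be non-empty")
    if top_n is None:
        top_n = len(truth)
    hits = [set(h) for h in list(reported)[:top_n]]
    truths = [set(t) for t in truth]
    if mode == "positional":
        per = [
            jaccard(hits[i], truths[i]) if i < len(hits) else 0.0
            for i in range(len(truths))
        ]
        return ScoreReport(per)
    if mode != "assignment":
        raise ValueError(f"unknown scoring mode {mode!r}")
    if not hits:
        return ScoreReport([0.0] * len(truths))
    ji = np.zeros((len(truths), len(hits)))
    for i, t in enumerate(truths):
        for j, h in enumerate(hits):
            ji[i, j] = jaccard(t, h)
    rows, cols = linear_sum_assignment(-ji)
    per = [0.0] * len(truths)
    for r, c in zip(rows, cols):
        per[r] = float(ji[r, c])
    return ScoreReport(per)


def genomic_window_sets(
    gene_coords: Sequence[tuple[str, str, int, int]],
    window_sizes: Sequence[int],
    overlap_step: float = 0.5,
) -> SetCollection:
    """Partition genes into overlapping genomic-window gene sets.

    For each window size, windows tile each chromosome starting at base 1
    with a stride of ``overlap_step * size``.  A gene belongs to a window if
    its start coordinate lies inside it; windows covering no gene are not
    emitted.  Set ids encode ``chrom:start-end``.
    """
    if not window_sizes or any(w <= 0 for w in window_sizes):
        raise ValueError("window sizes must be positive")
    if not 0 < overlap_step <= 1:
        raise ValueError("overlap_step must be in (0, 1]")
    by_chrom: dict[str, list[tuple[str, int]]] = {}
    for gene, chrom, start, _end in gene_coords:
        by_chrom.setdefault(chrom, []).append((gene, start))
    sets: dict[str, frozenset[str]] = {}
    for size in window_sizes:
        stride = max(1, int(round(size * overlap_step)))
        for chrom, genes in by_chrom.items():
            max_start = max(s for _, s in genes)
            wstart = 1
            while wstart <= max_start:
                wend = wstart + size - 1
                members = frozenset(g for g, s in genes if wstart <= s <= wend)
                if members:
                    sets[f"{chrom}:{wstart}-{wend}"] = members
                wstart += stride
    return SetCollection(sets)
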