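# Methods

This note documents the model choices, parameters, numerical details, and
the synthetic-data generators behind `kbdiffuse`, and what the test results
do and do not establish about real data.

## Encoding

Tokenization lowercases, splits on whitespace, and strips leading/trailing
punctuation, so gene symbols (`ATM`) and ontology identifiers (`HP:0001`)
survive as single tokens.  Words of length ≤ k pass through whole; longer
words contribute all overlapping k-mers.  The value a word contributes to
each of its k-mers is

    (1 + ln t) · w_f · min(1, k / L)

where *t* is the word's count within the item, *w_f* the catalog weight,
and L the word length.  The k/L factor compensates for overlapping k-mers
of one long word sharing content, so a word's total mass is roughly one
token regardless of length; it is the simplest rule with that property and
is a deliberate stand-in where the exact adjustment is an open design
choice.  The log-frequency term uses the natural log, the standard
sublinear term-frequency form.

Feature weights `w = c0 − c1·log10(n/N)` are clipped at zero: a negative
importance for a ubiquitous feature has no retrieval meaning.  The catalog
caps at `max_features = 200,000` distinct k-mers, keeping the most
document-frequent features with lexicographic tie-breaks (a deterministic
eviction rule; the cap exists to bound memory on large text corpora).
Default k = 6 for gene-set instances (most gene symbols fit in one k-mer)
and uniform weighting (`c0 = 1, c1 = 0`) for unweighted gene sets;
information-content weighting (`c0 = 0, c1 = 1`) for natural-language
collections.

## Store and retrieval

Collections are either primary (built once) or user tier (writable at run
time); the split is strict, and dropping the user tier restores primary
results exactly.  The catalog is fixed at build time: user items and
queries are encoded against it, and unknown k-mers are dropped.  Run-time
snippets should therefore reuse vocabulary the build has seen — the
fixtures include a dictionary collection for exactly this reason.

Similarity is cosine on unit vectors (equivalently, nearest Euclidean
distance on the unit sphere); the index is an exact brute-force sparse
matrix-vector product with deterministic id tie-breaks.  An approximate
backend is a config-level extension point but is not included: at the
scales this package targets, exactness costs little and keeps every ranking
oracle-checkable.

Co-occurrence: an item with L distinct features increments every ordered
feature pair, diagonal included, by 1/L.  "Length" here means distinct
feature count — co-occurrence within short items counts more.  Rows are
stored unpruned; memory grows with the square of typical item feature
counts, which is acceptable for items up to a few hundred features.

## Diffusion

`D_ij = (c_ij / c_ii) · 2 w_i w_j / (w_i + w_j)` with `q → q + Σ_d s_d D_d q`.
Row normalization sets the diagonal of the normalized co-occurrence to one,
so `D_ii = w_i`.  The harmonic-mean factor gates diffusion symmetrically: a
zero-weight feature neither sources nor receives imputed weight.  Sources
are restricted to the original query's features (1-step diffusion); with
several collections the per-collection imputations are computed from those
same sources and summed, so the multi-collection result is exactly additive.
This is the conservative reading of applying the transforms "in two passes":
pass one computes every collection's imputation from the original query,
pass two accumulates them.  Iterated multi-step diffusion is deliberately
out of scope (over-smoothing).

The transform itself is linear and is not re-normalized; the query engine
normalizes the diffused query before cosine ranking, since stored items are
unit vectors.  Features never seen in a collection (`c_ii = 0`) contribute
nothing — no smoothing prior.  Strengths `s_d ≥ 0` are user-set per
collection; a sweep utility rather than an optimizer is the intended
calibration workflow.

## Decomposition

Greedy matching pursuit.  At each iteration the best cosine match to the
current residual is added, then the coefficients of *all* selected items are
refit to the original query by unconstrained least squares (refitting is the
default; a frozen-coefficient variant is available behind `refit=False`).
Termination: requested component count, a non-positive refit coefficient
(the offending component is discarded), a non-positive best match, or
residual norm below 1e-6 of the query norm (a numerical floor).  Nested
least-squares makes the residual norm non-increasing by construction.  The
solution is greedy and non-unique; with `max_components = 1` it coincides
with the top search hit.

## Gene-set benchmarks

Synthetic benchmarks draw from a reference collection by three recipes:
number of source components (1–4), coverage (fraction of each source's
genes transferred; exact rounded fraction by default, Bernoulli sampling
optional), and signal (fraction of the benchmark originating from sources,
the remainder random universe genes).  The full grid is 4 components × 4
coverages × 4 signals × 1000 replicates = 64,000 sets.

Scoring: each method reports at most five ranked hits; the score sums
Jaccard indexes between hits and the true source sets.  Hits are paired to
truth components by the one-to-one assignment maximizing total Jaccard
(Hungarian algorithm) over the top *n* hits, *n* defaulting to the number
of components.  A positional mode (i-th hit vs i-th component) exists, but
since component order is arbitrary, assignment is the order-invariant
default.  The score lies in [0, components] and counts recovered
components.

The Fisher baseline ranks sets by the one-sided hypergeometric tail
p-value of the query/set overlap over the universe, ascending, with id
tie-breaks.

Genomic-window sets: windows of each configured size tile each chromosome
from base 1 with a stride of `overlap_step × size`; a gene belongs to a
window if its start coordinate lies inside (genes straddling an edge are
assigned by start), and empty windows are not emitted.  Window sizes are
configuration, not constants, since use cases range from sub-megabase to
chromosome-arm scales.

## Ontology translation

OBO terms are flattened to text: name, definition, comment, synonyms,
is_a-parent names, and the top ancestor's name (ties between multiple roots
broken by smallest id).  Obsolete terms are excluded.  The evaluation graph
uses is_a edges only, undirected and unweighted; `part_of` and other
relations are excluded to keep path lengths interpretable as hierarchy
distance.  Precision is exact id match; path length is the shortest is_a
path (0 exact, 1 parent/child, 2 sibling/grandparent).  Unreachable pairs
are excluded from mean path lengths and reported as a separate count, since
any numeric placeholder would distort the mean.

## Synthetic data: what it emulates and what it does not

`make_set_collection` emulates a filtered GO biological-process collection:
by default 500 sets of 5–100 genes over a 20,000-symbol universe (6-char
symbols, so each gene is one feature at k = 6).  Independent sampling makes
base sets near-disjoint — unlike real GO, where overlap is pervasive.  The
`nesting_fraction` option adds strict supersets (~1.25× and ~1.5× the base
size, clipped to the size bound) for a fraction of base sets.  With
heterogeneous component sizes, such supersets retain every sampled source
gene and outrank smaller true sources under both Fisher and cosine, which
reproduces the redundancy that crowds top-k hit lists in real ontologies;
decomposition subtracts explained features and is largely immune.  Passing
the benchmark tests therefore shows the methods behave correctly under
controlled redundancy, not that the absolute scores transfer to real GO,
whose overlap structure is richer.

`make_toy_ontology_pair` builds two parallel ontologies with a known
bijective translation.  Easy pairs share their distinctive words.  Hard
pairs use disjoint vocabularies (synthetic words with provably disjoint
k-mer sets) plus a decoy word planted into unrelated target terms, so plain
search verifiably misses the expected term; bridge snippets pairing the two
vocabularies provide the co-occurrence that diffusion needs.  This isolates
the rescue mechanism; real cross-ontology vocabulary gaps are noisier and
bridged by imperfect corpora, so rescue rates on real data will be lower.

`make_corpus` produces random word-salad documents with planted
co-occurring word pairs, for store- and diffusion-level tests.

## Problem sizes and numerics

The shipped acceptance run uses 500 sets and 200 benchmark replicates per
regime (100 for four-component runs), sizes at which the exact index and
scalar hypergeometric evaluations complete in seconds on one core while
leaving medians stable.  All randomness flows through
`numpy.random.default_rng` seeds; fixtures are byte-reproducible under a
fixed seed.  Equality tolerances: unit norms to 1e-9, sparse-vs-dense
diffusion to 1e-10, Fisher vs enumeration to 1e-12.

## Known limitations

- No stemming, stop-words, or learned embeddings — by design; k-mers carry
  the generalization.
- The feature catalog is frozen at build; genuinely novel vocabulary in
  user snippets is invisible until a rebuild.
- User-tier search indexes are rebuilt per insert (cheap for small user
  collections; not suited to thousands of user items).
- Single-process, embedded storage; no concurrent writers, no service
  layer.
- Search hits carry no p-values; statistical calibration is post-processing.
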