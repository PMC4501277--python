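# Methods

## Data model and inputs

The pipeline consumes four tab-separated mapping tables:

* **disease_gene** (`icd10cm_code`, `gene_symbol`) — one row per
  association between an ICD-10-CM disease code and a gene carrying a
  phenotype-causing mutation.  This is the pre-curated, flattened form of
  an OMIM-morbid-map-like catalogue; parsing OMIM's native format (with
  its parenthesized mapping keys and comma-separated symbol lists) and
  the manual assignment of ICD codes to phenotypes are explicitly out of
  scope — both involve curation judgment that cannot be reproduced
  mechanically.
* **hgnc** (`approved_symbol`, `previous_symbols`, `alias_symbols`,
  `status`) — a gene-symbol authority.  Multi-symbol cells are
  '|'-separated.
* **gene_pathway** (`gene_symbol`, `pathway_id`) — memberships in
  KEGG-style entries.  The three identifier classes — pathway maps
  (`ko`), modules (`M`) and disease entries (`H`) — are pooled into one
  pathway universe; no per-class analysis is done.
* **chapters** (`range`, `name`) — ICD-10-CM chapter ranges.  A default
  21-chapter table (A00-B99 … Z00-Z99) ships with the package and can be
  overridden by file.

Association tables have set semantics: duplicate rows merge, and the
readers report the merge count.

### ICD ordering and chapter assignment

Chapter membership compares the 3-character code root against the
chapter's inclusive [start, end] range under ICD tabular order:
position 1 is the letter; positions 2–3 order digits 0–9 before letters
A–Z.  This places O9A after O99 and therefore *inside* O00-O9A, which
plain lexicographic comparison would break.  The shipped chapter table
spans A00–Z99 but is not gapless — real ICD-10-CM reserves gaps (F00,
K96–K99, the U chapter, …) — so codes falling in a gap raise a
classified "unassignable code" error rather than being silently binned.

### Symbol normalization

Raw symbols resolve with precedence approved > previous > alias; a hit
at a higher tier suppresses lower tiers, and a symbol matching two
approved records at the same tier raises an ambiguity error listing the
candidates rather than guessing.  Withdrawn authority records are
excluded entirely, so their symbols count as unmatched and the
corresponding rows are dropped.  Normalization is idempotent by
construction: its outputs are approved symbols, which resolve to
themselves.

## Networks

The bipartite network links codes to genes (edges are the deduplicated
associations); the tripartite network is the equijoin on genes of the
disease-gene and gene-pathway edge sets, so its size is exactly
Σ_g deg_dg(g)·deg_gp(g).  Disease *profiles* are the per-code gene sets
(bipartite adjacency) or pathway sets (union over tripartite triples).
Projection links two codes when their profiles intersect; the shared set
is kept and becomes the exported edge weight.  Diseases with empty
profiles are excluded from projection rather than emitted with zero
pairs.  The projection uses an inverted element→diseases index so cost
scales with co-memberships, not with all C(n,2) pairs; a brute-force
double loop over pairs serves as its independent test oracle.  Exports
are TSV edge lists and GraphML (via networkx), deterministically sorted.

## Inclusion index

τ_{x→y} = |X ∩ Y| / |X| is stored as an exact `fractions.Fraction`, so
the cross-identity τ_{x→y}·n_x = τ_{y→x}·n_y = |X∩Y| and the τ = 1 ⇔
X ⊆ Y equivalence hold bit-exactly; floats appear only in summaries and
serialized output.  Both directed records are materialized per
undirected pair because directionality is the analysis's central object.

Summaries are five-number distributions (min, Q1, median, Q3, max) with
linear-interpolation ("type 7") quartiles — the convention is recorded in
the output metadata.  The same-category view pools *directed* records
whose two codes share a chapter (each unordered pair contributes both
directions); this choice is documented here because pooling directed
versus undirected values is a genuinely open convention, and directed
pooling keeps the summary consistent with the directed records the
package emits.  The focal-chapter view assigns a record to role `as_X`
when its x-code is in the focal chapter and its y-code is not (and
symmetrically for `as_Y`); pairs entirely inside the focal chapter
belong to the same-category view and are excluded from the cross-chapter
roles.  No statistical test of directionality differences is performed —
only the distributions are emitted.

## Enrichment prediction

Candidate genes are those with ≥ 1 pathway membership and no
disease-gene association.  For each candidate × disease pair sharing at
least one pathway, a 2×2 table is built and a two-tailed Fisher exact
test applied; pairs with raw p ≤ α (default 0.001) are kept and ranked.

**Table construction.**  Two modes exist because the natural reading of
the source table conflicts with the standard 2×2 partition:

* `paper_literal` (default): a = |N_g ∩ N_d|, b = N_g − a, c = N_d,
  d = N − N_d.  The disease column counts *all* of the disease's
  pathways, so shared pathways appear in both columns and the table
  total exceeds N by a.  This mode keeps that literal tabulation intact.
* `conventional`: c = N_d − a, d = N − N_g − N_d + a — the standard
  partition of the universe, available for users who prefer a
  well-formed hypergeometric model.  Given N ≥ |N_g ∪ N_d| (enforced),
  all cells are provably non-negative in both modes.

**Universe.**  By default N = |union of pathways over disease profiles|
("disease-linked"); `universe="all"` adds candidate-only pathways.  Both
readings of "the total number of pathways" are defensible, so both are
exposed; the disease-linked one is the default.  Under the disease-linked
universe, candidate profiles are intersected with the universe before
table construction so that a + b ≤ N always holds.

**Two-sided p-value.**  p is the sum of hypergeometric point
probabilities, over all tables with the observed margins, that do not
exceed the observed table's point probability, with a 1e-7 relative
slack for floating-point ties — the same definition
`scipy.stats.fisher_exact` implements.  The implementation evaluates
`scipy.stats.hypergeom.pmf` vectorized over the margin support and
caches per margin triple (n, row1, col1), which makes runs with
hundreds of thousands of pairs take seconds; scipy's own pmf is
log-space internally, so large margins stay finite.  Tests verify
agreement with (a) an exact-rational exhaustive enumeration over all
2×2 tables with cells ≤ 8 (worst observed deviation ~3e-16, asserted
< 1e-9) and (b) `scipy.stats.fisher_exact` on assorted tables.

**Ranking and correction.**  Ties break by ascending p, then descending
shared-pathway count, then (gene, code) lexicographically, making the
ranked output byte-deterministic.  No multiple-testing correction is
applied by default (the method filters on raw p ≤ 0.001); an optional
Benjamini–Hochberg flag (via statsmodels) applies the α cut to adjusted
p-values instead, while reported p-values stay raw.

## Synthetic studies

The generator emits all four tables plus machine-readable ground truth
from a single integer seed (one `numpy` Generator stream; all iteration
orders are sorted, so output is byte-identical across runs and across
processes).

What it emulates: within-chapter gene sharing (each disease draws its
genes from its chapter's pool with probability `p_within`, a random
other chapter's pool with `p_between`, the global pool otherwise);
subset relationships (planted pairs where Y's gene set is X's plus ≥ 1
extra gene, on disjoint codes, giving τ = 1 forward and τ < 1 reversed
by construction); pathway-mediated gene–disease signal (planted
candidate genes whose pathway sets are drawn from the target disease's
pathway profile to cover a `planted_overlap` fraction of it, with no
disease-gene edge, so they are guaranteed candidates); and nomenclature
drift (an `alias_rate` fraction of appearing genes written into the
disease-gene table under a synthetic previous/alias symbol).

Defaults (chosen once as a realistic small study): 21 chapters × 10
codes, 800 genes, 2–10 genes per disease, p_within = 0.3,
p_between = 0.02, 300 pathways, 1–6 pathways per gene, 10 subset pairs,
20 planted enriched pairs at 0.8 overlap, alias_rate = 0.2, 200
background candidates.  Disease codes are drawn inside the real chapter
ranges (digit suffixes first, alphanumeric suffixes only when a chapter's
digit space is exhausted), so the real chapter-assignment logic —
including the O9A boundary — is exercised.

What it does **not** emulate: realistic OMIM phenotype text, real KEGG
topology or pathway-size distributions, correlated pathway memberships,
or literature-level validity of specific gene–disease pairs.  Passing
recovery tests therefore demonstrates that the pipeline's machinery is
correct and sensitive to the planted effect sizes, not that its
predictions on real catalogues are clinically valid.

Recovery measurement: recall = |planted ∩ kept| / |planted| at the α
cut; ranks are compared over the full evaluated list, and the planted
set "outranks" the background when its median rank is at or better than
the 5th numeric percentile of background ranks (rank 1 = best).  A
planted pair absent from a non-empty evaluated list indicates
predictions and truth from different studies and raises an integrity
error.

## Problem sizes and numerical choices

The test suite and acceptance script run at three scales, chosen so the
full suite completes in well under a minute of CPU per heavy test: small
fixtures (hand-checkable), recovery studies of 200 diseases × 300
pathways × 1,000 candidates (≈ 50k evaluated pairs), and a study-scale
smoke run of 882 codes × 3,000 disorder genes × 800 pathways × 5,000
candidates (≈ 150k pathway-sharing disease pairs, ≈ 400k evaluated
gene-disease pairs), which exercises the same magnitudes as a real
OMIM/KEGG snapshot.  Degenerate inputs are contracts, not silent
defaults: empty X sets in τ, negative or inconsistent contingency
cells, mixed profile modes in projection, and infeasible generator
configurations all raise classified errors before producing output.

## Known limitations

* The paper_literal table is not a partition of the universe; its
  p-values follow that literal tabulation rather than a textbook
  hypergeometric model.  Use `conventional` mode for the latter.
* Exact snapshot counts from 2015-era OMIM/HGNC/KEGG (880 codes, 4241
  associations, 15,455 triples, …) are not reproducible from current or
  synthetic data and are not targets of this package.
* The inclusion analysis emits distributions only; it deliberately does
  not test directionality differences for significance.
* The CLI-free surface is intentional: the library plus `examples/` and
  `scripts/acceptance.py` are the supported entry points.
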