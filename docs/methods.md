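# Methods

## Data model and its assumptions

The analysis substrate is a typed directed multigraph: entities (genes,
microRNAs, conditions, annotation terms) and interactions with an open
relation vocabulary and optional PubMed provenance. Three modeling choices
shape everything downstream:

* **Gene/protein merging.** A gene row and a protein row sharing a symbol
  become one node. Curated disease networks report "genes/proteins" as
  single members, and keeping them separate would split link counts
  arbitrarily between the two.
* **Parallel links retained, collapsed per metric.** Literature extraction
  records one typed link per supporting statement, so multi-edges are
  meaningful counts, not noise. They are kept in storage and in the link
  counts `K` and `M`; topological metrics (betweenness, neighbor degree) run
  on the undirected simple projection. Self-interactions are stored but
  excluded from all metrics.
* **Symbol normalization.** Symbols are uppercased and passed through a
  small alias table (shipped: G6PC→G6PC1, GLUT2→SLC2A2, user-extensible as
  TSV). The packaged curated tables themselves mix aliases across rows,
  which is exactly the failure mode this guards against. No external
  identifier service is consulted.

A *condition network* contains exactly the gene-like entities with at least
one interaction to the condition node, in either direction, plus the simple
undirected edge set among them. A condition with no linked genes yields an
empty network with a warning flag, not an error.

## Per-node metrics

For member gene *i*:

* `K_i` — links incident to *i* whose other endpoint is a network member or
  the condition itself, parallel links counted. Includes the gene–condition
  links, so `K_i ≥ 1` for every member. Because whether a given visual
  analytics tool counts parallel typed links or distinct neighbors is
  generally undocumented, the distinct-neighbor count is emitted alongside
  as `neighbor_degree`.
* `B_i` — betweenness centrality by Brandes' algorithm on the simple
  gene–gene graph (condition node excluded), unweighted, unnormalized,
  unordered pairs counted once, shortest-path credit split equally among
  ties. Disconnected components are handled natively; cross-component pairs
  contribute nothing, and degree ≤ 1 nodes score exactly 0. Normalization is
  deliberately omitted because only rankings are consumed downstream; the
  convention is pinned by a brute-force path-enumeration oracle and by an
  independent library implementation in the test suite.
* `CTS_i = K_i / M_i` with `M_i` the gene's total link count in the whole
  knowledge base. `M_i ≥ K_i ≥ 1` by construction, so CTS ∈ (0, 1]; a
  member with `M_i = 0` would violate referential integrity and raises an
  internal-consistency error. CTS is invariant under duplicating the entire
  knowledge base (both counts double), which the suite property-tests.

Rankings sort descending by the chosen key with lexicographic tie-break on
the symbol, making output order deterministic.

## Overlap and term enrichment

Overrepresentation is the exact hypergeometric upper tail `P(X ≥ k)` — the
survival function evaluated at `k − 1`. The off-by-one convention is the
classic defect of enrichment code, so it is fixed by definition here and
pinned against exhaustive draw enumeration for every parameter combination
with `N ≤ 12`.

The tail is accumulated in log-space: each term
`C(K,i)·C(N−K,n−i)/C(N,n)` is evaluated as a difference of log-gamma values
and the sum is taken with `logsumexp`. `log10 p` is the authoritative
output; the linear `p_raw` is clamped to the smallest positive float when it
underflows. At the scale these analyses reach (overlaps of hundreds of genes
in backgrounds of tens of thousands), tails below 1e-300 occur and remain
finite and accurate in log-space.

Choices a user can change, with defaults and rationale:

* **Background `N`** — defaults to the number of gene-like entities in the
  loaded knowledge base, always overridable. Literature systems rarely
  publish their universe size, and the tail is strictly decreasing in `N`
  for fixed nonzero overlap, so `background_sensitivity` tabulates
  `log10 p` over an `N`-grid to make the assumption explicit rather than
  guessed.
* **Correction** — Bonferroni (`min(1, m·p)`) by default with `m` = number
  of terms sharing at least one query gene, matching common enrichment-tool
  behavior; Benjamini–Hochberg by flag.
* **α = 0.01** on the corrected p-value.
* **EASE-style variant** (tail at `k − 1`) behind a flag, off by default:
  popular annotation servers use this conservative score internally, and the
  flag makes their behavior reproducible without changing the default
  definition.

Annotated genes outside the background are dropped with a logged count; a
query that is not a subset of the background is an error, not a silent drop.

## Multi-way comparison

The Venn partition assigns every gene of the union to the single region
keyed by its membership bitmask over the declared set order ("10110" = in
sets 1, 3, 4 of five). Disjointness, union coverage and size conservation
are property-tested over random families of 2–6 sets, and the all-ones
region provably equals the intersection. The TSV region table is the
supported output for > 3 sets; a plain-matplotlib figure exists for ≤ 3 sets
as presentation only. Shared enriched terms are those significant in every
condition, sorted by worst corrected p (the most honest summary of a term
that must hold everywhere).

## Link-pattern classification

The six classes (UP, DOWN, CAUSAL, PROTECTIVE, SNP_RISK, OTHER) are assigned
by a rulemap over (relation type, direction relative to the condition):

    UPREGULATES      condition → gene   UP
    DOWNREGULATES    condition → gene   DOWN
    CAUSES           gene → condition   CAUSAL
    PROTECTS_AGAINST gene → condition   PROTECTIVE
    SNP_RISK         gene → condition   SNP_RISK

Semantics are multi-label — curated tables genuinely list genes as both up-
and down-regulated — and OTHER is exclusive: it marks exactly the genes none
of whose links fire a rule (pure associations, protein interactions, unknown
relation types, which are logged). Classification is order-independent and
round-trips: synthesizing a knowledge base from an assignment and
classifying it recovers the assignment, a property the suite exercises over
random multi-label assignments. The packaged curated class table is shipped
as data, separate from the rulemap machinery, so table-level checks never
depend on rule choices.

The cross-classification of two conditions restricts to genes present in
both and places each gene in every (row class, column class) cell its labels
generate. One caveat found while transcribing the source tables: the curated
class table and the published cross table disagree on one symbol
(SERPINA1/SERPINE1), so the cross-table fixture is kept self-contained (its
row and column classifications both derive from the cross table itself) and
the discrepancy is asserted explicitly in the tests rather than smoothed
over.

## Synthetic knowledge bases

The generator emulates the statistical shape of a literature-derived
knowledge base:

* **Global graph**: preferential attachment — node *i* attaches
  `min(m, i)` edges to earlier nodes with probability proportional to
  degree — produces the heavy-tailed degree distribution that makes CTS
  informative. Defaults `n_genes = 3000`, `m = 3` give a median degree near
  2·m and hubs of degree in the hundreds.
* **Condition modules**: drawn without replacement with weight
  (degree + 1), emulating curation's bias toward well-studied hubs — the
  very bias CTS exists to counteract. A planted core is shared by all
  conditions; each declared pairwise overlap beyond the core is drawn as
  genes shared by exactly that pair; remaining members are module-unique,
  so every pairwise intersection equals core + declared extra by
  construction.
* **Gene–condition links** are typed by a class mixture (default: the
  frequencies of the packaged curated class table, 43:17:16:22:34:19), so
  the classifier has planted truth.
* **Annotations**: background terms of uniform random size in
  `term_size_range` (default 10–40 genes), plus one planted term per
  condition containing `planted_term_fraction` (default 0.8) of the module
  padded with a quarter as many off-module genes.

Default module sizes (141, 494, 424, 685, 130), core 14 and overlaps
47/50/62/22 are the study conditions this package models. All discrete draws
go through integer arithmetic on PCG64 (`rng.integers`), so bundles are
reproducible across platforms; no floating-point RNG enters a discrete
choice.

What the generator does **not** emulate: real knowledge-base degree
distributions (no attempt to fit one), correlated annotation structure (no
ontology DAG, terms are flat and independent), textual provenance, multiple
organisms, or biased relation-type composition per gene. Passing recovery
tests therefore demonstrates correctness of the pipeline's bookkeeping and
statistics under a realistic topology — not that any biological conclusion
drawn from a real knowledge base is right.

## Problem sizes used by the test and acceptance runs

Planted-truth recovery runs 20 seeds of a five-condition bundle at
`n_genes = 400` with modules 30/40/35/45/25, core 5 and overlaps 8/7/9/6 —
small enough to iterate quickly, large enough that module, overlap, class
and term recovery are non-trivial. The published-scale bundle (3000 genes,
modules up to 685) is generated in full for the overlap/Venn recomputation;
it builds in about a second. Oracle comparisons use 1000 random graphs of
≤ 8 nodes for betweenness and all `N ≤ 12` parameter combinations for the
hypergeometric tail. Null calibration draws 1000 replicate set pairs of
sizes 141 and 494 from a 5000-gene background; note the exact discrete test
is conservative — its attained level at nominal 0.05 is P(X ≥ 21) ≈ 0.035
at these sizes — so uniformity diagnostics use the mid-p transform.

## Known limitations

* No text mining: the package consumes knowledge graphs, it does not build
  them, and no live database or web service is queried.
* Identifier handling is the alias table only; symbols from different
  nomenclature eras must be reconciled by the user's table.
* Enrichment treats annotation as flat; no GO DAG propagation, so parent
  terms must be materialized in the annotation table if wanted.
* Printed p-values of third-party enrichment servers are not reproduction
  targets: they depend on the server's annotation release and undisclosed
  background, which is precisely what `background_sensitivity` maps.
* Betweenness is exact, not sampled; networks of tens of thousands of
  members would need an approximate variant that is not provided.
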