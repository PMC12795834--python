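# Methods

## The model

`agnet` operates on a typed knowledge graph: entities belong to a closed
class vocabulary {gene, protein, disease, drug, process, other}, and
relations are directed, typed, and may be parallel (several relations of
different types between one pair). Relation types are data, not code: a
TSV vocabulary assigns each label a category — *regulatory* (expression/
activity up-/down-regulation and the like) or *associative* (association,
marker, risk factor, ...) — and a polarity in {+1, −1, 0}. Associative
types are always unsigned. The shipped 14-type default vocabulary
(9 regulatory + 5 associative) is illustrative; users of a real curated
knowledge base supply their own vocabulary file.

### Associative gene networks

An AGN is the star of gene/protein neighbours of one or more focus
entities. Relations are stored directed but neighbourhood extraction is
undirected, because disease–gene association edges are semantically
bidirectional; mechanism search (below) is the directed consumer. The
star invariant — every edge has exactly one endpoint among the foci — is
asserted on every reconstruction. Member counts exclude the foci
(a star of 2,178 genes and 2,507 proteins is reported as 4,685 members,
not 4,686 nodes), and parallel edges are retained, so `n_edges ≥
n_members`. Drug-group AGNs are built jointly over all drugs of a group,
with per-focus edge counts retained; members reachable from several
drugs are deduplicated.

For enrichment, an AGN's members collapse to a gene list: genes pass
through, proteins map to their coding gene via an explicit
`protein_id → gene_id` table (never name matching — the collapse must be
auditable, since a network typically contains both a gene and its
protein as distinct nodes). Unmapped proteins are dropped with a warning.

### Overrepresentation

For query size n (after intersection with the universe), term size K,
universe N and overlap k, the raw p-value is the hypergeometric upper
tail P[X ≥ k], computed through `scipy.stats.hypergeom.sf` (stable far
into the tail; the test suite pins it against exact rational enumeration
on the full grid N ≤ 60). Bonferroni uses m = the number of terms
actually tested, i.e. those with k ≥ `min_overlap` (default 1) — the
standard reading when the testing universe is filter-dependent; both the
filter and a user-supplied background universe are exposed. The default
universe is the union of all annotated genes in the GMT. Results sort by
(p_adj, term_id) so output is byte-stable. An optional `ease=True`
scores P[X ≥ k−1], the conservative variant popularized by the DAVID
server, for users comparing against its output; the plain tail is the
default because it is the stated test of the workflow this package
implements.

### The cascade

Four stages, each emitting its count:

1. significant disease-AGN terms (Bonferroni α = 0.05);
2. keep terms with ≥ 1 regulation-type relation (either direction) to the
   disease node. The filter names — Regulation, Downregulation,
   Upregulation — are coarser than typical edge-label vocabularies, so
   matching is case-insensitive through an explicit alias table
   (e.g. "positive regulation" ↦ Upregulation); the default table maps
   all nine shipped regulatory labels onto the three filter names.
   Enriched terms are matched to process nodes by GO id (entity id or
   xref); terms without a node cannot be checked and are dropped with a
   warning;
3. subtract the union of significant terms across all drug-group
   enrichments (a single union subtraction against all drug lists
   at once, e.g. 71 → 59 on the study-scale fixture);
4. mark terms with a regulation-type relation to any configured drug;
   the unmarked remainder are the candidates.

Every significant disease term receives exactly one status (candidate or
one of three exclusion reasons), so statuses partition the stage-1 set —
an invariant the tests assert. The report carries all stage counts, so
any real-data run exposes its own 381/71/59/11-style audit trail.

### Mechanisms

Signed paths are simple directed paths over polarity-bearing regulatory
edges; the path sign is the polarity product. Parallel edges yield
distinct paths — each relation type is a separate mechanism hypothesis.
Feedback loops are simple directed cycles (length ≤ `max_len`, default 4;
mechanism diagrams in this domain are rarely deeper, and enumeration
stays desk-scale), reported once per parallel-edge combination in a
canonical rotation starting at the lexicographically smallest node, and
classified positive/negative by sign. Unsigned (associative) edges are
excluded by default; `include_unsigned=True` admits them as
sign-neutral, and affected paths/loops are reported with sign 0 /
class "unclassified" rather than being given a fabricated polarity.
Path and cycle enumeration is delegated to networkx
(`all_simple_edge_paths`, `simple_cycles`); the test suite checks
equality with an independent recursive enumeration on random digraphs.

## The synthetic generator

The generator emulates the structure of a curated biomedical knowledge
base without its content:

* a star-dominated disease neighbourhood (default 2,178 genes + 2,507
  proteins behind 9,877 edges — one edge per member plus parallel extras
  of distinct types);
* per-drug response neighbourhoods whose members are a subset of the
  disease members (drug-response genes are also disease genes), with
  per-drug incident-edge counts as the primitive (defaults 160/73/26/17
  for the four conventional and 60/26 for the two targeted
  antirheumatics). Member slices overlap across drugs of a group, so
  some members are shared — mirroring real drug-response networks;
* relation types sampled from a weight table skewed toward
  expression-regulation types. Note the marginal type frequencies match
  the weights exactly only for first edges: parallel extras are
  constrained to differ per pair, which slightly depresses the most
  common types at high multi-edge density;
* GO-style gene sets over a universe of member plus background genes
  (default N = 10,000), with planted enrichment;
* planted regulation links between disease/drugs and process nodes
  driving the cascade, plus a few associative disease–process links that
  must *not* pass the regulation filter;
* planted signed loops among member genes (default one positive
  2-cycle), specified as polarity tuples.

**Exact mode** (the default) plants constructively: each of the
`planted_enriched_terms` gene sets is a subset of the relevant query
gene list (disease-only, or a drug group's genes — which are a subset of
the disease's, so drug-enriched terms are automatically
disease-enriched), and null terms are subsets of background genes. With
the default sizes this forces p_adj below 10⁻¹⁴ for planted terms and
overlap k = 0 (untested) for null terms, so stage counts equal the
parameters on every seed — the right regime for reproducing point facts
of a database snapshot. **Stochastic mode** samples `planted_effect` of
each planted term from the query and the rest uniformly; it is used for
the statistical properties (planted-signal recovery at effect 0.6,
type-I error under the null, sampling-weight contracts).

What the generator does **not** emulate: literature-evidence counts and
confidence scores, the GO DAG (terms are flat, disjointly pooled rather
than nested), realistic degree distributions beyond the star, and
identifier semantics. Consequently, passing tests demonstrate the
pipeline's arithmetic, invariants and statistical calibration — not that
any particular real disease's candidate processes would be recovered,
which depends entirely on the knowledge base supplied.

A `truth.json` accompanies every bundle (planted term ids per stage,
queries, loops) for recovery assertions.

## Numerical and design choices

* Hypergeometric tails via the survival function; exact-rational
  enumeration exists only as an independent oracle in the tests.
* Bonferroni multiplier = tested terms (post `min_overlap`), not the
  collection size; configurable.
* Ties in p_adj break by term id; all outputs (TSV/JSON) are
  deterministically ordered and manifests carry no timestamps, so a rerun
  with the same seed and config is byte-identical.
* Degenerate inputs: empty relation sets raise on distribution tables;
  an empty effective query (no universe overlap) is an explicit error
  naming the cause; unknown entity classes load as `other` with a
  warning, while referential-integrity and vocabulary violations are
  hard errors.
* The acceptance script and the heavier tests run the study-scale preset
  (~13,000 entities, ~10,500 relations, 500 terms) in under a second;
  statistical suites use 100 generator seeds (recovery) and 1,000
  replicate null queries × 200 terms (type-I error), sizes at which the
  binomial tolerances in the assertions are meaningful.

## Known limitations

* No GO DAG propagation: a gene annotated to a child term does not count
  toward the parent. Real GO-based runs should pre-propagate their GMT.
* Only Bonferroni is offered; the workflow this package implements
  specifies no other correction.
* Gene-level target nomination, comorbidity analysis and any text-mining
  /knowledge-extraction machinery are out of scope: the graph is an
  input, not a product.
* The default relation vocabulary is illustrative; analyses against a
  real knowledge base should load that base's own vocabulary and alias
  table.
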