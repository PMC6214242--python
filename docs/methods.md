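# Methods

This note documents the models, conventions and design choices behind
`sitegraphs`, in the package's own terms.  Nothing here states an
empirical result that the test suite or `scripts/acceptance.py` does not
itself compute.

## Graph constructions

All graphs are undirected and simple, over one shared node set: one node
per protected-site designation record.  A site holding both SPA and SCI
designations contributes **two** nodes, declared *zero-distance
partners*: their distance is forced to 0 after the geometric computation,
so they fall inside any distance threshold.  Partner nodes may be linked
to each other in every graph kind whenever the non-distance criteria
pass; no special exclusion is applied.

* *Raw-distance graph*: pairs with distance ≤ threshold (default 30 km).
  The comparison is inclusive at exactly the threshold; since distances
  are continuous this is a measure-zero choice, but it is fixed and
  documented here.
* *Single-species graph*: occupied sites linked within the threshold; the
  *full* variant keeps the whole node set so edge sets are comparable
  across graphs.  Hit-rate evaluation uses the full variant; the
  candidate finder uses the non-full variant's connected components,
  including singleton components from isolated occupied sites.
* *Similarity-based graph*: raw-distance edges with similarity ≥ the
  minimum score (exact ≥ at double precision, no tolerance).  This is
  equivalent to removing low-similarity edges from the raw-distance
  graph; the test suite asserts the equivalence of both constructions.

Distance modes: `planar` (Euclidean on projected km coordinates — the
synthetic generator's native frame), `geodesic` (great circle, mean Earth
radius 6371.0088 km), `boundary` (minimum distance between boundary
polygons, via shapely).  Projected distances are treated as an acceptable
approximation at regional scale.

## Vectors and similarity

Vector universes contain only the codes observed across included sites:
Jaccard and cosine are unaffected by shared all-zero attributes, so a
fixed external code list would change nothing measurable.  Land-use codes
are truncated to CLC level 3 before aggregation (deeper levels are rarely
consistent in regional data); habitat occurrence vectors use the patch
`count` column.  Species vectors are presence-only, hence binary, and
only the Jaccard measure applies to them; abundance-weighted species
vectors are out of scope because abundance is sparse in the data this
models.

Degenerate input conventions, chosen so that sparse data degrades
gracefully rather than aborting a run:

* Jaccard of two all-zero vectors is **0** (a site with no reported
  attributes is never similarity-linked); a warning is counted.
* Cosine of a zero-magnitude vector is **undefined** (the measure
  requires non-zero magnitude): the scalar raises, the pairwise matrix
  stores NaN with a `defined=False` mask, and such pairs are never
  linked — distinguishing data gaps from true dissimilarity in logs.
* Sites with no rows for a dataset keep an all-zero row so every graph
  shares one node set.

## Evaluation

For species *s* with *m* single-species edges and *h* of them present in
a similarity graph with |E| edges, rate = h/m; the average hit rate R is
the unweighted mean over species with m > 0 (0/0 is undefined; a switch
`zero_edge_species_as_zero` counts them as 0 instead, for sensitivity
checks).  Relative density is |E|/n with n the raw-distance edge count;
normalized hit rate is R·n/|E|, and the identity NHR × density = R is
asserted to 1e-9 on every summary row.  A similarity graph with no edges
at the chosen threshold gets NaN in the summary rather than aborting.

Spearman correlation is the Pearson correlation of mid-ranks
(scipy's implementation; an independent rank-then-Pearson oracle backs it
in the tests).  Undefined entries are removed listwise before ranking;
fewer than 3 complete pairs or a constant column raises, and the pipeline
records NaN for such pairs instead of crashing.

Node indices (degree, betweenness, closeness, clustering, topological
coefficient) follow the conventions of the common network-analysis
suites for disconnected undirected graphs: closeness is component-local
(1 / mean shortest-path length to reachable nodes, 0 for isolates) so
every node has a finite value; betweenness is normalized by
(N−1)(N−2)/2 over the full node count, with unreachable pairs
contributing 0.  The topological coefficient of node v averages, over
partners m sharing ≥ 1 neighbour with v, |shared neighbours| + 1 if
(v, m) is an edge, divided by deg(v); 0 when v has no neighbour-sharing
partner.  Absolute centrality values differ across software conventions;
the analysis only consumes within-graph rank order, which these choices
preserve.  networkx provides degree/betweenness/closeness/clustering;
the topological coefficient is implemented here and all five are checked
against brute-force enumeration oracles on random small graphs.

Candidate sites: for each connected component V′ of a species'
(non-full) graph, the finder returns exactly the pairs (i, j) with
i ∈ V′, j a node outside V′, and (i, j) an edge of the reference
similarity graph.  Because that graph only links pairs within the
distance threshold, such a j can never be occupied (it would belong to
the component), so candidates are always unoccupied sites.

## Synthetic landscape generator

The generator emulates the structure of a regional protected-site
dataset; every draw comes from one seeded `numpy` generator, so identical
config + seed gives byte-identical tables.

* **Sites**: `n_sites` (default 100) uniform points in a square region of
  side `region_extent_km` (default 150 km — at the 30 km threshold this
  yields a raw-distance density around 13% of pairs, the scale of a
  real regional network).  A fraction (default 0.15) are emitted as
  SPA/SCI partner pairs; a configurable fraction can be flagged as
  missing land-use data, which the site filter then excludes.
* **Composition**: `n_archetypes` (8) regional archetype profiles over
  the code pool share a heavy-tailed base (rank⁻², shuffled) perturbed
  multiplicatively (lognormal σ = 1), so a few classes are common
  everywhere and each region has its own character.  A site's expected
  mixture blends archetypes with exp(−d/`spatial_range_km`) weights
  (default 20 km, deliberately *below* the 30 km link threshold so that
  similarity varies within a node's linking radius and carries
  information beyond distance).  The realized per-site composition is a
  Dirichlet resample of the mixture (concentration 4) — sites are
  idiosyncratic realizations of their neighbourhood, which keeps count
  vectors from all pointing along one dominant class — from which
  ~`patches_per_site_mean` (15) patches are drawn; patch areas split a
  lognormal site total (median 2000 ha).  Land use uses the same
  mechanism with its own independent archetypes: spatially structured
  but uninformative about species.
* **Occupancy**: each species prefers 2 habitat codes drawn from a
  tempered (∝ √abundance) archetype profile — characteristic rather than
  ubiquitous habitats.  Occupancy probability is
  `logistic(intercept + a_s + coupling · (f − f̄))` with f the fraction
  of preferred codes present at the site, f̄ its across-site mean
  (centering makes coupling move species between sites without shifting
  prevalence, giving a fair coupling-0 null), `a_s ~ N(0, 2)` a
  species-level effect producing the heavy-tailed prevalence mix of real
  inventories (its widespread-species tail also keeps the species-set
  similarity graph non-empty when coupling is 0), intercept −1.0, and
  coupling default 6 (the generator's "high" setting; 0 severs the
  habitat–species link entirely).

What the generator does **not** emulate: real biogeography and coastline
geometry, polygon-level patch shapes, survey effort bias, species
abundance, and dispersal-mediated spatial autocorrelation of occupancy
*beyond* habitat (occupancy draws are independent Bernoulli given the
habitat fields).  Passing tests therefore show that the pipeline
recovers a habitat→species signal of the planted kind and strength, not
that it would do so on any particular real dataset.  One visible
consequence: cosine similarities between nearby sites run higher in the
synthetic world than in typical regional data, so cosine-based graphs at
the 0.5 threshold stay denser (and their normalized hit rates closer
to 1) than practitioners should expect from real land-cover tables —
the measure's known leniency, exaggerated.

## Numerical and degenerate-input choices

* Similarity matrices are symmetrized exactly ((S + Sᵀ)/2) and the
  diagonal set to 1 for non-zero vectors; scores are double precision
  throughout, and threshold comparisons are exact ≥.
* The distance matrix is validated as a pseudometric in tests (symmetry,
  zero diagonal, non-negativity; triangle inequality in planar mode —
  the zero-distance override can only tighten it).
* Empty graphs produce empty index tables; isolated nodes get closeness
  0 and clustering 0 (degree < 2).
* Species graphs with zero edges are excluded from R (see above) and
  from correlation columns via listwise deletion.
* The pipeline derives the missing-data injection seed as
  `landscape seed + 1` so generation and injection are independently
  reproducible.

## Problem sizes

The shipped test suite and acceptance script run entirely on generated
data at the scale the method targets: landscapes of 100–104 base sites
(115–120 nodes), 131 species, and similarity sweeps over 7–10 threshold
levels; oracle checks use exhaustive enumeration on graphs of ≤ 8 nodes
(500 random instances) and 100 random candidate-finder fixtures; the
signal-recovery check uses 20 independent seeds per coupling regime.
The full suite completes in about a minute on one CPU.

## Known limitations

* Boundary-polygon distance is exact for the vertex/segment geometry
  given, but the generator emits point sites by default; polygon support
  is exercised only by fixtures.
* The updating/downdating/rewiring budget-optimization family of network
  modifications is out of scope; the candidate finder enumerates
  candidate edges but does not rank them by predicted index improvement.
* Whether a real dataset's dual-designation bookkeeping counts partner
  edges in its published edge totals is not recoverable from summary
  tables; this implementation always counts them.
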