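# sitegraphs

Similarity-based graph models of protected-site ecological networks.

## The problem

Ecological networks such as the EU's Natura 2000 system are analysed with
graph models: nodes are protected sites, edges are possible connections.
The standard *functional* approach builds one graph per target species —
sites where the species is reported, linked when they lie within a
dispersal-scale distance of each other — which is informative for that
species but gives no general picture of the network, and no guidance when
a land manager must propose a relocation site or a habitat corridor for
species whose habitat requirements are not explicitly recorded.

`sitegraphs` implements and evaluates an alternative: describe each site
by an attribute vector — the set of species reported there, its habitat
composition, or its land-use (CLC level-3) composition — and link two
sites when they are both geographically close **and** compositionally
similar.  The package is aimed at researchers and land-management analysts
who want to build these graphs from tabular site data, score how well each
construction anticipates species-level connectivity, and shortlist
candidate sites for relocation or corridor proposals.

## The model

Sites are vectors over a code universe, in three modes: binary
(presence), occurrence counts, or summed patch area.  Two bounded
similarity measures are used:

* Jaccard coefficient of binary vectors,
  `J = f11 / (f01 + f10 + f11)`, where `f11` counts attributes set in
  both vectors and `f10`, `f01` those set in only one;
* cosine similarity of non-negative vectors,
  `cos(x, y) = x·y / (‖x‖ ‖y‖)`, in [0, 1].

Four graph families share one node set *V* (sites; an overlapping
SPA/SCI designation contributes two nodes at zero distance):

* **raw-distance graph** — all pairs within a distance threshold
  (default 30 km) linked; its edge count *n* is the reference budget;
* **single-species graph** — occupied sites linked within the threshold
  (the *full* variant keeps all of *V* as nodes);
* **similarity-based graph** `G_s = (V, E_s)` — raw-distance edges kept
  when similarity ≥ a minimum score (default 0.5).

A similarity graph is scored against the single-species graphs by its
**hit rate** per species (fraction of that species' edges present in
`E_s`), the average hit rate *R*, and the **normalized hit rate**

```
NHR = R / (|E_s| / n) = R · n / |E_s|
```

which corrects for the fact that denser graphs hit more edges by chance
(NHR ≈ 1 means no better than random edge selection).  Spearman rank
correlations compare hit-rate columns and node-index columns (degree,
betweenness, closeness, clustering, topological coefficient) across graph
constructions.  Finally, for a connected component *V′* of a species'
graph, any similarity edge `(i, j)` with `i ∈ V′`, `j ∈ V`, `j ∉ V′`
marks *j* as a **candidate site** for relocation or corridor design.

Because the regional dataset this kind of analysis is run on is not
freely redistributable, the package ships a synthetic landscape generator
(`sitegraphs.landscape`) that reproduces the statistical structure the
method assumes — spatially autocorrelated habitat composition, land use
independent of species, species occupancy coupled to habitat — so the
whole pipeline is testable end to end.

## Worked example

```
sitegraphs all --synthetic --n-sites 104 --seed 2 --out runs/demo
```

generates a 104-site landscape (120 nodes after dual SPA/SCI
designations), builds the seven standard similarity graphs, and prints,
among other tables:

```
hit-rate summary (R, |E|, relative density, normalized hit rate)
                      avg_hit_rate  edges  raw_edges  relative_density  normalized_hit_rate
graph
landuse_jaccard            0.32822    232        750           0.30933              1.06106
habitat_jaccard            0.34907    209        750           0.27867              1.25263
species_jaccard            0.13425     57        750           0.07600              1.76645
...

hit-rate Spearman correlations [jaccard]
        graph_a         graph_b  spearman_rho
landuse_jaccard species_jaccard      -0.03634
landuse_jaccard habitat_jaccard      +0.04131
species_jaccard habitat_jaccard      +0.72756
```

Reading this: the raw-distance graph has n = 750 edges.  The
habitat-based Jaccard graph keeps 209 of them (density 0.279) and attains
a normalized hit rate of 1.25 — habitat-similar site pairs host shared
species 25% more often than randomly kept edges would — while the
land-use graph is barely better than random (1.06), and the species-set
graph, built from the same occupancy data it is scored against, is the
most enriched (1.77).  The correlation block makes the same point per
species: habitat hit rates track species-set hit rates (rho = +0.73),
land-use hit rates do not (−0.04).  This is the expected signature when
species occupancy follows habitat while land-use mapping comes from an
unrelated source.

The same run writes GraphML graphs, sweep tables, node-index tables,
hit-rate and correlation CSVs, per-species candidate lists and a
checksummed manifest under `runs/demo/`.  The library API mirrors the
CLI: see `sitegraphs.RunConfig` / `sitegraphs.run_pipeline`.

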