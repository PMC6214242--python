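"""Hit rates, normalized hit rate, rank correlations, and candidate sites.

A similarity-based graph is judged by how well it anticipates the edges of
single-species graphs: for each species, the *hit rate* is the fraction of
that species' graph edges also present in the similarity graph.  Because a
denser graph hits more edges by chance, the average hit rate R is
normalized by the graph's relative density |E|/n (n = raw-distance edge
count)::

    normalized hit rate = R / (|E| / n) = R · n / |E|

Spearman rank correlations compare per-species hit-rate columns between
graphs, and node-index columns between graphs, to ask whether two graph
constructions express the same concept.

The candidate finder formalizes relocation-site proposals: given a
connected component V′ of a species' graph, an edge (i, j) of the
similarity graph with i ∈ V′ and j ∉ V′ marks j — necessarily a site not
hosting the species — as a candidate site, and (i, j) as the candidate
edge linking it to the component.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Mapping, NamedTuple, Sequence

import networkx as nx
import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "HitRate",
    "GraphEvaluation",
    "CandidateSet",
    "hit_rate",
    "summarize",
    "spearman",
    "build_hit_rate_table",
    "summarize_graphs",
    "correlate_hit_rates",
    "correlate_indices",
    "find_candidates",
]


class HitRate(NamedTuple):
    """Edge count m of one species graph, hits h, and rate h/m (NaN if m=0)."""

    m: int
    h: int
    rate: float


@dataclass(frozen=True)
class GraphEvaluation:
    """Summary row for one similarity graph: average hit rate and its density-normalized form."""

    label: str
    R: float
    E: int
    n: int
    density: float
    nhr: float

    def __post_init__(self) -> None:
        if not 0.0 <= self.density <= 1.0:
            raise ValueError(f"relative density {self.density} outside [0, 1]")
        if abs(self.nhr * self.density - self.R) > 1e-9:
            raise ValueError("normalized hit rate × density must equal R")


@dataclass(frozen=True)
class CandidateSet:
    """Candidate relocation edges for one connected component of a species graph."""

    species_code: str
    component: frozenset[str]
    candidates: frozenset[tuple[str, str]]  # (i in component, j outside)


def hit_rate(species_graph, sim_graph) -> HitRate:
    """Hits of one species graph's edges in a similarity graph.

    Both graphs must have been built with the same distance threshold.
    Returns (m, h, rate) with rate = h/m, NaN when the species graph has
    no edges.
    """
    ta = species_graph.params.get("distance_threshold_km")
    tb = sim_graph.params.get("distance_threshold_km")
    if ta is not None and tb is not None and ta != tb:
        raise ValueError(f"distance thresholds differ: {ta} vs {tb}")
    m = len(species_graph.edges)
    h = len(species_graph.edges & sim_graph.edges)
    return HitRate(m=m, h=h, rate=h / m if m else math.nan)


def summarize(
    rates: Iterable[float],
    E: int,
    n: int,
    label: str = "",
    zero_edge_species_as_zero: bool = False,
) -> GraphEvaluation:
    """Average defined hit rates and normalize by relative density.

    ``rates`` may contain NaN for species without edges; by default those
    are excluded from the average (0/0 is undefined, and the hit-rate
    table only lists species with edges).  Set
    ``zero_edge_species_as_zero`` to count them as rate 0 instead.
    Requires E > 0 and n > 0.
    """
    if n <= 0:
        raise ValueError("raw-distance edge count n must be positive")
    if E <= 0:
        raise ValueError("similarity-graph edge count E must be positive "
                         "(normalized hit rate undefined)")
    if zero_edge_species_as_zero:
        defined = [0.0 if math.isnan(r) else r for r in rates]
    else:
        defined = [r for r in rates if not math.isnan(r)]
    if not defined:
        raise ValueError("no species with a defined hit rate")
    R = float(np.mean(defined))
    density = E / n
    return GraphEvaluation(
        label=label, R=R, E=E, n=n, density=density, nhr=R * n / E
    )


def spearman(a: Sequence[float], b: Sequence[float]) -> float:
    """Spearman rank correlation with mid-rank ties and listwise NaN deletion.

    Equals the Pearson correlation of average ranks.  Raises on fewer than
    3 complete pairs or when either column is constant after deletion
    (zero rank variance).
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.shape != b.shape:
        raise ValueError("columns differ in length")
    keep = ~(np.isnan(a) | np.isnan(b))
    a, b = a[keep], b[keep]
    if a.size < 3:
        raise ValueError(f"need ≥ 3 complete pairs, have {a.size}")
    if np.all(a == a[0]) or np.all(b == b[0]):
        raise ValueError("zero rank variance: a column is constant")
    rho = stats.spearmanr(a, b).statistic
    return float(rho)


def build_hit_rate_table(
    species_graphs: Mapping[str, object], sim_graphs: Mapping[str, object]
) -> pd.DataFrame:
    """Per-species hit counts and rates against each similarity graph.

    Returns a DataFrame indexed by species code with an ``edges`` column
    (m, the species-graph edge count) and, per similarity-graph label,
    ``hits_<label>`` and ``rate_<label>`` columns.  Rates are NaN for
    species with no edges.
    """
    rows = {}
    for code, sg in species_graphs.items():
        row: dict[str, float] = {"edges": len(sg.edges)}
        for label, simg in sim_graphs.items():
            hr = hit_rate(sg, simg)
            row[f"hits_{label}"] = hr.h
            row[f"rate_{label}"] = hr.rate
        rows[code] = row
    table = pd.DataFrame.from_dict(rows, orient="index")
    table.index.name = "species_code"
    return table


def summarize_graphs(
    hit_rate_table: pd.DataFrame, sim_graphs: Mapping[str, object], raw_graph
) -> pd.DataFrame:
    """One evaluation row (R, |E|, density, normalized hit rate) per graph.

    A graph with no edges at the chosen threshold has an undefined
    normalized hit rate; its row carries NaN instead of aborting the run.
    """
    n = len(raw_graph.edges)
    rows = []
    for label, simg in sim_graphs.items():
        if len(simg.edges) == 0:
            rows.append(
                {
                    "graph": label,
                    "avg_hit_rate": math.nan,
                    "edges": 0,
                    "raw_edges": n,
                    "relative_density": 0.0,
                    "normalized_hit_rate": math.nan,
                }
            )
            continue
        ev = summarize(
            hit_rate_table[f"rate_{label}"].tolist(),
            E=len(simg.edges),
            n=n,
            label=label,
        )
        rows.append(
            {
                "graph": ev.label,
                "avg_hit_rate": ev.R,
                "edges": ev.E,
                "raw_edges": ev.n,
                "relative_density": ev.density,
                "normalized_hit_rate": ev.nhr,
            }
        )
    return pd.DataFrame(rows).set_index("graph")


def correlate_hit_rates(
    hit_rate_table: pd.DataFrame, pairing: Sequence[tuple[str, str]]
) -> pd.DataFrame:
    """Spearman rho between per-species hit-rate columns of graph pairs."""
    rows = []
    for la, lb in pairing:
        rho = spearman(
            hit_rate_table[f"rate_{la}"].to_numpy(),
            hit_rate_table[f"rate_{lb}"].to_numpy(),
        )
        rows.append({"graph_a": la, "graph_b": lb, "spearman_rho": rho})
    return pd.DataFrame(rows)


def correlate_indices(
    index_tables: Mapping[str, pd.DataFrame],
    index_name: str,
    pairing: Sequence[tuple[str, str]],
) -> pd.DataFrame:
    """Spearman rho of one node index between graph pairs, nodes aligned by id."""
    rows = []
    for la, lb in pairing:
        ta, tb = index_tables[la], index_tables[lb]
        if set(ta.index) != set(tb.index):
            raise ValueError(f"graphs {la} and {lb} have different node sets")
        aligned = tb.loc[ta.index]
        rho = spearman(
            ta[index_name].to_numpy(), aligned[index_name].to_numpy()
        )
        rows.append({"graph_a": la, "graph_b": lb, "spearman_rho": rho})
    return pd.DataFrame(rows)


def find_candidates(species_graph, occupancy, sim_graph) -> list[CandidateSet]:
    """Candidate relocation sites per connected component of a species graph.

    ``species_graph`` is the non-full variant (nodes = occupied sites);
    isolated occupied sites form singleton components and are scanned too.
    A pair (i, j) is a candidate when i belongs to the component, j is a
    node outside it, and (i, j) is an edge of the similarity graph.  Since
    the similarity graph links only pairs within the distance threshold,
    such a j can never host the species (it would be in the component).
    """
    g = nx.Graph()
    g.add_nodes_from(species_graph.nodes)
    g.add_edges_from(species_graph.edges)
    all_nodes = set(sim_graph.nodes)
    adjacency = {v: set() for v in all_nodes}
    for a, b in sim_graph.edges:
        adjacency[a].add(b)
        adjacency[b].add(a)
    out = []
    for component in nx.connected_components(g):
        cands = {
            (i, j)
            for i in component
            for j in adjacency.get(i, ())
            if j in all_nodes and j not in component
        }
        out.append(
            CandidateSet(
                species_code=occupancy.species_code,
                component=frozenset(component),
                candidates=frozenset(cands),
            )
        )
    out.sort(key=lambda cs: sorted(cs.component)[0])
    return out
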