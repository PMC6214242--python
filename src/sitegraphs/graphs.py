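"""The four graph families of the site-network model.

All graphs share the same undirected, simple structure over site-id nodes:

* **raw-distance graph** — every site pair within the geographical distance
  threshold (default 30 km) is linked; this fixes the edge budget *n* that
  all other graphs are measured against.
* **single-species graph** — nodes are the sites where one target species
  is reported; pairs within the distance threshold are linked.
* **full single-species graph** — same edges, but on the full node set, so
  that edge sets are directly comparable across graphs.
* **similarity-based graph** — raw-distance edges filtered to pairs whose
  attribute-vector similarity is at or above a minimum score (inclusive ≥).

Zero-distance partner nodes (overlapping SPA/SCI designations) are distinct
nodes at distance 0 and may be linked to each other whenever the
non-distance criteria pass.  Pairs whose similarity is undefined (zero
vector under cosine) are never linked.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping

import numpy as np

__all__ = [
    "EcoGraph",
    "SpeciesOccupancy",
    "species_occupancy",
    "build_raw_distance",
    "build_single_species",
    "build_similarity_graph",
    "edge_count_sweep",
]

Edge = tuple[str, str]


def _edge(a: str, b: str) -> Edge:
    return (a, b) if a <= b else (b, a)


@dataclass(frozen=True)
class EcoGraph:
    """Undirected simple graph over site nodes, tagged with its construction.

    ``kind`` is one of ``raw_distance``, ``single_species``,
    ``full_single_species``, ``similarity``; ``params`` records the
    thresholds (and species code or similarity recipe) used to build it.
    Edges are stored as sorted site-id pairs, so (a, b) and (b, a) are the
    same edge and self-loops cannot be represented.
    """

    kind: str
    nodes: tuple[str, ...]
    edges: frozenset[Edge]
    params: Mapping[str, object] = field(default_factory=dict)

    def __post_init__(self) -> None:
        nodeset = set(self.nodes)
        for a, b in self.edges:
            if a == b:
                raise ValueError(f"self-loop on {a!r}")
            if a not in nodeset or b not in nodeset:
                raise ValueError(f"edge ({a!r}, {b!r}) references unknown node")

    @property
    def n_edges(self) -> int:
        return len(self.edges)

    def has_edge(self, a: str, b: str) -> bool:
        return _edge(a, b) in self.edges

    def to_networkx(self):
        import networkx as nx

        g = nx.Graph()
        g.graph.update({"kind": self.kind})
        g.graph.update({k: str(v) for k, v in self.params.items()})
        g.add_nodes_from(self.nodes)
        g.add_edges_from(self.edges)
        return g


@dataclass(frozen=True)
class SpeciesOccupancy:
    """The set of sites where one species is reported present."""

    species_code: str
    occupied: frozenset[str]


def species_occupancy(compositions, sites=None) -> dict[str, SpeciesOccupancy]:
    """Species code → occupied-site set from composition records.

    When ``sites`` is given, occupancy is restricted to those site ids
    (after the inclusion filter, species reports on excluded sites are
    dropped).
    """
    keep = None
    if sites is not None:
        keep = {getattr(s, "site_id", s) for s in sites}
    occupied: dict[str, set[str]] = {}
    for rec in compositions:
        if rec.dataset != "species":
            continue
        if keep is not None and rec.site_id not in keep:
            continue
        occupied.setdefault(rec.code, set()).add(rec.site_id)
    return {
        code: SpeciesOccupancy(species_code=code, occupied=frozenset(members))
        for code, members in sorted(occupied.items())
    }


def _close_pairs(D, threshold_km: float) -> set[Edge]:
    ids = D.site_ids
    iu, ju = np.triu_indices(len(ids), k=1)
    mask = D.values[iu, ju] <= threshold_km
    return {_edge(ids[i], ids[j]) for i, j in zip(iu[mask], ju[mask])}


def build_raw_distance(sites, D, threshold_km: float = 30.0) -> EcoGraph:
    """Link every site pair within ``threshold_km`` (inclusive ≤).

    Zero-distance partner pairs have distance 0 in ``D`` and are therefore
    always linked.  The edge count of this graph is the *n* against which
    similarity-graph densities are measured.
    """
    if threshold_km < 0:
        raise ValueError("distance threshold must be ≥ 0")
    sites = list(sites)
    ids = tuple(getattr(s, "site_id", s) for s in sites)
    if ids != D.site_ids:
        raise ValueError("site list does not match distance matrix order")
    return EcoGraph(
        kind="raw_distance",
        nodes=ids,
        edges=frozenset(_close_pairs(D, threshold_km)),
        params={"distance_threshold_km": threshold_km},
    )


def build_single_species(
    occupancy: SpeciesOccupancy, D, threshold_km: float = 30.0, full: bool = False
) -> EcoGraph:
    """Link occupied site pairs within the distance threshold.

    With ``full=False`` the node set is the occupied sites only (the
    single-species graph); with ``full=True`` all sites remain as nodes
    with the same edge set (the full single-species graph, used when edge
    sets must be comparable across graphs).
    """
    unknown = occupancy.occupied - set(D.site_ids)
    if unknown:
        raise ValueError(
            f"occupancy for {occupancy.species_code} references unknown sites "
            f"{sorted(unknown)}"
        )
    edges = {
        e for e in _close_pairs(D, threshold_km)
        if e[0] in occupancy.occupied and e[1] in occupancy.occupied
    }
    nodes = D.site_ids if full else tuple(
        s for s in D.site_ids if s in occupancy.occupied
    )
    return EcoGraph(
        kind="full_single_species" if full else "single_species",
        nodes=nodes,
        edges=frozenset(edges),
        params={
            "distance_threshold_km": threshold_km,
            "species_code": occupancy.species_code,
        },
    )


def build_similarity_graph(
    sites, D, S, threshold_km: float = 30.0, min_sim: float = 0.5
) -> EcoGraph:
    """Link pairs within the distance threshold whose similarity ≥ ``min_sim``.

    Equivalent to removing from the raw-distance graph every edge whose
    similarity score is below the minimum.  The comparison is an exact ≥ at
    double precision.  Pairs with undefined similarity are never linked.
    """
    if not 0.0 <= min_sim <= 1.0:
        raise ValueError("similarity threshold must be in [0, 1]")
    raw = build_raw_distance(sites, D, threshold_km)
    if S.site_ids != D.site_ids:
        raise ValueError("similarity matrix order does not match distance matrix")
    index = {s: i for i, s in enumerate(S.site_ids)}
    edges = set()
    for a, b in raw.edges:
        i, j = index[a], index[b]
        if S.defined[i, j] and S.values[i, j] >= min_sim:
            edges.add((a, b))
    return EcoGraph(
        kind="similarity",
        nodes=raw.nodes,
        edges=frozenset(edges),
        params={
            "distance_threshold_km": threshold_km,
            "similarity_threshold": min_sim,
            "measure": S.measure,
            "dataset": S.dataset,
            "mode": S.mode,
        },
    )


def edge_count_sweep(
    sites, D, S, threshold_km: float = 30.0, sim_levels: Iterable[float] = ()
):
    """Edge counts of similarity graphs across a sweep of minimum scores.

    Returns a :class:`pandas.DataFrame` with columns ``min_sim`` and
    ``edges``; the count at level 0.0 equals the raw-distance edge count
    minus any undefined-similarity pairs, and counts are non-increasing in
    the level (nested thresholds).
    """
    import pandas as pd

    levels = list(sim_levels)
    if any(not 0.0 <= lv <= 1.0 for lv in levels):
        raise ValueError("sweep levels must be in [0, 1]")
    rows = [
        (lv, build_similarity_graph(sites, D, S, threshold_km, lv).n_edges)
        for lv in levels
    ]
    return pd.DataFrame(rows, columns=["min_sim", "edges"])
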