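"""Tabular I/O, inter-site distances, and site inclusion filters.

Two CSV tables drive the pipeline:

* the **site table** — one row per site node with its designation(s)
  (SPA and/or SCI), coordinates, optional boundary polygon,
  zero-distance partners, and inclusion flags;
* the **composition table** — one row per (site, dataset, code) with a
  patch count and a surface area in hectares.

Overlapping SPA/SCI designations are modelled as two distinct site nodes
declared as *zero-distance partners*: whatever their stored coordinates,
their distance is forced to 0, so they are always within any distance
threshold.

Distances are in kilometres.  ``planar`` mode is Euclidean distance on
projected km coordinates; ``geodesic`` is the great-circle distance on
lon/lat degrees (mean Earth radius 6371.0088 km); ``boundary`` is the
minimum distance between site boundary polygons.  Projected distance is an
approximation, acceptable at the regional scales this model targets.
"""

from __future__ import annotations

import csv
import logging
from dataclasses import dataclass, field, replace

import numpy as np

__all__ = [
    "SiteRecord",
    "CompositionRecord",
    "DistanceMatrix",
    "read_site_table",
    "write_site_table",
    "read_composition_table",
    "write_composition_table",
    "filter_sites",
    "compute_distances",
    "write_graph",
    "read_graphml",
]

logger = logging.getLogger(__name__)

EARTH_RADIUS_KM = 6371.0088
DESIGNATIONS = ("SPA", "SCI")

SITE_COLUMNS = [
    "site_id",
    "designations",
    "x_km",
    "y_km",
    "zero_distance_partners",
    "missing_landuse",
    "on_mainland",
    "boundary",
]
COMPOSITION_COLUMNS = ["site_id", "dataset", "code", "count", "area_ha"]


@dataclass(frozen=True)
class SiteRecord:
    """One protected-site node.

    ``x_km``/``y_km`` are planar projected coordinates by default; with
    ``coordinate_mode="lonlat"`` they hold longitude/latitude degrees.
    ``boundary`` is an optional polygon as a tuple of (x, y) vertices.
    """

    site_id: str
    designations: frozenset[str]
    x_km: float
    y_km: float
    zero_distance_partners: tuple[str, ...] = ()
    missing_landuse: bool = False
    on_mainland: bool = True
    boundary: tuple[tuple[float, float], ...] | None = None

    def __post_init__(self) -> None:
        if not self.designations or not self.designations <= set(DESIGNATIONS):
            raise ValueError(
                f"site {self.site_id}: designations must be a non-empty subset "
                f"of {DESIGNATIONS}, got {sorted(self.designations)}"
            )


@dataclass(frozen=True)
class CompositionRecord:
    """One (site, dataset, code) composition entry."""

    site_id: str
    dataset: str
    code: str
    count: int = 1
    area_ha: float = 0.0

    def __post_init__(self) -> None:
        if self.count < 1:
            raise ValueError(f"composition count must be ≥ 1, got {self.count}")
        if self.area_ha < 0:
            raise ValueError(f"composition area must be ≥ 0, got {self.area_ha}")


@dataclass(frozen=True)
class DistanceMatrix:
    """Symmetric km distances with zero diagonal, indexed by site id."""

    site_ids: tuple[str, ...]
    values: np.ndarray

    def __post_init__(self) -> None:
        n = len(self.site_ids)
        if self.values.shape != (n, n):
            raise ValueError("distance matrix shape does not match site list")

    def get(self, a: str, b: str) -> float:
        return float(
            self.values[self.site_ids.index(a), self.site_ids.index(b)]
        )


# ---------------------------------------------------------------------------
# site / composition tables
# ---------------------------------------------------------------------------

def _parse_bool(token: str) -> bool:
    return token.strip().lower() in ("1", "true", "yes")


def _parse_boundary(token: str):
    token = token.strip()
    if not token:
        return None
    vertices = []
    for pair in token.split(";"):
        x, y = pair.split()
        vertices.append((float(x), float(y)))
    return tuple(vertices)


def _format_boundary(boundary) -> str:
    if boundary is None:
        return ""
    return ";".join(f"{x:g} {y:g}" for x, y in boundary)


def read_site_table(path) -> list[SiteRecord]:
    """Read a site table CSV; enforce unique ids and partner symmetry."""
    records: list[SiteRecord] = []
    with open(path, newline="", encoding="utf-8") as handle:
        reader = csv.DictReader(handle)
        missing = {"site_id", "designations", "x_km", "y_km"} - set(
            reader.fieldnames or []
        )
        if missing:
            raise ValueError(f"site table {path}: missing columns {sorted(missing)}")
        for row in reader:
            designations = frozenset(
                tok.strip() for tok in row["designations"].split("|") if tok.strip()
            )
            unknown = designations - set(DESIGNATIONS)
            if unknown:
                raise ValueError(
                    f"site {row['site_id']}: unknown designation {sorted(unknown)}"
                )
            partners = tuple(
                tok.strip()
                for tok in (row.get("zero_distance_partners") or "").split("|")
                if tok.strip()
            )
            records.append(
                SiteRecord(
                    site_id=row["site_id"],
                    designations=designations,
                    x_km=float(row["x_km"]),
                    y_km=float(row["y_km"]),
                    zero_distance_partners=partners,
                    missing_landuse=_parse_bool(row.get("missing_landuse") or ""),
                    on_mainland=_parse_bool(row.get("on_mainland") or "true"),
                    boundary=_parse_boundary(row.get("boundary") or ""),
                )
            )
    validate_sites(records)
    return records


def validate_sites(records) -> None:
    """Check id uniqueness and zero-distance partnership symmetry."""
    seen: set[str] = set()
    for rec in records:
        if rec.site_id in seen:
            raise ValueError(f"duplicate site_id {rec.site_id!r}")
        seen.add(rec.site_id)
    partners = {rec.site_id: set(rec.zero_distance_partners) for rec in records}
    for rec in records:
        for other in rec.zero_distance_partners:
            if other not in partners:
                raise ValueError(
                    f"site {rec.site_id}: unknown zero-distance partner {other!r}"
                )
            if rec.site_id not in partners[other]:
                raise ValueError(
                    f"asymmetric zero-distance partnership: {rec.site_id} lists "
                    f"{other} but not vice versa"
                )


def write_site_table(records, path) -> None:
    with open(path, "w", newline="", encoding="utf-8") as handle:
        writer = csv.writer(handle)
        writer.writerow(SITE_COLUMNS)
        for rec in records:
            writer.writerow(
                [
                    rec.site_id,
                    "|".join(sorted(rec.designations)),
                    repr(rec.x_km),
                    repr(rec.y_km),
                    "|".join(rec.zero_distance_partners),
                    str(rec.missing_landuse).lower(),
                    str(rec.on_mainland).lower(),
                    _format_boundary(rec.boundary),
                ]
            )


def read_composition_table(path) -> list[CompositionRecord]:
    records: list[CompositionRecord] = []
    seen: set[tuple[str, str, str]] = set()
    with open(path, newline="", encoding="utf-8") as handle:
        reader = csv.DictReader(handle)
        missing = set(COMPOSITION_COLUMNS) - set(reader.fieldnames or [])
        if missing:
            raise ValueError(
                f"composition table {path}: missing columns {sorted(missing)}"
            )
        for row in reader:
            key = (row["site_id"], row["dataset"], row["code"])
            if key in seen:
                raise ValueError(f"duplicate composition row {key}")
            seen.add(key)
            records.append(
                CompositionRecord(
                    site_id=row["site_id"],
                    dataset=row["dataset"],
                    code=row["code"],
                    count=int(row["count"]),
                    area_ha=float(row["area_ha"]),
                )
            )
    return records


def write_composition_table(records, path) -> None:
    with open(path, "w", newline="", encoding="utf-8") as handle:
        writer = csv.writer(handle)
        writer.writerow(COMPOSITION_COLUMNS)
        for rec in records:
            writer.writerow(
                [rec.site_id, rec.dataset, rec.code, rec.count, repr(rec.area_ha)]
            )


def filter_sites(
    sites, require_landuse: bool = False, mainland_only: bool = False
) -> list[SiteRecord]:
    """Apply the study-area inclusion filters.

    ``require_landuse`` drops sites flagged as missing land-use data;
    ``mainland_only`` drops minor-island sites so that results apply to
    land animals.  Excluded ids are logged with the reason.  Idempotent.
    """
    kept = []
    for rec in sites:
        if require_landuse and rec.missing_landuse:
            logger.info("excluding %s: missing land-use data", rec.site_id)
            continue
        if mainland_only and not rec.on_mainland:
            logger.info("excluding %s: not on mainland", rec.site_id)
            continue
        kept.append(rec)
    if not kept:
        logger.warning("site filter removed every site")
    return kept


# ---------------------------------------------------------------------------
# distances
# ---------------------------------------------------------------------------

def _great_circle_km(lon, lat) -> np.ndarray:
    lon = np.radians(lon)
    lat = np.radians(lat)
    dlat = lat[:, None] - lat[None, :]
    dlon = lon[:, None] - lon[None, :]
    h = (
        np.sin(dlat / 2) ** 2
        + np.cos(lat)[:, None] * np.cos(lat)[None, :] * np.sin(dlon / 2) ** 2
    )
    return 2 * EARTH_RADIUS_KM * np.arcsin(np.sqrt(np.clip(h, 0.0, 1.0)))


def compute_distances(sites, mode: str = "planar") -> DistanceMatrix:
    """Pairwise inter-site distances in km.

    Modes: ``planar`` (Euclidean on km coordinates), ``geodesic``
    (great-circle on lon/lat degrees), ``boundary`` (minimum distance
    between boundary polygons; requires every site to carry one).
    Declared zero-distance partner pairs are forced to 0 after the
    geometric computation, matching the rule for overlapping SPA/SCI
    boundaries.
    """
    sites = list(sites)
    ids = tuple(rec.site_id for rec in sites)
    index = {s: i for i, s in enumerate(ids)}
    if mode == "planar":
        xy = np.array([[rec.x_km, rec.y_km] for rec in sites])
        from scipy.spatial.distance import squareform, pdist

        values = squareform(pdist(xy)) if len(sites) > 1 else np.zeros((1, 1))
    elif mode == "geodesic":
        lon = np.array([rec.x_km for rec in sites])
        lat = np.array([rec.y_km for rec in sites])
        values = _great_circle_km(lon, lat)
    elif mode == "boundary":
        from shapely.geometry import Polygon

        polys = []
        for rec in sites:
            if rec.boundary is None or len(rec.boundary) < 3:
                raise ValueError(
                    f"boundary mode requires a polygon for every site; "
                    f"{rec.site_id} has none"
                )
            polys.append(Polygon(rec.boundary))
        n = len(polys)
        values = np.zeros((n, n))
        for i in range(n):
            for j in range(i + 1, n):
                d = polys[i].distance(polys[j])
                values[i, j] = values[j, i] = d
    else:
        raise ValueError(f"unknown distance mode {mode!r}")

    np.fill_diagonal(values, 0.0)
    for rec in sites:
        for other in rec.zero_distance_partners:
            if other in index:
                i, j = index[rec.site_id], index[other]
                values[i, j] = values[j, i] = 0.0
    return DistanceMatrix(site_ids=ids, values=values)


# ---------------------------------------------------------------------------
# graph output
# ---------------------------------------------------------------------------

def write_graph(graph, path, format: str = "graphml", node_attrs=None) -> None:
    """Write an :class:`~sitegraphs.graphs.EcoGraph` to GraphML or edge-list CSV.

    GraphML preserves graph-level parameters plus any per-node attributes
    passed in ``node_attrs`` (a mapping node id → {name: value}, e.g.
    designations or species-occupancy marks); the edge list is a
    two-column CSV with header.
    """
    if format == "graphml":
        import networkx as nx

        g = graph.to_networkx()
        if node_attrs:
            for node, attrs in node_attrs.items():
                if node in g.nodes:
                    g.nodes[node].update(attrs)
        nx.write_graphml(g, path)
    elif format == "edgelist_csv":
        with open(path, "w", newline="", encoding="utf-8") as handle:
            writer = csv.writer(handle)
            writer.writerow(["source", "target"])
            for a, b in sorted(graph.edges):
                writer.writerow([a, b])
    else:
        raise ValueError(f"unknown graph format {format!r}")


def read_graphml(path):
    """Read a GraphML file back into a networkx graph (round-trip checks)."""
    import networkx as nx

    return nx.read_graphml(path)
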