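"""End-to-end runs: data → vectors → similarity graphs → evaluation reports.

A run, configured by :class:`RunConfig`, either loads the site and
composition tables from CSV or generates a synthetic landscape, applies the
inclusion filters, and then builds the whole graph battery: the
raw-distance graph, one similarity graph per recipe (a (dataset, mode,
measure) triple), the full single-species graph for every species, the
threshold sweep tables, node-index tables, the hit-rate table and its
summary, the rank-correlation tables, and per-species candidate lists.
Outputs are plain CSV/GraphML files plus a JSON manifest with content
checksums; identical config and seed reproduce identical outputs.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

from . import evaluation, graphs, indices, io_tables, landscape, vectors
from .similarity import pairwise_similarity

__all__ = ["RunConfig", "DEFAULT_RECIPES", "recipe_label", "run_pipeline", "make_report"]

logger = logging.getLogger(__name__)

Recipe = tuple[str, str, str]  # (dataset, mode, measure)

#: The seven graph recipes of the standard comparison: Jaccard on binary
#: land-use, habitat and species vectors; cosine on occurrence and on area
#: vectors for land use and habitats.
DEFAULT_RECIPES: tuple[Recipe, ...] = (
    ("landuse", "binary", "jaccard"),
    ("habitat", "binary", "jaccard"),
    ("species", "binary", "jaccard"),
    ("landuse", "count", "cosine"),
    ("habitat", "count", "cosine"),
    ("landuse", "area", "cosine"),
    ("habitat", "area", "cosine"),
)

DEFAULT_SWEEP = (0.0, 0.4, 0.5, 0.6, 0.7, 0.8, 0.9)


def recipe_label(recipe: Recipe) -> str:
    dataset, mode, measure = recipe
    if measure == "jaccard":
        return f"{dataset}_jaccard"
    return f"{dataset}_cosine_{mode}"


def _validate_recipe(recipe: Recipe) -> None:
    dataset, mode, measure = recipe
    if dataset not in vectors.DATASETS:
        raise ValueError(f"invalid recipe {recipe}: unknown dataset")
    if mode not in vectors.MODES:
        raise ValueError(f"invalid recipe {recipe}: unknown mode")
    if measure not in ("jaccard", "cosine"):
        raise ValueError(f"invalid recipe {recipe}: unknown measure")
    if dataset == "species" and (mode, measure) != ("binary", "jaccard"):
        raise ValueError(
            f"invalid recipe {recipe}: species vectors are binary/jaccard only"
        )
    if measure == "jaccard" and mode != "binary":
        raise ValueError(f"invalid recipe {recipe}: jaccard requires binary mode")


@dataclass(frozen=True)
class RunConfig:
    """Configuration of one pipeline run.

    Either ``sites_path``/``compositions_path`` point at CSV inputs, or
    ``synthetic`` holds a :class:`~sitegraphs.landscape.LandscapeConfig`
    to generate them.  ``distance_threshold_km`` and
    ``similarity_threshold`` default to the standard 30 km / 0.5 setting.
    """

    sites_path: str | None = None
    compositions_path: str | None = None
    synthetic: landscape.LandscapeConfig | None = None
    distance_threshold_km: float = 30.0
    similarity_threshold: float = 0.5
    sweep_levels: tuple[float, ...] = DEFAULT_SWEEP
    recipes: tuple[Recipe, ...] = DEFAULT_RECIPES
    candidate_recipe: Recipe = ("habitat", "binary", "jaccard")
    require_landuse: bool = True
    mainland_only: bool = True
    out_dir: str | None = None
    seed: int = 0
    log_level: str = "INFO"

    def __post_init__(self) -> None:
        if self.distance_threshold_km < 0:
            raise ValueError("distance_threshold_km must be ≥ 0")
        if not 0.0 <= self.similarity_threshold <= 1.0:
            raise ValueError("similarity_threshold must be in [0, 1]")
        if any(not 0.0 <= lv <= 1.0 for lv in self.sweep_levels):
            raise ValueError("sweep levels must be in [0, 1]")
        for recipe in self.recipes + (self.candidate_recipe,):
            _validate_recipe(tuple(recipe))
        if self.sites_path is None and self.synthetic is None:
            raise ValueError("either input paths or a synthetic config is required")


def _load_bundle(config: RunConfig):
    if config.synthetic is not None:
        bundle = landscape.generate_landscape(config.synthetic)
        if config.synthetic.missing_data_fraction > 0:
            bundle = landscape.inject_missing_data(
                bundle, config.synthetic.missing_data_fraction,
                seed=config.synthetic.seed + 1,
            )
        return list(bundle.sites), list(bundle.compositions)
    sites = io_tables.read_site_table(config.sites_path)
    comps = io_tables.read_composition_table(config.compositions_path)
    return sites, comps


def run_pipeline(config: RunConfig) -> dict:
    """Execute a full run; return the in-memory results and output paths.

    The returned dict holds the site list, raw graph, per-recipe similarity
    graphs, sweep tables, index tables, hit-rate table, evaluation summary,
    correlation tables and candidate lists; when ``config.out_dir`` is set,
    everything is also written to disk and listed in ``manifest``.
    """
    logging.basicConfig(level=config.log_level)
    sites_all, compositions = _load_bundle(config)
    sites = io_tables.filter_sites(
        sites_all,
        require_landuse=config.require_landuse,
        mainland_only=config.mainland_only,
    )
    kept = {s.site_id for s in sites}
    # a kept site may declare a partner that the filter dropped
    sites = [
        dataclasses.replace(
            s,
            zero_distance_partners=tuple(
                p for p in s.zero_distance_partners if p in kept
            ),
        )
        for s in sites
    ]
    D = io_tables.compute_distances(sites, mode="planar")
    raw = graphs.build_raw_distance(sites, D, config.distance_threshold_km)

    sim_graphs: dict[str, graphs.EcoGraph] = {}
    sweeps: dict[str, pd.DataFrame] = {}
    index_tables: dict[str, pd.DataFrame] = {}
    for recipe in config.recipes:
        dataset, mode, measure = recipe
        label = recipe_label(recipe)
        vs = vectors.build_vector_set(compositions, sites, dataset, mode)
        S = pairwise_similarity(vs, measure)
        sim_graphs[label] = graphs.build_similarity_graph(
            sites, D, S, config.distance_threshold_km, config.similarity_threshold
        )
        sweeps[label] = graphs.edge_count_sweep(
            sites, D, S, config.distance_threshold_km, config.sweep_levels
        )
        index_tables[label] = indices.compute_indices(sim_graphs[label])

    occupancy = graphs.species_occupancy(compositions, sites)
    full_species_graphs = {
        code: graphs.build_single_species(occ, D, config.distance_threshold_km,
                                          full=True)
        for code, occ in occupancy.items()
    }
    hit_table = evaluation.build_hit_rate_table(full_species_graphs, sim_graphs)
    summary = evaluation.summarize_graphs(hit_table, sim_graphs, raw)

    pairings = hit_rate_pairings(config.recipes)
    hit_corr = {
        group: _safe_correlation(
            lambda pair: evaluation.correlate_hit_rates(hit_table, [pair]),
            pairing,
        )
        for group, pairing in pairings.items()
    }
    index_corr = {
        group: pd.concat(
            [
                _safe_correlation(
                    lambda pair, n=name: evaluation.correlate_indices(
                        index_tables, n, [pair]
                    ),
                    pairing,
                ).assign(index=name)
                for name in indices.INDEX_NAMES
            ],
            ignore_index=True,
        )
        for group, pairing in pairings.items()
    }

    cand_label = recipe_label(config.candidate_recipe)
    candidates: dict[str, list[evaluation.CandidateSet]] = {}
    if cand_label in sim_graphs:
        for code, occ in occupancy.items():
            sg = graphs.build_single_species(
                occ, D, config.distance_threshold_km, full=False
            )
            candidates[code] = evaluation.find_candidates(
                sg, occ, sim_graphs[cand_label]
            )

    results = {
        "config": config,
        "sites": sites,
        "compositions": compositions,
        "distances": D,
        "raw_graph": raw,
        "sim_graphs": sim_graphs,
        "sweeps": sweeps,
        "index_tables": index_tables,
        "hit_rate_table": hit_table,
        "summary": summary,
        "hit_rate_correlations": hit_corr,
        "index_correlations": index_corr,
        "candidates": candidates,
    }
    if config.out_dir is not None:
        results["manifest"] = _write_outputs(results, Path(config.out_dir))
    return results


def _safe_correlation(correlate_one, pairing) -> pd.DataFrame:
    """Run a correlation per pair; a degenerate pair yields NaN, not a crash.

    Sparse graphs can leave an index column constant (zero rank variance),
    for which Spearman's rho is undefined.
    """
    rows = []
    for pair in pairing:
        try:
            rows.append(correlate_one(pair))
        except ValueError as exc:
            logger.warning("correlation %s undefined: %s", pair, exc)
            rows.append(
                pd.DataFrame(
                    [{"graph_a": pair[0], "graph_b": pair[1],
                      "spearman_rho": float("nan")}]
                )
            )
    return pd.concat(rows, ignore_index=True)


def hit_rate_pairings(recipes) -> dict[str, list[tuple[str, str]]]:
    """The standard comparison pairings, grouped by similarity measure.

    Within each measure, land-use and habitat graphs are compared with each
    other and with the species-set graph (always Jaccard-based, the only
    measure species data permits).
    """
    labels = {recipe_label(r) for r in recipes}
    species = "species_jaccard"
    groups = {
        "jaccard": ("landuse_jaccard", "habitat_jaccard"),
        "cosine_count": ("landuse_cosine_count", "habitat_cosine_count"),
        "cosine_area": ("landuse_cosine_area", "habitat_cosine_area"),
    }
    out: dict[str, list[tuple[str, str]]] = {}
    for group, (lu, hab) in groups.items():
        pairing = []
        if lu in labels and species in labels:
            pairing.append((lu, species))
        if lu in labels and hab in labels:
            pairing.append((lu, hab))
        if species in labels and hab in labels:
            pairing.append((species, hab))
        if pairing:
            out[group] = pairing
    return out


def _sha256(path: Path) -> str:
    digest = hashlib.sha256()
    digest.update(path.read_bytes())
    return digest.hexdigest()


def _write_outputs(results: dict, out: Path) -> dict:
    out.mkdir(parents=True, exist_ok=True)
    config: RunConfig = results["config"]
    files: list[Path] = []

    node_attrs = {
        s.site_id: {"designations": "|".join(sorted(s.designations))}
        for s in results["sites"]
    }
    io_tables.write_site_table(results["sites"], out / "sites_used.csv")
    files.append(out / "sites_used.csv")
    io_tables.write_graph(results["raw_graph"], out / "raw_distance.graphml",
                          node_attrs=node_attrs)
    files.append(out / "raw_distance.graphml")

    for label, g in results["sim_graphs"].items():
        path = out / f"graph_{label}.graphml"
        io_tables.write_graph(g, path, node_attrs=node_attrs)
        files.append(path)
    for label, table in results["sweeps"].items():
        path = out / f"sweep_{label}.csv"
        table.to_csv(path, index=False)
        files.append(path)
    for label, table in results["index_tables"].items():
        path = out / f"indices_{label}.csv"
        table.to_csv(path)
        files.append(path)

    results["hit_rate_table"].to_csv(out / "hit_rates.csv")
    files.append(out / "hit_rates.csv")
    results["summary"].to_csv(out / "evaluation_summary.csv")
    files.append(out / "evaluation_summary.csv")
    for group, table in results["hit_rate_correlations"].items():
        path = out / f"hit_rate_correlations_{group}.csv"
        table.to_csv(path, index=False)
        files.append(path)
    for group, table in results["index_correlations"].items():
        path = out / f"index_correlations_{group}.csv"
        table.to_csv(path, index=False)
        files.append(path)

    cand_rows = []
    for code, sets in results["candidates"].items():
        for comp_id, cs in enumerate(sets):
            for i, j in sorted(cs.candidates):
                cand_rows.append(
                    {"species_code": code, "component": comp_id,
                     "occupied_site": i, "candidate_site": j}
                )
    pd.DataFrame(
        cand_rows,
        columns=["species_code", "component", "occupied_site", "candidate_site"],
    ).to_csv(out / "candidates.csv", index=False)
    files.append(out / "candidates.csv")

    report_path = out / "report.txt"
    report_path.write_text(make_report(results), encoding="utf-8")
    files.append(report_path)

    import networkx
    import numpy
    import pandas

    from . import __version__

    manifest = {
        "config": _config_dict(config),
        "seed": config.seed,
        "versions": {
            "sitegraphs": __version__,
            "numpy": numpy.__version__,
            "pandas": pandas.__version__,
            "networkx": networkx.__version__,
        },
        "n_sites_used": len(results["sites"]),
        "raw_edges": len(results["raw_graph"].edges),
        "n_species": int(results["hit_rate_table"].shape[0]),
        "files": {
            str(p.relative_to(out)): {"sha256": _sha256(p)} for p in files
        },
    }
    with open(out / "manifest.json", "w", encoding="utf-8") as handle:
        json.dump(manifest, handle, indent=2, sort_keys=True)
    return manifest


def _config_dict(config: RunConfig) -> dict:
    d = dataclasses.asdict(config)
    return d


def make_report(results: dict) -> str:
    """Render sweeps, hit-rate summary, correlations and candidates as text."""
    lines: list[str] = []
    raw = results["raw_graph"]
    lines.append(f"raw-distance graph: {len(raw.nodes)} nodes, "
                 f"{len(raw.edges)} edges")
    lines.append("")
    lines.append("edge counts along the similarity sweep")
    sweep = pd.DataFrame(
        {label: table.set_index("min_sim")["edges"]
         for label, table in results["sweeps"].items()}
    )
    lines.append(sweep.to_string())
    lines.append("")
    lines.append("hit-rate summary (R, |E|, relative density, normalized hit rate)")
    lines.append(results["summary"].to_string(float_format=lambda v: f"{v:.5f}"))
    lines.append("")
    for group, table in results["hit_rate_correlations"].items():
        lines.append(f"hit-rate Spearman correlations [{group}]")
        lines.append(table.to_string(index=False,
                                     float_format=lambda v: f"{v:+.5f}"))
        lines.append("")
    for group, table in results["index_correlations"].items():
        lines.append(f"node-index Spearman correlations [{group}]")
        lines.append(table.to_string(index=False,
                                     float_format=lambda v: f"{v:+.5f}"))
        lines.append("")
    lines.append("candidate sites")
    for code, sets in results["candidates"].items():
        total = sum(len(cs.candidates) for cs in sets)
        if total == 0:
            lines.append(f"  species {code}: no candidates")
        else:
            lines.append(f"  species {code}: {total} candidate edge(s) over "
                         f"{len(sets)} component(s)")
    lines.append("")
    return "\n".join(lines)
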