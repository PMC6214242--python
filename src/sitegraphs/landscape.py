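"""Synthetic protected-site landscapes with habitat-coupled species occupancy.

The real inputs this pipeline was designed for — standard data forms for a
regional network of protected sites plus land-cover patches from a separate
mapping programme — are not redistributable, so this module generates
landscapes with the same statistical structure:

* ~100 point sites scattered uniformly over a square region, a fraction of
  them emitted as overlapping SPA/SCI node pairs at zero distance;
* habitat composition drawn from a small set of regional *archetype*
  mixtures with distance-decaying interpolation weights, so nearby sites
  have similar habitat mixes (the structure a ~30 km linking threshold
  presumes);
* land-use composition generated by the same mechanism from its own,
  independent archetypes — spatially structured but carrying no
  information about species;
* species occupancy drawn per (site, species) with probability
  ``logistic(intercept + species effect + coupling · (f − f̄))``, where f
  is the fraction of the species' preferred habitat codes reported present
  at the site and f̄ its mean across sites: species occur where their
  habitat occurs, with tunable strength, while prevalence stays comparable
  across coupling settings.  The species effect spreads prevalence
  heavy-tailed (a few widespread species, many rare ones), and
  ``coupling = 0`` makes occupancy independent of habitat.

Every quantity is drawn from one seeded generator: identical config and
seed give byte-identical tables.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field

import numpy as np

from .io_tables import (
    CompositionRecord,
    SiteRecord,
    write_composition_table,
    write_site_table,
)

__all__ = [
    "LandscapeConfig",
    "LandscapeBundle",
    "generate_landscape",
    "inject_missing_data",
    "write_landscape",
]


@dataclass(frozen=True)
class LandscapeConfig:
    """Generation parameters for a synthetic site network.

    Defaults emulate a regional network of the scale the model targets:
    ~100 usable sites, a 131-species pool, level-3 land-cover codes, and a
    habitat autocorrelation range comparable to the 30 km graph threshold.
    """

    n_sites: int = 100
    region_extent_km: float = 150.0
    n_species: int = 131
    n_habitat_codes: int = 40
    n_landuse_codes: int = 44
    dual_designation_fraction: float = 0.15
    missing_data_fraction: float = 0.0
    habitat_species_coupling: float = 6.0
    spatial_range_km: float = 20.0
    patches_per_site_mean: float = 15.0
    prevalence_intercept: float = -1.0
    n_archetypes: int = 8
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("n_sites", "n_species", "n_habitat_codes",
                     "n_landuse_codes", "n_archetypes"):
            if int(getattr(self, name)) < 1:
                raise ValueError(f"{name} must be ≥ 1, got {getattr(self, name)}")
        for name in ("region_extent_km", "spatial_range_km",
                     "patches_per_site_mean"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be > 0, got {getattr(self, name)}")
        for name in ("dual_designation_fraction", "missing_data_fraction"):
            value = getattr(self, name)
            if not 0.0 <= value <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {value}")
        if self.habitat_species_coupling < 0:
            raise ValueError(
                f"habitat_species_coupling must be ≥ 0, "
                f"got {self.habitat_species_coupling}"
            )


@dataclass(frozen=True)
class LandscapeBundle:
    """Generated sites and compositions plus the generation truth record."""

    sites: tuple[SiteRecord, ...]
    compositions: tuple[CompositionRecord, ...]
    truth: dict

    def __post_init__(self) -> None:
        ids = {s.site_id for s in self.sites}
        for rec in self.compositions:
            if rec.site_id not in ids:
                raise ValueError(
                    f"composition row references unknown site {rec.site_id!r}"
                )


def _distinct_codes(rng, pool, k):
    return [str(c) for c in rng.choice(pool, size=k, replace=False)]


def _mixtures(rng, xy, n_codes, n_archetypes, range_km, extent_km):
    """Per-site probability mixtures interpolated from regional archetypes.

    Archetype profiles share a heavy-tailed regional base (a few classes
    are common everywhere, as in real habitat/land-cover inventories),
    each perturbed multiplicatively; a site's mixture blends the archetype
    profiles with exponentially distance-decaying weights, so nearby sites
    have similar, realistically overlapping composition.
    """
    arch_xy = rng.uniform(0, extent_km, size=(n_archetypes, 2))
    base = (1.0 + np.arange(n_codes)) ** -2.0
    rng.shuffle(base)
    profiles = base * rng.lognormal(0.0, 1.0, size=(n_archetypes, n_codes))
    profiles /= profiles.sum(axis=1, keepdims=True)
    d = np.linalg.norm(xy[:, None, :] - arch_xy[None, :, :], axis=2)
    w = np.exp(-d / range_km)
    w /= w.sum(axis=1, keepdims=True)
    mixtures = w @ profiles
    mixtures /= mixtures.sum(axis=1, keepdims=True)
    return mixtures, arch_xy, profiles


#: Dirichlet concentration of per-site composition around the local
#: mixture: sites are idiosyncratic realizations of their neighbourhood's
#: expected composition, so which class dominates varies from site to site.
SITE_HETEROGENEITY = 4.0


def _compose(rng, site_id, dataset, codes, mixture, patches_mean):
    """Sample patch counts and areas for one site node from its mixture."""
    site_mix = rng.dirichlet(SITE_HETEROGENEITY * mixture + 1e-9)
    n_patches = 1 + rng.poisson(max(patches_mean - 1.0, 0.0))
    drawn = rng.choice(len(codes), size=n_patches, p=site_mix)
    counts = np.bincount(drawn, minlength=len(codes))
    total_area = rng.lognormal(mean=np.log(2000.0), sigma=0.7)
    shares = rng.dirichlet(np.ones(n_patches))
    area = np.zeros(len(codes))
    np.add.at(area, drawn, shares * total_area)
    return [
        CompositionRecord(
            site_id=site_id,
            dataset=dataset,
            code=codes[k],
            count=int(counts[k]),
            area_ha=float(area[k]),
        )
        for k in np.flatnonzero(counts)
    ]


def generate_landscape(config: LandscapeConfig) -> LandscapeBundle:
    """Generate a full synthetic landscape bundle from a seeded config."""
    rng = np.random.default_rng(config.seed)
    n = config.n_sites
    extent = config.region_extent_km

    base_xy = rng.uniform(0, extent, size=(n, 2))
    n_dual = int(round(config.dual_designation_fraction * n))
    dual = set(rng.choice(n, size=n_dual, replace=False).tolist())

    habitat_codes = _distinct_codes(rng, np.arange(1000, 10000), config.n_habitat_codes)
    species_codes = _distinct_codes(rng, np.arange(1000, 10000), config.n_species)
    clc_pool = [f"{a}{b}{c}" for a in range(1, 6) for b in range(1, 5)
                for c in range(1, 5)]
    landuse_codes = _distinct_codes(rng, np.array(clc_pool), config.n_landuse_codes)

    hab_mix, hab_arch_xy, hab_profiles = _mixtures(
        rng, base_xy, config.n_habitat_codes, config.n_archetypes,
        config.spatial_range_km, extent,
    )
    lu_mix, _, _ = _mixtures(
        rng, base_xy, config.n_landuse_codes, config.n_archetypes,
        config.spatial_range_km, extent,
    )

    # Each species prefers a small set of specific habitat codes;
    # occupancy probability rises with the fraction of those codes
    # actually reported at a site.  Preferred codes are drawn from a
    # tempered archetype profile (∝ sqrt of abundance): species prefer
    # *characteristic* habitats of their home archetype rather than the
    # ubiquitous regional background, which would carry no spatial
    # information.  The species-level intercept noise gives the
    # heavy-tailed prevalence mix (a few widespread species, many rare
    # ones) typical of regional inventories.
    species_arch = rng.integers(0, config.n_archetypes, size=config.n_species)
    n_pref = 2
    tempered = np.sqrt(hab_profiles)
    tempered /= tempered.sum(axis=1, keepdims=True)
    pref_codes = np.array(
        [
            rng.choice(config.n_habitat_codes, size=n_pref, replace=False,
                       p=tempered[species_arch[s]])
            for s in range(config.n_species)
        ]
    )
    species_effect = rng.normal(0.0, 2.0, size=config.n_species)

    # pass 1 — site records and habitat/land-use composition per node
    sites: list[SiteRecord] = []
    node_base: list[int] = []  # base-site index behind each node
    habitat_by_node: list[list[CompositionRecord]] = []
    landuse_by_node: list[list[CompositionRecord]] = []

    for i in range(n):
        if i in dual:
            ids = (f"S{i:03d}A", f"S{i:03d}B")
            desigs = (frozenset({"SPA"}), frozenset({"SCI"}))
            partners = ((ids[1],), (ids[0],))
        else:
            ids = (f"S{i:03d}",)
            desigs = (
                frozenset({"SPA"}) if rng.random() < 0.5 else frozenset({"SCI"}),
            )
            partners = ((),)
        for sid, dg, pt in zip(ids, desigs, partners):
            sites.append(
                SiteRecord(
                    site_id=sid,
                    designations=dg,
                    x_km=float(base_xy[i, 0]),
                    y_km=float(base_xy[i, 1]),
                    zero_distance_partners=pt,
                )
            )
            node_base.append(i)
            habitat_by_node.append(
                _compose(rng, sid, "habitat", habitat_codes, hab_mix[i],
                         config.patches_per_site_mean)
            )
            landuse_by_node.append(
                _compose(rng, sid, "landuse", landuse_codes, lu_mix[i],
                         config.patches_per_site_mean)
            )

    # pass 2 — occupancy from the realized habitat sets; the habitat-match
    # fraction is centered per species so coupling moves species between
    # sites without shifting their prevalence
    code_index = {c: k for k, c in enumerate(habitat_codes)}
    present = np.zeros((len(sites), config.n_habitat_codes))
    for node, rows in enumerate(habitat_by_node):
        for row in rows:
            present[node, code_index[row.code]] = 1.0
    f = present[:, pref_codes].mean(axis=2)  # nodes × species
    logit = (
        config.prevalence_intercept
        + species_effect[None, :]
        + config.habitat_species_coupling * (f - f.mean(axis=0, keepdims=True))
    )
    occupancy_p = 1.0 / (1.0 + np.exp(-logit))

    compositions: list[CompositionRecord] = []
    for node, site in enumerate(sites):
        compositions.extend(habitat_by_node[node])
        compositions.extend(landuse_by_node[node])
        occupied = rng.random(config.n_species) < occupancy_p[node]
        compositions.extend(
            CompositionRecord(site_id=site.site_id, dataset="species",
                              code=species_codes[j], count=1, area_ha=0.0)
            for j in np.flatnonzero(occupied)
        )

    truth = {
        "config": dataclasses.asdict(config),
        "species_codes": species_codes,
        "species_preferred_codes": [
            [habitat_codes[k] for k in row] for row in pref_codes
        ],
        "species_effect": species_effect.tolist(),
        "habitat_archetype_xy": hab_arch_xy.tolist(),
        "node_base_site": node_base,
    }
    return LandscapeBundle(
        sites=tuple(sites), compositions=tuple(compositions), truth=truth
    )


def inject_missing_data(
    bundle: LandscapeBundle, fraction: float, seed: int
) -> LandscapeBundle:
    """Flag a random fraction of site nodes as missing land-use data.

    Their land-use composition rows are removed and the sites are marked
    ``missing_landuse``, so the pipeline's site filter excludes them.
    ``fraction = 0`` returns the bundle unchanged.
    """
    if not 0.0 <= fraction <= 1.0:
        raise ValueError(f"fraction must be in [0, 1], got {fraction}")
    if fraction == 0.0:
        return bundle
    rng = np.random.default_rng(seed)
    ids = [s.site_id for s in bundle.sites]
    n_flag = int(round(fraction * len(ids)))
    flagged = set(rng.choice(ids, size=n_flag, replace=False).tolist())
    sites = tuple(
        dataclasses.replace(s, missing_landuse=True) if s.site_id in flagged else s
        for s in bundle.sites
    )
    compositions = tuple(
        rec for rec in bundle.compositions
        if not (rec.dataset == "landuse" and rec.site_id in flagged)
    )
    truth = dict(bundle.truth)
    truth["missing_landuse_sites"] = sorted(flagged)
    return LandscapeBundle(sites=sites, compositions=compositions, truth=truth)


def write_landscape(bundle: LandscapeBundle, out_dir) -> dict:
    """Write sites.csv, compositions.csv and truth.json; return the paths."""
    from pathlib import Path

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths = {
        "sites": out / "sites.csv",
        "compositions": out / "compositions.csv",
        "truth": out / "truth.json",
    }
    write_site_table(bundle.sites, paths["sites"])
    write_composition_table(bundle.compositions, paths["compositions"])
    with open(paths["truth"], "w", encoding="utf-8") as handle:
        json.dump(bundle.truth, handle, indent=2, sort_keys=True)
    return {k: str(v) for k, v in paths.items()}
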