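"""Per-site attribute vectors over species, habitat and land-use codes.

Each protected site is represented as a vector over a code universe — the
sorted union of codes observed across the included sites for one dataset.
Three vector modes are supported:

* ``binary`` — 1 iff the code was reported for the site;
* ``count``  — number of patches (occurrences) of the code in the site;
* ``area``   — total surface area (ha) covered by the code in the site.

Species data carries presence only, so species vectors are binary by
construction and the other modes are rejected.  Land-use codes follow the
hierarchical CORINE Land Cover scheme and are truncated to their level-3
(three-digit) class before aggregation, since deeper levels are not
consistently available in the kind of regional dataset this pipeline
consumes.

Sites with no rows for a dataset get an all-zero row and are retained, so
every graph built downstream shares one node set.
"""

from __future__ import annotations

import re
from dataclasses import dataclass

import numpy as np

__all__ = ["SiteVectorSet", "clc_level3", "build_vector_set"]

DATASETS = ("species", "habitat", "landuse")
MODES = ("binary", "count", "area")

_DIGITS = re.compile(r"\d")


@dataclass(frozen=True)
class SiteVectorSet:
    """Site-by-code attribute matrix for one dataset and mode."""

    dataset: str
    mode: str
    site_ids: tuple[str, ...]
    codes: tuple[str, ...]
    matrix: np.ndarray  # len(site_ids) × len(codes), non-negative

    def __post_init__(self) -> None:
        if self.matrix.shape != (len(self.site_ids), len(self.codes)):
            raise ValueError("matrix shape does not match site/code lists")

    def row(self, site_id: str) -> np.ndarray:
        return self.matrix[self.site_ids.index(site_id)]

    def to_frame(self):
        """Wide site × code :class:`pandas.DataFrame` (for CSV export)."""
        import pandas as pd

        return pd.DataFrame(
            self.matrix, index=list(self.site_ids), columns=list(self.codes)
        )


def clc_level3(code: str) -> str:
    """Truncate a CORINE land-cover code to its level-3 class.

    Accepts dotted ("3.1.1") or plain ("311", "3111") spellings and returns
    the first three digits with separators removed.  Codes with fewer than
    three digits carry insufficient depth and are rejected.
    """
    digits = "".join(_DIGITS.findall(code))
    if len(digits) < 3:
        raise ValueError(f"land-use code {code!r} has fewer than 3 digits")
    return digits[:3]


def build_vector_set(compositions, sites, dataset: str, mode: str) -> SiteVectorSet:
    """Build the site × code matrix for one dataset in one mode.

    Parameters
    ----------
    compositions
        Iterable of composition records (``site_id``, ``dataset``, ``code``,
        ``count``, ``area_ha``); rows for other datasets are ignored.
    sites
        The included site records (or bare site ids); fixes row order.
        Sites without rows get an all-zero vector.
    dataset
        ``"species"``, ``"habitat"`` or ``"landuse"``.  Land-use codes are
        truncated to CLC level 3 and their counts/areas aggregated over the
        truncation.
    mode
        ``"binary"``, ``"count"`` or ``"area"``.  Species data permits only
        ``"binary"``.
    """
    if dataset not in DATASETS:
        raise ValueError(f"unknown dataset {dataset!r}; expected one of {DATASETS}")
    if mode not in MODES:
        raise ValueError(f"unknown mode {mode!r}; expected one of {MODES}")
    if dataset == "species" and mode != "binary":
        raise ValueError("species vectors are presence-only: only binary mode is valid")

    site_ids = tuple(getattr(s, "site_id", s) for s in sites)
    known = set(site_ids)
    if len(known) != len(site_ids):
        raise ValueError("duplicate site ids in site list")

    # (site, level-adjusted code) → aggregated (count, area)
    agg: dict[tuple[str, str], list[float]] = {}
    for rec in compositions:
        if rec.dataset != dataset or rec.site_id not in known:
            continue
        code = clc_level3(rec.code) if dataset == "landuse" else rec.code
        cell = agg.setdefault((rec.site_id, code), [0.0, 0.0])
        cell[0] += rec.count
        cell[1] += rec.area_ha

    codes = tuple(sorted({code for (_, code) in agg}))
    col = {c: j for j, c in enumerate(codes)}
    rowi = {s: i for i, s in enumerate(site_ids)}
    matrix = np.zeros((len(site_ids), len(codes)))
    for (site, code), (count, area) in agg.items():
        if mode == "binary":
            value = 1.0
        elif mode == "count":
            value = count
        else:
            value = area
        matrix[rowi[site], col[code]] = value

    if mode == "area":
        with_rows = {site for (site, _) in agg}
        present = np.array([s in with_rows for s in site_ids])
        zero_rows = present & ~matrix.any(axis=1)
        if zero_rows.any():
            bad = [s for s, z in zip(site_ids, zero_rows) if z]
            raise ValueError(
                f"area mode requested but sites {bad} have rows with zero total area"
            )

    return SiteVectorSet(
        dataset=dataset, mode=mode, site_ids=site_ids, codes=codes, matrix=matrix
    )
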