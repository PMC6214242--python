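"""Jaccard and cosine similarity of site attribute vectors.

Similarity scores between protected sites are the building block of the
similarity-based graph model: a pair of sites may only be linked when their
attribute vectors (species presence, habitat composition, land-use
composition) score at or above a minimum similarity.  Both measures used
here are bounded in [0, 1] for the non-negative vectors this pipeline
produces, which makes a single threshold meaningful across datasets.

Conventions for degenerate input:

* Jaccard of two all-zero binary vectors is defined as 0 (a site with no
  reported attributes is never similarity-linked); a warning is logged.
* Cosine similarity of a zero-magnitude vector is *undefined* (the measure
  requires non-zero magnitude).  The scalar :func:`cosine` raises; the
  pairwise wrapper records the pair as undefined so that downstream edge
  construction can skip it rather than impute a score.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

__all__ = ["SimilarityMatrix", "jaccard", "cosine", "pairwise_similarity"]

logger = logging.getLogger(__name__)

JACCARD = "jaccard"
COSINE = "cosine"
MEASURES = (JACCARD, COSINE)


@dataclass(frozen=True)
class SimilarityMatrix:
    """Symmetric site-by-site similarity scores for one vector set.

    Attributes
    ----------
    site_ids
        Site identifiers, fixing row/column order.
    values
        Square float array; entry (i, j) is the similarity of sites i and j.
        Entries whose similarity is undefined hold NaN.
    defined
        Boolean mask, True where the similarity is defined.
    measure
        ``"jaccard"`` or ``"cosine"``.
    dataset, mode
        Provenance of the vector set the scores were computed from.
    """

    site_ids: tuple[str, ...]
    values: np.ndarray
    defined: np.ndarray
    measure: str
    dataset: str = ""
    mode: str = ""

    def __post_init__(self) -> None:
        n = len(self.site_ids)
        if self.values.shape != (n, n) or self.defined.shape != (n, n):
            raise ValueError("similarity matrix shape does not match site list")

    def get(self, a: str, b: str) -> float:
        """Similarity of a named site pair (NaN when undefined)."""
        i = self.site_ids.index(a)
        j = self.site_ids.index(b)
        return float(self.values[i, j])

    def to_frame(self):
        """Square :class:`pandas.DataFrame` view (for CSV export)."""
        import pandas as pd

        ids = list(self.site_ids)
        return pd.DataFrame(self.values, index=ids, columns=ids)


def _check_binary(v: np.ndarray, name: str) -> None:
    if not np.isin(v, (0, 1)).all():
        raise ValueError(f"{name} is not a binary vector")


def jaccard(u, v) -> float:
    """Jaccard coefficient of two equal-length binary vectors.

    With f11 the number of attributes set in both vectors, f10 set only in
    the first and f01 only in the second::

        J = f11 / (f01 + f10 + f11)

    Two all-zero vectors (all three counts 0) score 0 with a logged warning.
    """
    u = np.asarray(u)
    v = np.asarray(v)
    if u.shape != v.shape:
        raise ValueError(f"length mismatch: {u.shape} vs {v.shape}")
    _check_binary(u, "first argument")
    _check_binary(v, "second argument")
    f11 = int(np.sum((u == 1) & (v == 1)))
    f10 = int(np.sum((u == 1) & (v == 0)))
    f01 = int(np.sum((u == 0) & (v == 1)))
    denom = f11 + f10 + f01
    if denom == 0:
        logger.warning("Jaccard of two empty vectors: defined as 0")
        return 0.0
    return f11 / denom


def cosine(x, y) -> float:
    """Cosine of the angle between two non-negative vectors.

    Returns x·y / (‖x‖ ‖y‖), in [0, 1] for non-negative inputs.  Raises
    :class:`ValueError` for a zero-magnitude vector, for which the measure
    is undefined.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape:
        raise ValueError(f"length mismatch: {x.shape} vs {y.shape}")
    nx = float(np.linalg.norm(x))
    ny = float(np.linalg.norm(y))
    if nx == 0.0 or ny == 0.0:
        raise ValueError("cosine similarity undefined for zero-magnitude vector")
    return float(np.dot(x, y) / (nx * ny))


def pairwise_similarity(vector_set, measure: str) -> SimilarityMatrix:
    """Full symmetric similarity matrix over a :class:`~sitegraphs.vectors.SiteVectorSet`.

    ``measure="jaccard"`` requires binary mode; ``"cosine"`` accepts any
    mode.  Pairs involving a vector for which the measure is undefined
    (zero vector under cosine) are NaN with ``defined=False`` and are
    treated as below any threshold downstream.  The diagonal is 1 for sites
    with a non-zero vector.
    """
    if measure not in MEASURES:
        raise ValueError(f"unknown measure {measure!r}; expected one of {MEASURES}")
    if measure == JACCARD and vector_set.mode != "binary":
        raise ValueError("jaccard requires a binary vector set")

    m = np.asarray(vector_set.matrix, dtype=float)
    n = m.shape[0]
    defined = np.ones((n, n), dtype=bool)

    if measure == JACCARD:
        # |u ∩ v| and |u ∪ v| via boolean matrix products
        b = m > 0
        inter = b.astype(float) @ b.astype(float).T
        sizes = b.sum(axis=1, dtype=float)
        union = sizes[:, None] + sizes[None, :] - inter
        with np.errstate(invalid="ignore", divide="ignore"):
            values = np.where(union > 0, inter / np.where(union > 0, union, 1.0), 0.0)
        n_empty = int((sizes == 0).sum())
        if n_empty:
            logger.warning(
                "Jaccard: %d site(s) with empty vectors scored 0 against all pairs",
                n_empty,
            )
        # empty-vs-empty pairs (union 0) already 0 by construction
    else:
        norms = np.linalg.norm(m, axis=1)
        zero = norms == 0
        safe = np.where(zero, 1.0, norms)
        unit = m / safe[:, None]
        values = unit @ unit.T
        np.clip(values, 0.0, 1.0, out=values)
        if zero.any():
            logger.warning(
                "cosine: %d site(s) with zero-magnitude vectors marked undefined",
                int(zero.sum()),
            )
            defined[zero, :] = False
            defined[:, zero] = False
            values = np.where(defined, values, np.nan)

    values = (values + values.T) / 2.0  # enforce exact symmetry
    nonzero = np.asarray(m).any(axis=1)
    values[np.diag_indices(n)] = np.where(nonzero, 1.0, values.diagonal())
    return SimilarityMatrix(
        site_ids=tuple(vector_set.site_ids),
        values=values,
        defined=defined,
        measure=measure,
        dataset=vector_set.dataset,
        mode=vector_set.mode,
    )
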