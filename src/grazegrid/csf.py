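"""Cross-scale feature (CSF) extraction.

County-level training samples average away the within-county heterogeneity
that pixel-level prediction needs. CSF extraction recovers an intermediate
"group" level: within each county the dasymetrically distributed density is
graded by agglomerative (Ward) hierarchical clustering, the group count k
is chosen by minimizing the Davies-Bouldin index (DBI),

    DBI_k = (1/k) * sum_x max_{y != x} (abar_x + abar_y) / |delta_x - delta_y|

where abar_x is the mean within-group distance to the group centroid
delta_x, and one training row per group carries the group means of the
response and of every covariate.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.cluster import AgglomerativeClustering

from grazegrid.disturbance import DistributedDensity
from grazegrid.raster import RasterField

__all__ = ["ClusterSelection", "davies_bouldin", "select_group_count", "extract_csf"]

logger = logging.getLogger(__name__)

DEFAULT_K_RANGE = tuple(range(2, 7))


@dataclass
class ClusterSelection:
    """DBI curve over candidate group counts and the selected k."""

    k_candidates: list[int]
    dbi_values: list[float]
    k_selected: int
    labels: np.ndarray = field(default_factory=lambda: np.empty(0, dtype=int))


def davies_bouldin(values: np.ndarray, labels: np.ndarray) -> float:
    """Davies-Bouldin index of a 1-D grouping.

    Distances are absolute differences; group centroids are means. Returns
    ``inf`` when two group centroids coincide (the pairwise term divides by
    zero), which candidate selection treats as a rejected k.
    """
    values = np.asarray(values, dtype=float).ravel()
    labels = np.asarray(labels)
    groups = np.unique(labels)
    k = len(groups)
    if k < 2:
        raise ValueError("davies_bouldin requires at least 2 groups")
    centroids = np.array([values[labels == g].mean() for g in groups])
    spreads = np.array([np.abs(values[labels == g] - c).mean()
                        for g, c in zip(groups, centroids)])
    total = 0.0
    for x in range(k):
        worst = 0.0
        for y in range(k):
            if y == x:
                continue
            sep = abs(centroids[x] - centroids[y])
            if sep == 0.0:
                return float("inf")
            worst = max(worst, (spreads[x] + spreads[y]) / sep)
        total += worst
    return total / k


def select_group_count(
    values: np.ndarray,
    k_range: tuple[int, ...] = DEFAULT_K_RANGE,
    seed: int | None = None,
) -> ClusterSelection:
    """Choose the group count by Ward clustering + DBI minimization.

    Each candidate k in ``k_range`` (capped at the sample size) is fitted
    with agglomerative Ward clustering on the 1-D values; the k with the
    smallest DBI wins, ties going to the smaller k. Hierarchical clustering
    is deterministic, so ``seed`` is accepted only for interface symmetry.

    Samples with fewer than 2 points, or with all values identical, take
    the degenerate single-group path (k_selected = 1, empty DBI curve).
    """
    values = np.asarray(values, dtype=float).ravel()
    n = len(values)
    if n < 2 or np.all(values == values[0]):
        return ClusterSelection([], [], 1, np.zeros(n, dtype=int))

    candidates = sorted({k for k in k_range if 2 <= k <= n})
    if not candidates:
        return ClusterSelection([], [], 1, np.zeros(n, dtype=int))

    X = values.reshape(-1, 1)
    best_k, best_dbi, best_labels = 1, np.inf, np.zeros(n, dtype=int)
    dbis = []
    for k in candidates:
        labels = AgglomerativeClustering(n_clusters=k, linkage="ward").fit_predict(X)
        dbi = davies_bouldin(values, labels)
        dbis.append(dbi)
        if dbi < best_dbi:  # strict: ties keep the smaller k
            best_k, best_dbi, best_labels = k, dbi, labels
    if not np.isfinite(best_dbi):
        return ClusterSelection(candidates, dbis, 1, np.zeros(n, dtype=int))
    return ClusterSelection(candidates, dbis, best_k, best_labels)


def extract_csf(
    dist: DistributedDensity,
    covariates: dict[str, RasterField | np.ndarray],
    zones: RasterField | None = None,
    k_range: tuple[int, ...] = DEFAULT_K_RANGE,
    grassland_type: RasterField | np.ndarray | None = None,
) -> pd.DataFrame:
    """Build the group-level training table from a distributed density.

    Per county: cluster the county's pixel SU values, then emit one row per
    group with the group-mean SU (``response``), the group mean of every
    covariate, the modal grassland type, and the pixel count. Counties with
    fewer pixels than ``min(k_range)`` (or no within-county structure)
    yield a single row — the traditional county mean. Groups partition each
    county's masked pixels exactly.

    Returns a DataFrame with columns
    ``county_id, group_id, n_pixels, response, grassland_type, <covariates...>``.
    """
    zone_arr = (zones or dist.county_zones).values
    su = dist.su.values
    cov_arrays = {
        name: (f.values if isinstance(f, RasterField) else np.asarray(f))
        for name, f in covariates.items()
    }
    for name, arr in cov_arrays.items():
        if arr.shape != su.shape:
            raise ValueError(f"covariate {name!r} not on the shared lattice")
    gtype = None
    if grassland_type is not None:
        gtype = grassland_type.values if isinstance(grassland_type, RasterField) else np.asarray(grassland_type)

    valid = np.isfinite(su)
    rows = []
    for county in np.unique(zone_arr[valid]):
        sel = valid & (zone_arr == county)
        vals = su[sel]
        if len(vals) == 0:
            logger.info("county %s empty after masking, skipped", county)
            continue
        selection = select_group_count(vals, k_range)
        labels = selection.labels if selection.k_selected > 1 else np.zeros(len(vals), dtype=int)
        for g in np.unique(labels):
            in_g = labels == g
            row = {
                "county_id": int(county),
                "group_id": int(g),
                "n_pixels": int(in_g.sum()),
                "response": float(vals[in_g].mean()),
            }
            if gtype is not None:
                types = gtype[sel][in_g]
                uniq, counts = np.unique(types, return_counts=True)
                row["grassland_type"] = uniq[np.argmax(counts)]
            for name, arr in cov_arrays.items():
                row[name] = float(np.nanmean(arr[sel][in_g]))
            rows.append(row)

    lead = ["county_id", "group_id", "n_pixels", "response"]
    if gtype is not None:
        lead.append("grassland_type")
    df = pd.DataFrame(rows)
    return df[lead + [c for c in df.columns if c not in lead]]
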