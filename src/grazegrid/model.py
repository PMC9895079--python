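"""Partitioned random-forest spatializer (variants M1-M4).

The four model variants ladder two independent improvements over the
traditional census-downscaling regression:

* **M1** — one random forest trained on county-mean features;
* **M2** — two forests partitioned at a carrying-capacity density threshold
  per grassland type, county-mean features;
* **M3** — one forest trained on group-level cross-scale features (CSF);
* **M4** — partition + CSF (the full method).

The response is natural-log transformed (``log1p`` to admit zero-density
rows), samples are split 3:1 into training and testing sets, and the fitted
grid is finished by county residual correction so administrative means are
honored exactly.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.ensemble import RandomForestRegressor
from sklearn.model_selection import train_test_split

from grazegrid.census import CensusTable
from grazegrid.metrics import spatial_metrics
from grazegrid.raster import RasterField
from grazegrid.suitability import SuitabilityMask

__all__ = [
    "GRASSLAND_TYPES",
    "DEFAULT_TYPE_THRESHOLDS",
    "PartitionSpec",
    "Spatializer",
    "GriddedGrazing",
    "theoretical_capacity_threshold",
    "partition_samples",
    "fit",
    "predict",
    "residual_correct",
]

logger = logging.getLogger(__name__)

GRASSLAND_TYPES = ("alpine_meadow", "alpine_steppe", "alpine_desert_steppe")

#: Carrying-capacity density thresholds (SU/hm^2) per grassland type.
DEFAULT_TYPE_THRESHOLDS = {
    "alpine_meadow": 0.43,
    "alpine_steppe": 0.35,
    "alpine_desert_steppe": 0.21,
}

_NON_FEATURE_COLUMNS = {"county_id", "group_id", "n_pixels", "response", "grassland_type", "year"}


@dataclass
class PartitionSpec:
    """Density thresholds routing samples/pixels to the low or high submodel.

    ``thresholds_by_type`` is keyed by grassland-type label in SU/hm^2;
    ``pixel_area`` (hm^2/pixel) converts the per-pixel SU response to a
    density before comparison. Rows exactly at the threshold go low.
    """

    thresholds_by_type: dict = field(default_factory=lambda: dict(DEFAULT_TYPE_THRESHOLDS))
    pixel_area: float = 1.0

    def __post_init__(self) -> None:
        if any(t <= 0 for t in self.thresholds_by_type.values()):
            raise ValueError("partition thresholds must be positive")
        if self.pixel_area <= 0:
            raise ValueError("pixel_area must be positive")

    def threshold_for(self, gtype) -> float:
        try:
            return float(self.thresholds_by_type[gtype])
        except KeyError:
            raise ValueError(f"unknown grassland type {gtype!r}; no threshold configured") from None


@dataclass
class Spatializer:
    """A fitted spatialization model with its partition and transform metadata."""

    variant: str
    submodels: dict  # keys: "pooled" and, for M2/M4, "low"/"high"
    feature_names: list
    partition: PartitionSpec | None
    log_offset: float
    split_seed: int
    model_seed: int
    importances: dict = field(default_factory=dict)  # per submodel, per feature
    test_metrics: dict = field(default_factory=dict)  # per submodel: (r2, rmse, mae)
    fallback_single_model: bool = False

    @property
    def is_partitioned(self) -> bool:
        return self.variant in ("M2", "M4") and not self.fallback_single_model


@dataclass
class GriddedGrazing:
    """Model output grid, raw and (after residual correction) corrected."""

    su_raw: RasterField
    su_corrected: RasterField | None = None
    year: int | None = None
    uncorrected_counties: list = field(default_factory=list)


def theoretical_capacity_threshold(
    forage_yield: float, utilization: float, intake: float, grazing_days: float
) -> float:
    """Carrying-capacity density (SU/hm^2) from forage supply and demand.

    threshold = forage_yield * utilization / (intake * grazing_days), with
    forage_yield in kg/hm^2, utilization a fraction of yield actually
    available, intake in kg per sheep unit per day. Used to derive partition
    thresholds when the standard printed values do not apply.
    """
    if forage_yield <= 0 or intake <= 0 or grazing_days <= 0:
        raise ValueError("forage_yield, intake and grazing_days must be positive")
    if not 0 < utilization <= 1:
        raise ValueError("utilization must be in (0, 1]")
    return forage_yield * utilization / (intake * grazing_days)


def partition_samples(table: pd.DataFrame, spec: PartitionSpec) -> dict[str, pd.DataFrame]:
    """Split a feature table into low/high subsets at the type threshold.

    A row goes high iff its response density (response / pixel_area,
    SU/hm^2) strictly exceeds the threshold of its grassland type. All
    columns are retained in both subsets.
    """
    if "grassland_type" not in table.columns:
        raise ValueError("partition_samples requires a grassland_type column")
    density = table["response"].to_numpy(dtype=float) / spec.pixel_area
    thresholds = np.array([spec.threshold_for(g) for g in table["grassland_type"]])
    high = density > thresholds
    return {"low": table[~high].copy(), "high": table[high].copy()}


def _fit_submodel(table: pd.DataFrame, feature_names: list, log_offset: float,
                  split_seed: int, model_seed: int, n_estimators: int,
                  min_rows: int, name: str):
    if len(table) < min_rows:
        raise ValueError(f"partition {name!r} has {len(table)} rows; need >= {min_rows}")
    X = table[feature_names].to_numpy(dtype=float)
    y = np.log(table["response"].to_numpy(dtype=float) + log_offset)
    X_tr, X_te, y_tr, y_te = train_test_split(X, y, test_size=0.25, random_state=split_seed)
    rf = RandomForestRegressor(n_estimators=n_estimators, random_state=model_seed, n_jobs=1)
    rf.fit(X_tr, y_tr)
    pred = np.clip(np.exp(rf.predict(X_te)) - log_offset, 0.0, None)
    obs = np.exp(y_te) - log_offset
    metrics = spatial_metrics(pred, obs) if len(obs) >= 2 else (np.nan, np.nan, np.nan)
    return rf, metrics


def fit(
    table: pd.DataFrame,
    variant: str = "M4",
    partition: PartitionSpec | None = None,
    split_seed: int = 0,
    model_seed: int = 0,
    n_estimators: int = 500,
    log_offset: float = 1.0,
    min_rows: int = 8,
) -> Spatializer:
    """Train a spatializer on a county- (M1/M2) or group-level (M3/M4) table.

    The response is mapped through ``ln(y + log_offset)``; each submodel is
    fitted on a random 3:1 train/test split governed by ``split_seed`` and
    its held-out R^2/RMSE/MAE (back-transformed scale) recorded. For the
    partitioned variants a partition with fewer than ``min_rows`` rows
    triggers a single-model fallback with a warning rather than an error.
    """
    if variant not in ("M1", "M2", "M3", "M4"):
        raise ValueError(f"unknown variant {variant!r}")
    feature_names = [c for c in table.columns if c not in _NON_FEATURE_COLUMNS]
    if not feature_names:
        raise ValueError("feature table has no covariate columns")
    if len(table) < min_rows:
        raise ValueError(f"feature table has {len(table)} rows; need >= {min_rows}")

    submodels: dict = {}
    test_metrics: dict = {}
    importances: dict = {}
    fallback = False

    pooled, pooled_metrics = _fit_submodel(
        table, feature_names, log_offset, split_seed, model_seed, n_estimators, min_rows, "pooled")
    submodels["pooled"] = pooled
    test_metrics["pooled"] = pooled_metrics
    importances["pooled"] = dict(zip(feature_names, pooled.feature_importances_))

    if variant in ("M2", "M4"):
        if partition is None:
            partition = PartitionSpec()
        parts = partition_samples(table, partition)
        if any(len(sub) < min_rows for sub in parts.values()):
            sizes = {k: len(v) for k, v in parts.items()}
            logger.warning(
                "variant %s: partition too small for separate models (%s); "
                "falling back to the pooled single model", variant, sizes)
            fallback = True
        else:
            for name, sub in parts.items():
                rf, m = _fit_submodel(sub, feature_names, log_offset, split_seed,
                                      model_seed, n_estimators, min_rows, name)
                submodels[name] = rf
                test_metrics[name] = m
                importances[name] = dict(zip(feature_names, rf.feature_importances_))

    return Spatializer(
        variant=variant,
        submodels=submodels,
        feature_names=feature_names,
        partition=partition if variant in ("M2", "M4") else None,
        log_offset=log_offset,
        split_seed=split_seed,
        model_seed=model_seed,
        importances=importances,
        test_metrics=test_metrics,
        fallback_single_model=fallback,
    )


def predict(
    model: Spatializer,
    covariates: dict[str, RasterField | np.ndarray],
    grassland_type: RasterField | np.ndarray | None = None,
    mask: SuitabilityMask | RasterField | np.ndarray | None = None,
    year: int | None = None,
) -> GriddedGrazing:
    """Predict the raw SU grid from pixel-level covariates.

    For partitioned variants, pixels are routed by a provisional estimate
    from the pooled model: its density (via the partition's pixel area)
    compared against the pixel's grassland-type threshold decides whether
    the low or the high submodel produces the final value. Predictions are
    back-transformed from log scale and clipped at zero; pixels outside the
    mask are nodata.
    """
    arrays = {}
    for name in model.feature_names:
        if name not in covariates:
            missing = [n for n in model.feature_names if n not in covariates]
            raise ValueError(f"covariate stack missing features: {missing}")
        f = covariates[name]
        arrays[name] = f.values if isinstance(f, RasterField) else np.asarray(f)
    shape = next(iter(arrays.values())).shape

    if mask is None:
        mask_arr = np.ones(shape, dtype=bool)
    else:
        mask_arr = mask.values if isinstance(mask, (SuitabilityMask, RasterField)) else np.asarray(mask)
        mask_arr = np.asarray(mask_arr, dtype=bool)
    valid = mask_arr.copy()
    for arr in arrays.values():
        if np.issubdtype(arr.dtype, np.floating):
            valid &= np.isfinite(arr)

    out = np.full(shape, np.nan)
    if not valid.any():
        return GriddedGrazing(RasterField(out, "su_raw"), year=year)

    X = np.column_stack([arrays[name][valid] for name in model.feature_names])

    def back(raw_log: np.ndarray) -> np.ndarray:
        return np.clip(np.exp(raw_log) - model.log_offset, 0.0, None)

    if not model.is_partitioned:
        pred = back(model.submodels["pooled"].predict(X))
    else:
        if grassland_type is None:
            raise ValueError("partitioned prediction requires a grassland_type raster")
        gt = grassland_type.values if isinstance(grassland_type, RasterField) else np.asarray(grassland_type)
        gt_pix = gt[valid]
        provisional = back(model.submodels["pooled"].predict(X))
        thresholds = np.array([model.partition.threshold_for(g) for g in gt_pix])
        high = (provisional / model.partition.pixel_area) > thresholds
        pred = np.empty(len(X))
        if (~high).any():
            pred[~high] = back(model.submodels["low"].predict(X[~high]))
        if high.any():
            pred[high] = back(model.submodels["high"].predict(X[high]))

    out[valid] = pred
    return GriddedGrazing(RasterField(out, "su_raw"), year=year)


def residual_correct(
    grid: GriddedGrazing,
    census: dict[int, float] | CensusTable,
    zones: RasterField,
    tol: float = 1e-9,
    max_iter: int = 200,
) -> GriddedGrazing:
    """Add the county residual so corrected county means equal census means.

    R_j = census_j / n_j - mean(su_raw over county j); every pixel of
    county j gets +R_j. Where the shift drives pixels negative they are
    clipped at zero and the clipped mass is re-spread proportionally over
    the positive pixels, iterating until the county total matches to
    ``tol`` (relative) — keeping both nonnegativity and the census mass.
    Counties absent from the census are left uncorrected and reported.
    """
    if isinstance(census, CensusTable):
        if grid.year is None:
            raise ValueError("grid has no year; cannot look up census")
        totals = census.totals_for_year(grid.year)
    else:
        totals = {int(k): float(v) for k, v in census.items()}

    raw = grid.su_raw.values
    zone_arr = zones.values
    corrected = raw.copy()
    valid = np.isfinite(raw)
    uncorrected = []

    for county in np.unique(zone_arr[valid]):
        sel = valid & (zone_arr == county)
        if int(county) not in totals:
            uncorrected.append(int(county))
            logger.warning("county %s missing from census; left uncorrected", county)
            continue
        target = totals[int(county)]
        x = raw[sel] + (target / sel.sum() - raw[sel].mean())
        scale = max(abs(target), 1.0)
        for _ in range(max_iter):
            x = np.clip(x, 0.0, None)
            deficit = target - x.sum()
            if abs(deficit) <= tol * scale:
                break
            pos = x > 0
            if pos.any() and x[pos].sum() > 0:
                x[pos] += deficit * x[pos] / x[pos].sum()
            else:
                x += deficit / len(x)
        corrected[sel] = np.clip(x, 0.0, None)

    return GriddedGrazing(
        su_raw=grid.su_raw,
        su_corrected=RasterField(corrected, "su_corrected"),
        year=grid.year,
        uncorrected_counties=uncorrected,
    )
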