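"""M1-M4 model-ladder comparison on synthetic landscapes.

Runs the four spatialization variants on identical inputs and seeds and
scores each twice: against the county census (the only validation available
with real data) and against the synthetic pixel truth (the signal the
census cannot provide). The headline statistic is the relative improvement
of the full method over the traditional county-mean model,
(R2_M4 - R2_M1) / R2_M1.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from grazegrid.csf import extract_csf, DEFAULT_K_RANGE
from grazegrid.disturbance import ad_index, dasymetric_distribute
from grazegrid.metrics import ValidationReport, spatial_metrics, mre
from grazegrid.model import PartitionSpec, fit, predict, residual_correct
from grazegrid.raster import RasterField, zonal_sum
from grazegrid.synthetic import SyntheticTruth

__all__ = ["VariantResult", "run_ladder", "ladder_summary"]

logger = logging.getLogger(__name__)

ALL_VARIANTS = ("M1", "M2", "M3", "M4")


@dataclass
class VariantResult:
    """Scores for one model variant on one landscape-year."""

    variant: str
    county_metrics: ValidationReport | None = None
    truth_r2: float = np.nan          # corrected grid vs pixel truth
    truth_r2_raw: float = np.nan      # raw model output vs pixel truth
    runtime_note: str = ""
    error: str | None = None


def _county_table(dist, covariates, gtype_labels):
    """County-mean feature table (the traditional M1/M2 training samples)."""
    return extract_csf(dist, covariates, k_range=(), grassland_type=gtype_labels)


def run_ladder(
    truth: SyntheticTruth,
    variants: tuple[str, ...] = ALL_VARIANTS,
    year: int | None = None,
    k_range: tuple[int, ...] = DEFAULT_K_RANGE,
    split_seed: int = 0,
    model_seed: int = 0,
    n_estimators: int = 500,
) -> list[VariantResult]:
    """Fit, predict and score every requested variant on identical inputs.

    All variants share one AD field, one dasymetric distribution, one
    train/test split seed and one forest seed; they differ only in their
    training table (county vs group level) and in whether they partition.
    A failing variant yields a partial result carrying the error message
    instead of aborting the ladder.
    """
    unknown = set(variants) - set(ALL_VARIANTS)
    if unknown:
        raise ValueError(f"unknown variants: {sorted(unknown)}")
    if year is None:
        year = truth.years[0]

    zones = truth.county_zones
    mask = np.ones(zones.shape, dtype=bool)
    gtype_labels = RasterField(truth.grassland_type_labels(), "grassland_type")
    spec = PartitionSpec(pixel_area=truth.config.pixel_area)
    census_year = truth.census.totals_for_year(year)
    truth_pix = truth.truth_density[truth.years.index(year)]

    ad = ad_index(truth.ndvi, valid_mask=mask)
    dist = dasymetric_distribute(census_year, ad, zones, mask)
    tables = {
        "county": _county_table(dist, truth.covariates, gtype_labels),
        "group": extract_csf(dist, truth.covariates, k_range=k_range,
                             grassland_type=gtype_labels),
    }

    results = []
    for variant in variants:
        level = "group" if variant in ("M3", "M4") else "county"
        try:
            model = fit(tables[level], variant=variant, partition=spec,
                        split_seed=split_seed, model_seed=model_seed,
                        n_estimators=n_estimators)
            grid = predict(model, truth.covariates, gtype_labels, mask, year=year)
            grid = residual_correct(grid, census_year, zones)

            pred_totals = zonal_sum(grid.su_raw.values, zones.values)
            counties = sorted(census_year)
            pred_vec = np.array([pred_totals.get(c, 0.0) for c in counties])
            cens_vec = np.array([census_year[c] for c in counties])
            r2, rmse, mae = spatial_metrics(pred_vec, cens_vec)
            mre_val, n_excl = mre(pred_vec, cens_vec)
            county_metrics = ValidationReport(
                r2=r2, rmse=rmse, mae=mae, mre_percent=mre_val,
                n=len(counties), level="county", n_excluded_zero_census=n_excl)

            ok = np.isfinite(grid.su_corrected.values) & np.isfinite(truth_pix)
            truth_r2 = spatial_metrics(grid.su_corrected.values[ok], truth_pix[ok])[0]
            truth_r2_raw = spatial_metrics(grid.su_raw.values[ok], truth_pix[ok])[0]

            note = "single-model fallback" if model.fallback_single_model else ""
            results.append(VariantResult(variant, county_metrics, truth_r2,
                                         truth_r2_raw, runtime_note=note))
        except Exception as exc:  # noqa: BLE001 - partial report by contract
            logger.exception("variant %s failed", variant)
            results.append(VariantResult(variant, error=str(exc)))
    return results


def ladder_summary(results: list[VariantResult]) -> dict:
    """JSON-able ladder report with the M4-over-M1 improvement statistic."""
    by = {r.variant: r for r in results}
    out: dict = {"variants": {}}
    for r in results:
        entry = {"truth_r2": r.truth_r2, "truth_r2_raw": r.truth_r2_raw,
                 "runtime_note": r.runtime_note, "error": r.error}
        if r.county_metrics is not None:
            entry["county_r2"] = r.county_metrics.r2
            entry["county_rmse"] = r.county_metrics.rmse
            entry["county_mae"] = r.county_metrics.mae
            entry["county_mre_percent"] = r.county_metrics.mre_percent
        out["variants"][r.variant] = entry
    if "M1" in by and "M4" in by and by["M1"].error is None and by["M4"].error is None:
        r1, r4 = by["M1"].truth_r2, by["M4"].truth_r2
        if np.isfinite(r1) and r1 > 0:
            out["improvement_percent"] = float((r4 - r1) / r1 * 100.0)
        out["ordering_m4_gt_m1"] = bool(r4 > r1)
    return out
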