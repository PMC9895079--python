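"""Absolute-disturbance index and dasymetric distribution.

The absolute disturbance (AD) index treats each pixel's deviation between
observed and potential NDVI time series, D_i = NDVI_obs_i - NDVI_pot_i
(a length-T vector), as a point in T-dimensional feature space and scores
it by Mahalanobis distance from the population mean:

    AD_i = sqrt((D_i - u)^T cov^{-1} (D_i - u))

with u and cov the mean and T x T covariance of D over all valid pixels of
the study area. The AD field then serves as the dasymetric weight layer:
each county's census sheep-unit total is split across its suitable pixels
in proportion to AD, which conserves the county total exactly.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import linalg

from grazegrid.census import CensusTable
from grazegrid.raster import RasterField, zonal_sum
from grazegrid.suitability import SuitabilityMask

__all__ = ["NdviSeriesStack", "AdField", "DistributedDensity", "ad_index", "dasymetric_distribute"]

logger = logging.getLogger(__name__)


@dataclass
class NdviSeriesStack:
    """Observed and potential NDVI time-series stacks (T, rows, cols)."""

    observed: np.ndarray
    potential: np.ndarray

    def __post_init__(self) -> None:
        self.observed = np.asarray(self.observed, dtype=float)
        self.potential = np.asarray(self.potential, dtype=float)
        if self.observed.shape != self.potential.shape:
            raise ValueError("observed and potential NDVI stacks must share shape")
        if self.observed.ndim != 3:
            raise ValueError("NDVI stacks must be (T, rows, cols)")

    @property
    def n_steps(self) -> int:
        return self.observed.shape[0]


@dataclass
class AdField:
    """Per-pixel AD index with covariance-conditioning diagnostics."""

    ad: RasterField
    cov_condition: float = np.nan
    ridge_lambda: float = 0.0


@dataclass
class DistributedDensity:
    """Pixel SU field whose zonal sums reproduce the county census."""

    su: RasterField
    county_zones: RasterField
    undistributable: pd.DataFrame = field(
        default_factory=lambda: pd.DataFrame(columns=["county_id", "su_total", "reason"]))
    uniform_fallback_counties: list[int] = field(default_factory=list)


def ad_index(series: NdviSeriesStack, valid_mask: RasterField | np.ndarray | None = None) -> AdField:
    """Mahalanobis AD index of observed-vs-potential NDVI deviations.

    Pixels with any missing NDVI step are excluded from both the population
    statistics and the output. A numerically singular covariance is ridge-
    regularized with ``lambda = 1e-8 * trace(cov) / T`` (logged); if every
    valid pixel shares one deviation vector the covariance is identically
    zero and AD is 0 everywhere without inversion.
    """
    T = series.n_steps
    if T == 0:
        raise ValueError("NDVI stacks have zero time steps")
    diff = series.observed - series.potential  # (T, rows, cols)
    valid = np.isfinite(diff).all(axis=0)
    if valid_mask is not None:
        vm = valid_mask.values if isinstance(valid_mask, RasterField) else valid_mask
        valid &= np.asarray(vm, dtype=bool)
    n_valid = int(valid.sum())
    if n_valid < 2:
        raise ValueError("ad_index needs at least 2 valid pixels")

    D = diff[:, valid].T  # (n_valid, T)
    u = D.mean(axis=0)
    centered = D - u
    if np.allclose(centered, 0.0):
        ad = np.full(diff.shape[1:], np.nan)
        ad[valid] = 0.0
        return AdField(RasterField(ad, "ad"), cov_condition=np.inf, ridge_lambda=0.0)

    cov = np.cov(D, rowvar=False).reshape(T, T)
    ridge = 0.0
    try:
        cond = np.linalg.cond(cov)
    except np.linalg.LinAlgError:  # pragma: no cover
        cond = np.inf
    if not np.isfinite(cond) or cond > 1e12:
        ridge = 1e-8 * np.trace(cov) / T
        if ridge <= 0:
            ridge = 1e-12
        cov = cov + ridge * np.eye(T)
        logger.info("ad_index: singular covariance, ridge lambda=%g applied", ridge)
    cov_inv = linalg.inv(cov)

    maha_sq = np.einsum("ij,jk,ik->i", centered, cov_inv, centered)
    ad = np.full(diff.shape[1:], np.nan)
    ad[valid] = np.sqrt(np.maximum(maha_sq, 0.0))
    return AdField(RasterField(ad, "ad"), cov_condition=float(np.linalg.cond(cov)), ridge_lambda=ridge)


def dasymetric_distribute(
    census: dict[int, float] | CensusTable,
    ad: AdField,
    zones: RasterField,
    mask: SuitabilityMask | RasterField | np.ndarray,
    year: int | None = None,
) -> DistributedDensity:
    """Distribute county census SU totals to pixels by AD-index weight.

    SU_i = SU_j^C * AD_i / sum_{i' in county j} AD_{i'}. Counties whose AD
    sum is zero fall back to uniform weights (recorded); counties with a
    positive census but no masked pixel are listed in the undistributable
    report and excluded rather than aborting the run.

    Parameters
    ----------
    census
        Either a ``{county_id: su_total}`` mapping or a :class:`CensusTable`
        together with ``year``.
    """
    if isinstance(census, CensusTable):
        if year is None:
            raise ValueError("year is required when census is a CensusTable")
        totals = census.totals_for_year(year)
    else:
        totals = {int(k): float(v) for k, v in census.items()}

    mask_arr = mask.values if isinstance(mask, (SuitabilityMask, RasterField)) else np.asarray(mask)
    mask_arr = np.asarray(mask_arr, dtype=bool)
    ad_vals = ad.ad.values
    zone_arr = zones.values
    if not (mask_arr.shape == ad_vals.shape == zone_arr.shape):
        raise ValueError("AD field, zones and mask must share the lattice")

    usable = mask_arr & np.isfinite(ad_vals)
    su = np.full(ad_vals.shape, np.nan)
    undist_rows = []
    uniform_counties: list[int] = []

    for county, total in totals.items():
        sel = usable & (zone_arr == county)
        n = int(sel.sum())
        if n == 0:
            if total > 0:
                undist_rows.append((county, total, "no masked pixels"))
            continue
        w = ad_vals[sel]
        wsum = w.sum()
        if wsum <= 0:
            su[sel] = total / n
            uniform_counties.append(county)
            logger.info("county %s: zero AD sum, uniform fallback", county)
        else:
            su[sel] = total * w / wsum

    report = pd.DataFrame(undist_rows, columns=["county_id", "su_total", "reason"])
    return DistributedDensity(RasterField(su, "su_distributed"), zones, report, uniform_counties)
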