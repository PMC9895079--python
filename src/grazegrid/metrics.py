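"""Validation metrics for census-vs-predicted comparisons.

R^2 here is the one-minus-error-ratio form computed against the census
variance (it can be negative for a predictor worse than the census mean),
not a squared correlation from a regression refit — the two diverge for
biased predictors. NSE applies the identical functional form along the
time axis; MRE is the mean absolute county-level relative deviation in
percent, with zero-census counties excluded and counted.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = ["ValidationReport", "spatial_metrics", "nse", "mre"]


@dataclass
class ValidationReport:
    """Bundle of spatial (R^2/RMSE/MAE), temporal (NSE) and relative (MRE) scores."""

    r2: float = np.nan
    rmse: float = np.nan
    mae: float = np.nan
    nse: float = np.nan
    mre_percent: float = np.nan
    n: int = 0
    level: str = "county"
    n_excluded_zero_census: int = 0


def _pair(predicted, census) -> tuple[np.ndarray, np.ndarray]:
    p = np.asarray(predicted, dtype=float).ravel()
    c = np.asarray(census, dtype=float).ravel()
    if p.shape != c.shape:
        raise ValueError("predicted and census vectors must have equal length")
    if len(p) < 2:
        raise ValueError("need at least 2 paired values")
    return p, c


def spatial_metrics(predicted, census) -> tuple[float, float, float]:
    """(R^2, RMSE, MAE) of predicted vs census values.

    R^2 = 1 - sum (c - p)^2 / sum (c - mean(c))^2. A constant census vector
    leaves R^2 undefined (NaN); RMSE and MAE are still returned.
    """
    p, c = _pair(predicted, census)
    err = c - p
    rmse = float(np.sqrt(np.mean(err**2)))
    mae = float(np.mean(np.abs(err)))
    denom = np.sum((c - c.mean()) ** 2)
    r2 = float(1.0 - np.sum(err**2) / denom) if denom > 0 else float("nan")
    return r2, rmse, mae


def nse(predicted_yearly, census_yearly) -> float:
    """Nash-Sutcliffe efficiency of a predicted vs census time series.

    NSE = 1 - sum_t (p_t - c_t)^2 / sum_t (c_t - mean(c))^2; 1 means
    perfect temporal agreement, 0 matches the census-mean null model.
    Constant census series return NaN (undefined).
    """
    p, c = _pair(predicted_yearly, census_yearly)
    denom = np.sum((c - c.mean()) ** 2)
    if denom == 0:
        return float("nan")
    return float(1.0 - np.sum((p - c) ** 2) / denom)


def mre(predicted, census) -> tuple[float, int]:
    """Mean relative error in percent, excluding zero-census counties.

    MRE = mean_j |c_j - p_j| / c_j * 100 over counties with c_j > 0.
    Returns (mre_percent, n_excluded). All-zero census raises.
    """
    p, c = _pair(predicted, census)
    ok = c > 0
    n_excluded = int((~ok).sum())
    if not ok.any():
        raise ValueError("all census values are zero; MRE undefined")
    value = float(np.mean(np.abs(c[ok] - p[ok]) / c[ok]) * 100.0)
    return value, n_excluded


def validation_report(predicted, census, level: str = "county",
                      predicted_yearly=None, census_yearly=None) -> ValidationReport:
    """Convenience bundle: spatial metrics + MRE, plus NSE when series given."""
    r2, rmse, mae = spatial_metrics(predicted, census)
    mre_val, n_excl = mre(predicted, census)
    report = ValidationReport(r2=r2, rmse=rmse, mae=mae, mre_percent=mre_val,
                              n=len(np.asarray(census).ravel()), level=level,
                              n_excluded_zero_census=n_excl)
    if predicted_yearly is not None and census_yearly is not None:
        report.nse = nse(predicted_yearly, census_yearly)
    return report
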