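"""Synthetic test landscapes with known pixel-level grazing truth.

Real census downscaling can only be validated against the census itself;
a synthetic landscape additionally carries the pixel-level truth the method
is trying to recover, so every pipeline stage — and the M1-M4 model ladder
— is testable end to end. The generator emulates the statistical structure
the method assumes, not any real geography:

* a contiguous county mosaic (Voronoi tessellation of random seed pixels);
* spatially autocorrelated covariate fields (Gaussian-smoothed noise);
* a truth density that is a sparse linear-plus-interaction function of the
  first three covariates, clipped at zero — right-skewed, as observed
  grazing densities are (many lightly grazed pixels, a heavy tail);
* an NDVI pair in which grazing depresses the observed series below the
  potential series through a strictly increasing saturating deficit;
* census tables formed as exact zonal sums of the truth, so conservation
  checks have a bit-exact reference.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
import yaml
from scipy.ndimage import gaussian_filter

from grazegrid.census import CensusTable
from grazegrid.disturbance import NdviSeriesStack
from grazegrid.model import GRASSLAND_TYPES
from grazegrid.raster import RasterField, write_tiff

__all__ = ["LandscapeConfig", "SyntheticTruth", "generate_landscape", "write_landscape"]

#: Covariate names, loosely following the feature taxonomy of grazing drivers.
_COVARIATE_NAMES = (
    "precipitation", "temperature", "radiation", "soil_moisture", "soil_ph",
    "ndvi_mean", "river_distance", "relief", "pasture_suitability",
    "residential_density",
)

#: Default truth-density coefficients (SU/pixel) over standardized covariates:
#: density = b0 + b1*x1 + b2*x2 + b3*x3 + b12*x1*x2, clipped at 0.
DEFAULT_DENSITY_COEFFICIENTS = {"b0": 8.0, "b1": 14.0, "b2": 9.0, "b3": 6.0, "b12": 4.0}


@dataclass
class LandscapeConfig:
    """Full description of one synthetic landscape.

    ``noise_sd`` is pixel density noise in SU/pixel; ``ndvi_noise_sd`` the
    NDVI measurement noise; ``spatial_range`` the Gaussian-smoothing length
    (pixels) controlling covariate autocorrelation; ``pixel_area`` (hm^2)
    converts SU/pixel to SU/hm^2 densities; ``year_trend`` the fractional
    per-year intensification of the truth field.
    """

    grid_rows: int = 60
    grid_cols: int = 60
    n_counties: int = 25
    n_years: int = 3
    n_covariates: int = 6
    noise_sd: float = 0.5
    ndvi_noise_sd: float = 0.005
    spatial_range: float = 6.0
    pixel_area: float = 50.0
    year_trend: float = 0.04
    deficit_scale: float = 0.25
    deficit_half_density: float = 20.0
    density_coefficients: dict = field(default_factory=lambda: dict(DEFAULT_DENSITY_COEFFICIENTS))
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_counties < 2:
            raise ValueError("need at least 2 counties")
        if self.n_counties > self.grid_rows * self.grid_cols:
            raise ValueError("n_counties exceeds pixel count")
        if self.n_years < 1:
            raise ValueError("n_years must be >= 1")
        if self.noise_sd < 0 or self.ndvi_noise_sd < 0:
            raise ValueError("noise standard deviations must be >= 0")
        if self.n_covariates < 3:
            raise ValueError("need at least 3 covariates (the informative ones)")

    def covariate_names(self) -> list[str]:
        names = list(_COVARIATE_NAMES[: self.n_covariates])
        names += [f"cov{i}" for i in range(len(names), self.n_covariates)]
        return names


@dataclass
class SyntheticTruth:
    """A generated landscape: inputs for the pipeline plus the hidden truth."""

    config: LandscapeConfig
    truth_density: np.ndarray  # (n_years, rows, cols), SU/pixel
    covariates: dict  # name -> RasterField
    ndvi: NdviSeriesStack
    county_zones: RasterField  # integer labels 0..n_counties-1
    grassland_type: RasterField  # integer codes into grassland_type_names
    grassland_type_names: tuple = GRASSLAND_TYPES
    census: CensusTable = None
    years: list = field(default_factory=list)

    def grassland_type_labels(self) -> np.ndarray:
        """Grassland type raster as a string-label array."""
        return np.asarray(self.grassland_type_names)[self.grassland_type.values]


def _smooth_field(rng: np.random.Generator, shape: tuple[int, int], sigma: float) -> np.ndarray:
    """Standardized spatially autocorrelated field from smoothed white noise."""
    f = gaussian_filter(rng.standard_normal(shape), sigma=sigma, mode="reflect")
    return (f - f.mean()) / f.std()


def _voronoi_zones(rng: np.random.Generator, shape: tuple[int, int], n: int) -> np.ndarray:
    """Contiguous county mosaic: nearest of n uniformly sampled seed pixels."""
    rows, cols = shape
    idx = rng.choice(rows * cols, size=n, replace=False)
    seeds = np.column_stack(np.unravel_index(idx, shape))
    rr, cc = np.mgrid[0:rows, 0:cols]
    d2 = (rr[None] - seeds[:, 0, None, None]) ** 2 + (cc[None] - seeds[:, 1, None, None]) ** 2
    return np.argmin(d2, axis=0).astype(np.int32)


def generate_landscape(config: LandscapeConfig) -> SyntheticTruth:
    """Generate a seeded landscape with exact census/truth consistency.

    The census table is formed as the zonal sum of the truth density per
    county and year, so conservation checks downstream have an exact
    reference. The NDVI deficit ``h(d) = s * d / (d + d0)`` is strictly
    increasing in density, and observed NDVI never exceeds potential NDVI
    on grazed pixels.
    """
    rng = np.random.default_rng(config.seed)
    shape = (config.grid_rows, config.grid_cols)
    names = config.covariate_names()

    zones = _voronoi_zones(rng, shape, config.n_counties)
    covs = {name: RasterField(_smooth_field(rng, shape, config.spatial_range), name)
            for name in names}

    # grassland type from an independent smooth "productivity" field:
    # top tercile alpine meadow, middle alpine steppe, bottom desert steppe
    prod = _smooth_field(rng, shape, config.spatial_range)
    q1, q2 = np.quantile(prod, [1 / 3, 2 / 3])
    gtype = np.where(prod >= q2, 0, np.where(prod >= q1, 1, 2)).astype(np.int32)

    b = config.density_coefficients
    x1, x2, x3 = (covs[names[i]].values for i in range(3))
    base = b["b0"] + b["b1"] * x1 + b["b2"] * x2 + b["b3"] * x3 + b["b12"] * x1 * x2

    years = list(range(config.n_years))
    truth = np.empty((config.n_years, *shape))
    for t in years:
        yearly = base * (1.0 + config.year_trend * t)
        if config.noise_sd > 0:
            yearly = yearly + rng.normal(0.0, config.noise_sd, shape)
        truth[t] = np.clip(yearly, 0.0, None)

    # potential NDVI: smooth field squashed into a plausible [0.35, 0.85] band
    pot_base = 0.6 + 0.125 * np.tanh(_smooth_field(rng, shape, config.spatial_range))
    potential = np.repeat(pot_base[None], config.n_years, axis=0)
    s, d0 = config.deficit_scale, config.deficit_half_density
    deficit = s * truth / (truth + d0)
    observed = potential - deficit
    if config.ndvi_noise_sd > 0:
        observed = observed + rng.normal(0.0, config.ndvi_noise_sd, observed.shape)
    grazed = truth > 0
    observed[grazed] = np.minimum(observed[grazed], potential[grazed])
    observed = np.clip(observed, -1.0, 1.0)

    rows = []
    for t in years:
        for county in range(config.n_counties):
            sel = zones == county
            rows.append((county, t, float(truth[t][sel].sum()), "recorded"))
    census = CensusTable(pd.DataFrame(rows, columns=["county_id", "year", "su_total", "provenance"]))

    return SyntheticTruth(
        config=config,
        truth_density=truth,
        covariates=covs,
        ndvi=NdviSeriesStack(observed=observed, potential=potential),
        county_zones=RasterField(zones, "county_zones"),
        grassland_type=RasterField(gtype, "grassland_type"),
        census=census,
        years=years,
    )


def write_landscape(truth: SyntheticTruth, outdir: str | Path) -> None:
    """Write a landscape to disk: TIFF rasters, CSV census, YAML config."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    write_tiff(outdir / "covariates.tif", {n: f.values for n, f in truth.covariates.items()})
    write_tiff(outdir / "truth_density.tif",
               {f"year_{t}": truth.truth_density[t] for t in truth.years})
    write_tiff(outdir / "ndvi_observed.tif",
               {f"year_{t}": truth.ndvi.observed[t] for t in truth.years})
    write_tiff(outdir / "ndvi_potential.tif",
               {f"year_{t}": truth.ndvi.potential[t] for t in truth.years})
    write_tiff(outdir / "county_zones.tif", {"county_zones": truth.county_zones.values})
    write_tiff(outdir / "grassland_type.tif", {"grassland_type": truth.grassland_type.values})
    truth.census.to_csv(outdir / "census.csv")
    with open(outdir / "landscape.yaml", "w") as fh:
        yaml.safe_dump(asdict(truth.config), fh, sort_keys=False)
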