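"""Gridded variables on a shared lattice.

A :class:`RasterField` is the universal carrier of covariates, masks, zone
labels and model outputs: a single 2-D array on a common row/column lattice
with NaN as the nodata convention (boolean and integer fields carry an
explicit validity mask instead, since neither dtype can hold NaN).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np

__all__ = ["RasterField", "zonal_sum", "zonal_mean", "write_tiff", "read_tiff"]


@dataclass
class RasterField:
    """One gridded variable on the shared lattice.

    Parameters
    ----------
    values
        2-D array (rows x cols). Float fields use NaN for nodata.
    name
        Variable name used in stacks and file output.
    """

    values: np.ndarray
    name: str = ""

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values)
        if self.values.ndim != 2:
            raise ValueError(f"RasterField must be 2-D, got shape {self.values.shape}")

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape

    @property
    def valid(self) -> np.ndarray:
        """Boolean array of valid (non-nodata) pixels."""
        if np.issubdtype(self.values.dtype, np.floating):
            return ~np.isnan(self.values)
        return np.ones(self.values.shape, dtype=bool)

    def same_lattice(self, other: "RasterField") -> bool:
        return self.shape == other.shape

    def copy(self) -> "RasterField":
        return RasterField(self.values.copy(), self.name)


def _check_lattice(fields: Iterable[RasterField]) -> tuple[int, int]:
    shapes = {f.shape for f in fields}
    if len(shapes) > 1:
        raise ValueError(f"rasters are not on a shared lattice: shapes {sorted(shapes)}")
    return shapes.pop()


def zonal_sum(values: np.ndarray, zones: np.ndarray, mask: np.ndarray | None = None) -> dict[int, float]:
    """Sum of ``values`` per integer zone label, optionally restricted to ``mask``."""
    values = np.asarray(values, dtype=float)
    zones = np.asarray(zones)
    ok = ~np.isnan(values)
    if mask is not None:
        ok &= np.asarray(mask, dtype=bool)
    labels = np.unique(zones[ok])
    sums = {}
    for lab in labels:
        sel = ok & (zones == lab)
        sums[int(lab)] = float(values[sel].sum())
    return sums


def zonal_mean(values: np.ndarray, zones: np.ndarray, mask: np.ndarray | None = None) -> dict[int, float]:
    """Mean of ``values`` per integer zone label, optionally restricted to ``mask``."""
    values = np.asarray(values, dtype=float)
    zones = np.asarray(zones)
    ok = ~np.isnan(values)
    if mask is not None:
        ok &= np.asarray(mask, dtype=bool)
    means = {}
    for lab in np.unique(zones[ok]):
        sel = ok & (zones == lab)
        means[int(lab)] = float(values[sel].mean())
    return means


def write_tiff(path: str | Path, fields: Mapping[str, np.ndarray] | RasterField) -> None:
    """Write one raster or a named stack as a multi-page TIFF.

    Plain TIFF (no geo-tags): grids in this package live on an abstract
    lattice. Band names go into the page description tag.
    """
    import tifffile

    if isinstance(fields, RasterField):
        fields = {fields.name or "band": fields.values}
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with tifffile.TiffWriter(path) as tw:
        for name, arr in fields.items():
            tw.write(np.asarray(arr), description=str(name))


def read_tiff(path: str | Path) -> dict[str, np.ndarray]:
    """Read a multi-page TIFF written by :func:`write_tiff` back into a stack."""
    import tifffile

    out: dict[str, np.ndarray] = {}
    with tifffile.TiffFile(path) as tf:
        for i, page in enumerate(tf.pages):
            name = page.description or f"band_{i}"
            out[name] = page.asarray()
    return out
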