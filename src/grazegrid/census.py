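"""Livestock census ingestion and sheep-unit conversion.

County-level year-end stocking numbers for eight species are converted to
standard sheep units (SU) with the national-standard coefficients
(NY/T 635-2015): sheep 1, goats 0.8, cattle 5, yaks 5, horses 6, donkeys 3,
mules 6, camels 7. Missing county-years are filled from a parent
(city/province) series by ratio scaling, or linearly when no parent series
is available, and flagged in a provenance column.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = [
    "SU_COEFFICIENTS",
    "LivestockCounts",
    "CensusTable",
    "to_sheep_units",
    "fill_missing_years",
]

#: Standard sheep-unit coefficients per head, by species (NY/T 635-2015).
SU_COEFFICIENTS: dict[str, float] = {
    "sheep": 1.0,
    "goats": 0.8,
    "cattle": 5.0,
    "yaks": 5.0,
    "horses": 6.0,
    "donkeys": 3.0,
    "mules": 6.0,
    "camels": 7.0,
}


@dataclass
class LivestockCounts:
    """Head counts for one county-year, all species nonnegative."""

    sheep: float = 0
    goats: float = 0
    cattle: float = 0
    yaks: float = 0
    horses: float = 0
    donkeys: float = 0
    mules: float = 0
    camels: float = 0

    def __post_init__(self) -> None:
        for name in SU_COEFFICIENTS:
            if getattr(self, name) < 0:
                raise ValueError(f"negative head count for {name}")


@dataclass
class CensusTable:
    """County x year sheep-unit totals.

    ``data`` columns: county_id, year, su_total, provenance
    (``recorded`` or ``interpolated``). (county_id, year) pairs are unique
    and su_total is nonnegative.
    """

    data: pd.DataFrame = field(default_factory=lambda: pd.DataFrame(
        columns=["county_id", "year", "su_total", "provenance"]))

    def __post_init__(self) -> None:
        required = {"county_id", "year", "su_total"}
        missing = required - set(self.data.columns)
        if missing:
            raise ValueError(f"census table missing columns: {sorted(missing)}")
        if "provenance" not in self.data.columns:
            self.data = self.data.assign(provenance="recorded")
        if (self.data["su_total"] < 0).any():
            raise ValueError("negative su_total in census table")
        if self.data.duplicated(["county_id", "year"]).any():
            raise ValueError("duplicate (county_id, year) in census table")

    def totals_for_year(self, year: int) -> dict[int, float]:
        sub = self.data[self.data["year"] == year]
        return dict(zip(sub["county_id"].astype(int), sub["su_total"].astype(float)))

    def to_csv(self, path: str | Path) -> None:
        self.data.to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path: str | Path) -> "CensusTable":
        return cls(pd.read_csv(path))


def to_sheep_units(counts: LivestockCounts, coefficients: dict[str, float] | None = None) -> float:
    """Convert species head counts to standard sheep units.

    SU = N_sheep + 0.8 N_goats + 5 N_cattle + 5 N_yaks + 6 N_horses
         + 3 N_donkeys + 6 N_mules + 7 N_camels

    Coefficients are overridable because the underlying national standard
    may be revised.
    """
    coef = dict(SU_COEFFICIENTS)
    if coefficients:
        coef.update(coefficients)
    return float(sum(coef[name] * getattr(counts, name) for name in SU_COEFFICIENTS))


def fill_missing_years(
    table: CensusTable,
    years: list[int] | None = None,
    parent_series: dict[int, float] | pd.Series | None = None,
) -> CensusTable:
    """Fill gap years in a county census table.

    For each county, a missing year is filled by scaling the nearest
    recorded county value by the parent series' relative change between the
    two years (``value * parent[gap] / parent[anchor]``). Without a parent
    series the fallback is linear interpolation between the bracketing
    recorded years (edge gaps take the nearest recorded value). Recorded
    rows are never altered; filled rows carry provenance ``interpolated``.

    Parameters
    ----------
    years
        Year range to make gap-free. Defaults to the min..max recorded year
        across the whole table.
    parent_series
        SU totals at the city/province level, indexed by year, defining the
        temporal trend used for ratio scaling.
    """
    df = table.data.copy()
    if df.empty:
        raise ValueError("cannot fill an empty census table")
    if years is None:
        years = list(range(int(df["year"].min()), int(df["year"].max()) + 1))
    if parent_series is not None:
        parent = pd.Series(parent_series, dtype=float)

    rows = []
    for county, sub in df.groupby("county_id"):
        recorded = sub.set_index("year")["su_total"].astype(float).sort_index()
        if recorded.empty:
            raise ValueError(f"county {county} has no recorded anchor year")
        for year in years:
            if year in recorded.index:
                continue
            if parent_series is not None and year in parent.index:
                # nearest recorded year that the parent series also covers
                anchors = [y for y in recorded.index if y in parent.index]
                if anchors:
                    anchor = min(anchors, key=lambda y: abs(y - year))
                    value = recorded[anchor] * parent[year] / parent[anchor]
                    rows.append((county, year, max(value, 0.0)))
                    continue
            # linear interpolation between bracketing recorded years
            before = recorded.index[recorded.index < year]
            after = recorded.index[recorded.index > year]
            if len(before) and len(after):
                y0, y1 = before.max(), after.min()
                w = (year - y0) / (y1 - y0)
                value = recorded[y0] * (1 - w) + recorded[y1] * w
            elif len(before):
                value = recorded[before.max()]
            else:
                value = recorded[after.min()]
            rows.append((county, year, float(value)))

    if not rows:
        return CensusTable(df)
    filled = pd.DataFrame(rows, columns=["county_id", "year", "su_total"])
    filled["provenance"] = "interpolated"
    out = pd.concat([df, filled], ignore_index=True)
    out = out.sort_values(["county_id", "year"]).reset_index(drop=True)
    return CensusTable(out)
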