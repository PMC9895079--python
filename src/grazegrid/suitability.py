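"""Theoretical suitable grazing areas.

A stepwise decision tree carves the suitable-grazing mask out of the
grassland extent: pixels above a maximum elevation, closer to towns than a
minimum distance, or inside national nature-reserve core zones are removed
in turn, and the number of pixels each rule removes is logged. The paper
leaves the altitude and town-proximity cutoffs open, so both are explicit
parameters and appear in the criteria log.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from grazegrid.raster import RasterField, _check_lattice

__all__ = ["SuitabilityMask", "build_suitability_mask"]

logger = logging.getLogger(__name__)

#: Example defaults; the source method states no numeric cutoffs.
DEFAULT_THRESHOLDS = {"max_elevation": 5500.0, "min_town_distance": 2000.0}


@dataclass
class SuitabilityMask:
    """Boolean suitable-grazing mask with a per-rule removal audit trail."""

    mask: RasterField
    criteria_log: list[tuple[str, int]] = field(default_factory=list)
    thresholds: dict = field(default_factory=dict)

    @property
    def values(self) -> np.ndarray:
        return self.mask.values

    def n_pixels(self) -> int:
        return int(self.mask.values.sum())


def build_suitability_mask(
    grassland: RasterField,
    elevation: RasterField | None = None,
    town_distance: RasterField | None = None,
    reserve_core: RasterField | None = None,
    thresholds: dict | None = None,
) -> SuitabilityMask:
    """Apply the suitable-area decision tree to the grassland extent.

    Rules, in order: keep grassland; drop elevation > ``max_elevation``;
    drop town_distance < ``min_town_distance``; drop reserve core pixels.
    A missing layer skips its rule with a logged warning. The resulting
    mask is order-invariant (pure intersection); only the per-rule removal
    counts depend on order.
    """
    thr = dict(DEFAULT_THRESHOLDS)
    if thresholds:
        thr.update(thresholds)

    layers = [f for f in (grassland, elevation, town_distance, reserve_core) if f is not None]
    _check_lattice(layers)

    mask = np.asarray(grassland.values, dtype=bool).copy()
    log: list[tuple[str, int]] = []

    def apply_rule(name: str, remove: np.ndarray | None) -> None:
        if remove is None:
            logger.warning("suitability rule %r skipped: layer missing", name)
            log.append((name + " (skipped)", 0))
            return
        removed = int((mask & remove).sum())
        mask[remove] = False
        log.append((name, removed))

    apply_rule(
        "elevation > max_elevation",
        None if elevation is None else np.asarray(elevation.values) > thr["max_elevation"],
    )
    apply_rule(
        "town_distance < min_town_distance",
        None if town_distance is None else np.asarray(town_distance.values) < thr["min_town_distance"],
    )
    apply_rule(
        "reserve core",
        None if reserve_core is None else np.asarray(reserve_core.values, dtype=bool),
    )

    return SuitabilityMask(RasterField(mask, "suitable"), log, thr)
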