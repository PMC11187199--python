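"""Channel-sphere volumetrics and resection bookkeeping.

SOZ, resection, and resected-SOZ extents are estimated at the channel
level: every channel of interest is inflated to a 5 mm radius sphere and
the union volume is counted on a 0.5 mm grid (a voxel counts iff its
center falls inside any sphere), so overlapping spheres are never double
counted.  Percent-SOZ-resected is a set ratio over atlas region labels
projected per contact; the projection itself is an input.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Optional, Sequence

import numpy as np
from scipy.spatial import cKDTree

from .core import FrameworkConfig

__all__ = [
    "VolumeEstimate",
    "sphere_union_volume",
    "percent_soz_resected",
    "incomplete_resection_threshold",
]


@dataclass(frozen=True)
class VolumeEstimate:
    soz_cm3: float
    resected_cm3: float
    resected_soz_cm3: float
    soz_pct_resected: Optional[float]  # None when SOZ region set is empty/unknown

    def __post_init__(self) -> None:
        if min(self.soz_cm3, self.resected_cm3, self.resected_soz_cm3) < 0:
            raise ValueError("volumes must be non-negative")


def sphere_union_volume(
    coordinates: Sequence[Iterable[float]], cfg: FrameworkConfig
) -> float:
    """Union volume (cm^3) of radius-``sphere_radius_mm`` balls on a voxel grid.

    The grid is axis-aligned to the bounding box of the centers padded by
    the radius, at ``cfg.grid_resolution_mm`` spacing; a voxel is counted
    when its center lies within any ball.  Returns 0 for an empty set.
    """
    centers = np.asarray(list(coordinates), dtype=float)
    if centers.size == 0:
        return 0.0
    centers = centers.reshape(-1, 3)
    r = cfg.sphere_radius_mm
    h = cfg.grid_resolution_mm
    lo = centers.min(axis=0) - r - h
    hi = centers.max(axis=0) + r + h
    axes = [np.arange(lo[k] + h / 2, hi[k], h) for k in range(3)]
    # query voxel centers against sphere centers; chunk the largest axis to
    # bound memory on wide implantations
    tree = cKDTree(centers)
    count = 0
    gy, gz = np.meshgrid(axes[1], axes[2], indexing="ij")
    yz = np.column_stack([gy.ravel(), gz.ravel()])
    for x in axes[0]:
        pts = np.column_stack([np.full(len(yz), x), yz])
        d, _ = tree.query(pts, k=1, distance_upper_bound=r + 1e-12)
        count += int(np.sum(np.isfinite(d)))
    return count * (h ** 3) / 1000.0  # mm^3 -> cm^3


def percent_soz_resected(
    soz_regions: Iterable[str], resected_regions: Iterable[str]
) -> Optional[float]:
    """|SOZ ∩ Resected| / |SOZ| over atlas region labels.

    Returns ``None`` for an empty SOZ set (e.g. palliative cases where no
    apparent SOZ region was removed and the ratio is undefined).
    """
    soz = set(soz_regions)
    if not soz:
        return None
    return len(soz & set(resected_regions)) / len(soz)


def incomplete_resection_threshold(
    resected_soz_volumes: Sequence[float], cfg: FrameworkConfig
) -> float:
    """Upper-quartile cutoff of resected-SOZ volumes (cm^3).

    Patients marked as incompletely resected whose resected-SOZ volume
    falls below this percentile (default 75th, linear interpolation) are
    excluded from corrected performance reporting.
    """
    vols = np.asarray(resected_soz_volumes, dtype=float)
    if vols.size < 4:
        raise ValueError("need at least 4 volumes to set the threshold")
    return float(np.percentile(vols, cfg.incomplete_resection_percentile))
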