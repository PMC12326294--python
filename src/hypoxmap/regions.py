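"""Coastal mask construction and region/box assignment for the northern
Indian Ocean analysis domain (32-114° E, 8.6° S - 30.3° N).

A cell is "coastal" if it lies within 100 km of the shore OR inshore of
the 1000 m isobath, whichever reaches farther offshore.  "Inshore of the
isobath" is evaluated as membership in a shallow (depth <= isobath)
connected component that touches land, so detached shallow seamounts are
excluded from the coastal band.

Regions: the eastern Arabian Sea (EAS) south of 18° N and west of 79° E;
the Bay of Bengal delta regions (BoB-DR) between 85° E and 97° E where the
annual-mean surface salinity falls below 29 (takes precedence); the
western (WBoB) and eastern (EBoB) Bay of Bengal split at configurable
longitudes (defaults 85° E / 92° E — the split is not pinned down by the
region definitions themselves).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Dict, Optional, Tuple

import numpy as np
from scipy import ndimage

DOMAIN_LON = (32.0, 114.0)
DOMAIN_LAT = (-8.6, 30.3)

REGION_LABELS = ("EAS", "WBoB", "BoB-DR", "EBoB", "none")


@dataclass(frozen=True)
class CoastalGrid:
    """Bathymetry + shore-distance grids; land is NaN depth."""

    lon: np.ndarray
    lat: np.ndarray
    depth: np.ndarray           # m, positive down; NaN over land
    shore_distance: np.ndarray  # km

    def __post_init__(self):
        d = np.asarray(self.depth)
        s = np.asarray(self.shore_distance)
        if d.shape != s.shape:
            raise ValueError("depth and shore_distance grids differ in shape")
        if np.nanmin(s) < 0:
            raise ValueError("shore_distance must be >= 0")

    @property
    def land(self) -> np.ndarray:
        return ~np.isfinite(np.asarray(self.depth))


def coastal_mask(grid: CoastalGrid, distance_km: float = 100.0,
                 isobath_m: float = 1000.0) -> np.ndarray:
    """Boolean coastal mask (see module docstring for the rule)."""
    land = grid.land
    ocean = ~land
    if not ocean.any():
        warnings.warn("all-land grid: empty coastal mask", stacklevel=2)
        return np.zeros_like(land, dtype=bool)
    near = ocean & (np.asarray(grid.shore_distance) <= distance_km)

    shallow = ocean & (np.asarray(grid.depth) <= isobath_m)
    lab, nlab = ndimage.label(shallow)  # 4-connectivity
    # components adjacent to land: dilate land and intersect
    land_halo = ndimage.binary_dilation(land)
    touching = np.unique(lab[shallow & land_halo])
    touching = touching[touching > 0]
    inshore = np.isin(lab, touching)
    return near | inshore


@dataclass(frozen=True)
class RegionSet:
    """Per-cell region labels plus the named 1°x1° case-study boxes."""

    labels: np.ndarray
    boxes: Dict[str, Tuple[float, float, float, float]]


def case_study_boxes(box_ir: Optional[Tuple[float, float, float, float]] = None
                     ) -> Dict[str, Tuple[float, float, float, float]]:
    """The four 1°x1° case-study boxes as (lat_min, lat_max, lon_min, lon_max).

    Box-IR (Irrawaddy-Sittang) has no published corners and is only
    included when passed explicitly.
    """
    boxes = {
        "EAS": (10.0, 11.0, 75.0, 76.0),
        "WBoB": (17.2, 18.2, 83.2, 84.2),
        "EBoB": (8.5, 9.5, 97.5, 98.5),
        "GB": (21.5, 22.5, 91.0, 92.0),
    }
    if box_ir is not None:
        lat0, lat1, lon0, lon1 = box_ir
        if not (lat0 < lat1 and lon0 < lon1):
            raise ValueError("box corners must be ordered")
        boxes["IR"] = tuple(box_ir)
    return boxes


def assign_region(lon, lat, annual_salinity,
                  wbob_east_lon: float = 85.0,
                  ebob_west_lon: float = 92.0,
                  dr_salinity_max: float = 29.0):
    """Region label(s) for coordinates and annual-mean surface salinity.

    BoB-DR (85-97° E, salinity < limit) takes precedence; remaining cells
    follow the latitude/longitude rules; unmatched cells get "none".
    """
    lon_a = np.atleast_1d(np.asarray(lon, dtype=float))
    lat_a = np.atleast_1d(np.asarray(lat, dtype=float))
    sal_a = np.atleast_1d(np.asarray(annual_salinity, dtype=float))
    lon_a, lat_a, sal_a = np.broadcast_arrays(lon_a, lat_a, sal_a)
    finite = np.isfinite(lon_a) & np.isfinite(lat_a)
    bad = finite & ((lon_a < DOMAIN_LON[0]) | (lon_a > DOMAIN_LON[1])
                    | (lat_a < DOMAIN_LAT[0]) | (lat_a > DOMAIN_LAT[1]))
    if bad.any():
        i = np.argwhere(bad)[0]
        raise ValueError(
            f"coordinates outside the model domain at {tuple(i)}: "
            f"lon={lon_a[tuple(i)]}, lat={lat_a[tuple(i)]}")

    out = np.full(lon_a.shape, "none", dtype=object)
    dr = (lon_a >= 85.0) & (lon_a <= 97.0) & (sal_a < dr_salinity_max)
    eas = ~dr & (lat_a < 18.0) & (lon_a < 79.0)
    wbob = ~dr & ~eas & (lon_a >= 79.0) & (lon_a < wbob_east_lon)
    ebob = ~dr & (lon_a >= ebob_west_lon)
    out[dr] = "BoB-DR"
    out[eas] = "EAS"
    out[wbob] = "WBoB"
    out[ebob] = "EBoB"
    if np.ndim(lon) == 0 and np.ndim(lat) == 0:
        return str(out.ravel()[0])
    return out


def label_regions(grid: CoastalGrid, annual_salinity,
                  mask: Optional[np.ndarray] = None, **kwargs) -> RegionSet:
    """Assign region labels over a grid, restricted to a coastal mask."""
    if mask is None:
        mask = coastal_mask(grid)
    lon2, lat2 = np.meshgrid(grid.lon, grid.lat) \
        if np.ndim(grid.lon) == 1 else (grid.lon, grid.lat)
    labels = assign_region(lon2, lat2, annual_salinity, **kwargs)
    labels = np.where(mask, labels, "none").astype(object)
    return RegionSet(labels, case_study_boxes())
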