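"""Synthetic 2-D/3-D gridded fixtures for the spatial diagnostics.

Builds SLA maps with planted Gaussian eddies (plus optional large-scale
tilt and noise), oxygen column fields with a sigmoid oxycline displaced
under planted eddy centers (raised under cyclones, deepened under
anticyclones), and shelf bathymetry/shore-distance grids.  Every field
ships a ground-truth table so detector tests can score recall and
precision against what was actually planted.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Tuple

import numpy as np
import pandas as pd


@dataclass(frozen=True)
class PlantedEddy:
    x_km: float
    y_km: float
    sign: int          # -1 cyclonic (SLA low), +1 anticyclonic
    amplitude_m: float
    radius_km: float   # Gaussian sigma

    def __post_init__(self):
        if self.sign not in (-1, 1):
            raise ValueError("eddy sign must be -1 or +1")
        if self.amplitude_m <= 0 or self.radius_km <= 0:
            raise ValueError("eddy amplitude and radius must be > 0")


@dataclass(frozen=True)
class FixtureSpec:
    """Grid geometry + planted-eddy list for one synthetic scene."""

    nx: int = 160
    ny: int = 128
    dx_km: float = 6.0
    eddies: Tuple[PlantedEddy, ...] = ()
    tilt_m: float = 0.0            # peak-to-peak large-scale SLA tilt
    tilt_wavelength_km: float = 3000.0
    noise_sd_m: float = 0.0
    oxycline_depth_m: float = 80.0
    oxycline_width_m: float = 15.0
    o2_surface: float = 210.0
    o2_deep: float = 20.0
    displacement_m: float = 20.0   # oxycline shift magnitude per eddy
    seed: int = 0

    def __post_init__(self):
        if self.nx < 4 or self.ny < 4 or self.dx_km <= 0:
            raise ValueError("invalid grid geometry")
        edd = list(self.eddies)
        for i, a in enumerate(edd):
            for b in edd[i + 1:]:
                d = np.hypot(a.x_km - b.x_km, a.y_km - b.y_km)
                if d < 2.0 * (a.radius_km + b.radius_km):
                    raise ValueError(
                        "planted eddies overlap at 2x radius: "
                        f"({a.x_km},{a.y_km}) vs ({b.x_km},{b.y_km})")
        if edd:
            rmin = min(e.radius_km for e in edd)
            if self.dx_km > rmin / 4:
                raise ValueError(
                    "grid spacing must resolve the smallest eddy radius "
                    f"by >= 4 cells (dx={self.dx_km} km, rmin={rmin} km)")

    @property
    def x_km(self) -> np.ndarray:
        return np.arange(self.nx) * self.dx_km

    @property
    def y_km(self) -> np.ndarray:
        return np.arange(self.ny) * self.dx_km


def make_sla_field(spec: FixtureSpec):
    """SLA map (ny, nx) in metres plus the planted-truth table."""
    x, y = np.meshgrid(spec.x_km, spec.y_km)
    sla = np.zeros((spec.ny, spec.nx))
    for e in spec.eddies:
        r2 = (x - e.x_km) ** 2 + (y - e.y_km) ** 2
        sla += e.sign * e.amplitude_m * np.exp(-r2 / (2 * e.radius_km ** 2))
    if spec.tilt_m:
        sla += spec.tilt_m * 0.5 * np.sin(
            2 * np.pi * x / spec.tilt_wavelength_km)
    if spec.noise_sd_m:
        rng = np.random.default_rng([spec.seed, 10])
        sla += spec.noise_sd_m * rng.standard_normal(sla.shape)
    truth = pd.DataFrame(
        [{"x_km": e.x_km, "y_km": e.y_km, "sign": e.sign,
          "amplitude_m": e.amplitude_m, "radius_km": e.radius_km,
          "row": int(round(e.y_km / spec.dx_km)),
          "col": int(round(e.x_km / spec.dx_km))}
         for e in spec.eddies],
        columns=["x_km", "y_km", "sign", "amplitude_m", "radius_km",
                 "row", "col"])
    return sla, truth


def make_o2_column_field(spec: FixtureSpec, truth: pd.DataFrame,
                         depths=None) -> np.ndarray:
    """3-D O2 field (depth, ny, nx) with per-eddy oxycline displacement.

    The background profile is a sigmoid dropping from ``o2_surface`` to
    ``o2_deep`` across the oxycline.  Columns under cyclonic truth centers
    have the oxycline raised by ``displacement_m`` (Gaussian-tapered with
    distance from the center), anticyclonic columns have it deepened.
    """
    if spec.displacement_m >= spec.oxycline_depth_m:
        raise ValueError("displacement exceeds the oxycline depth")
    z = np.asarray(depths, dtype=float) if depths is not None \
        else np.arange(5.0, 205.0, 10.0)
    x, y = np.meshgrid(spec.x_km, spec.y_km)
    shift = np.zeros((spec.ny, spec.nx))
    for _, e in truth.iterrows():
        r2 = (x - e.x_km) ** 2 + (y - e.y_km) ** 2
        taper = np.exp(-r2 / (2 * e.radius_km ** 2))
        # cyclone (sign -1) raises the oxycline (shallower => less O2 above)
        shift += e.sign * spec.displacement_m * taper
    zc = spec.oxycline_depth_m + shift  # (ny, nx)
    arg = (z[:, None, None] - zc[None, :, :]) / spec.oxycline_width_m
    o2 = spec.o2_deep + (spec.o2_surface - spec.o2_deep) / (1 + np.exp(arg))
    return o2


def standard_eddy_fixture(seed: int = 0, n_per_sign: int = 10,
                          amplitude_range=(0.08, 0.2),
                          radius_km: float = 30.0,
                          noise_sd_m: float = 0.005,
                          tilt_m: float = 0.3) -> FixtureSpec:
    """The 20-eddy benchmark scene: jittered grid placement, 10 per sign."""
    rng = np.random.default_rng([seed, 20])
    nx, ny, dx = 200, 160, 6.0
    cols, rows = 5, 4
    spacing_x = nx * dx / cols
    spacing_y = ny * dx / rows
    cells = [(i, j) for j in range(rows) for i in range(cols)]
    signs = np.array([-1] * n_per_sign + [1] * n_per_sign)
    rng.shuffle(signs)
    eddies = []
    for (i, j), s in zip(cells, signs):
        cx = (i + 0.5) * spacing_x + rng.uniform(-0.08, 0.08) * spacing_x
        cy = (j + 0.5) * spacing_y + rng.uniform(-0.08, 0.08) * spacing_y
        amp = rng.uniform(*amplitude_range)
        eddies.append(PlantedEddy(cx, cy, int(s), float(amp), radius_km))
    return FixtureSpec(nx=nx, ny=ny, dx_km=dx, eddies=tuple(eddies),
                       tilt_m=tilt_m, noise_sd_m=noise_sd_m, seed=seed)


def make_shelf_grid(nx: int = 60, ny: int = 40, dx_km: float = 10.0,
                    shelf_width_cells: int = 12,
                    shelf_depth_m: float = 200.0,
                    deep_depth_m: float = 3000.0):
    """Idealized coastal grid: land strip at the west edge, a shelf, then a
    deep basin.  Returns a :class:`hypoxmap.regions.CoastalGrid`."""
    from .regions import CoastalGrid

    depth = np.full((ny, nx), deep_depth_m)
    depth[:, 0] = np.nan  # land column
    ramp = np.linspace(shelf_depth_m * 0.1, deep_depth_m,
                       shelf_width_cells)
    depth[:, 1:1 + shelf_width_cells] = ramp[None, :]
    shore = (np.arange(nx) - 0.5) * dx_km
    shore = np.clip(shore, 0, None)
    shore_distance = np.tile(shore, (ny, 1))
    lon = 70.0 + np.arange(nx) * dx_km / 111.0
    lat = 8.0 + np.arange(ny) * dx_km / 111.0
    return CoastalGrid(lon=lon, lat=lat, depth=depth,
                       shore_distance=shore_distance)
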