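"""Oxygen-budget depth averaging and physical/biological driver attribution.

The oxygen tendency closes as  ∂tO2 = ∂tO2_phys + ∂tO2_bio + F_airsea,
with the biological term further split into primary production (source)
and water-column respiration, sediment oxygen demand and nitrification
(sinks).  Attribution works on anomalies of the depth-averaged physical
and biological tendencies (each relative to its record mean): an oxygen
change is physically driven when its sign matches the physical anomaly
and not the biological one, biologically driven in the mirror case, and
driven by both when the two anomalies share a sign.  Timesteps where an
anomaly sits inside a small dead-band (the sign of near-zero noise is
meaningless) or where the oxygen change matches neither anomaly are
labelled "undetermined".
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

LABELS = ("physical", "biological", "both", "undetermined")


def layer_interfaces(depths) -> np.ndarray:
    """Layer edges from level-center depths: midpoints, 0 at top, and a
    bottom edge extended by half the last spacing."""
    z = np.asarray(depths, dtype=float)
    if z.ndim != 1 or z.size < 1 or np.any(np.diff(z) <= 0):
        raise ValueError("depths must be strictly increasing 1-D")
    if z.size == 1:
        half = z[0]
        return np.array([max(z[0] - half, 0.0), z[0] + half])
    mid = 0.5 * (z[:-1] + z[1:])
    top = 0.0
    bottom = z[-1] + 0.5 * (z[-1] - z[-2])
    return np.concatenate([[top], mid, [bottom]])


def depth_average(field, depths, z1: float, z2: float, interfaces=None):
    """Layer-thickness-weighted mean of a (time x depth) field over [z1, z2].

    Levels partially inside the range are weighted by their overlap with
    it.  ``interfaces`` (n+1 edges) overrides the default edges derived
    from level centers.
    """
    if z2 <= z1:
        raise ValueError("need z1 < z2")
    a = np.asarray(field, dtype=float)
    edges = np.asarray(interfaces, dtype=float) if interfaces is not None \
        else layer_interfaces(depths)
    if a.shape[-1] != edges.size - 1:
        raise ValueError("field depth axis does not match layer count")
    top = np.clip(edges[:-1], z1, z2)
    bot = np.clip(edges[1:], z1, z2)
    w = np.maximum(bot - top, 0.0)
    if w.sum() <= 0:
        raise ValueError(f"depth range [{z1}, {z2}] m does not overlap the grid")
    return (a * w).sum(axis=-1) / w.sum()


def tendency_anomalies(phys_series, bio_series, baseline: str = "record-mean",
                       years=None):
    """Anomalies of the physical and biological tendencies.

    baseline="record-mean" removes the record-long mean (the default:
    a climatological annual mean with no December/January discontinuity);
    baseline="per-year" removes each calendar year's own mean and needs
    ``years`` labels.
    """
    p = np.asarray(phys_series, dtype=float).ravel()
    b = np.asarray(bio_series, dtype=float).ravel()
    if p.shape != b.shape:
        raise ValueError("physical and biological series differ in length")
    if baseline == "record-mean":
        return p - p.mean(), b - b.mean()
    if baseline == "per-year":
        if years is None:
            raise ValueError("per-year baseline needs year labels")
        y = np.asarray(years).ravel()
        if y.shape != p.shape:
            raise ValueError("year labels differ in length")
        pa, ba = p.copy(), b.copy()
        for yy in np.unique(y):
            sel = y == yy
            pa[sel] -= p[sel].mean()
            ba[sel] -= b[sel].mean()
        return pa, ba
    raise ValueError(f"unknown baseline {baseline!r}")


def _sign_dead(x, eps):
    """-1/0/+1 with a +-eps dead-band mapped to 0."""
    s = np.sign(x)
    s[np.abs(x) <= eps] = 0.0
    return s


def attribute(dO2, phys_anom, bio_anom, eps=None) -> np.ndarray:
    """Per-timestep driver labels from the sign rule.

    eps defaults to 1e-3 x the record standard deviation of each anomaly
    (a scalar eps is applied to both).
    """
    d = np.asarray(dO2, dtype=float).ravel()
    p = np.asarray(phys_anom, dtype=float).ravel()
    b = np.asarray(bio_anom, dtype=float).ravel()
    if not (d.shape == p.shape == b.shape):
        raise ValueError("inputs differ in length")
    if not (np.all(np.isfinite(d)) and np.all(np.isfinite(p))
            and np.all(np.isfinite(b))):
        raise ValueError("non-finite inputs")
    if eps is None:
        eps_p = 1e-3 * (np.std(p) if p.size > 1 else 0.0)
        eps_b = 1e-3 * (np.std(b) if b.size > 1 else 0.0)
        eps_d = 0.0
    else:
        if eps < 0:
            raise ValueError("eps must be >= 0")
        eps_p = eps_b = eps_d = float(eps)
    sd = _sign_dead(d, eps_d)
    sp = _sign_dead(p, eps_p)
    sb = _sign_dead(b, eps_b)

    out = np.full(d.shape, "undetermined", dtype=object)
    determined = (sp != 0) & (sb != 0)
    both = determined & (sp == sb) & (sd == sp)
    phys = determined & (sp != sb) & (sd == sp)
    bio = determined & (sp != sb) & (sd == sb)
    out[both] = "both"
    out[phys] = "physical"
    out[bio] = "biological"
    # everything else (dead-band anomalies, or dO2 matching neither sign,
    # including the same-sign case opposed by dO2) stays undetermined
    return out


def residual_check(total, phys, bio, airsea) -> float:
    """Max |∂tO2 - (phys + bio + airsea)| — a budget data-quality gate."""
    t = np.asarray(total, dtype=float)
    r = t - (np.asarray(phys, dtype=float) + np.asarray(bio, dtype=float)
             + np.asarray(airsea, dtype=float))
    return float(np.max(np.abs(r))) if r.size else 0.0


@dataclass(frozen=True)
class AttributionSeries:
    """Depth-averaged oxygen change and its per-timestep driver labels."""

    dO2: np.ndarray            # μmol/kg per timestep (centered difference)
    phys_anom: np.ndarray      # μmol/kg/s
    bio_anom: np.ndarray       # μmol/kg/s
    labels: np.ndarray

    def fractions(self) -> dict:
        n = self.labels.size
        return {k: float(np.sum(self.labels == k)) / n for k in LABELS}

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({
            "dO2": self.dO2, "phys_anom": self.phys_anom,
            "bio_anom": self.bio_anom, "label": self.labels,
        })


def centered_diff(series) -> np.ndarray:
    """Centered finite difference per timestep; one-sided at the ends."""
    x = np.asarray(series, dtype=float).ravel()
    if x.size < 2:
        raise ValueError("need at least two timesteps")
    d = np.empty_like(x)
    d[1:-1] = 0.5 * (x[2:] - x[:-2])
    d[0] = x[1] - x[0]
    d[-1] = x[-1] - x[-2]
    return d


def attribute_box(ds, z1: float = None, z2: float = None,
                  baseline: str = "record-mean", eps=None) -> AttributionSeries:
    """Attribution for a simulator/hindcast budget dataset.

    ``ds`` is an xarray Dataset with o2, do2_phys, do2_bio on (time, depth);
    the depth range defaults to the dataset's ``budget_depth_range`` attr.
    """
    depths = np.asarray(ds["depth"].values, dtype=float)
    if z1 is None or z2 is None:
        z1, z2 = ds.attrs["budget_depth_range"]
    o2 = depth_average(ds["o2"].values, depths, z1, z2)
    phys = depth_average(ds["do2_phys"].values, depths, z1, z2)
    bio = depth_average(ds["do2_bio"].values, depths, z1, z2)
    years = ds["year"].values if "year" in ds else None
    pa, ba = tendency_anomalies(phys, bio, baseline=baseline, years=years)
    d = centered_diff(o2)
    labels = attribute(d, pa, ba, eps=eps)
    return AttributionSeries(d, pa, ba, labels)
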