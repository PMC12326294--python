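"""Hypoxia occurrence, frequency classification, and timing of highest hazard.

Hypoxia is dissolved oxygen below 61 μmol/kg, evaluated on the minimum
oxygen concentration in the upper 200 m of each water column.  Occurrence
is the percentage of valid timesteps below the threshold, binned into five
frequency classes (No hypoxia / Episodic / Seasonal / Chronic / Persistent).
The timing diagnostics locate the calendar month and the Indian Ocean
Dipole (IOD) phase with the highest hazard; a phase is flagged as the
highest-risk phase only if its occurrence exceeds both others by at least
4 percentage points, otherwise the IOD influence is labelled "weak".
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Optional

import numpy as np
import pandas as pd

HYPOXIA_THRESHOLD = 61.0  # μmol/kg
IOD_DELTA_DEFAULT = 4.0  # percentage points

CLASS_NAMES = ("No hypoxia", "Episodic", "Seasonal", "Chronic", "Persistent")
PHASES = ("positive", "negative", "neutral")

#: IOD phase years (June 1 - May 31 windows, keyed by starting calendar year)
#: used throughout the 1980-2020 analyses; unlisted years are neutral.
DEFAULT_POSITIVE_YEARS = (1982, 1994, 1997, 2006, 2012, 2015, 2018, 2019)
DEFAULT_NEGATIVE_YEARS = (1992, 1996, 1998, 2010, 2016)


def min_o2_upper(o2, depths, zmax: float = 200.0):
    """Minimum oxygen over depth levels shallower than ``zmax``.

    ``o2`` has depth as its last axis.  Columns entirely shallower than
    ``zmax`` use every level; NaN levels are ignored; an all-NaN column
    propagates NaN (excluded later from occurrence denominators).
    """
    o2 = np.asarray(o2, dtype=float)
    depths = np.asarray(depths, dtype=float)
    if o2.shape[-1] != depths.size:
        raise ValueError("depth axis length mismatch")
    sel = depths <= zmax
    if not sel.any():  # column starts deeper than zmax: use whole column
        sel = np.ones_like(sel, dtype=bool)
    sub = o2[..., sel]
    all_nan = np.all(np.isnan(sub), axis=-1)
    with np.errstate(all="ignore"):
        out = np.nanmin(sub, axis=-1)
    return np.where(all_nan, np.nan, out)


def occurrence_percent(min_o2_series, threshold: float = HYPOXIA_THRESHOLD) -> float:
    """Percentage of valid timesteps with min O2 strictly below threshold."""
    x = np.asarray(min_o2_series, dtype=float).ravel()
    valid = np.isfinite(x)
    n = int(valid.sum())
    if n == 0:
        raise ValueError("occurrence_percent needs at least one valid timestep")
    return 100.0 * float(np.sum(x[valid] < threshold)) / n


def classify_occurrence(pct: float) -> str:
    """Map an occurrence percentage to its frequency class.

    Intervals are half-open on the left except Chronic, which includes the
    99% boundary: No hypoxia [0, 0.01), Episodic [0.01, 10), Seasonal
    [10, 50), Chronic [50, 99], Persistent (99, 100].
    """
    if not np.isfinite(pct) or pct < 0 or pct > 100:
        raise ValueError(f"occurrence percentage outside [0, 100]: {pct!r}")
    if pct < 0.01:
        return "No hypoxia"
    if pct < 10:
        return "Episodic"
    if pct < 50:
        return "Seasonal"
    if pct <= 99:
        return "Chronic"
    return "Persistent"


def month_of_highest_hazard(min_o2_series, months,
                            threshold: float = HYPOXIA_THRESHOLD) -> Optional[int]:
    """Calendar month with the highest pooled hypoxia percentage.

    Percentages are computed per month across all years; ties resolve to
    the earliest month. Returns None when no timestep is hypoxic.
    """
    x = np.asarray(min_o2_series, dtype=float).ravel()
    m = np.asarray(months).ravel()
    if x.size != m.size:
        raise ValueError("series and month labels differ in length")
    valid = np.isfinite(x)
    if not valid.any():
        raise ValueError("no valid timesteps")
    pct = np.zeros(12)
    for k in range(1, 13):
        inm = valid & (m == k)
        if inm.any():
            pct[k - 1] = 100.0 * np.sum(x[inm] < threshold) / inm.sum()
    if np.all(pct == 0):
        return None
    return int(np.argmax(pct)) + 1  # argmax returns first (earliest) max


@dataclass(frozen=True)
class PhaseCalendar:
    """Mapping of IOD years (June 1 - May 31) to phases.

    Years absent from the table are neutral.
    """

    table: Mapping[int, str] = field(default_factory=dict)

    def __post_init__(self):
        for y, p in self.table.items():
            if p not in PHASES:
                raise ValueError(f"unknown phase {p!r} for year {y}")

    def phase_of(self, iod_year):
        """Phase label(s) for IOD-year value(s)."""
        ys = np.atleast_1d(np.asarray(iod_year, dtype=int))
        out = np.array([self.table.get(int(y), "neutral") for y in ys], dtype=object)
        return out if np.ndim(iod_year) else str(out[0])

    def phase_of_dates(self, times):
        """Per-timestep labels for real calendar dates."""
        idx = pd.DatetimeIndex(times)
        iod_year = np.where(idx.month >= 6, idx.year, idx.year - 1)
        return self.phase_of(iod_year)


def build_phase_calendar(year_phase_table) -> PhaseCalendar:
    """Validate a (year, phase) table into a :class:`PhaseCalendar`.

    Accepts a mapping or an iterable of (year, phase) pairs; duplicate
    years raise.
    """
    if isinstance(year_phase_table, Mapping):
        pairs = list(year_phase_table.items())
    else:
        pairs = [(int(y), str(p)) for y, p in year_phase_table]
    years = [y for y, _ in pairs]
    if len(set(years)) != len(years):
        raise ValueError("duplicate IOD years in phase table")
    return PhaseCalendar(dict(pairs))


def default_phase_calendar() -> PhaseCalendar:
    table = {y: "positive" for y in DEFAULT_POSITIVE_YEARS}
    table.update({y: "negative" for y in DEFAULT_NEGATIVE_YEARS})
    return PhaseCalendar(table)


def per_phase_occurrence(min_o2_series, phase_labels,
                         threshold: float = HYPOXIA_THRESHOLD) -> dict:
    """Occurrence percentage within each IOD phase."""
    x = np.asarray(min_o2_series, dtype=float).ravel()
    lab = np.asarray(phase_labels, dtype=object).ravel()
    out = {}
    for p in PHASES:
        sel = (lab == p) & np.isfinite(x)
        out[p] = (100.0 * np.sum(x[sel] < threshold) / sel.sum()) if sel.any() else 0.0
    return out


def phase_of_highest_risk(per_phase_pct: Mapping[str, float],
                          delta: float = IOD_DELTA_DEFAULT) -> str:
    """Phase whose occurrence exceeds BOTH others by >= delta, else "weak".

    The margin requires a unique leader: two co-leading phases yield
    "weak" regardless of how far they sit above the third.
    """
    vals = {p: float(per_phase_pct[p]) for p in PHASES}
    for p in PHASES:
        others = [vals[q] for q in PHASES if q != p]
        if all(vals[p] - v >= delta for v in others):
            return p
    return "weak"


@dataclass(frozen=True)
class HazardSummary:
    """Per-location hypoxia hazard metrics."""

    occurrence_pct: float
    hazard_class: str
    peak_month: Optional[int]
    phase_risk: str
    per_phase_pct: dict

    def as_row(self) -> dict:
        row = {
            "occurrence_pct": self.occurrence_pct,
            "class": self.hazard_class,
            "peak_month": self.peak_month if self.peak_month is not None else "",
            "phase_risk": self.phase_risk,
        }
        row.update({f"pct_{p}": self.per_phase_pct[p] for p in PHASES})
        return row


def summarize_hazard(min_o2_series, months, iod_years,
                     calendar: Optional[PhaseCalendar] = None,
                     threshold: float = HYPOXIA_THRESHOLD,
                     delta: float = IOD_DELTA_DEFAULT) -> HazardSummary:
    """Full hazard summary for one oxygen-minimum series."""
    calendar = calendar if calendar is not None else default_phase_calendar()
    pct = occurrence_percent(min_o2_series, threshold)
    cls = classify_occurrence(pct)
    peak = month_of_highest_hazard(min_o2_series, months, threshold)
    phases = calendar.phase_of(np.asarray(iod_years))
    per_phase = per_phase_occurrence(min_o2_series, phases, threshold)
    risk = phase_of_highest_risk(per_phase, delta)
    return HazardSummary(pct, cls, peak, risk, per_phase)
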