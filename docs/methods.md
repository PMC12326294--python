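# Methods

`hypoxmap` implements a coastal hypoxia hazard analysis for dissolved-oxygen
time series: occurrence classification, timescale decomposition of the
oxygen-minimum signal, timing of highest hazard (calendar month and Indian
Ocean Dipole phase), driver attribution from a term-wise oxygen budget, and
mesoscale eddy diagnostics from sea-level anomaly (SLA). Because the
multi-decadal eddy-resolving hindcasts these methods are designed for are
far beyond desk scale, the package ships a synthetic coastal box simulator
and spatial fixture generators that reproduce the statistical structure the
methods are meant to detect; every stage is exercised and tested end to end
on those synthetic inputs.

## Hypoxia occurrence and classification

Hypoxia is dissolved oxygen strictly below 61 μmol/kg. All occurrence and
timing metrics operate on the minimum oxygen concentration in the upper
200 m of each column (`min_o2_upper`); columns shallower than 200 m use the
whole column, so shallow shelf signals are not silently dropped. Occurrence
is the percentage of valid timesteps below threshold; missing timesteps are
excluded from numerator and denominator alike.

Occurrence percentages map to five frequency classes. The published
interval styles overlap at their endpoints, so the package freezes one
convention — half-open on the left, except that Chronic includes 99%
exactly:

| class | interval |
|---|---|
| No hypoxia | [0, 0.01)% |
| Episodic | [0.01, 10)% |
| Seasonal | [10, 50)% |
| Chronic | [50, 99]% |
| Persistent | (99, 100]% |

Values equal to 61 μmol/kg are *not* hypoxic (the threshold is quoted as a
strict "< 61" everywhere it is defined).

## Timing of highest hazard

The peak-hazard month is the calendar month with the highest pooled
hypoxia percentage across all years; ties resolve deterministically to the
earliest month. IOD years span June 1 – May 31 (the IOD peaks in fall) and
are labelled positive/negative/neutral from a year→phase table; the
built-in calendar lists 1982/83, 1994/95, 1997/98, 2006/07, 2012/13,
2015/16, 2018/19, 2019/20 as positive and 1992/93, 1996/97, 1998/99,
2010/11, 2016/17 as negative, with unlisted years neutral. Phases are
consumed, never derived: the package does not compute a Dipole Mode Index.

A phase is the phase of highest risk only if its occurrence exceeds *both*
others by at least 4 percentage points (at weekly sampling, roughly two
extra hypoxic timesteps — small enough to matter, large enough not to be
noise); the rule demands a unique leader, so two co-leading phases yield
"weak" regardless of the third.

## Timescale decomposition

Variability is reported as 2σ of the band-filtered oxygen-minimum series in
three bands: intraseasonal 14–120 days, seasonal 4–12 months (120–365 days),
interannual 1–5 years (365–1825 days). The filter is a 4th-order
Butterworth bandpass applied forward–backward (zero phase), after linear
detrending (so trends cannot masquerade as interannual variability) and
reflect padding by one long-period length; the first and last half
long-period of output are excluded from σ so edge transients never enter
the statistics.

Two numerical choices deserve note:

- **Nyquist edge.** Weekly sampling places the 14-day band edge exactly at
  the Nyquist period. The filter accepts dt = low_period/2 and clamps the
  normalized upper edge to 0.98 (a band-edge shift from 14.0 to ~14.3 days)
  so the design remains valid; anything coarser raises an error naming the
  violated precondition.
- **Annual-cycle ownership.** The annual harmonic sits exactly on the
  nominal 12-month seasonal/interannual boundary. A zero-phase 4th-order
  filter with its half-power edge right there splits the annual peak
  equally between the two bands, which contradicts what "seasonal" and
  "interannual" are meant to measure. The decomposition therefore places
  the half-power edge of that split at 456 days (~15 months): the annual
  harmonic retains ≥ 85% of its amplitude in the seasonal band and leaks
  ≤ 15% into the interannual band. The nominal band definitions are still
  reported in `VariabilityReport.bands`; `bandpass` itself is generic and
  takes explicit periods.

Records shorter than 15 years omit the interannual entry with a warning
rather than reporting an unstable value. Gaps of up to two consecutive
missing weeks may be filled linearly (`fill_short_gaps`); longer gaps are
left to fail the length preconditions.

## Oxygen budget and driver attribution

The budget closes as ∂tO₂ = ∂tO₂_phys + ∂tO₂_bio + F_airsea, with
∂tO₂_bio = PP + WCR + SOD + Nitrif (primary production a source; water
column respiration, sediment oxygen demand and nitrification sinks).
Advective and diffusive transport are not separated: the physical term is a
single aggregate. `residual_check` exposes the max closure residual as a
data-quality gate for ingested budgets.

Attribution works on depth-averaged series over a region-appropriate layer
(40–200 m for shelf boxes, 5–20 m for shallow river-plume boxes), with
layer-thickness weights and partial-overlap handling. The oxygen change
dO₂ is a centered finite difference (one-sided at the ends). Physical and
biological anomalies subtract each series' record-long mean; a
per-calendar-year baseline is available as an option, but the record mean
is the default because it introduces no December/January discontinuity.

The sign rule labels each timestep:

- **physical** — sign(dO₂) = sign(phys′) ≠ sign(bio′);
- **biological** — sign(dO₂) = sign(bio′) ≠ sign(phys′);
- **both** — sign(phys′) = sign(bio′) = sign(dO₂);
- **undetermined** — an anomaly lies inside the dead-band, or dO₂'s sign
  matches neither anomaly (e.g. an air–sea- or residual-driven change).

The dead-band defaults to 10⁻³ × each anomaly's record standard deviation:
the sign of near-zero noise carries no information. Labels are invariant
under any common positive rescaling of the three inputs.

## Eddy diagnostics

The SLA field is high-passed by subtracting a Gaussian-smoothed copy. The
smoothing scale is σ = 0.4 × cutoff wavelength (120 km for the 300 km
cutoff): this suppresses basin-scale signals (≥ 10× the cutoff) by more
than 90% while preserving ≥ 85% of the amplitude of mesoscale bumps
narrower than about a third of the cutoff — a sigma tied literally to a
300-km half-power point would remove a quarter of a 60-km eddy's
amplitude, defeating the filter's purpose.

Detection mirrors closed-contour SLA trackers at reduced complexity.
Candidate cores are local extrema with topographic prominence at or above
the amplitude threshold, computed by a union-find persistence sweep —
noise dimples riding on an eddy's flank die in the sweep almost
immediately and cannot terminate a contour search. Each candidate is grown
through discrete SLA levels (0.005 m) until its enclosing contour opens
onto the domain boundary or absorbs a competing candidate; the outermost
closed contour defines the eddy. Amplitude is |extremum − outermost
level|; the equivalent radius comes from the enclosed area; the centroid
is the SLA-anomaly-weighted center of the enclosed region (robust to noise
displacing the discrete extremum). Cyclones are SLA lows. Defaults:
min amplitude 0.02 m, min radius 30 km. There is no temporal tracking —
each snapshot is detected independently, as the compositing analysis only
needs instantaneous centroids.

Composites average oxygen profiles (0–200 m) beneath the centroids of each
polarity and subtract a reference profile (domain mean by default). With a
raised oxycline under cyclones the cyclonic composite anomaly is negative
at oxycline depths, and the anticyclonic mirror case is positive.

## Synthetic coastal box simulator

The simulator generates weekly, multi-decadal series for one coastal
column with the budget closed *by construction*: tendencies are computed
term by term, stored, summed into the total, and the oxygen field is the
forward time-integral of that stored total. Re-integrating the stored
budget reproduces the stored oxygen to ≤ 10⁻⁹ μmol/kg.

- **Calendar** — years of exactly 52 weeks (364 days) with civil month
  lengths, so weekly sampling divides every year evenly and no filter
  window straddles a leap-week; real-calendar data enters through a
  separate conversion path.
- **Physical term** — relaxation (exact exponential update per step)
  toward a target profile depressed by an upwelling drawdown
  D(t) = seasonal raised-cosine + band-limited intraseasonal noise +
  a step offset in flagged IOD-phase years + white noise, applied below a
  configurable depth ramp. The forcing functional forms are this package's
  own constructions; only their timescales and signs are constrained by
  the phenomenology they emulate.
- **Biological term** — consumption (WCR 60%, SOD 25% at the deepest
  level, nitrification 15%) proportional to primary production, which
  follows the runoff seasonal cycle (river regimes) or the upwelling cycle
  (shelf regimes) lagged by `bio_lag_days` (default 30 d); production adds
  oxygen in the surface layers. `bio_amp` is the peak consumption rate in
  μmol/kg/day.
- **Air–sea flux** — linear restoring of the surface layer toward a fixed
  saturation value (210 μmol/kg); the simplest closure for the flux term.
- **SLA** — proportional to minus the normalized drawdown plus small
  noise, so negative SLA coincides with upwelling by construction.
- **Low-oxygen floor** — oxygen-consuming tendencies are scaled by the
  smooth factor (eʳ − 1)/r, where r ≤ 0 is the fraction of available
  oxygen the step would consume. The state update is then
  o2 → (o2 + dt·sources)·eʳ, positive for any forcing, and closure is
  untouched because the damped tendencies are what is stored. Steps ending
  below the diagnostic `o2_floor` (10 μmol/kg) are counted.
- **Reproducibility** — one integer seed; each stochastic component draws
  from its own deterministic child stream, so runs are bit-identical for
  identical (config, seed).

### Regime presets

Preset constants (`data/presets.yml`) are repository fixtures chosen once
to land each regime in its documented hazard class and peak-hazard window;
they are not published model or field values, and none of the qualitative
fingerprints depends on a particular seed:

- **EAS** (eastern Arabian Sea): strong seasonal upwelling drawdown peaking
  in August → "Seasonal" class (~35% occurrence), hypoxia June–September,
  seasonal 2σ ≈ 75 μmol/kg with intraseasonal roughly half and interannual
  weakest; extra drawdown in negative-IOD years.
- **WBoB** (western Bay of Bengal): moderate April-peaking seasonal cycle
  with comparable intraseasonal variability (2σ ratio ~0.65) → episodic
  spring hypoxia.
- **EBoB** (eastern Bay of Bengal): mild spring seasonal cycle with a
  large positive-IOD drawdown, so hypoxia is almost exclusive to
  positive-phase years.
- **GB** (Ganges–Brahmaputra plume): shallow column (budget layer 5–20 m);
  biological consumption driven by production lagging the July runoff peak
  by ~1 month, with weak physical relaxation (τ = 40 d) so consumption
  accumulates → "Chronic" occurrence with a July–October hazard window.

### What the simulator does and does not emulate

It reproduces weekly sampling over multi-decadal spans, a seasonal
subsurface drawdown anticorrelated with SLA, band-limited intraseasonal
fluctuations, interannual modulation tied to labelled IOD years, lagged
runoff-driven biological consumption, and exact budget closure. It has no
3-D circulation, no separate advection/diffusion operators, no ecosystem
state variables, no realistic bathymetry, and a single column per regime.
Passing tests therefore demonstrate that the *analysis chain* recovers
structure that is present by construction — not that real coastal oxygen
behaves like the simulator.

## Regions and masks

A cell is coastal if it lies within 100 km of shore *or* inshore of the
1000 m isobath (whichever reaches farther). "Inshore of the isobath" is a
coast-connected shallow component (flood fill from land-adjacent cells), so
detached shallow seamounts are excluded. Region labels: BoB-DR takes
precedence where 85–97° E and annual surface salinity < 29; EAS is south
of 18° N and west of 79° E; the WBoB/EBoB split is not pinned down by the
region definitions, so the defaults (WBoB west of 85° E, EBoB east of
92° E) are configurable. The four 1°×1° case-study boxes are fixed; the
Irrawaddy–Sittang box has no published corners and is only included when
passed explicitly.

## Problem sizes

Default analyses run 41-year weekly records (2132 steps × ≤ 12 depths) per
regime; the eddy benchmark uses a 200×160 grid at 6 km spacing with 20
planted eddies; the closure sweep uses 100 random 1–3-year configurations.
The full test suite and the acceptance script each complete in well under
a minute of CPU apiece for any fixed seed.

## Known limitations

- The attribution rule is sign-based: when physics and biology genuinely
  cooperate, it reports "both" rather than apportioning magnitudes.
- Filter behaviour within ~half an octave of band edges depends on the
  (unpublished) original filter choice; mid-band results do not.
- The eddy detector is not a published tracker reimplementation: no
  lifetime tracking, no merging/splitting, no shape criteria beyond the
  closed contour.
- The simulator's IOD response is a step offset per phase year; real
  events ramp up and decay within a season.
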