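# hypoxmap

Coastal hypoxia hazard mapping and driver attribution for dissolved-oxygen
time series, built for the northern Indian Ocean's coastal regimes
(eastern Arabian Sea, western and eastern Bay of Bengal, and the large
river deltas) but applicable to any coastal oxygen record with depth and
time coordinates.

Coastal "dead zones" — waters with dissolved oxygen below 61 μmol/kg —
devastate fisheries and benthic ecosystems, and their hazard differs
radically by region: some shelves go hypoxic on schedule every summer with
the seasonal upwelling, others only in particular Indian Ocean Dipole (IOD)
years, others in unpredictable two-to-four-week bursts driven by coastal
currents and mesoscale eddies, and river plumes in step with peak
discharge. `hypoxmap` turns a weekly oxygen/SLA/production/runoff record
into exactly that characterization, for researchers and monitoring
programs who need to know *when* and *why* a stretch of coast is at risk.

## What it computes

Working on the minimum oxygen concentration in the upper 200 m, O₂min(t):

- **Occurrence and class** — % of timesteps with O₂min < 61 μmol/kg,
  classified as No hypoxia (< 0.01%), Episodic (0.01–10%), Seasonal
  (10–50%), Chronic (50–99%) or Persistent (> 99%).
- **Timescale decomposition** — 2σ of O₂min bandpass-filtered to
  intraseasonal (14–120 d), seasonal (4–12 months) and interannual
  (1–5 yr) bands (zero-phase 4th-order Butterworth).
- **Timing of highest hazard** — the calendar month with the highest
  pooled hypoxia percentage, and the IOD phase (June 1–May 31 years) whose
  occurrence exceeds both others by ≥ 4 percentage points ("weak"
  otherwise).
- **Driver attribution** — from a closed oxygen budget
  ∂tO₂ = ∂tO₂phy + ∂tO₂bio + F, each timestep of the depth-averaged
  record is labelled physically driven (sign(∂tO₂) = sign(∂tO₂phy′) ≠
  sign(∂tO₂bio′)), biologically driven (the mirror case), "both" (the
  anomalies agree in sign), or undetermined.
- **Eddy diagnostics** — closed-contour detection of cyclones and
  anticyclones in high-passed sea-level anomaly, and composite oxygen
  profiles beneath their centroids.
- **Regions and masks** — the coastal band (within 100 km of shore or
  inshore of the 1000 m isobath), region labels (EAS / WBoB / BoB-DR /
  EBoB) and the 1°×1° case-study boxes.

A bundled synthetic coastal box simulator (`simulate_box` with presets
EAS, WBoB, EBoB, GB) generates budget-closed weekly records that carry
each regime's statistical fingerprint, so the whole chain runs and is
tested without any external data. See `docs/methods.md` for the model,
parameter and numerical details.

## Worked example

Simulate 41 years of the eastern Arabian Sea regime and run the analysis:

```sh
$ hypoxmap simulate --regime EAS --years 41 --seed 0 --out box.nc
wrote box.nc (2132 weekly steps, 29 low-oxygen damping events)

$ hypoxmap hazard --in box.nc --out hazard.csv
occurrence 35.23% -> Seasonal; peak month 8; IOD risk negative

$ hypoxmap variability --in box.nc --out var.csv
2-sigma total 83.7 umol/kg

$ hypoxmap attribute --in box.nc --out attrib.csv
physical: 39.4%, biological: 14.1%, both: 32.4%, undetermined: 14.2%
```

Reading the numbers: the column is hypoxic 35% of the time — a *Seasonal*
regime — with the hazard peaking in August (month 8) and deepening in
negative-IOD years. The variability report (`var.csv`) splits the total
2σ of 83.7 μmol/kg into seasonal 74.7, intraseasonal 31.2 and interannual
7.7 μmol/kg: the seasonal upwelling cycle dominates, so this regime's
hypoxia is predictable. The attribution fractions confirm that physical
transport, not biology, leads the oxygen declines.

The same stages are available as library calls (`hypoxmap.simulate_box`,
`hypoxmap.summarize_hazard`, `hypoxmap.decompose`,
`hypoxmap.attribute_box`, `hypoxmap.detect_eddies`, ...), and
`hypoxmap run` executes the full pipeline into an output directory with a
checksummed provenance manifest. Gridded I/O is CF-style NetCDF; tabular
I/O is CSV.

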