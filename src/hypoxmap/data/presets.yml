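# Regime presets for the synthetic coastal oxygen simulator.
#
# Each preset encodes the qualitative fingerprint of one coastal regime of
# the northern Indian Ocean:
#   EAS  - eastern Arabian Sea shelf: strong seasonal upwelling drawdown,
#          summer/fall hypoxia, weaker intraseasonal/interannual signals,
#          deeper drawdown during negative-IOD years.
#   WBoB - western Bay of Bengal shelf: moderate spring seasonal signal with
#          comparable intraseasonal fluctuations (episodic hypoxia).
#   EBoB - eastern Bay of Bengal (Andaman Sea): mild spring seasonal cycle;
#          hypoxia almost exclusively during positive-IOD years.
#   GB   - Ganges-Brahmaputra river plume: shallow column, oxygen drawdown
#          driven by biological consumption fueled by primary production
#          that lags the July runoff peak by ~1 month; summer/fall hypoxia.
#
# Amplitudes are repository constants chosen once to land each regime in its
# documented hazard class and peak-hazard window; they are not published
# model or field values.

EAS:
  depth_levels: [5, 10, 20, 30, 40, 60, 80, 100, 125, 150, 175, 200]
  o2_baseline: [210, 205, 195, 185, 175, 165, 160, 155, 150, 148, 145, 140]
  seasonal_amp: 110.0
  seasonal_peak_month: 8
  intraseasonal_amp: 35.0
  iod_delta: 12.0
  iod_sensitive_phase: negative
  river_amp: 0.0
  runoff_peak_month: 7
  bio_lag_days: 30.0
  bio_amp: 0.3
  noise_sd: 3.0
  budget_depth_range: [40, 200]
  drawdown_ramp: [10, 40]
  phys_tau_days: 10.0
  airsea_tau_days: 10.0

WBoB:
  depth_levels: [5, 10, 20, 30, 40, 60, 80, 100, 125, 150, 175, 200]
  o2_baseline: [210, 204, 192, 180, 168, 150, 138, 126, 115, 108, 103, 100]
  seasonal_amp: 28.0
  seasonal_peak_month: 4
  intraseasonal_amp: 14.0
  iod_delta: 10.0
  iod_sensitive_phase: positive
  river_amp: 0.0
  runoff_peak_month: 7
  bio_lag_days: 30.0
  bio_amp: 0.2
  noise_sd: 3.0
  budget_depth_range: [40, 200]
  drawdown_ramp: [10, 40]
  phys_tau_days: 10.0
  airsea_tau_days: 10.0

EBoB:
  depth_levels: [5, 10, 20, 30, 40, 60, 80, 100, 125, 150, 175, 200]
  o2_baseline: [208, 202, 190, 176, 162, 140, 124, 110, 98, 92, 88, 85]
  seasonal_amp: 18.0
  seasonal_peak_month: 3
  intraseasonal_amp: 6.0
  iod_delta: 45.0
  iod_sensitive_phase: positive
  river_amp: 0.0
  runoff_peak_month: 7
  bio_lag_days: 30.0
  bio_amp: 0.2
  noise_sd: 2.0
  budget_depth_range: [40, 200]
  drawdown_ramp: [10, 40]
  phys_tau_days: 10.0
  airsea_tau_days: 10.0

GB:
  depth_levels: [2, 5, 8, 12, 16, 20, 25]
  o2_baseline: [180, 170, 160, 150, 140, 132, 125]
  seasonal_amp: 25.0
  seasonal_peak_month: 7
  intraseasonal_amp: 8.0
  iod_delta: 0.0
  iod_sensitive_phase: none
  river_amp: 1.0
  runoff_peak_month: 7
  bio_lag_days: 30.0
  bio_amp: 3.0
  noise_sd: 3.0
  budget_depth_range: [5, 20]
  drawdown_ramp: [3, 10]
  phys_tau_days: 40.0
  airsea_tau_days: 10.0
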