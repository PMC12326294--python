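"""Simulator contracts: budget closure, determinism, forcing placement and
the qualitative fingerprints of the four regime presets."""

import numpy as np
import pytest

import hypoxmap as hm
from hypoxmap.simulator import SECONDS_PER_DAY

from conftest import random_config


def reintegrate(ds):
    dt = float(ds.attrs["dt_days"]) * SECONDS_PER_DAY
    return ds["o2"].values[0] + np.cumsum(
        ds["do2_total"].values[:-1] * dt, axis=0)


class TestPresets:
    def test_budget_depth_ranges(self):
        assert hm.preset_regime("GB").budget_depth_range == (5, 20)
        assert hm.preset_regime("EAS").budget_depth_range == (40, 200)

    def test_eas_peaks_in_summer(self):
        assert hm.preset_regime("EAS").seasonal_peak_month in range(6, 10)

    def test_unknown_preset(self):
        with pytest.raises(ValueError, match="EAS"):
            hm.preset_regime("XYZ")

    def test_invalid_configs_rejected(self):
        with pytest.raises(ValueError):
            hm.RegimeConfig(depth_levels=(10, 5), o2_baseline=(100, 100))
        with pytest.raises(ValueError):
            hm.RegimeConfig(seasonal_amp=-1)
        with pytest.raises(ValueError):
            hm.RegimeConfig(seasonal_amp=float("nan"))
        with pytest.raises(ValueError):
            hm.RegimeConfig(budget_depth_range=(0, 500))


class TestBudgetClosure:
    def test_closure_and_reintegration_random_configs(self):
        """Total tendency = sum of stored terms, and integrating the stored
        budget reproduces the stored oxygen, across random configs."""
        rng = np.random.default_rng(1234)
        for _ in range(25):
            cfg = random_config(rng)
            ds = hm.simulate_box(cfg).data
            total = ds["do2_total"].values
            parts = (ds["do2_phys"] + ds["do2_bio"] + ds["do2_airsea"]).values
            scale = max(np.abs(total).max(), 1e-30)
            assert np.max(np.abs(total - parts)) <= 1e-12 * scale
            assert np.max(np.abs(reintegrate(ds) - ds["o2"].values[1:])) \
                <= 1e-9

    def test_bio_components_sum_and_signs(self, gb_sim):
        ds = gb_sim.data
        comp = (ds["bio_pp"] + ds["bio_wcr"] + ds["bio_sod"]
                + ds["bio_nitrif"]).values
        assert np.array_equal(comp, ds["do2_bio"].values)
        assert ds["bio_pp"].values.min() >= 0
        for sink in ("bio_wcr", "bio_sod", "bio_nitrif"):
            assert ds[sink].values.max() <= 0

    def test_oxygen_stays_nonnegative(self):
        for name in ("EAS", "WBoB", "EBoB", "GB"):
            sim = hm.simulate_box(hm.preset_regime(name, seed=2))
            assert sim.data["o2"].values.min() >= 0


class TestDeterminism:
    def test_identical_seed_bit_identical(self):
        a = hm.simulate_box(hm.preset_regime("WBoB", seed=7)).data
        b = hm.simulate_box(hm.preset_regime("WBoB", seed=7)).data
        for v in a.data_vars:
            assert np.array_equal(a[v].values, b[v].values), v

    def test_different_seed_differs(self):
        a = hm.simulate_box(hm.preset_regime("WBoB", seed=7)).data
        c = hm.simulate_box(hm.preset_regime("WBoB", seed=8)).data
        assert (a["o2"].values != c["o2"].values).any()


class TestForcing:
    def test_zero_forcing_constant_oxygen(self):
        cfg = hm.RegimeConfig(duration_years=2, seasonal_amp=0,
                              intraseasonal_amp=0, iod_delta=0, river_amp=0,
                              bio_amp=0, noise_sd=0, airsea_tau_days=None)
        ds = hm.simulate_box(cfg).data
        assert np.allclose(ds["o2"].values,
                           np.asarray(cfg.o2_baseline)[None, :])
        assert np.all(ds["do2_total"].values == 0)

    @pytest.mark.parametrize("peak_month", [2, 8, 12])
    def test_seasonal_min_month_matches_peak(self, peak_month):
        """With only seasonal forcing, the annual oxygen minimum falls in
        the configured peak upwelling month, every year."""
        cfg = hm.RegimeConfig(duration_years=4, seasonal_amp=60,
                              seasonal_peak_month=peak_month,
                              intraseasonal_amp=0, iod_delta=0, river_amp=0,
                              bio_amp=0, noise_sd=0, airsea_tau_days=None,
                              phys_tau_days=3.0)
        sim = hm.simulate_box(cfg)
        m = sim.min_o2
        months = sim.data["month"].values
        years = sim.data["year"].values
        for y in np.unique(years)[1:]:  # skip the spin-in year
            sel = years == y
            assert months[sel][np.argmin(m[sel])] == peak_month

    def test_intraseasonal_variance_in_band(self):
        """With only intraseasonal forcing, >=80% of subsurface oxygen
        variance lies in the 14-120 day band (FFT periodogram)."""
        cfg = hm.RegimeConfig(duration_years=20, seasonal_amp=0,
                              intraseasonal_amp=10, iod_delta=0,
                              river_amp=0, bio_amp=0, noise_sd=0,
                              airsea_tau_days=None, seed=3)
        ds = hm.simulate_box(cfg).data
        x = ds["o2"].values[:, -1]
        x = x - x.mean()
        freq = np.fft.rfftfreq(x.size, d=cfg.dt_days)
        power = np.abs(np.fft.rfft(x)) ** 2
        inband = (freq >= 1 / 120) & (freq <= 1 / 14)
        assert power[inband].sum() / power[1:].sum() >= 0.8

    def test_sla_anticorrelated_with_upwelling(self, eas_sim):
        """Negative SLA marks upwelling: SLA correlates positively with
        subsurface oxygen (and negatively with its drawdown)."""
        ds = eas_sim.data
        r = np.corrcoef(ds["sla"].values, ds["o2"].values[:, -1])[0, 1]
        assert r > 0.5


class TestRegimeFingerprints:
    def test_eas_seasonal_class_and_summer_peak(self, eas_sim):
        summ = hm.summarize_hazard(eas_sim.min_o2,
                                   eas_sim.data["month"].values,
                                   eas_sim.data["iod_year"].values)
        assert summ.hazard_class == "Seasonal"
        assert summ.peak_month in (6, 7, 8, 9)

    def test_wbob_intraseasonal_comparable_and_spring_peak(self, wbob_sim):
        rep = hm.decompose(wbob_sim.min_o2, 7.0)
        ratio = rep.intraseasonal_2sigma / rep.seasonal_2sigma
        assert 0.5 <= ratio <= 2.0
        peak = hm.month_of_highest_hazard(wbob_sim.min_o2,
                                          wbob_sim.data["month"].values)
        assert peak in (3, 4, 5)

    def test_ebob_hypoxia_tied_to_positive_iod(self, ebob_sim):
        cal = hm.default_phase_calendar()
        phases = cal.phase_of(ebob_sim.data["iod_year"].values)
        per = hm.per_phase_occurrence(ebob_sim.min_o2, phases)
        assert per["positive"] > per["negative"]

    def test_gb_summer_fall_peak_and_intpp_lag(self, gb_sim):
        peak = hm.month_of_highest_hazard(gb_sim.min_o2,
                                          gb_sim.data["month"].values)
        assert peak in (7, 8, 9, 10)
        ip = gb_sim.data["intpp"].values
        ro = gb_sim.data["runoff"].values
        ip = ip - ip.mean()
        ro = ro - ro.mean()
        lags = np.arange(-26, 27)
        cc = [np.corrcoef(np.roll(ro, k), ip)[0, 1] for k in lags]
        lag_days = lags[int(np.argmax(cc))] * 7.0
        assert abs(lag_days - gb_sim.config.bio_lag_days) <= 7.0


class TestNetcdfRoundTrip:
    def test_write_read_preserves_schema(self, tmp_path, gb_sim):
        path = tmp_path / "box.nc"
        gb_sim.to_netcdf(path)
        ds = hm.read_box_netcdf(path)
        for v in ("o2", "sla", "intpp", "runoff", "do2_total", "do2_phys",
                  "do2_bio", "do2_airsea", "bio_pp", "bio_wcr", "bio_sod",
                  "bio_nitrif"):
            assert v in ds
            assert "units" in ds[v].attrs
            np.testing.assert_allclose(ds[v].values, gb_sim.data[v].values,
                                       rtol=0, atol=0)
        assert tuple(ds.attrs["budget_depth_range"]) == (5, 20)
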