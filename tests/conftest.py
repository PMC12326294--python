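import numpy as np
import pytest

import hypoxmap as hm


@pytest.fixture(scope="session")
def eas_sim():
    """41-year EAS-preset simulation, fixed seed (shared, read-only)."""
    return hm.simulate_box(hm.preset_regime("EAS", seed=0))


@pytest.fixture(scope="session")
def gb_sim():
    return hm.simulate_box(hm.preset_regime("GB", seed=0))


@pytest.fixture(scope="session")
def wbob_sim():
    return hm.simulate_box(hm.preset_regime("WBoB", seed=0))


@pytest.fixture(scope="session")
def ebob_sim():
    return hm.simulate_box(hm.preset_regime("EBoB", seed=0))


@pytest.fixture(scope="session")
def eddy_scene():
    """Standard 20-eddy SLA fixture with planted truth."""
    spec = hm.standard_eddy_fixture(seed=0)
    sla, truth = hm.make_sla_field(spec)
    return spec, sla, truth


def random_config(rng: np.random.Generator) -> hm.RegimeConfig:
    """A random, valid simulator configuration (for closure sweeps)."""
    nz = rng.integers(3, 9)
    depths = np.sort(rng.uniform(2, 250, nz))
    depths += np.arange(nz)  # enforce strict increase
    base = rng.uniform(80, 220, nz)
    return hm.RegimeConfig(
        duration_years=int(rng.integers(1, 4)),
        depth_levels=tuple(depths),
        o2_baseline=tuple(base),
        seasonal_amp=float(rng.uniform(0, 120)),
        seasonal_peak_month=int(rng.integers(1, 13)),
        intraseasonal_amp=float(rng.uniform(0, 30)),
        iod_delta=float(rng.uniform(0, 40)),
        iod_sensitive_phase=str(rng.choice(["positive", "negative", "none"])),
        river_amp=float(rng.uniform(0, 2)),
        bio_amp=float(rng.uniform(0, 3)),
        noise_sd=float(rng.uniform(0, 5)),
        budget_depth_range=(float(depths[0]), float(depths[-1])),
        seed=int(rng.integers(0, 2**31 - 1)),
    )


def score_detections(records, truth, max_dist_cells=1.0):
    """Recall / polarity precision / max centroid error vs. planted truth.

    Centroid error uses the Chebyshev distance (cells), so "within one
    grid cell" allows a diagonal neighbour.
    """
    hits = 0
    polarity_ok = 0
    max_err = 0.0
    for _, e in truth.iterrows():
        best = None
        for r in records:
            d = max(abs(r.centroid_index[0] - e.row),
                    abs(r.centroid_index[1] - e.col))
            if best is None or d < best[0]:
                best = (d, r)
        if best is not None and best[0] <= max_dist_cells:
            hits += 1
            max_err = max(max_err, best[0])
            want = "cyclonic" if e.sign < 0 else "anticyclonic"
            polarity_ok += best[1].polarity == want
    recall = hits / len(truth)
    precision = polarity_ok / hits if hits else 0.0
    return recall, precision, max_err
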