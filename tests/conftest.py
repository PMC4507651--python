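"""Shared scene fixtures.

The heavier simulated-scene batteries are session-scoped: the same
scenes back several independent checks (bound, recovery, statistics),
mirroring how a field campaign's plots serve multiple analyses.
"""

import numpy as np
import pytest

import canoheight as ch


@pytest.fixture(scope="session")
def flat_run():
    """Flat, noiseless, smooth scene: the correction must be a no-op."""
    spec = ch.random_forest_scene(seed=1, slope_deg=0.0, n_trees=3,
                                  noise_sd_z=0.0)
    return ch.run_scene(spec)


@pytest.fixture(scope="session")
def slope30_run():
    """Noiseless planar 30-degree scene for closed-form geometry checks."""
    spec = ch.random_forest_scene(seed=3, slope_deg=30.0, n_trees=3,
                                  noise_sd_z=0.0)
    return ch.run_scene(spec)


@pytest.fixture(scope="session")
def bench20():
    """20 seeded plot scenes, slopes 10-40 deg, crowns 3-10 m, 15 p/m2,
    sensor-grade 0.04 m ranging noise; full pipeline on each."""
    runs = []
    for s in range(20):
        slope = 10 + 30 * s / 19
        spec = ch.random_forest_scene(seed=100 + s, slope_deg=slope,
                                      n_trees=4, crown_range=(3.0, 10.0),
                                      noise_sd_z=0.04)
        runs.append(ch.run_scene(spec))
    return runs


@pytest.fixture(scope="session")
def slope_battery():
    """20 scenes with fixed 8 m crowns across slopes 0-40 deg, with the
    per-scene exceedance proportions p_k of the normalization
    difference."""
    slopes, stats = [], []
    for s in range(20):
        slope = 40 * s / 19
        spec = ch.random_forest_scene(seed=200 + s, slope_deg=slope,
                                      n_trees=4, crown_range=(8.0, 8.0),
                                      noise_sd_z=0.04)
        run = ch.run_scene(spec)
        ds = ch.difference_stats(run.result.conventional, run.result.corrected)
        slopes.append(slope)
        stats.append(ds)
    return np.asarray(slopes), stats
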