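import numpy as np
import pandas as pd
import pytest

import eaglestates as es


@pytest.fixture(scope="session")
def landscape():
    """Moderate-resolution landscape; domain still dwarfs the longest step."""
    cfg = es.LandscapeConfig(n_cells=256, cell_size_m=960.0, seed=7)
    return es.make_landscape(cfg)


@pytest.fixture(scope="session")
def terrain_layers(landscape):
    from eaglestates.terrain import classify_tpi, derive_terrain
    layers = derive_terrain(landscape.dem)
    layers_tpi = classify_tpi(layers["tpi"], layers["slope"])
    return layers, layers_tpi


@pytest.fixture(scope="session")
def small_sim():
    return es.SimConfig(n_birds=2, fixes_per_bird=1500, seed=3)


@pytest.fixture(scope="session")
def small_tracks(landscape, small_sim):
    fixes, truth = es.simulate_tracks(landscape, es.default_states(), small_sim)
    return fixes, truth


@pytest.fixture(scope="session")
def corrupted_tracks(landscape, small_tracks, small_sim):
    fixes, truth = small_tracks
    corrupted, ledger = es.corrupt_fixes(fixes, small_sim)
    return corrupted, ledger, truth


def _ar1(n, mu, sigma, rho, rng):
    x = np.empty(n)
    x[0] = mu + sigma * rng.standard_normal()
    c = sigma * np.sqrt(1 - rho ** 2)
    for i in range(1, n):
        x[i] = mu + rho * (x[i - 1] - mu) + c * rng.standard_normal()
    return x


@pytest.fixture(scope="session")
def ar1():
    return _ar1


def make_steps_frame(x, dt_h=0.25, burst=0, bird="b1"):
    """Wrap a raw persistence-velocity series as a step table."""
    return pd.DataFrame({
        "fix_id": np.arange(len(x)),
        "bird_id": bird,
        "t": pd.date_range("2015-06-01 15:00", periods=len(x), freq="15min"),
        "x": 0.0, "y": 0.0,
        "dt_h": dt_h,
        "speed_kmh": np.abs(x),
        "turn_deg": 0.0, "turn_abs_deg": 0.0, "turn_defined": True,
        "vp_kmh": x,
        "agl_m": 10.0,
        "burst": burst,
    })


@pytest.fixture(scope="session")
def steps_frame():
    return make_steps_frame
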