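import numpy as np
import pandas as pd
import pytest

from exposeg import CityConfig, generate_city, generate_traces


@pytest.fixture(scope="session")
def tiny_city_cfg():
    """Small noiseless city without duplicate devices: ground truth equals
    what detection should find."""
    return CityConfig(n_individuals=80, n_tracts=9, n_pois=15, n_hubs=3,
                      n_days=4, accuracy_noise_sd=0.0,
                      duplicate_device_frac=0.0, seed=3)


@pytest.fixture(scope="session")
def tiny_city(tiny_city_cfg):
    city = generate_city(tiny_city_cfg)
    pings, events = generate_traces(city)
    return city, pings, events


@pytest.fixture(scope="session")
def noisy_city():
    """Small city with positional noise and duplicate devices, for the
    inference-side tests."""
    cfg = CityConfig(n_individuals=100, n_tracts=9, n_pois=15, n_hubs=3,
                     n_days=5, accuracy_noise_sd=20.0,
                     duplicate_device_frac=0.02, seed=4)
    city = generate_city(cfg)
    pings, _ = generate_traces(city, compute_truth=False)
    return city, pings


def make_random_pings(rng, n, n_users, span_s=3600, extent_m=400,
                      lat0=38.0, lon0=-95.0):
    """Random ping cloud dense enough to produce plenty of crossings."""
    return pd.DataFrame({
        "user_id": np.array([f"u{int(u):03d}"
                             for u in rng.integers(0, n_users, n)]),
        "timestamp_s": rng.integers(0, span_s, n).astype(np.int64),
        "lat": lat0 + rng.uniform(0, extent_m / 111_320.0, n),
        "lon": lon0 + rng.uniform(0, extent_m / 87_800.0, n),
        "accuracy_m": np.full(n, 10.0),
    })


@pytest.fixture
def random_pings_factory():
    return make_random_pings
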