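import numpy as np
import pytest
from hypothesis import HealthCheck, settings

import stidw

settings.register_profile(
    "ci", deadline=None, derandomize=True,
    suppress_health_check=[HealthCheck.too_slow])
settings.load_profile("ci")

# printed extent of the 2009 CONUS monitoring network
CONUS = (-124.1775, -68.0162, 25.4714, 48.3997)


@pytest.fixture(scope="session")
def conus_bbox():
    return CONUS


@pytest.fixture(scope="session")
def small_field():
    """Low-noise field over a short period, cheap enough for many tests."""
    return stidw.FieldSpec(n_days=10, noise_sd=0.5, seed=7)


@pytest.fixture(scope="session")
def small_stations(small_field):
    return stidw.sample_stations(small_field, 40)


@pytest.fixture(scope="session")
def small_scales(small_field):
    return stidw.AxisScales.from_extent(*small_field.bbox, small_field.n_days)


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)


def brute_force_knn(points, query, k):
    """Independent k-NN oracle: full distance enumeration with numpy."""
    pts = np.asarray(points, dtype=float)
    d = np.linalg.norm(pts - np.asarray(query, dtype=float), axis=1)
    order = np.argsort(d, kind="stable")[:k]
    return [(int(i), float(d[i])) for i in order]
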