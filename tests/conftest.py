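import numpy as np
import pytest

from aneuwall import CohortConfig, generate_aneurysm_mesh
from aneuwall.fields import WSSFieldSeries


@pytest.fixture(scope="session")
def coarse_mesh():
    return generate_aneurysm_mesh(2.5, 1.2, "coarse", seed=1)


@pytest.fixture(scope="session")
def medium_mesh():
    return generate_aneurysm_mesh(2.5, 1.2, "medium", seed=1)


@pytest.fixture
def quiet_config():
    """A small, effect-free configuration for null-generator checks."""
    return CohortConfig(
        n_patients=1,
        thin_effect_multipliers={"wss": 1.0, "wssd": 1.0, "pressure": 1.0},
        patient_sd=0.0, region_sd=0.0, noise_sd=0.0, oscillatory_sd=0.0,
        mesh_resolution="coarse", seed=0)


def make_series(mesh, fn, n_times=65, T=1.0, pressure_fn=None):
    """Build a WSSFieldSeries from a vector-valued function of (points, t)."""
    times = np.linspace(0.0, T, n_times)
    wss = np.stack([fn(mesh.points, t) for t in times])
    if pressure_fn is None:
        pressure = np.zeros((n_times, mesh.n_nodes))
    else:
        pressure = np.stack([pressure_fn(mesh.points, t) for t in times])
    return WSSFieldSeries(times, T, wss, pressure)


@pytest.fixture
def series_factory():
    return make_series
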