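import numpy as np
import pytest

import cistrack as ct


@pytest.fixture(scope="session")
def small_config():
    """Tiny single-frame acquisition for fast rendering tests."""
    return ct.preset_config("maturation", nx=40, ny=40, n_frames=1, seed=7)


@pytest.fixture(scope="session")
def noiseless_config():
    return ct.preset_config(
        "maturation",
        nx=40,
        ny=40,
        n_frames=1,
        seed=7,
        read_noise_sd=0.0,
        camera_offset=0.0,
        photons_per_unit=1e6,
    )


def static_cisterna(position, diameter=0.5, amplitude=1.0):
    """A non-moving single-frame cisterna bright in channel 0 only."""
    return ct.SimCisterna(
        cisterna_id=0,
        birth_time=0.0,
        death_time=10.0,
        trajectory=np.asarray(position, dtype=float)[None, :],
        diameter=diameter,
        kinetics=(
            ct.MarkerKinetics(peak_time=0.0, rise_sigma=1e4, decay_sigma=1e4, amplitude=amplitude),
            ct.MarkerKinetics(peak_time=0.0, amplitude=0.0),
        ),
    )


@pytest.fixture(scope="session")
def phantom_config():
    """Wider single-frame field so hundreds of spots stay sparse."""
    return ct.preset_config("maturation", nx=96, ny=96, n_frames=1, seed=7)


@pytest.fixture(scope="session")
def maturation_replicate():
    """One full simulated delay experiment (shared across tests: ~2 s)."""
    config, scene = ct.maturation_scene(31.0, 24.1, 10, seed=11)
    stack, truth = ct.generate_movie(config, scene)
    return config, scene, stack, truth
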