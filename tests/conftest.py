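import numpy as np
import pytest

import coronakit as ck


@pytest.fixture(scope="session")
def tiny_params():
    """A small, fast colony for unit tests (not a preset)."""
    return ck.ColonyParams(
        mode="kinematic",
        n_cells=1200,
        drop_radius=600.0,
        core_radius=250.0,
        ring_start_radius=520.0,
        corona_band=80.0,
        ring_formation_time=20.0,
        ring_speed_initial=2.2,
        ring_speed_late=0.67,
        speed_crossover_time=200.0,
        duration_h=1.0,
        pixel_size=3.0,
        image_size=512,
        seed=11,
    )


@pytest.fixture(scope="session")
def uniform_params():
    return ck.get_preset(
        "uniform-motility", seed=5, n_cells=120, image_size=512, duration_h=1.0 / 6.0
    )


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(2024)
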