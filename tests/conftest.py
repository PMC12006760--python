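import numpy as np
import pytest

from lymphomi import SimConfig, gaussian_irf
from lymphomi.simulate import (
    ChannelPopulation,
    PopulationParams,
    default_activated,
    default_quiescent,
)


@pytest.fixture(scope="session")
def irf():
    """Default Gaussian IRF on the 80 MHz / 256-bin time base."""
    return gaussian_irf()


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)


def fixed_population(**over) -> PopulationParams:
    """A population with zero spread: every cell draws identical parameters."""
    kw = dict(
        nadh=ChannelPopulation(0.4, 0.0, 2.5, 0.0, 0.70, 0.0),
        fad=ChannelPopulation(0.30, 0.0, 2.0, 0.0, 0.72, 0.0),
        nadh_photons_mean=120_000.0, nadh_photons_sd=0.0,
        orr_mean=0.45, orr_sd=0.0,
        background_fraction_mean=0.0, background_fraction_sd=0.0,
        cd69_positive_prob=0.0,
    )
    kw.update(over)
    return PopulationParams(**kw)


@pytest.fixture(scope="session")
def small_sim_config():
    """A small, fast field: 128 px grid, 12 cells."""
    return SimConfig(
        image_size=(128, 128), n_cells=12, cell_radius_px=(5.0, 7.0),
        quiescent=default_quiescent(), activated=default_activated(),
    )


@pytest.fixture(scope="session")
def small_field(small_sim_config):
    from lymphomi import simulate_field

    return simulate_field(small_sim_config, "stimulated", seed=42, batch_id="b0")
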