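import numpy as np
import pytest

from atpuncta.simulate import (
    AccumulationSpec,
    NoiseSpec,
    PlaqueSpec,
    SimulationConfig,
    SynapseFieldSpec,
    simulate_ribbon,
)


@pytest.fixture(scope="session")
def small_plaque_sim():
    """One modest plaque-bearing ribbon with accumulations, shared
    across tests that only read from it."""
    cfg = SimulationConfig(
        shape=(24, 384, 384),
        accumulations=(
            AccumulationSpec(count=8, mode_distance_um=10.0, spread_um=3.0,
                             volume_mixture=(1.0, 0.0, 0.0)),
        ),
        synapses=(),
        nuclei_count=4,
        noise=NoiseSpec(background=200.0, background_sd=40.0, shot_scale=1.0),
        seed=101,
    )
    return cfg, simulate_ribbon(cfg)


@pytest.fixture
def rng():
    return np.random.default_rng(2024)


def make_speckle_config(seed: int, shape=(10, 96, 96)) -> SimulationConfig:
    """Multi-section puncta plus single-section speckles in one channel."""
    return SimulationConfig(
        shape=shape,
        plaque=PlaqueSpec(kind="none"),
        synapses=(SynapseFieldSpec(channel="cspalpha", count=6,
                                   punctum_diameter_um=0.5,
                                   mean_intensity=900.0, intensity_sd=100.0,
                                   min_separation_um=0.3),),
        accumulations=(),
        nuclei_count=0,
        n_speckles=3,
        speckle_channel="cspalpha",
        noise=NoiseSpec(background=200.0, background_sd=30.0, shot_scale=1.0),
        seed=seed,
    )
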