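import numpy as np
import pytest

from adherens.image import ImageChannel
from adherens.simulate import SimulationConfig, generate_monolayer


def noiseless_config(n_cells: int = 9, seed: int = 3, size: int = 256) -> SimulationConfig:
    """Clean render: no noise, no illumination, no gaps."""
    return SimulationConfig(
        image_size=(size, size),
        n_cells=n_cells,
        gap_fraction=0.0,
        noise_sigma=0.0,
        illumination_amplitude=0.0,
        rng_seed=seed,
    )


@pytest.fixture(scope="session")
def clean_monolayer():
    """One noiseless gap-free monolayer shared across tests."""
    return generate_monolayer(noiseless_config())


@pytest.fixture()
def rng():
    return np.random.default_rng(0)


def make_channel(pixels, **kw) -> ImageChannel:
    return ImageChannel(np.asarray(pixels, dtype=np.uint8), **kw)
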