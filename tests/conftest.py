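import numpy as np
import pytest

import colorquant as cq


@pytest.fixture(scope="session")
def random_image() -> np.ndarray:
    """A small random RGB image exercising the full 0-255 range."""
    rng = np.random.default_rng(1234)
    return rng.integers(0, 256, size=(9, 11, 3), dtype=np.uint8)


@pytest.fixture(scope="session")
def gray_image() -> np.ndarray:
    return np.full((5, 6, 3), 77, dtype=np.uint8)


@pytest.fixture(scope="session")
def full83(random_image) -> cq.ChannelSet:
    return cq.derive_channel_set(random_image, mode="full83")


@pytest.fixture(scope="session")
def cod_study() -> cq.SyntheticStudy:
    """A full 83-channel synthetic chemical-oxygen-demand study.

    Study conditions: 8 levels x 5 packs x 10 train / 5 validation
    pixels, within-pack pixel CV 0.5%, between-pack CV 3%, seed 7.
    """
    design = cq.cod_design()
    library = cq.make_response_library(seed=7)
    return cq.simulate_study(library, design, seed=8)


@pytest.fixture(scope="session")
def noiseless_library() -> cq.ResponseLibrary:
    noise = cq.NoiseModel(within_pack_cv=0.0, between_pack_cv=0.0, between_scan_cv=0.0)
    return cq.make_response_library(seed=3, noise=noise)
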