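import numpy as np
import pytest

from ghostseg.data_synth import SynthParams, synthesize_sample


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


@pytest.fixture(scope="session")
def small_synth_params():
    """64x64 generator settings used for desk-scale training tests."""
    return SynthParams(canvas_size=64, blob_radius=(6.0, 20.0), seed=7)


@pytest.fixture(scope="session")
def overfit_records(small_synth_params):
    """Eight fixed synthetic patches (mixed positive/negative)."""
    return [synthesize_sample(small_synth_params, i) for i in range(8)]


def random_mask_pair(rng, shape=(16, 16), p=0.3):
    a = (rng.random(shape) < p).astype(np.uint8)
    b = (rng.random(shape) < p).astype(np.uint8)
    return a, b
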