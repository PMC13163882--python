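import logging

import numpy as np
import pytest

from nucself import SynthConfig, generate_sample

logging.getLogger("nucself").setLevel(logging.ERROR)


@pytest.fixture(scope="session")
def default_sample():
    """One default-config synthetic patch (128 px, ~12 nuclei)."""
    return generate_sample(SynthConfig(seed=7), 0)


@pytest.fixture(scope="session")
def small_sample():
    """A small patch for fast model-level tests."""
    cfg = SynthConfig(image_size=(64, 64), n_nuclei_range=(4, 6), seed=3)
    return generate_sample(cfg, 0)


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)


def random_prob_stack(rng, K=None, shape=None):
    """Random per-instance probability stack with blob-like structure so all
    branches of the refinement logic get exercised."""
    K = K if K is not None else int(rng.integers(1, 5))
    shape = shape or (int(rng.integers(8, 33)), int(rng.integers(8, 33)))
    m = rng.random((K,) + shape) ** rng.uniform(0.5, 3.0)
    return m.astype(np.float64)
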