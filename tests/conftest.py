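import numpy as np
import pytest

from petdmax import GeneratorConfig, SUVVolume


@pytest.fixture
def rng():
    return np.random.default_rng(20260101)


@pytest.fixture
def small_config():
    """A compact phantom configuration for fast image-level tests."""
    return GeneratorConfig(n_patients=6, shape=(32, 32, 72),
                           spacing=(4.0, 4.0, 4.0), n_nodes_mean=1.2,
                           n_distant_mean=1.2, radius_range_mm=(6.0, 14.0),
                           seed=7)


def random_volume(rng, max_side=20, hot_fraction=0.3, spacing=(2.0, 3.0, 4.0)):
    """A random SUV grid with roughly `hot_fraction` voxels above 2.5."""
    shape = tuple(rng.integers(6, max_side + 1, size=3))
    values = np.where(rng.random(shape) < hot_fraction,
                      rng.uniform(2.6, 10.0, shape),
                      rng.uniform(0.0, 2.4, shape))
    return SUVVolume(values=values, spacing=spacing, patient_id="rand")
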