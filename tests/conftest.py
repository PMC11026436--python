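import warnings

import numpy as np
import pytest

from esoatlas.synthetic import AtlasConfig, generate_atlas


@pytest.fixture(autouse=True)
def _quiet_statistical_warnings():
    """Model-fit convergence chatter is expected on tiny fixtures."""
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        yield


@pytest.fixture(scope="session")
def small_atlas():
    """A compact multi-sample atlas shared by read-only tests."""
    cfg = AtlasConfig(seed=11, n_cell_types=6, n_genes=120, cells_per_sample=120)
    return generate_atlas(cfg)


@pytest.fixture()
def rng():
    return np.random.default_rng(0)
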