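import numpy as np
import pytest

from isletflow import synth


@pytest.fixture(scope="session")
def small_population():
    """A small 3-condition population shared by read-only tests."""
    cfg = synth.SynthConfig(
        n_cells_per_condition=250, n_genes=80, seed=11
    )
    cm, truth = synth.gen_population(cfg)
    return cfg, cm, truth


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
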