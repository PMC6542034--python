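import numpy as np
import pytest

import microbiability as mb


@pytest.fixture(scope="session")
def small_study():
    """A modest synthetic herd with both genomic and microbial signal."""
    cfg = mb.SimulationConfig(n_animals=100, n_snps=300, n_otus=200,
                              target_h2_g=0.4, target_h2_b=0.3, seed=42)
    return mb.simulate_study(cfg)


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)


def random_otu_table(rng, n=6, c=8, low=0, high=50):
    counts = rng.integers(low, high, size=(n, c))
    return mb.OtuCountTable([f"a{i}" for i in range(n)],
                            [f"o{j}" for j in range(c)], counts)
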