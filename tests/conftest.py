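import numpy as np
import pandas as pd
import pytest

from bulkadmix import synthetic


@pytest.fixture(scope="session")
def small_panel():
    """Three well-drifted groups, four reference populations each."""
    return synthetic.simulate_reference_panel(K=3, L=300, n_populations_per_group=4,
                                              drift=50, seed=11)


@pytest.fixture(scope="session")
def pools_pair():
    """Calibration and validation controlled-pool sets under study noise."""
    return synthetic.simulate_controlled_pools(
        frequency_grid=tuple(np.round(np.arange(0.1, 0.95, 0.1), 2)),
        n_snps=1000, noise_sd=0.03, seed=1,
    )


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)


@pytest.fixture()
def random_freqs(rng):
    pops = [f"P{i}" for i in range(8)]
    loci = [f"L{j}" for j in range(60)]
    return pd.DataFrame(rng.random((8, 60)), index=pops, columns=loci)
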