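import numpy as np
import pytest

import taxometrics as tx

#: Reduced procedure settings for small fixtures and fast engine tests.
FAST_PARAMS = {
    "mambac": dict(n_cuts=15, end_margin=15, replications=3),
    "maxeig": dict(n_windows=15, overlap=0.8, replications=3),
    "lmode": dict(grid_size=256),
}


@pytest.fixture(scope="session")
def taxonic_sample():
    """Clear planted taxon: p=.25, d=2, within-group r=.2, n=1000."""
    return tx.make_taxonic(1000, n_indicators=4, base_rate=0.25, separation=2.0,
                           within_group_r=0.2, seed=11)


@pytest.fixture(scope="session")
def dimensional_sample():
    """Clear single-factor continuum: mean r=.6, n=1000."""
    return tx.make_dimensional(1000, n_indicators=4, target_mean_r=0.6, seed=3)


@pytest.fixture()
def rng():
    return np.random.default_rng(0)
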