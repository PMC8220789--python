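import numpy as np
import pandas as pd
import pytest
from scipy.stats import norm

import delphiframe as df


@pytest.fixture(scope="session")
def codebook():
    return df.load_default_codebook()


@pytest.fixture()
def small_responses():
    """A tiny 6-panellist table over two 2-item domains."""
    return pd.DataFrame(
        {
            "1.1": [4, 4, 4, 4, 4, 4],
            "1.2": [3, 4, 4, 4, 5, 5],
            "5.1": [1, 2, 3, 4, 5, np.nan],
            "5.2": [5, 5, 5, 5, 5, 5],
        },
        index=pd.Index([f"P{i}" for i in range(6)], name="panellist"),
    ).astype(float)


def discretise_bivariate(rho, n, rng, cum_probs=(0.2, 0.4, 0.6, 0.8)):
    """Latent bivariate-normal draw discretised at fixed cutpoints."""
    z = rng.multivariate_normal([0.0, 0.0], [[1.0, rho], [rho, 1.0]], size=n)
    cuts = norm.ppf(cum_probs)
    x = 1 + np.searchsorted(cuts, z[:, 0])
    y = 1 + np.searchsorted(cuts, z[:, 1])
    return x.astype(float), y.astype(float)


@pytest.fixture(scope="session")
def study_spec(codebook):
    return df.study_panel_spec(codebook, seed=7)
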