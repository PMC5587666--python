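import numpy as np
import pytest

import dpreg


@pytest.fixture(scope="session")
def tiny_data():
    """Small dense regression problem with a polygenic signal."""
    rng = np.random.default_rng(0)
    n, p = 40, 8
    X = rng.standard_normal((n, p))
    beta = rng.standard_normal(p) * 0.3
    y = X @ beta + rng.standard_normal(n)
    return dpreg.RegressionData(y=y, W=np.ones((n, 1)), X=X)


@pytest.fixture(scope="session")
def sim_panel():
    """A reusable simulated genotype panel (300 samples, 100 SNPs)."""
    return dpreg.simulate_genotypes(300, 100, seed=1)
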