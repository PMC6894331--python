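import warnings

import numpy as np
import pytest

from ordifactor.polychoric import polychoric_matrix
from ordifactor.simulate import GeneratorConfig, simulate_bifactor_ordinal

warnings.filterwarnings("ignore", message=".*Heywood.*")
warnings.filterwarnings("ignore", message=".*boundary.*")


@pytest.fixture(scope="session")
def onefactor_data():
    """5-item one-factor ordinal dataset (n = 1500) with its summary."""
    cfg = GeneratorConfig.simple(p=5, n_sub=1, lambda_general=0.7,
                                 lambda_sub=0.0, n_per_group=(1500,), seed=42)
    ds = simulate_bifactor_ordinal(cfg)
    return cfg, ds, polychoric_matrix(ds.matrix)


@pytest.fixture(scope="session")
def bifactor_data():
    """9-item, 3-subdomain bifactor dataset (n = 2500) with its summary."""
    cfg = GeneratorConfig.simple(p=9, n_sub=3, lambda_general=0.62,
                                 lambda_sub=0.38, n_per_group=(2500,), seed=7)
    ds = simulate_bifactor_ordinal(cfg)
    return cfg, ds, polychoric_matrix(ds.matrix)


@pytest.fixture(scope="session")
def twogroup_data():
    """9-item bifactor data in two groups with identical parameters."""
    cfg = GeneratorConfig.simple(p=9, n_sub=3, lambda_general=0.6,
                                 lambda_sub=0.35, n_per_group=(1200, 1200),
                                 groups=("g1", "g2"), seed=11)
    ds = simulate_bifactor_ordinal(cfg)
    return cfg, ds


def true_raw_loadings(cfg):
    """Generating loadings on the raw theta-parameterized scale
    (residual variances fixed at 1)."""
    evar = 1.0 - cfg.lambda_general**2 - cfg.lambda_sub**2
    return cfg.lambda_general / np.sqrt(evar), cfg.lambda_sub / np.sqrt(evar)
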