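import numpy as np
import pandas as pd
import pytest

from orgenrich.simulate import SimConfig, gen_gene_table


@pytest.fixture(scope="session")
def cfg_small() -> SimConfig:
    return SimConfig(seed=7, n_genes=600, n_samples=800, n_traits=8, planted_set_size=60)


@pytest.fixture(scope="session")
def genes_small(cfg_small) -> pd.DataFrame:
    return gen_gene_table(cfg_small)


@pytest.fixture(scope="session")
def covariates_small(genes_small) -> pd.DataFrame:
    return genes_small.set_index("gene")[["length", "snp_density", "inv_mac"]]


def ols_oracle(X: np.ndarray, y: np.ndarray):
    """Normal-equations OLS oracle: beta, se, t via explicit inverse."""
    xtx = X.T @ X
    beta = np.linalg.solve(xtx, X.T @ y)
    resid = y - X @ beta
    dof = len(y) - X.shape[1]
    sigma2 = resid @ resid / dof
    se = np.sqrt(sigma2 * np.diag(np.linalg.inv(xtx)))
    return beta, se, dof
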