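import numpy as np
import pytest

from cgwas.summary_io import GwasPanel, table_from_arrays


def exchangeable(psi: float, K: int) -> np.ndarray:
    mat = np.full((K, K), psi)
    np.fill_diagonal(mat, 1.0)
    return mat


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def toy_panel():
    """Tiny 3-GWAS panel with constant unit standard errors."""
    rng = np.random.default_rng(7)
    M = 500
    ids = [f"rs{i}" for i in range(M)]
    tables = [
        table_from_arrays(ids, rng.standard_normal(M), np.ones(M), np.full(M, 1000), label=f"g{k}")
        for k in range(3)
    ]
    return GwasPanel(tables)


def correlated_t(rng, M, Psi, p_effect=0.0, Pi=None, theta=None):
    """Null + optional causal-stratum T draws; causal variants come first."""
    Psi = np.asarray(Psi, float)
    K = Psi.shape[0]
    T = rng.standard_normal((M, K)) @ np.linalg.cholesky(Psi).T
    n_causal = int(p_effect * M)
    if n_causal:
        cov = np.asarray(Pi, float) * np.outer(theta, theta)
        vals, vecs = np.linalg.eigh(cov)
        root = (vecs * np.sqrt(np.clip(vals, 0, None))) @ vecs.T
        T[:n_causal] += rng.standard_normal((n_causal, K)) @ root.T
    return T
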