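import warnings

import numpy as np
import pandas as pd
import pytest
from hypothesis import HealthCheck, settings

from awmnet.sim import SimConfig, simulate_genotypes, simulate_phenotypes

settings.register_profile(
    "ci", derandomize=True, deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture(autouse=True)
def _quiet_expected_warnings():
    with warnings.catch_warnings():
        warnings.filterwarnings("ignore", message=".*QTL variance.*")
        warnings.filterwarnings("ignore", message=".*constant AWM rows.*")
        yield


@pytest.fixture(scope="session")
def small_config():
    return SimConfig(
        n_animals=200, n_sires=15, n_snps=1000, n_chromosomes=4, n_traits=6,
        n_qtl=6, pleiotropy_block_size=3, n_contemporary_groups=4, seed=11,
    )


@pytest.fixture(scope="session")
def small_dataset(small_config):
    geno = simulate_genotypes(small_config)
    pheno, truth = simulate_phenotypes(geno, small_config)
    return geno, pheno, truth


@pytest.fixture
def toy_gwas_table():
    """Two-trait toy GWAS table with hand-set p-values and effects."""
    rows = []
    pvals_key = [0.01, 0.02, 0.04, 0.2, 0.3, 0.5, 0.6, 0.7, 0.9, 1.0]
    for i, p in enumerate(pvals_key):
        rows.append({"snp_id": f"s{i}", "trait": "key", "effect": 0.1 * (i + 1),
                     "p_value": p, "se": 0.1, "n_used": 100})
        rows.append({"snp_id": f"s{i}", "trait": "other", "effect": -0.05 * (i + 1),
                     "p_value": 0.01 if i < 2 else 0.5, "se": 0.1, "n_used": 100})
    return pd.DataFrame(rows)


def naive_pcit(r: np.ndarray) -> np.ndarray:
    """Independent scalar triple-loop PCIT reference (kept deliberately
    naive; shared by unit and acceptance tests)."""
    n = r.shape[0]
    sig = np.ones((n, n), dtype=bool)
    np.fill_diagonal(sig, False)
    if n < 3:
        return sig
    tol = 1e-12

    def partial(a, b, c):
        den = (1 - r[a, c] ** 2) * (1 - r[b, c] ** 2)
        if den < tol:
            return None
        return (r[a, b] - r[a, c] * r[b, c]) / np.sqrt(den)

    for x in range(n):
        for y in range(n):
            if x == y:
                continue
            for z in range(n):
                if z == x or z == y:
                    continue
                pxy = partial(x, y, z)
                pxz = partial(x, z, y)
                pyz = partial(y, z, x)
                if pxy is None or pxz is None or pyz is None:
                    continue
                if r[x, y] == 0 or r[x, z] == 0 or r[y, z] == 0:
                    continue
                eps = (pxy / r[x, y] + pxz / r[x, z] + pyz / r[y, z]) / 3.0
                if not np.isfinite(eps):
                    continue
                if abs(r[x, y]) <= abs(eps * r[x, z]) and abs(r[x, y]) <= abs(eps * r[y, z]):
                    sig[x, y] = False
                    break
    return sig & sig.T


def random_correlation(rng: np.random.Generator, n: int) -> np.ndarray:
    """Random correlation matrix from a low-rank factor model plus noise."""
    k = rng.integers(2, 6)
    L = rng.normal(size=(n, k))
    S = L @ L.T + np.diag(rng.uniform(0.5, 2.0, size=n))
    d = np.sqrt(np.diag(S))
    r = S / np.outer(d, d)
    np.fill_diagonal(r, 1.0)
    return np.clip(r, -1.0, 1.0)
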