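"""Mixed-model association: REML against grid and dense oracles, the GLS
scan against an explicit-inverse oracle, OLS convergence, and multi-trait
orchestration."""

import warnings

import numpy as np
import pandas as pd
import pytest
from scipy.stats import t as t_dist

from awmnet.containers import GenotypeMatrix, PhenotypeTable
from awmnet.grm import GRM, compute_grm, stabilize
from awmnet.gwas import (
    VarianceComponents,
    design_matrix,
    emmax_scan,
    estimate_variance_components,
    genomic_control_lambda,
    ols_scan,
    pseudo_heritability,
    run_multitrait_gwas,
)
from awmnet.sim import SimConfig, simulate_genotypes, simulate_phenotypes


def dense_reml_loglik(y, X, K, sigma_a2, delta):
    """Independent dense-matrix restricted log-likelihood (Harville)."""
    n, p = X.shape
    V = sigma_a2 * (K + delta * np.eye(n))
    Vi = np.linalg.inv(V)
    XtViX = X.T @ Vi @ X
    beta = np.linalg.solve(XtViX, X.T @ Vi @ y)
    r = y - X @ beta
    _, ld_V = np.linalg.slogdet(V)
    _, ld_XtViX = np.linalg.slogdet(XtViX)
    _, ld_XtX = np.linalg.slogdet(X.T @ X)
    return -0.5 * (
        (n - p) * np.log(2 * np.pi) + ld_V + ld_XtViX - ld_XtX + r @ Vi @ r
    )


def dense_gls_oracle(y, X, K, G, vc):
    """Explicit-inverse GLS per SNP: fit y on [X | g] with correlation
    K + delta I, residual variance re-estimated, Wald t."""
    n = len(y)
    H = K + vc.delta * np.eye(n)
    Hi = np.linalg.inv(H)
    ps = []
    effs = []
    for j in range(G.shape[1]):
        D = np.column_stack([X, G[:, j]])
        A = D.T @ Hi @ D
        if np.linalg.matrix_rank(A) < A.shape[0]:
            ps.append(1.0)
            effs.append(0.0)
            continue
        b = np.linalg.solve(A, D.T @ Hi @ y)
        r = y - D @ b
        df = n - D.shape[1]
        s2 = (r @ Hi @ r) / df
        se = np.sqrt(s2 * np.linalg.inv(A)[-1, -1])
        t = b[-1] / se
        ps.append(2 * t_dist.sf(abs(t), df))
        effs.append(b[-1])
    return np.array(effs), np.array(ps)


def _sim(n=120, m=300, seed=0, h2=0.5, n_sires=8):
    cfg = SimConfig(
        n_animals=n, n_sires=n_sires, n_snps=m, n_traits=1, heritabilities=h2,
        n_qtl=0, missing_pheno_rate=0.0, n_contemporary_groups=3, seed=seed,
    )
    geno = simulate_genotypes(cfg)
    pheno, _ = simulate_phenotypes(geno, cfg)
    y = pheno.trait("trait_1")
    X = design_matrix(pheno.data["cg"])
    K = stabilize(compute_grm(geno))
    return y, X, K, geno


# ---------------------------------------------------------------------------
# pseudo-heritability arithmetic


@pytest.mark.parametrize(
    "sa2,se2,expected", [(2.0, 2.0, 0.5), (0.0, 1.0, 0.0), (0.38, 0.62, 0.38)]
)
def test_pseudo_heritability_ratio(sa2, se2, expected):
    vc = VarianceComponents(sa2, se2, delta=se2 / max(sa2, 1e-12),
                            pseudo_h2=0.0, loglik=0.0)
    assert pseudo_heritability(vc) == pytest.approx(expected)


def test_pseudo_heritability_zero_components_error():
    vc = VarianceComponents(0.0, 0.0, 0.0, 0.0, 0.0)
    with pytest.raises(ValueError):
        pseudo_heritability(vc)


# ---------------------------------------------------------------------------
# variance components


def test_identity_kinship_flags_flat_likelihood():
    rng = np.random.default_rng(0)
    y = rng.normal(size=50)
    X = np.ones((50, 1))
    vc = estimate_variance_components(y, X, np.eye(50))
    assert not vc.identifiable  # sigma_a2 and sigma_e2 inseparable when K = I


def test_constant_phenotype_rejected():
    with pytest.raises(ValueError, match="constant"):
        estimate_variance_components(np.ones(30), np.ones((30, 1)), np.eye(30))


def test_non_psd_kinship_directs_to_stabilize():
    K = np.eye(20)
    K[0, 0] = -1.0
    with pytest.raises(ValueError, match="stabilize"):
        estimate_variance_components(np.random.default_rng(1).normal(size=20),
                                     np.ones((20, 1)), K)


def test_optimum_beats_fine_grid():
    """REML profile at the returned optimum >= every point of a 1,000-point
    log-delta grid (within 1e-6): the bounded search finds the optimum."""
    y, X, K, _ = _sim(n=30, m=120, seed=4)
    from awmnet.gwas import _reml_profile

    d, U = np.linalg.eigh(K.matrix)
    d = np.clip(d, 0, None)
    ys, Xs = U.T @ y, U.T @ X
    _, ld = np.linalg.slogdet(X.T @ X)
    vc = estimate_variance_components(y, X, K)
    grid_best = max(
        _reml_profile(g, d, Xs, ys, ld, "REML")[0]
        for g in np.linspace(-10, 10, 1000)
    )
    assert vc.loglik >= grid_best - 1e-6


def test_reml_loglik_matches_dense_oracle():
    y, X, K, _ = _sim(n=60, m=200, seed=5)
    vc = estimate_variance_components(y, X, K)
    dense = dense_reml_loglik(y, X, K.matrix, vc.sigma_a2, vc.delta)
    assert vc.loglik == pytest.approx(dense, abs=1e-6)


def test_h2_recovery_single_setting():
    ests = []
    for seed in range(6):
        cfg = SimConfig(n_animals=500, n_sires=25, n_snps=1500, n_traits=1,
                        heritabilities=0.5, n_qtl=0, missing_pheno_rate=0.0, seed=seed)
        geno = simulate_genotypes(cfg)
        pheno, _ = simulate_phenotypes(geno, cfg)
        K = stabilize(compute_grm(geno))
        vc = estimate_variance_components(
            pheno.trait("trait_1"), design_matrix(pheno.data["cg"]), K
        )
        ests.append(vc.pseudo_h2)
    assert np.mean(ests) == pytest.approx(0.5, abs=0.1)


# ---------------------------------------------------------------------------
# the scan


def test_hand_example_ols_slope():
    """K = I, X = intercept, y = (1,2,3,4), g = (0,1,1,2): the GLS effect
    reduces to the OLS slope 3/2."""
    y = np.array([1.0, 2, 3, 4])
    X = np.ones((4, 1))
    g = np.array([[0.0], [1], [1], [2]])
    vc = VarianceComponents(1e-8, 1.0, delta=1e8, pseudo_h2=0.0, loglik=0.0)
    out = emmax_scan(y, X, np.eye(4), g, vc)
    assert out["effect"].iloc[0] == pytest.approx(1.5, abs=1e-9)


def test_scan_matches_dense_gls_oracle():
    for seed in (0, 1):
        y, X, K, geno = _sim(n=40, m=60, seed=seed)
        G = geno.mean_imputed()
        vc = estimate_variance_components(y, X, K)
        scan = emmax_scan(y, X, K, G, vc)
        eff_o, p_o = dense_gls_oracle(y, X, K.matrix, G, vc)
        ok = ~scan["flagged"].to_numpy()
        np.testing.assert_allclose(scan["p_value"].to_numpy()[ok], p_o[ok], atol=1e-8)
        np.testing.assert_allclose(scan["effect"].to_numpy()[ok], eff_o[ok], atol=1e-8)


def test_emmax_reduces_to_ols_at_huge_delta():
    y, X, K, geno = _sim(n=80, m=150, seed=7)
    G = geno.mean_imputed()
    vc = VarianceComponents(1e-9, 1e3, delta=1e12, pseudo_h2=0.0, loglik=0.0)
    scan = emmax_scan(y, X, K, G, vc)
    ols = ols_scan(y, X, G)
    np.testing.assert_allclose(scan["p_value"], ols["p_value"], atol=1e-6)


def test_p_values_invariant_to_k_and_y_rescaling():
    y, X, K, geno = _sim(n=70, m=100, seed=8)
    G = geno.mean_imputed()

    def run(y_, Kmat):
        vc = estimate_variance_components(y_, X, Kmat)
        return emmax_scan(y_, X, Kmat, G, vc)["p_value"].to_numpy()

    base = run(y, K.matrix)
    np.testing.assert_allclose(run(y, 7.3 * K.matrix), base, atol=1e-6)
    np.testing.assert_allclose(run(2.5 * y, K.matrix), base, atol=1e-6)


def test_monomorphic_snp_flagged_not_tested():
    y, X, K, geno = _sim(n=50, m=30, seed=9)
    G = geno.mean_imputed()
    G[:, 0] = 1.0  # constant within used samples
    vc = estimate_variance_components(y, X, K)
    out = emmax_scan(y, X, K, G, vc)
    assert bool(out["flagged"].iloc[0])
    assert out["p_value"].iloc[0] == 1.0 and out["effect"].iloc[0] == 0.0


def test_permuted_null_calibration():
    y, X, K, geno = _sim(n=300, m=2000, seed=10, n_sires=15)
    rng = np.random.default_rng(0)
    yp = rng.permutation(y)
    vc = estimate_variance_components(yp, X, K)
    scan = emmax_scan(yp, X, K, geno.mean_imputed(), vc)
    frac = (scan["p_value"] < 0.05).mean()
    assert frac == pytest.approx(0.05, abs=0.02)


# ---------------------------------------------------------------------------
# multi-trait orchestration


def _multitrait_fixture(seed=13):
    cfg = SimConfig(n_animals=250, n_sires=12, n_snps=600, n_traits=3,
                    heritabilities=0.4, n_qtl=3, qtl_effect_sd=0.0,
                    missing_pheno_rate=0.05, seed=seed)
    geno = simulate_genotypes(cfg)
    pheno, truth = simulate_phenotypes(geno, cfg)
    K = stabilize(compute_grm(geno))
    return geno, pheno, truth, K


def test_duplicate_trait_column_gives_identical_rows():
    geno, pheno, _, K = _multitrait_fixture()
    df = pheno.data.copy()
    df["trait_dup"] = df["trait_1"]
    pheno2 = PhenotypeTable(df)
    table, _, _ = run_multitrait_gwas(pheno2, geno, K)
    a = table[table["trait"] == "trait_1"].reset_index(drop=True)
    b = table[table["trait"] == "trait_dup"].reset_index(drop=True)
    np.testing.assert_allclose(a["p_value"], b["p_value"])
    np.testing.assert_allclose(a["effect"], b["effect"])


def test_planted_large_qtl_attains_trait_minimum_p():
    geno, pheno, _, K = _multitrait_fixture()
    df = pheno.data.copy()
    # plant a 1-SD effect at a known SNP on trait_2
    g0 = geno.mean_imputed()[:, 5]
    df["trait_2"] = df["trait_2"] + 1.0 * (g0 - g0.mean()) / g0.std()
    table, _, _ = run_multitrait_gwas(PhenotypeTable(df), geno, K)
    t2 = table[table["trait"] == "trait_2"].set_index("snp_id")
    assert t2["p_value"].idxmin() == geno.snp_ids[5]


def test_low_n_trait_skipped_with_warning():
    geno, pheno, _, K = _multitrait_fixture()
    df = pheno.data.copy()
    df.loc[df.index[20:], "trait_3"] = np.nan  # 20 records < min_n
    with pytest.warns(UserWarning, match="skipped"):
        table, vcs, summary = run_multitrait_gwas(PhenotypeTable(df), geno, K, min_n=30)
    assert "trait_3" not in set(table["trait"])
    assert set(summary["trait"]) == {"trait_1", "trait_2"}


def test_summary_counts_match_table():
    geno, pheno, _, K = _multitrait_fixture()
    table, vcs, summary = run_multitrait_gwas(pheno, geno, K)
    for _, row in summary.iterrows():
        sub = table[table["trait"] == row["trait"]]
        assert row["n_p_lt_0.05"] == (sub["p_value"] < 0.05).sum()
        assert 0.0 <= row["pseudo_h2"] <= 1.0


def test_genomic_control_lambda_null_near_one():
    rng = np.random.default_rng(3)
    assert genomic_control_lambda(rng.uniform(size=20000)) == pytest.approx(1.0, abs=0.05)
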