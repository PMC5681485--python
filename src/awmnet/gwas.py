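"""EMMAX-style single-locus mixed-model association.

Model per trait:  y = X beta + g + e,  g ~ N(0, sigma_a^2 K),
e ~ N(0, sigma_e^2 I), with contemporary groups as fixed class effects.

Variance components are estimated once per trait under the null (no SNP)
by profiling the restricted likelihood in the single ratio
delta = sigma_e^2 / sigma_a^2, using one spectral decomposition of K.
Every SNP is then scored by generalized least squares with the correlation
structure K + delta I held fixed: the SNP coefficient is the
allele-substitution effect and its Wald t statistic (residual variance
re-estimated per SNP, df = n - rank([X | g])) gives the p-value. This
scale-free convention makes the scan invariant to rescaling K or y and
reduces exactly to OLS as sigma_a^2 -> 0.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.optimize import minimize_scalar
from scipy.stats import chi2 as chi2_dist
from scipy.stats import t as t_dist

from .containers import GenotypeMatrix, PhenotypeTable
from .grm import GRM

__all__ = [
    "VarianceComponents",
    "design_matrix",
    "estimate_variance_components",
    "pseudo_heritability",
    "emmax_scan",
    "ols_scan",
    "run_multitrait_gwas",
    "genomic_control_lambda",
]

LOG_DELTA_BOUNDS = (-10.0, 10.0)


@dataclass
class VarianceComponents:
    sigma_a2: float
    sigma_e2: float
    delta: float
    pseudo_h2: float
    loglik: float
    criterion: str = "REML"
    identifiable: bool = True  # False when the profile likelihood is flat

    def __post_init__(self) -> None:
        if self.sigma_a2 < 0 or self.sigma_e2 < 0:
            raise ValueError("variance components must be non-negative")


def pseudo_heritability(vc: VarianceComponents) -> float:
    """sigma_a^2 / (sigma_a^2 + sigma_e^2): share of phenotypic variance
    captured by the genomic random effect."""
    tot = vc.sigma_a2 + vc.sigma_e2
    if tot == 0:
        raise ValueError("both variance components are zero")
    return vc.sigma_a2 / tot


def design_matrix(cg_labels) -> np.ndarray:
    """Intercept + dummy columns for contemporary groups (first level
    dropped); guaranteed full column rank."""
    labels = pd.Series(cg_labels).astype(str)
    levels = sorted(labels.unique())
    X = np.ones((len(labels), 1 + max(len(levels) - 1, 0)))
    for k, lev in enumerate(levels[1:]):
        X[:, 1 + k] = (labels == lev).to_numpy(dtype=float)
    if np.linalg.matrix_rank(X) < X.shape[1]:
        raise ValueError("design matrix is rank deficient")
    return X


def _reml_profile(log_delta: float, d: np.ndarray, Xs: np.ndarray, ys: np.ndarray,
                  logdet_xtx: float, criterion: str) -> tuple[float, float, float]:
    """Profile (restricted) log-likelihood at a given log(delta).

    Returns (loglik, sigma_a2, rss_w). Everything is expressed in the
    eigenbasis of K: d are eigenvalues, Xs = U'X, ys = U'y.
    """
    delta = np.exp(log_delta)
    n, p = Xs.shape
    w = 1.0 / (d + delta)
    Xw = Xs * w[:, None]
    XtWX = Xs.T @ Xw
    XtWy = Xw.T @ ys
    beta = np.linalg.solve(XtWX, XtWy)
    r = ys - Xs @ beta
    rss = float(np.sum(w * r * r))
    if criterion == "REML":
        df = n - p
        sigma_a2 = rss / df
        sign, logdet_xtwx = np.linalg.slogdet(XtWX)
        ll = -0.5 * (
            df * np.log(2 * np.pi * sigma_a2)
            + np.sum(np.log(d + delta))
            + logdet_xtwx
            - logdet_xtx
            + df
        )
    else:  # ML
        sigma_a2 = rss / n
        ll = -0.5 * (n * np.log(2 * np.pi * sigma_a2) + np.sum(np.log(d + delta)) + n)
    return float(ll), float(sigma_a2), rss


def estimate_variance_components(
    y: np.ndarray,
    X: np.ndarray,
    K: GRM | np.ndarray,
    criterion: str = "REML",
    n_grid: int = 100,
    _eig: tuple[np.ndarray, np.ndarray] | None = None,
) -> VarianceComponents:
    """Null-model variance components by bounded 1-D search on log(delta).

    A coarse grid over log(delta) in [-10, 10] brackets the optimum, then
    Brent refinement inside the best bracket; this copes with the
    multimodal profiles that plague pure local search.
    """
    if criterion not in ("REML", "ML"):
        raise ValueError("criterion must be REML or ML")
    y = np.asarray(y, dtype=float)
    X = np.atleast_2d(np.asarray(X, dtype=float))
    if np.ptp(y) == 0:
        raise ValueError("phenotype is constant; variance components undefined")
    Kmat = K.matrix if isinstance(K, GRM) else np.asarray(K, dtype=float)
    if Kmat.shape[0] != len(y) or X.shape[0] != len(y):
        raise ValueError("y, X and K are not conformable")
    if _eig is None:
        d, U = np.linalg.eigh(Kmat)
    else:
        d, U = _eig
    if d[0] < -1e-8 * max(1.0, abs(d[-1])):
        raise ValueError("K is not positive semi-definite; run grm.stabilize() first")
    d = np.clip(d, 0.0, None)
    ys = U.T @ y
    Xs = U.T @ X
    _, logdet_xtx = np.linalg.slogdet(X.T @ X)

    lo, hi = LOG_DELTA_BOUNDS
    grid = np.linspace(lo, hi, n_grid)
    lls = np.array([_reml_profile(g, d, Xs, ys, logdet_xtx, criterion)[0] for g in grid])
    best = int(np.argmax(lls))
    flat = bool(lls.max() - lls.min() < 1e-6)
    a = grid[max(best - 1, 0)]
    b = grid[min(best + 1, n_grid - 1)]
    res = minimize_scalar(
        lambda g: -_reml_profile(g, d, Xs, ys, logdet_xtx, criterion)[0],
        bounds=(a, b),
        method="bounded",
        options={"xatol": 1e-8},
    )
    log_delta = float(res.x) if -res.fun >= lls[best] else float(grid[best])
    ll, sigma_a2, _ = _reml_profile(log_delta, d, Xs, ys, logdet_xtx, criterion)
    delta = float(np.exp(log_delta))
    sigma_e2 = sigma_a2 * delta
    return VarianceComponents(
        sigma_a2=sigma_a2,
        sigma_e2=sigma_e2,
        delta=delta,
        pseudo_h2=sigma_a2 / (sigma_a2 + sigma_e2),
        loglik=ll,
        criterion=criterion,
        identifiable=not flat,
    )


def _scan_core(
    y: np.ndarray,
    X: np.ndarray,
    G: np.ndarray,
    weights: np.ndarray | None,
    U: np.ndarray | None,
) -> pd.DataFrame:
    """Weighted (GLS in the rotated basis) or plain single-SNP regressions.

    Returns effect, se, p, flagged per SNP column of G; residual variance
    re-estimated per SNP, t reference with df = n - p - 1.
    """
    n, p = X.shape
    if U is not None:
        y = U.T @ y
        X = U.T @ X
        G = U.T @ G
    if weights is not None:
        sw = np.sqrt(weights)
        y = y * sw
        X = X * sw[:, None]
        G = G * sw[:, None]
    Q, _ = np.linalg.qr(X)
    y_r = y - Q @ (Q.T @ y)
    G_r = G - Q @ (Q.T @ G)
    gtg = np.einsum("ij,ij->j", G_r, G_r)
    gty = G_r.T @ y_r
    yty = float(y_r @ y_r)
    df = n - p - 1
    # scale-invariant collinearity guard: a SNP is testable when its
    # X-residualized (weighted) variance is non-negligible relative to the
    # best-conditioned SNP in the panel
    gmax = float(np.max(gtg)) if gtg.size else 0.0
    ok = gtg > 1e-10 * gmax if gmax > 0 else np.zeros_like(gtg, dtype=bool)
    effect = np.zeros(G.shape[1])
    se = np.full(G.shape[1], np.nan)
    pval = np.ones(G.shape[1])
    with np.errstate(divide="ignore", invalid="ignore"):
        b = np.where(ok, gty / np.where(ok, gtg, 1.0), 0.0)
        rss = np.maximum(yty - b * gty, 0.0)
        sigma2 = rss / df
        se_ok = np.sqrt(sigma2 / np.where(ok, gtg, np.nan))
        tstat = b / se_ok
        p_ok = 2.0 * t_dist.sf(np.abs(tstat), df)
    effect[ok] = b[ok]
    se[ok] = se_ok[ok]
    pval[ok] = np.clip(p_ok[ok], np.finfo(float).tiny, 1.0)
    return pd.DataFrame(
        {"effect": effect, "se": se, "p_value": pval, "flagged": ~ok, "n_used": n}
    )


def emmax_scan(
    y: np.ndarray,
    X: np.ndarray,
    K: GRM | np.ndarray,
    genotypes: np.ndarray,
    vc: VarianceComponents,
    snp_ids: list[str] | None = None,
    _eig: tuple[np.ndarray, np.ndarray] | None = None,
) -> pd.DataFrame:
    """GLS scan of every SNP with covariance structure K + delta I fixed
    from the null fit. ``genotypes`` must be mean-imputed (no NaN)."""
    y = np.asarray(y, dtype=float)
    X = np.atleast_2d(np.asarray(X, dtype=float))
    G = np.asarray(genotypes, dtype=float)
    if np.isnan(G).any():
        raise ValueError("genotypes must be mean-imputed before the scan")
    Kmat = K.matrix if isinstance(K, GRM) else np.asarray(K, dtype=float)
    if _eig is None:
        d, U = np.linalg.eigh(Kmat)
    else:
        d, U = _eig
    d = np.clip(d, 0.0, None)
    w = 1.0 / (d + vc.delta)
    out = _scan_core(y, X, G, weights=w, U=U)
    if snp_ids is not None:
        out.insert(0, "snp_id", snp_ids)
    return out


def ols_scan(
    y: np.ndarray, X: np.ndarray, genotypes: np.ndarray, snp_ids: list[str] | None = None
) -> pd.DataFrame:
    """Naive per-SNP fixed-effects regression ignoring relatedness; the
    family-structure foil for the mixed model."""
    out = _scan_core(
        np.asarray(y, float), np.atleast_2d(np.asarray(X, float)),
        np.asarray(genotypes, float), weights=None, U=None,
    )
    if snp_ids is not None:
        out.insert(0, "snp_id", snp_ids)
    return out


def genomic_control_lambda(p_values: np.ndarray) -> float:
    """Median chi-square (1 df) of the observed p-values over its null
    median (0.4549): > 1 signals test-statistic inflation."""
    p = np.asarray(p_values, dtype=float)
    p = p[np.isfinite(p)]
    stats = chi2_dist.isf(p, df=1)
    return float(np.median(stats) / chi2_dist.isf(0.5, df=1))


def run_multitrait_gwas(
    phenotypes: PhenotypeTable,
    genotypes: GenotypeMatrix,
    K: GRM,
    criterion: str = "REML",
    min_n: int = 30,
    traits: list[str] | None = None,
) -> tuple[pd.DataFrame, dict[str, VarianceComponents], pd.DataFrame]:
    """Per-trait EMMAX scans over a shared genotype panel.

    Returns (gwas table, per-trait variance components, per-trait summary
    with pseudo-h2 and significant-SNP counts at p < 0.05/0.01/0.001).
    Animals missing a trait are excluded for that trait; variance
    components are re-estimated on each trait's analysis subset.
    """
    traits = traits or phenotypes.trait_names
    if not traits:
        raise ValueError("no trait columns to analyse")
    order = {a: i for i, a in enumerate(genotypes.sample_ids)}
    ph = phenotypes.data.set_index(phenotypes.data["animal_id"].astype(str))
    common = [a for a in genotypes.sample_ids if a in ph.index]
    if len(common) < min_n:
        raise ValueError("too few animals shared between genotypes and phenotypes")
    G_full = genotypes.mean_imputed()

    rows = []
    vcs: dict[str, VarianceComponents] = {}
    summary = []
    mmap = genotypes.marker_map
    for trait in traits:
        yv = ph.loc[common, trait].to_numpy(dtype=float)
        use = ~np.isnan(yv)
        if use.sum() < min_n:
            warnings.warn(f"trait {trait}: only {int(use.sum())} records, skipped")
            continue
        idx = np.array([order[a] for a, u in zip(common, use) if u])
        y = yv[use]
        X = design_matrix(ph.loc[common, "cg"].to_numpy()[use])
        Ksub = K.matrix[np.ix_(idx, idx)]
        d, U = np.linalg.eigh(Ksub)
        d = np.clip(d, 0.0, None)
        vc = estimate_variance_components(y, X, Ksub, criterion=criterion, _eig=(d, U))
        vcs[trait] = vc
        scan = emmax_scan(y, X, Ksub, G_full[idx, :], vc, _eig=(d, U))
        scan.insert(0, "trait", trait)
        scan.insert(0, "pos", mmap["pos"].to_numpy())
        scan.insert(0, "chrom", mmap["chrom"].to_numpy())
        scan.insert(0, "snp_id", mmap["snp_id"].to_numpy())
        rows.append(scan)
        pv = scan["p_value"].to_numpy()
        summary.append(
            {
                "trait": trait,
                "n": int(use.sum()),
                "pseudo_h2": vc.pseudo_h2,
                "n_p_lt_0.05": int((pv < 0.05).sum()),
                "n_p_lt_0.01": int((pv < 0.01).sum()),
                "n_p_lt_0.001": int((pv < 0.001).sum()),
            }
        )
    if not rows:
        raise ValueError("no trait had enough records to analyse")
    table = pd.concat(rows, ignore_index=True)
    return table, vcs, pd.DataFrame(summary)
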