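"""Genomic relationship matrix (VanRaden method 1).

K = Z Z' / (2 * sum_j p_j (1 - p_j)), with Z the 2p-centered dosage matrix
and p the observed allele frequency per SNP. Missing genotypes are
mean-imputed per SNP before centering; monomorphic SNPs contribute nothing
and are skipped.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .containers import GenotypeMatrix

__all__ = ["GRM", "compute_grm", "stabilize"]


@dataclass
class GRM:
    matrix: np.ndarray
    sample_ids: list[str]
    n_snps_used: int
    method: str = "vanraden1"
    diag_adjustment: float = 0.0

    def __post_init__(self) -> None:
        K = np.asarray(self.matrix, dtype=float)
        if K.ndim != 2 or K.shape[0] != K.shape[1]:
            raise ValueError("GRM must be square")
        if not np.allclose(K, K.T, atol=1e-10):
            raise ValueError("GRM must be symmetric")
        self.matrix = K

    @property
    def n(self) -> int:
        return self.matrix.shape[0]


def compute_grm(genotypes: GenotypeMatrix, method: str = "vanraden1") -> GRM:
    if method != "vanraden1":
        raise ValueError(f"unknown GRM method {method!r}")
    if genotypes.n_animals < 2:
        raise ValueError("GRM needs at least two samples")
    G = genotypes.mean_imputed()
    p = G.mean(axis=0) / 2.0
    poly = (p > 0.0) & (p < 1.0)
    if not poly.any():
        raise ValueError("all SNPs monomorphic; GRM undefined")
    Z = G[:, poly] - 2.0 * p[poly]
    denom = 2.0 * np.sum(p[poly] * (1.0 - p[poly]))
    K = (Z @ Z.T) / denom
    K = (K + K.T) / 2.0  # kill round-off asymmetry
    return GRM(K, list(genotypes.sample_ids), n_snps_used=int(poly.sum()))


def stabilize(grm: GRM, epsilon: float = 1e-6) -> GRM:
    """Add ``epsilon`` to the diagonal only if the smallest eigenvalue is
    negative; otherwise return the input unchanged."""
    w = np.linalg.eigvalsh(grm.matrix)
    lam_min = float(w[0])
    if lam_min >= 0.0:
        return grm
    bump = epsilon - lam_min
    K = grm.matrix + bump * np.eye(grm.n)
    return GRM(K, grm.sample_ids, grm.n_snps_used, grm.method, diag_adjustment=bump)


def write_grm_tsv(grm: GRM, path: str) -> None:
    import pandas as pd

    pd.DataFrame(grm.matrix, index=grm.sample_ids, columns=grm.sample_ids).to_csv(
        path, sep="\t"
    )


def write_grm_lower_triangle(grm: GRM, path: str) -> None:
    """GCTA-style text: one line per (i, j<=i) pair: i j n_snps value."""
    with open(path, "w") as fh:
        for i in range(grm.n):
            for j in range(i + 1):
                fh.write(f"{i + 1}\t{j + 1}\t{grm.n_snps_used}\t{grm.matrix[i, j]:.6f}\n")
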