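"""Core in-memory containers shared across pipeline stages.

Genotypes are held as an animals x SNPs matrix of additive allele counts
(0/1/2 copies of the B allele), with ``numpy.nan`` marking missing calls.
The marker map travels with the matrix so positional filters (gene
proximity, per-chromosome reports) never lose sync with the columns.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

MISSING = np.nan


@dataclass
class GenotypeMatrix:
    """Additive-coded genotypes plus marker map.

    Attributes
    ----------
    genotypes : (n_animals, n_snps) float array with values {0, 1, 2, nan}.
    sample_ids : animal identifiers, row order.
    marker_map : DataFrame with columns ``snp_id``, ``chrom``, ``pos`` in
        column order of ``genotypes``. Positions are 1-based.
    """

    genotypes: np.ndarray
    sample_ids: list[str]
    marker_map: pd.DataFrame

    def __post_init__(self) -> None:
        self.genotypes = np.asarray(self.genotypes, dtype=float)
        if self.genotypes.ndim != 2:
            raise ValueError("genotypes must be 2-D (animals x SNPs)")
        if len(self.sample_ids) != self.genotypes.shape[0]:
            raise ValueError("sample_ids length does not match genotype rows")
        if len(self.marker_map) != self.genotypes.shape[1]:
            raise ValueError("marker_map length does not match genotype columns")
        ok = np.isnan(self.genotypes) | np.isin(self.genotypes, (0.0, 1.0, 2.0))
        if not ok.all():
            raise ValueError("genotype codes must be in {0, 1, 2, missing}")

    @property
    def n_animals(self) -> int:
        return self.genotypes.shape[0]

    @property
    def n_snps(self) -> int:
        return self.genotypes.shape[1]

    @property
    def snp_ids(self) -> list[str]:
        return list(self.marker_map["snp_id"])

    def allele_frequencies(self) -> np.ndarray:
        """Observed B-allele frequency per SNP over non-missing calls."""
        return np.nanmean(self.genotypes, axis=0) / 2.0

    def minor_allele_frequencies(self) -> np.ndarray:
        p = self.allele_frequencies()
        return np.minimum(p, 1.0 - p)

    def call_rate_snps(self) -> np.ndarray:
        return 1.0 - np.isnan(self.genotypes).mean(axis=0)

    def call_rate_samples(self) -> np.ndarray:
        return 1.0 - np.isnan(self.genotypes).mean(axis=1)

    def subset(self, sample_idx=None, snp_idx=None) -> "GenotypeMatrix":
        g = self.genotypes
        ids = self.sample_ids
        mmap = self.marker_map
        if sample_idx is not None:
            sample_idx = np.asarray(sample_idx)
            g = g[sample_idx, :]
            ids = [ids[i] for i in sample_idx]
        if snp_idx is not None:
            snp_idx = np.asarray(snp_idx)
            g = g[:, snp_idx]
            mmap = mmap.iloc[snp_idx].reset_index(drop=True)
        return GenotypeMatrix(g.copy(), list(ids), mmap.copy())

    def mean_imputed(self) -> np.ndarray:
        """Genotypes with per-SNP mean substituted for missing calls."""
        g = self.genotypes.copy()
        means = np.nanmean(g, axis=0)
        nan_r, nan_c = np.nonzero(np.isnan(g))
        g[nan_r, nan_c] = means[nan_c]
        return g


@dataclass
class PhenotypeTable:
    """Phenotypes and the contemporary-group fixed-effect label.

    ``data`` has one row per animal: ``animal_id``, ``cg`` (contemporary
    group label), then one column per trait; missing values are NaN.
    """

    data: pd.DataFrame
    trait_names: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        if not self.trait_names:
            self.trait_names = [
                c for c in self.data.columns if c not in ("animal_id", "cg")
            ]
        missing = [c for c in ("animal_id", "cg") if c not in self.data.columns]
        if missing:
            raise ValueError(f"phenotype table missing columns: {missing}")

    @property
    def animal_ids(self) -> list[str]:
        return list(self.data["animal_id"].astype(str))

    def trait(self, name: str) -> np.ndarray:
        return self.data[name].to_numpy(dtype=float)
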