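"""Association Weight Matrix construction.

The AWM distils a multi-trait GWAS into a SNP x trait matrix of additive
effects: rows are SNPs associated with a key phenotype (raw p below a
permissive threshold), further required to be associated with a minimum
number of other phenotypes (pleiotropy filter) and to lie within or near a
gene; columns are the trait effect vectors, optionally z-scored so traits
measured in different units contribute equally to row-row correlations.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .io import GeneModelSet

__all__ = [
    "AwmConfig",
    "AWM",
    "select_key_snps",
    "count_other_trait_hits",
    "filter_by_pleiotropy",
    "filter_by_gene_proximity",
    "build_awm",
]


@dataclass
class AwmConfig:
    key_trait: str = "WBSF"
    key_p_threshold: float = 0.05
    other_p_threshold: float = 0.05
    min_other_traits: int = 2
    gene_window_bp: int = 2_500
    standardize_columns: bool = True
    include_key_trait_column: bool = True

    def __post_init__(self) -> None:
        for name in ("key_p_threshold", "other_p_threshold"):
            v = getattr(self, name)
            if not (0.0 < v < 1.0):
                raise ValueError(f"{name} must lie in (0, 1)")
        if self.gene_window_bp < 0:
            raise ValueError("gene_window_bp must be >= 0")


@dataclass
class AWM:
    matrix: pd.DataFrame  # selected SNPs (rows, genome order) x traits
    row_meta: pd.DataFrame  # snp_id, chrom, pos, gene_id, location, n_other_traits
    provenance: dict[str, object] = field(default_factory=dict)

    @property
    def snp_ids(self) -> list[str]:
        return list(self.matrix.index)

    @property
    def trait_names(self) -> list[str]:
        return list(self.matrix.columns)


def _trait_pivot(gwas: pd.DataFrame, value: str) -> pd.DataFrame:
    return gwas.pivot_table(index="snp_id", columns="trait", values=value, aggfunc="first")


def select_key_snps(gwas: pd.DataFrame, config: AwmConfig) -> list[str]:
    """SNPs with key-trait p below threshold, ordered by p ascending
    (ties broken by snp_id for determinism)."""
    key = gwas[gwas["trait"] == config.key_trait]
    if key.empty:
        raise ValueError(f"key trait {config.key_trait!r} absent from GWAS table")
    hits = key[key["p_value"] < config.key_p_threshold]
    hits = hits.sort_values(["p_value", "snp_id"], kind="mergesort")
    return list(hits["snp_id"])


def count_other_trait_hits(
    gwas: pd.DataFrame, snp_list: list[str], config: AwmConfig
) -> tuple[pd.Series, float]:
    """Per selected SNP, the number of non-key traits with p below the
    threshold; also the mean count across the selection."""
    if not snp_list:
        raise ValueError("snp_list is empty")
    other = gwas[gwas["trait"] != config.key_trait]
    pmat = _trait_pivot(other, "p_value").reindex(snp_list)
    counts = (pmat < config.other_p_threshold).sum(axis=1).astype(int)
    counts.name = "n_other_traits"
    return counts, float(counts.mean())


def filter_by_pleiotropy(snp_list: list[str], counts: pd.Series, config: AwmConfig) -> list[str]:
    return [s for s in snp_list if int(counts.get(s, 0)) >= config.min_other_traits]


def filter_by_gene_proximity(
    snp_list: list[str],
    marker_map: pd.DataFrame,
    gene_models: GeneModelSet,
    window_bp: int = 2_500,
) -> tuple[list[str], pd.DataFrame]:
    """Keep SNPs within [gene start - window, gene end + window] of some
    gene (1-based inclusive intervals); map each kept SNP to its nearest
    gene (ties: smaller distance, then lexicographic gene id) and record
    within-gene vs near-gene."""
    from .enrich import nearest_genes

    mm = marker_map.set_index("snp_id")
    absent = [s for s in snp_list if s not in mm.index]
    if absent:
        raise KeyError(f"SNPs missing from marker map: {absent[:5]}")
    missing_chrom = sorted(
        set(mm.loc[snp_list, "chrom"]) - set(gene_models.genes["chrom"])
    )
    if missing_chrom:
        raise ValueError(f"chromosomes absent from gene models: {missing_chrom}")
    sub = mm.loc[snp_list].reset_index()[["snp_id", "chrom", "pos"]]
    near = nearest_genes(sub, gene_models)
    hit = near[(near["distance_bp"] >= 0) & (near["distance_bp"] <= window_bp)].copy()
    kept = list(hit["snp_id"])
    hit["location"] = np.where(hit["distance_bp"] == 0, "within_gene", "near_gene")
    mapping = hit[["snp_id", "gene_id", "distance_bp", "location"]].reset_index(drop=True)
    return kept, mapping


def build_awm(
    gwas: pd.DataFrame,
    snp_list: list[str],
    config: AwmConfig,
    marker_map: pd.DataFrame | None = None,
    gene_map: pd.DataFrame | None = None,
    counts: pd.Series | None = None,
) -> AWM:
    """Assemble the SNP x trait effect matrix for the selected SNPs.

    Rows follow genome order (chrom, pos) when a marker map is given,
    otherwise the selection order; columns follow the GWAS table's trait
    order, with the key trait first when included. Columns with any
    missing effect are dropped with a warning recorded in provenance.
    """
    if not snp_list:
        raise ValueError("no SNPs selected for the AWM")
    traits = list(dict.fromkeys(gwas["trait"]))
    if not config.include_key_trait_column:
        traits = [t for t in traits if t != config.key_trait]
    else:
        traits = [config.key_trait] + [t for t in traits if t != config.key_trait]
    eff = _trait_pivot(gwas, "effect").reindex(snp_list)[traits]

    dropped_cols = [c for c in eff.columns if eff[c].isna().any()]
    if dropped_cols:
        eff = eff.drop(columns=dropped_cols)
    if eff.shape[1] == 0:
        raise ValueError("every trait column had missing effects")

    if marker_map is not None:
        mm = marker_map.set_index("snp_id").loc[snp_list]
        order = mm.sort_values(["chrom", "pos"]).index
        eff = eff.loc[order]
    if config.standardize_columns:
        sd = eff.std(axis=0, ddof=0)
        if (sd == 0).any():
            zero = list(sd.index[sd == 0])
            eff = eff.drop(columns=zero)
            dropped_cols += zero
        eff = (eff - eff.mean(axis=0)) / eff.std(axis=0, ddof=0)

    meta = pd.DataFrame({"snp_id": eff.index})
    if marker_map is not None:
        mm = marker_map.set_index("snp_id")
        meta["chrom"] = [mm.at[s, "chrom"] for s in eff.index]
        meta["pos"] = [int(mm.at[s, "pos"]) for s in eff.index]
    if gene_map is not None and len(gene_map):
        gm = gene_map.set_index("snp_id")
        meta["gene_id"] = [gm.at[s, "gene_id"] if s in gm.index else "" for s in eff.index]
        meta["location"] = [gm.at[s, "location"] if s in gm.index else "" for s in eff.index]
    if counts is not None:
        meta["n_other_traits"] = [int(counts.get(s, 0)) for s in eff.index]

    prov = {
        "n_rows": len(eff),
        "n_cols": eff.shape[1],
        "dropped_columns": dropped_cols,
        "standardized": config.standardize_columns,
        "key_trait": config.key_trait,
    }
    return AWM(matrix=eff, row_meta=meta.reset_index(drop=True), provenance=prov)
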