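"""Readers and writers for the pipeline's public text formats.

PLINK .ped/.map (white-space delimited, alleles coded A/B), phenotype TSV
(animal_id, cg, trait columns; missing = "NA"), gene models as GFF3
(1-based, inclusive), term-gene annotations as GMT, networks as edge TSV
and GraphML (via networkx).
"""

from __future__ import annotations

import os
from dataclasses import dataclass

import networkx as nx
import numpy as np
import pandas as pd

from .containers import GenotypeMatrix, PhenotypeTable

# ---------------------------------------------------------------------------
# PLINK text genotypes


def write_plink(gm: GenotypeMatrix, prefix: str, pedigree: dict[str, str] | None = None) -> None:
    """Write `prefix`.ped and `prefix`.map.

    Genotype 0 -> "A A", 1 -> "A B", 2 -> "B B", missing -> "0 0".
    ``pedigree`` optionally maps animal id -> sire id (dam unknown).
    """
    mmap = gm.marker_map
    with open(prefix + ".map", "w") as fh:
        for _, row in mmap.iterrows():
            fh.write(f"{row['chrom']}\t{row['snp_id']}\t0\t{int(row['pos'])}\n")
    alleles = {0.0: "A A", 1.0: "A B", 2.0: "B B"}
    with open(prefix + ".ped", "w") as fh:
        for i, aid in enumerate(gm.sample_ids):
            sire = pedigree.get(aid, "0") if pedigree else "0"
            fields = ["FAM", str(aid), str(sire), "0", "0", "-9"]
            row = gm.genotypes[i]
            fields.extend(alleles.get(g, "0 0") for g in row)
            fh.write(" ".join(fields) + "\n")


def read_plink(prefix: str) -> GenotypeMatrix:
    """Read `prefix`.ped / `prefix`.map into a GenotypeMatrix."""
    mmap = pd.read_csv(
        prefix + ".map",
        sep=r"\s+",
        header=None,
        names=["chrom", "snp_id", "cm", "pos"],
        dtype={"chrom": str, "snp_id": str},
    )[["snp_id", "chrom", "pos"]]
    n_snps = len(mmap)
    sample_ids: list[str] = []
    rows: list[np.ndarray] = []
    code = {("A", "A"): 0.0, ("A", "B"): 1.0, ("B", "A"): 1.0, ("B", "B"): 2.0}
    with open(prefix + ".ped") as fh:
        for line in fh:
            parts = line.split()
            if not parts:
                continue
            if len(parts) != 6 + 2 * n_snps:
                raise ValueError(
                    f"ped line for {parts[1] if len(parts) > 1 else '?'} has "
                    f"{len(parts) - 6} allele fields, expected {2 * n_snps}"
                )
            sample_ids.append(parts[1])
            a1 = parts[6::2]
            a2 = parts[7::2]
            geno = np.fromiter(
                (code.get((x, y), np.nan) for x, y in zip(a1, a2)),
                dtype=float,
                count=n_snps,
            )
            rows.append(geno)
    return GenotypeMatrix(np.vstack(rows), sample_ids, mmap)


# ---------------------------------------------------------------------------
# Phenotypes


def write_phenotypes(pt: PhenotypeTable, path: str) -> None:
    pt.data.to_csv(path, sep="\t", index=False, na_rep="NA")


def read_phenotypes(path: str) -> PhenotypeTable:
    df = pd.read_csv(path, sep="\t", na_values=["NA"], dtype={"animal_id": str, "cg": str})
    return PhenotypeTable(df)


# ---------------------------------------------------------------------------
# Gene models (GFF3)


@dataclass
class GeneModelSet:
    """Flat gene intervals: DataFrame with gene_id, chrom, start, end (1-based
    inclusive) plus optional exon sub-features (feature, parent columns)."""

    genes: pd.DataFrame
    features: pd.DataFrame | None = None  # exon/UTR rows, optional

    def __post_init__(self) -> None:
        need = {"gene_id", "chrom", "start", "end"}
        if not need.issubset(self.genes.columns):
            raise ValueError(f"gene table needs columns {sorted(need)}")

    @property
    def gene_ids(self) -> list[str]:
        return list(self.genes["gene_id"])


def write_gff3(models: GeneModelSet, path: str) -> None:
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for _, row in models.genes.iterrows():
            fh.write(
                f"{row['chrom']}\tawmnet\tgene\t{int(row['start'])}\t{int(row['end'])}"
                f"\t.\t+\t.\tID={row['gene_id']}\n"
            )
        if models.features is not None:
            for _, row in models.features.iterrows():
                fh.write(
                    f"{row['chrom']}\tawmnet\t{row['feature']}\t{int(row['start'])}"
                    f"\t{int(row['end'])}\t.\t+\t.\tParent={row['parent']}\n"
                )


def read_gff3(path: str) -> GeneModelSet:
    cols = ["chrom", "source", "feature", "start", "end", "score", "strand", "frame", "attr"]
    df = pd.read_csv(path, sep="\t", comment="#", header=None, names=cols, dtype={"chrom": str})
    df["start"] = df["start"].astype(int)
    df["end"] = df["end"].astype(int)

    def _attr(s: str, key: str) -> str:
        for part in s.split(";"):
            if part.startswith(key + "="):
                return part[len(key) + 1 :]
        return ""

    genes = df[df["feature"] == "gene"].copy()
    genes["gene_id"] = genes["attr"].map(lambda s: _attr(s, "ID"))
    feats = df[df["feature"] != "gene"].copy()
    features = None
    if len(feats):
        feats["parent"] = feats["attr"].map(lambda s: _attr(s, "Parent"))
        features = feats[["chrom", "feature", "start", "end", "parent"]].reset_index(drop=True)
    return GeneModelSet(
        genes[["gene_id", "chrom", "start", "end"]].reset_index(drop=True), features
    )


# ---------------------------------------------------------------------------
# GMT term annotations


def write_gmt(terms: dict[str, list[str]], path: str, descriptions: dict[str, str] | None = None) -> None:
    """Write term -> gene list mapping as GMT. Empty terms are dropped."""
    with open(path, "w") as fh:
        for term, genes in terms.items():
            if not genes:
                continue
            desc = (descriptions or {}).get(term, "na")
            fh.write("\t".join([term, desc] + list(genes)) + "\n")


def read_gmt(path: str) -> dict[str, list[str]]:
    terms: dict[str, list[str]] = {}
    with open(path) as fh:
        for line in fh:
            parts = line.rstrip("\n").split("\t")
            if len(parts) < 3:
                continue
            terms[parts[0]] = [g for g in parts[2:] if g]
    return terms


# ---------------------------------------------------------------------------
# Networks


def write_edge_tsv(graph: nx.Graph, path: str) -> None:
    with open(path, "w") as fh:
        fh.write("node_a\tnode_b\tweight\n")
        for u, v, d in sorted(graph.edges(data=True)):
            fh.write(f"{u}\t{v}\t{d.get('weight', 1.0):.6g}\n")


def write_graphml(graph: nx.Graph, path: str) -> None:
    nx.write_graphml(graph, path)


def ensure_dir(path: str) -> str:
    os.makedirs(path, exist_ok=True)
    return path
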