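"""SNP-to-gene annotation and term enrichment.

Annotation is interval-based: a SNP is within_gene (distance 0), near_gene
(within a window of a gene boundary) or intergenic, with exon/intron and
upstream/downstream sub-categories when exon-level features are present.
Enrichment is the upper-tail hypergeometric test per term with
Benjamini-Hochberg FDR, DAVID-style cluster enrichment scores
(-log10 geometric mean p) and ClueGO-style grouping of terms whose gene
memberships agree beyond chance (Cohen's kappa above a threshold).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import networkx as nx
import numpy as np
import pandas as pd
from scipy.stats import hypergeom
from statsmodels.stats.multitest import multipletests

from .io import GeneModelSet

__all__ = [
    "SnpAnnotation",
    "annotate_snps",
    "hypergeometric_enrichment",
    "cluster_enrichment_score",
    "kappa_matrix",
    "group_terms",
    "TermGroup",
]


@dataclass
class SnpAnnotation:
    snp_id: str
    gene_id: str
    distance_bp: int
    category: str  # within_gene | near_gene | intergenic
    sub_category: str = ""  # intron/exon/upstream/downstream when resolvable

    def __post_init__(self) -> None:
        if self.category == "within_gene" and self.distance_bp != 0:
            raise ValueError("within_gene implies distance 0")
        if self.category == "near_gene" and not (0 < self.distance_bp):
            raise ValueError("near_gene implies positive distance")


def nearest_genes(snps: pd.DataFrame, gene_models: GeneModelSet) -> pd.DataFrame:
    """Nearest gene per SNP (snp_id, chrom, pos table).

    Vectorized per chromosome: genes sorted by start, candidates taken in
    a +/-3 neighborhood of the searchsorted insertion point (covers
    moderately overlapping gene models); ties resolve to the smaller
    distance, then the lexicographically smaller gene id. Returns columns
    snp_id, gene_id, distance_bp, side (in/upstream/downstream);
    distance -1 and empty gene when the chromosome has no genes.
    """
    snps = snps.reset_index(drop=True)
    out_gene = np.full(len(snps), "", dtype=object)
    out_dist = np.full(len(snps), -1, dtype=np.int64)
    out_side = np.full(len(snps), "", dtype=object)
    genes_by_chrom = {c: g.sort_values(["start", "gene_id"]) for c, g in gene_models.genes.groupby("chrom")}
    pos_all = snps["pos"].to_numpy(dtype=np.int64)
    for chrom, rows in snps.groupby("chrom").groups.items():
        g = genes_by_chrom.get(chrom)
        if g is None or not len(g):
            continue
        idx = np.asarray(rows, dtype=np.int64)
        pos = pos_all[idx]
        starts = g["start"].to_numpy(dtype=np.int64)
        ends = g["end"].to_numpy(dtype=np.int64)
        gids = g["gene_id"].to_numpy(dtype=object)
        ins = np.searchsorted(starts, pos, side="right")
        best_dist = np.full(len(pos), np.iinfo(np.int64).max)
        best_gene = np.full(len(pos), "", dtype=object)
        best_side = np.full(len(pos), "", dtype=object)
        for off in range(-3, 3):
            cand = np.clip(ins + off, 0, len(starts) - 1)
            d_lo = starts[cand] - pos  # >0 when gene downstream of SNP
            d_hi = pos - ends[cand]
            dist = np.maximum(np.maximum(d_lo, d_hi), 0)
            gid = gids[cand]
            better = (dist < best_dist) | ((dist == best_dist) & (gid < best_gene))
            best_dist = np.where(better, dist, best_dist)
            best_gene = np.where(better, gid, best_gene)
            side = np.where(dist == 0, "in", np.where(d_lo > 0, "upstream", "downstream"))
            best_side = np.where(better, side, best_side)
        out_gene[idx] = best_gene
        out_dist[idx] = best_dist
        out_side[idx] = best_side
    return pd.DataFrame(
        {
            "snp_id": snps["snp_id"].to_numpy(),
            "gene_id": out_gene,
            "distance_bp": out_dist,
            "side": out_side,
        }
    )


def annotate_snps(
    snps: pd.DataFrame,
    gene_models: GeneModelSet,
    window_bp: int = 2_500,
) -> list[SnpAnnotation]:
    """Nearest-gene annotation for a marker table (snp_id, chrom, pos).

    Ties resolve to the smaller distance, then the lexicographically
    smaller gene id. SNPs on chromosomes absent from the gene models are
    intergenic with a warning.
    """
    missing_chroms = sorted(set(snps["chrom"]) - set(gene_models.genes["chrom"]))
    if missing_chroms:
        warnings.warn(f"chromosomes missing from gene models: {missing_chroms}")
    feats_by_gene: dict[str, pd.DataFrame] = {}
    if gene_models.features is not None:
        feats_by_gene = {g: f for g, f in gene_models.features.groupby("parent")}
    near = nearest_genes(snps.reset_index(drop=True), gene_models)
    pos_of = dict(zip(snps["snp_id"], snps["pos"].astype(int)))
    out = []
    for _, row in near.iterrows():
        sid, gid, dist, side = row["snp_id"], row["gene_id"], int(row["distance_bp"]), row["side"]
        if dist < 0 or dist > window_bp:
            out.append(SnpAnnotation(sid, gid, dist, "intergenic"))
        elif dist == 0:
            sub = ""
            feats = feats_by_gene.get(gid)
            if feats is not None:
                pos = pos_of[sid]
                in_exon = (
                    (feats["feature"] == "exon") & (feats["start"] <= pos) & (pos <= feats["end"])
                ).any()
                sub = "exon" if in_exon else "intron"
            out.append(SnpAnnotation(sid, gid, 0, "within_gene", sub))
        else:
            out.append(SnpAnnotation(sid, gid, dist, "near_gene", side))
    return out


def hypergeometric_enrichment(
    gene_list: list[str],
    universe: list[str],
    terms: dict[str, list[str]],
    p_max: float = 1.0,
    fdr_method: str = "fdr_bh",
) -> pd.DataFrame:
    """Upper-tail hypergeometric enrichment of ``gene_list`` in each term.

    Term gene sets are intersected with the universe; terms with zero
    overlap with the list are skipped. Output columns mirror the usual
    functional-annotation chart: term, count, percent (of list), p_value,
    fold_enrichment, fdr; sorted by p ascending (tie: term id).
    """
    uni = set(universe)
    lst = set(gene_list) & uni
    if not lst or not uni:
        raise ValueError("gene list and universe must be non-empty")
    if set(gene_list) - uni:
        raise ValueError("gene list must be a subset of the universe")
    M, N = len(uni), len(lst)
    rows = []
    for term, genes in terms.items():
        tset = set(genes) & uni
        k = len(tset & lst)
        if k == 0 or not tset:
            continue
        n = len(tset)
        p = float(hypergeom.sf(k - 1, M, n, N))
        rows.append(
            {
                "term": term,
                "count": k,
                "list_size": N,
                "term_size": n,
                "universe_size": M,
                "percent": 100.0 * k / N,
                "p_value": min(p, 1.0),
                "fold_enrichment": (k / N) / (n / M),
            }
        )
    if not rows:
        return pd.DataFrame(
            columns=["term", "count", "list_size", "term_size", "universe_size",
                     "percent", "p_value", "fold_enrichment", "fdr"]
        )
    df = pd.DataFrame(rows)
    df["fdr"] = multipletests(df["p_value"].to_numpy(), method=fdr_method)[1]
    df = df.sort_values(["p_value", "term"], kind="mergesort").reset_index(drop=True)
    return df[df["p_value"] <= p_max].reset_index(drop=True)


def cluster_enrichment_score(p_values) -> float:
    """-log10 of the geometric mean of member p-values (DAVID's annotation
    cluster enrichment score; 1.3 corresponds to a mean p of 0.05)."""
    p = np.asarray(list(p_values), dtype=float)
    if p.size == 0:
        raise ValueError("empty member set")
    if np.any((p <= 0) | (p > 1)):
        raise ValueError("p-values must lie in (0, 1]")
    return float(-np.mean(np.log10(p)))


def kappa_matrix(terms: dict[str, list[str]], gene_list: list[str]) -> pd.DataFrame:
    """Cohen's kappa between term membership vectors over the analyzed
    gene list: kappa = (P_obs - P_exp) / (1 - P_exp).

    When both terms cover every gene (P_exp = 1) kappa is defined as 1 for
    identical vectors and 0 otherwise.
    """
    genes = list(gene_list)
    if len(genes) == 0:
        raise ValueError("gene list is empty")
    names = [t for t in terms if set(terms[t]) & set(genes)]
    if len(names) < 2:
        raise ValueError("need >= 2 terms with nonzero membership on the list")
    B = np.array([[g in set(terms[t]) for g in genes] for t in names], dtype=float)
    n = len(genes)
    K = np.eye(len(names))
    for i in range(len(names)):
        for j in range(i + 1, len(names)):
            a, b = B[i], B[j]
            p_obs = float(np.mean(a == b))
            pa, pb = a.mean(), b.mean()
            p_exp = pa * pb + (1 - pa) * (1 - pb)
            if abs(1.0 - p_exp) < 1e-12:
                k = 1.0 if p_obs == 1.0 else 0.0
            else:
                k = (p_obs - p_exp) / (1.0 - p_exp)
            K[i, j] = K[j, i] = k
    return pd.DataFrame(K, index=names, columns=names)


@dataclass
class TermGroup:
    members: list[str]
    representative: str
    score: float


def group_terms(
    kappa: pd.DataFrame,
    enrichment: pd.DataFrame,
    threshold: float = 0.3,
) -> list[TermGroup]:
    """Single-linkage groups over the kappa > threshold graph.

    The representative is the member with the smallest enrichment p; the
    group score is the cluster enrichment score of member p-values.
    Groups are ordered by representative p ascending.
    """
    pv = enrichment.set_index("term")["p_value"].to_dict()
    g = nx.Graph()
    g.add_nodes_from(kappa.index)
    for i, ti in enumerate(kappa.index):
        for tj in kappa.columns[i + 1 :]:
            if kappa.at[ti, tj] > threshold:
                g.add_edge(ti, tj)
    groups = []
    for comp in nx.connected_components(g):
        members = sorted(comp)
        ps = [pv.get(t, 1.0) for t in members]
        rep = members[int(np.argmin(ps))]
        groups.append(TermGroup(members, rep, cluster_enrichment_score(ps)))
    groups.sort(key=lambda gr: (pv.get(gr.representative, 1.0), gr.representative))
    return groups
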