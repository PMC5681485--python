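"""Annotation and enrichment: interval-oracle equivalence, exact
hypergeometric enumeration, DAVID-style cluster scores, kappa grouping."""

from fractions import Fraction
from itertools import combinations
from math import comb

import numpy as np
import pandas as pd
import pytest

from awmnet.enrich import (
    annotate_snps,
    cluster_enrichment_score,
    group_terms,
    hypergeometric_enrichment,
    kappa_matrix,
)
from awmnet.io import GeneModelSet


@pytest.fixture
def gff_fixture():
    genes = pd.DataFrame({
        "gene_id": ["gA", "gB"],
        "chrom": ["chr1", "chr1"],
        "start": [100_000, 300_000],
        "end": [110_000, 305_000],
    })
    features = pd.DataFrame({
        "chrom": ["chr1", "chr1"],
        "feature": ["exon", "exon"],
        "start": [100_000, 104_000],
        "end": [101_000, 105_000],
        "parent": ["gA", "gA"],
    })
    return GeneModelSet(genes, features)


def test_exonic_and_intronic_subcategories(gff_fixture):
    snps = pd.DataFrame({
        "snp_id": ["in_exon", "in_intron"],
        "chrom": "chr1",
        "pos": [100_500, 102_000],
    })
    annos = {a.snp_id: a for a in annotate_snps(snps, gff_fixture)}
    assert annos["in_exon"].category == "within_gene"
    assert annos["in_exon"].sub_category == "exon"
    assert annos["in_intron"].sub_category == "intron"


def test_window_boundary_upstream(gff_fixture):
    snps = pd.DataFrame({
        "snp_id": ["edge", "beyond"],
        "chrom": "chr1",
        "pos": [100_000 - 2_500, 100_000 - 2_501],
    })
    annos = {a.snp_id: a for a in annotate_snps(snps, gff_fixture, window_bp=2_500)}
    assert annos["edge"].category == "near_gene"
    assert annos["edge"].sub_category == "upstream"
    assert annos["beyond"].category == "intergenic"


def test_missing_chromosome_intergenic_with_warning(gff_fixture):
    snps = pd.DataFrame({"snp_id": ["sX"], "chrom": ["chrX"], "pos": [500]})
    with pytest.warns(UserWarning, match="chrX"):
        annos = annotate_snps(snps, gff_fixture)
    assert annos[0].category == "intergenic"


def test_annotation_matches_bruteforce_oracle():
    rng = np.random.default_rng(4)
    rows, pos = [], 1
    for k in range(25):
        start = pos + int(rng.integers(2_000, 20_000))
        end = start + int(rng.integers(500, 6_000))
        rows.append({"gene_id": f"g{k:02d}", "chrom": f"c{k % 3}", "start": start, "end": end})
        pos = end
    gm = GeneModelSet(pd.DataFrame(rows))
    snps = pd.DataFrame({
        "snp_id": [f"s{i}" for i in range(400)],
        "chrom": [f"c{i % 3}" for i in range(400)],
        "pos": rng.integers(1, pos + 10_000, size=400),
    })
    annos = {a.snp_id: a for a in annotate_snps(snps, gm, window_bp=2_500)}
    for _, s in snps.iterrows():
        best = None
        for _, g in gm.genes.iterrows():
            if g["chrom"] != s["chrom"]:
                continue
            d = max(g["start"] - s["pos"], s["pos"] - g["end"], 0)
            if best is None or (d, g["gene_id"]) < best:
                best = (d, g["gene_id"])
        a = annos[s["snp_id"]]
        if best is None or best[0] > 2_500:
            assert a.category == "intergenic"
        else:
            assert (a.distance_bp, a.gene_id) == best
            assert a.category == ("within_gene" if best[0] == 0 else "near_gene")


# ---------------------------------------------------------------------------
# hypergeometric enrichment


def exhaustive_tail(M, n, N, k):
    """P(overlap >= k) by exhaustive enumeration of C(M, N) draws."""
    total = Fraction(0)
    for x in range(k, min(n, N) + 1):
        total += Fraction(comb(n, x) * comb(M - n, N - x), comb(M, N))
    return float(total)


def test_full_overlap_worked_case():
    universe = [f"g{i}" for i in range(20)]
    term = {"T": universe[:5]}
    res = hypergeometric_enrichment(universe[:5], universe, term)
    assert res.iloc[0]["p_value"] == pytest.approx(1 / 15_504, rel=1e-12)


def test_fold_enrichment_arithmetic():
    # count 10 of list 100, term 20 of universe 2000 -> FE = (10/100)/(20/2000)
    universe = [f"g{i}" for i in range(2000)]
    term_genes = universe[:20]
    gene_list = universe[:10] + universe[100:190]
    res = hypergeometric_enrichment(gene_list, universe, {"T": term_genes})
    assert res.iloc[0]["count"] == 10
    assert res.iloc[0]["fold_enrichment"] == pytest.approx(10.0)


def test_matches_exhaustive_enumeration_small_universes():
    rng = np.random.default_rng(5)
    for _ in range(30):
        M = int(rng.integers(8, 31))
        universe = [f"g{i}" for i in range(M)]
        n = int(rng.integers(1, M))
        N = int(rng.integers(1, M))
        term = list(rng.choice(universe, n, replace=False))
        lst = list(rng.choice(universe, N, replace=False))
        k = len(set(term) & set(lst))
        if k == 0:
            continue
        res = hypergeometric_enrichment(lst, universe, {"T": term})
        assert res.iloc[0]["p_value"] == pytest.approx(
            exhaustive_tail(M, n, N, k), rel=1e-10
        )


def test_null_calibration_uniform_draws():
    """Uniformly drawn gene lists: ~5% of term tests fall below p = 0.05
    (slightly fewer, the discrete tail is conservative)."""
    rng = np.random.default_rng(6)
    universe = [f"g{i}" for i in range(2000)]
    terms = {
        f"T{j}": list(rng.choice(universe, 100, replace=False)) for j in range(20)
    }
    hits = trials = 0
    for _ in range(50):  # 50 draws x 20 terms = 1000 term tests
        lst = list(rng.choice(universe, 150, replace=False))
        res = hypergeometric_enrichment(lst, universe, terms)
        hits += int((res["p_value"] < 0.05).sum())
        trials += len(res)
    assert 0.02 <= hits / trials <= 0.08


def test_bh_fdr_monotone_in_p_ranking():
    rng = np.random.default_rng(7)
    universe = [f"g{i}" for i in range(300)]
    terms = {f"T{j}": list(rng.choice(universe, rng.integers(10, 60), replace=False))
             for j in range(15)}
    lst = list(rng.choice(universe, 50, replace=False))
    res = hypergeometric_enrichment(lst, universe, terms)
    fdr = res["fdr"].to_numpy()  # rows sorted by p ascending
    assert (np.diff(fdr) >= -1e-12).all()
    assert (res["fdr"] >= res["p_value"] - 1e-12).all()


def test_list_outside_universe_rejected():
    with pytest.raises(ValueError):
        hypergeometric_enrichment(["x"], ["a", "b"], {"T": ["a"]})


# ---------------------------------------------------------------------------
# cluster enrichment score


def test_cluster_score_worked_values():
    assert cluster_enrichment_score([0.05, 0.05, 0.05]) == pytest.approx(
        -np.log10(0.05), abs=1e-9
    )
    assert cluster_enrichment_score([0.1]) == pytest.approx(1.0)
    assert cluster_enrichment_score([0.01, 1.0]) == pytest.approx(1.0)
    with pytest.raises(ValueError):
        cluster_enrichment_score([])


# ---------------------------------------------------------------------------
# kappa grouping


def test_kappa_worked_values():
    genes = ["g1", "g2", "g3", "g4"]
    terms = {"A": ["g1", "g2"], "B": ["g1", "g2"], "C": ["g3", "g4"]}
    K = kappa_matrix(terms, genes)
    assert K.at["A", "B"] == pytest.approx(1.0)
    assert K.at["A", "C"] == pytest.approx(-1.0)  # P_obs=0, P_exp=0.5
    assert (np.diag(K.to_numpy()) == 1.0).all()
    assert np.allclose(K.to_numpy(), K.to_numpy().T)


def test_kappa_random_memberships_mean_zero():
    rng = np.random.default_rng(8)
    genes = [f"g{i}" for i in range(40)]
    vals = []
    for _ in range(500):
        a = set(np.array(genes)[rng.random(40) < 0.4])
        b = set(np.array(genes)[rng.random(40) < 0.4])
        if not a or not b:
            continue
        K = kappa_matrix({"A": list(a), "B": list(b)}, genes)
        vals.append(K.at["A", "B"])
    assert abs(np.mean(vals)) < 0.02


def test_group_terms_threshold_one_gives_singletons():
    genes = [f"g{i}" for i in range(10)]
    terms = {"A": genes[:4], "B": genes[3:7], "C": genes[6:]}
    enr = pd.DataFrame({"term": list(terms), "p_value": [0.01, 0.02, 0.03]})
    K = kappa_matrix(terms, genes)
    groups = group_terms(K, enr, threshold=1.0)
    assert len(groups) == 3
    assert all(len(g.members) == 1 for g in groups)


def test_two_disjoint_term_blocks_give_two_groups():
    genes = [f"g{i}" for i in range(12)]
    terms = {
        "A1": genes[:6], "A2": genes[:5] + [genes[6]],
        "B1": genes[6:], "B2": genes[7:] + [genes[0]],
    }
    enr = pd.DataFrame({"term": list(terms), "p_value": [0.01, 0.04, 0.02, 0.03]})
    K = kappa_matrix(terms, genes)
    groups = group_terms(K, enr, threshold=0.3)
    assert len(groups) == 2
    for g in groups:
        assert g.representative == min(g.members, key=lambda t: float(
            enr.set_index("term").at[t, "p_value"]))
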