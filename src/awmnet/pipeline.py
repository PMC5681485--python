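"""End-to-end orchestration: simulate (or load) -> QC -> GRM -> multi-trait
mixed-model GWAS -> AWM -> PCIT -> MCODE -> annotation -> enrichment.

Every stage writes its public text format into the output directory so any
stage can be re-entered from serialized inputs, and a RunManifest records
parameters and the surviving-count funnel per stage.
"""

from __future__ import annotations

import hashlib
import json
import logging
import os
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import awm as awm_mod
from . import enrich as enrich_mod
from . import io as io_mod
from . import mcode as mcode_mod
from . import pcit as pcit_mod
from .grm import compute_grm, stabilize
from .gwas import run_multitrait_gwas
from .qc import QCThresholds, apply_qc
from .sim import SimConfig, make_gene_models, make_term_annotation, simulate_genotypes, simulate_phenotypes

log = logging.getLogger("awmnet")

__all__ = ["PipelineConfig", "RunManifest", "run_all", "report"]


@dataclass
class PipelineConfig:
    # exactly one of (sim, real input paths) drives the run
    sim: SimConfig | None = None
    ped_prefix: str | None = None
    phenotypes_path: str | None = None
    gff3_path: str | None = None
    gmt_path: str | None = None
    out_dir: str = "awmnet_out"
    qc: QCThresholds = field(default_factory=QCThresholds)
    awm: awm_mod.AwmConfig = field(default_factory=awm_mod.AwmConfig)
    mcode: mcode_mod.McodeParams = field(default_factory=mcode_mod.McodeParams)
    enrichment_p_max: float = 0.05
    kappa_threshold: float = 0.3
    hwe_method: str = "chi2"  # exact available; chi2 default at panel scale
    reml_criterion: str = "REML"
    seed: int = 0
    write_outputs: bool = True

    def __post_init__(self) -> None:
        simulated = self.sim is not None
        real = self.ped_prefix is not None
        if simulated == real:
            raise ValueError("exactly one of a SimConfig or real input paths must be given")
        if real and self.phenotypes_path is None:
            raise ValueError("real inputs need a phenotype table")


@dataclass
class RunManifest:
    stages: dict[str, dict] = field(default_factory=dict)
    status: str = "ok"

    def record(self, stage: str, params: dict | None = None, **counts) -> None:
        self.stages[stage] = {"params": params or {}, "counts": counts}
        log.info("stage %s: %s", stage, counts)

    def funnel(self) -> dict[str, int]:
        keys = [
            ("qc", "n_snps_out"),
            ("gwas", "n_tests"),
            ("awm_key", "n_key_snps"),
            ("awm_pleiotropy", "n_pleiotropic"),
            ("awm_gene", "n_gene_proximal"),
            ("pcit", "n_nodes"),
            ("mcode", "n_clustered_nodes"),
        ]
        return {
            f"{s}.{k}": self.stages[s]["counts"][k]
            for s, k in keys
            if s in self.stages and k in self.stages[s]["counts"]
        }


def _hash_file(path: str) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(65536), b""):
            h.update(chunk)
    return h.hexdigest()[:16]


def run_all(config: PipelineConfig) -> RunManifest:
    manifest = RunManifest()
    out = config.out_dir
    if config.write_outputs:
        io_mod.ensure_dir(out)

    # --- stage 0: inputs
    truth = None
    models = None
    terms = None
    if config.sim is not None:
        geno = simulate_genotypes(config.sim)
        pheno, truth = simulate_phenotypes(geno, config.sim)
        models = make_gene_models(geno.marker_map, config.sim, truth)
        terms, descs = make_term_annotation(models, config.sim, truth)
        if config.write_outputs:
            io_mod.write_plink(geno, os.path.join(out, "genotypes"), getattr(geno, "sire_of", None))
            io_mod.write_phenotypes(pheno, os.path.join(out, "phenotypes.tsv"))
            io_mod.write_gff3(models, os.path.join(out, "genes.gff3"))
            io_mod.write_gmt(terms, os.path.join(out, "terms.gmt"), descs)
        manifest.record(
            "simulate",
            {"seed": config.sim.seed},
            n_animals=geno.n_animals,
            n_snps=geno.n_snps,
            n_traits=len(pheno.trait_names),
            n_qtl=len(truth.qtl_ids),
        )
    else:
        geno = io_mod.read_plink(config.ped_prefix)
        pheno = io_mod.read_phenotypes(config.phenotypes_path)
        if config.gff3_path:
            models = io_mod.read_gff3(config.gff3_path)
        if config.gmt_path:
            terms = io_mod.read_gmt(config.gmt_path)
        manifest.record(
            "load",
            {"ped": _hash_file(config.ped_prefix + ".ped")},
            n_animals=geno.n_animals,
            n_snps=geno.n_snps,
        )

    # --- QC
    geno_qc, qc_report = apply_qc(geno, config.qc, hwe_method=config.hwe_method)
    manifest.record(
        "qc",
        {"thresholds": vars(config.qc)},
        n_snps_in=qc_report.n_snps_in,
        n_snps_out=qc_report.n_snps_out,
        n_samples_out=qc_report.n_samples_out,
    )

    # --- GRM
    K = stabilize(compute_grm(geno_qc))
    manifest.record("grm", {"method": K.method}, n_snps_used=K.n_snps_used)

    # --- GWAS
    gwas_table, vcs, trait_summary = run_multitrait_gwas(
        pheno, geno_qc, K, criterion=config.reml_criterion
    )
    if config.write_outputs:
        gwas_table.to_csv(os.path.join(out, "gwas.tsv"), sep="\t", index=False)
        trait_summary.to_csv(os.path.join(out, "trait_summary.tsv"), sep="\t", index=False)
    manifest.record(
        "gwas",
        {"criterion": config.reml_criterion},
        n_tests=len(gwas_table),
        n_traits=len(vcs),
    )
    manifest.stages["gwas"]["trait_summary"] = trait_summary.to_dict("records")

    # --- AWM funnel
    acfg = config.awm
    if acfg.key_trait not in pheno.trait_names:
        raise ValueError(f"key trait {acfg.key_trait!r} not among traits {pheno.trait_names}")
    key_snps = awm_mod.select_key_snps(gwas_table, acfg)
    manifest.record("awm_key", {"p": acfg.key_p_threshold}, n_key_snps=len(key_snps))
    if not key_snps:
        manifest.status = "no key-trait associations"
        return manifest
    counts, mean_hits = awm_mod.count_other_trait_hits(gwas_table, key_snps, acfg)
    pleio = awm_mod.filter_by_pleiotropy(key_snps, counts, acfg)
    manifest.record(
        "awm_pleiotropy",
        {"min_other_traits": acfg.min_other_traits},
        n_pleiotropic=len(pleio),
        mean_other_trait_hits=round(mean_hits, 3),
    )
    gene_map = pd.DataFrame()
    if models is not None and pleio:
        pleio, gene_map = awm_mod.filter_by_gene_proximity(
            pleio, geno_qc.marker_map, models, acfg.gene_window_bp
        )
    manifest.record("awm_gene", {"window_bp": acfg.gene_window_bp}, n_gene_proximal=len(pleio))
    if len(pleio) < 3:
        manifest.status = "too few SNPs for network inference"
        return manifest
    awm = awm_mod.build_awm(
        gwas_table, pleio, acfg, geno_qc.marker_map,
        gene_map if len(gene_map) else None, counts,
    )
    if config.write_outputs:
        awm.matrix.to_csv(os.path.join(out, "awm.tsv"), sep="\t")
        awm.row_meta.to_csv(os.path.join(out, "awm_rows.tsv"), sep="\t", index=False)
    manifest.record("awm", vars(acfg), n_rows=len(awm.matrix), n_cols=awm.matrix.shape[1])

    # --- PCIT network
    corr = pcit_mod.correlate_rows(awm)
    mask = pcit_mod.pcit(corr)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", pcit_mod.EmptyNetworkWarning)
        network = pcit_mod.build_network(awm, corr, mask)
    if config.write_outputs and network.number_of_edges():
        io_mod.write_edge_tsv(network, os.path.join(out, "network_edges.tsv"))
        io_mod.write_graphml(network, os.path.join(out, "network.graphml"))
    manifest.record(
        "pcit", {}, n_nodes=network.number_of_nodes(), n_edges=network.number_of_edges()
    )
    if network.number_of_edges() == 0:
        manifest.status = "empty network"
        return manifest

    # --- MCODE clusters
    clusters = mcode_mod.find_clusters(network, config.mcode)
    clustered_nodes = sorted({n for c in clusters for n in c.nodes})
    if config.write_outputs:
        mcode_mod.cluster_report(clusters).to_csv(
            os.path.join(out, "clusters.tsv"), sep="\t", index=False
        )
    manifest.record(
        "mcode",
        vars(config.mcode),
        n_clusters=len(clusters),
        n_clustered_nodes=len(clustered_nodes),
    )
    manifest.stages["mcode"]["clusters"] = [
        {"rank": c.rank, "score": round(c.score, 2), "nodes": c.n_nodes,
         "edges": c.n_edges, "members": c.nodes}
        for c in clusters
    ]

    # --- annotation + enrichment
    if models is None:
        manifest.status = "annotation skipped (no gene models)"
        return manifest
    net_snps = geno_qc.marker_map[geno_qc.marker_map["snp_id"].isin(network.nodes)]
    annos = enrich_mod.annotate_snps(net_snps, models, config.awm.gene_window_bp)
    network_genes = sorted({a.gene_id for a in annos if a.category != "intergenic" and a.gene_id})
    cluster_snp_set = set(clustered_nodes)
    cluster_genes = sorted(
        {a.gene_id for a in annos if a.snp_id in cluster_snp_set and a.category != "intergenic" and a.gene_id}
    )
    manifest.record("annotate", {}, n_network_genes=len(network_genes),
                    n_cluster_genes=len(cluster_genes))
    manifest.stages["annotate"]["cluster_genes"] = cluster_genes

    if terms is None:
        manifest.status = "enrichment skipped (no GMT)"
        return manifest
    # universe: all genes hosting >= 1 post-QC SNP (within the gene window)
    all_annos = enrich_mod.annotate_snps(geno_qc.marker_map, models, config.awm.gene_window_bp)
    universe = sorted({a.gene_id for a in all_annos if a.category != "intergenic" and a.gene_id})
    if not network_genes:
        manifest.status = "enrichment skipped (no annotated network genes)"
        return manifest
    enr = enrich_mod.hypergeometric_enrichment(network_genes, universe, terms)
    groups = []
    sig = enr[enr["p_value"] < config.enrichment_p_max]
    if len(enr) >= 2:
        kap = enrich_mod.kappa_matrix(
            {t: terms[t] for t in enr["term"]}, network_genes
        )
        groups = enrich_mod.group_terms(kap, enr, config.kappa_threshold)
    if config.write_outputs:
        enr.to_csv(os.path.join(out, "enrichment.tsv"), sep="\t", index=False)
    manifest.record(
        "enrich",
        {"p_max": config.enrichment_p_max, "kappa": config.kappa_threshold,
         "universe": "genes hosting >=1 post-QC SNP"},
        n_terms_tested=len(enr),
        n_terms_significant=len(sig),
        n_groups=len(groups),
    )
    manifest.stages["enrich"]["top_terms"] = enr.head(10).to_dict("records")
    if truth is not None:
        manifest.stages["truth"] = {
            "qtl_ids": truth.qtl_ids,
            "qtl_genes": truth.qtl_genes,
            "pleiotropic_key_qtl": truth.pleiotropic_key_qtl(
                config.awm.key_trait, config.awm.min_other_traits
            ),
        }
    if config.write_outputs:
        with open(os.path.join(out, "manifest.json"), "w") as fh:
            json.dump({"status": manifest.status, "stages": manifest.stages}, fh,
                      indent=2, default=str)
    return manifest


def report(manifest: RunManifest) -> str:
    """Human-readable run summary: per-trait h2 and significance counts,
    the AWM funnel, the cluster score table, and top enriched terms."""
    lines = [f"status: {manifest.status}", ""]
    gw = manifest.stages.get("gwas", {})
    if "trait_summary" in gw:
        lines.append("trait\tn\tpseudo_h2\tp<0.05\tp<0.01\tp<0.001")
        for row in gw["trait_summary"]:
            lines.append(
                f"{row['trait']}\t{row['n']}\t{row['pseudo_h2']:.3f}\t"
                f"{row['n_p_lt_0.05']}\t{row['n_p_lt_0.01']}\t{row['n_p_lt_0.001']}"
            )
        lines.append("")
    lines.append("funnel: " + json.dumps(manifest.funnel()))
    mc = manifest.stages.get("mcode", {})
    if mc.get("clusters"):
        lines.append("")
        lines.append("network\tscore\tnodes\tedges")
        for c in mc["clusters"]:
            lines.append(f"{c['rank']}\t{c['score']}\t{c['nodes']}\t{c['edges']}")
    elif "mcode" in manifest.stages:
        lines.append("no clusters")
    en = manifest.stages.get("enrich", {})
    if en.get("top_terms"):
        lines.append("")
        lines.append("term\tcount\tpercent\tp_value\tFE\tFDR")
        for t in en["top_terms"]:
            lines.append(
                f"{t['term']}\t{t['count']}\t{t['percent']:.2f}\t"
                f"{t['p_value']:.3g}\t{t['fold_enrichment']:.2f}\t{t['fdr']:.3g}"
            )
    return "\n".join(lines)
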