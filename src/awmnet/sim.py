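"""Synthetic half-sib cattle study generator.

Emulates the design of a multi-trait beef-quality association study: a few
hundred sire half-sib families genotyped on a dense SNP panel, phenotyped
for a panel of correlated carcass/meat-quality traits recorded within
contemporary groups (sex x location x harvest-date classes), with a known
set of pleiotropic QTL planted so parameter recovery can be scored.

Model per trait t:

    y_t = cg_effect[group] + sum_q beta_qt * g_q + u_t + e_t

where u_t is a polygenic term built from all SNPs (traits in the same
pleiotropy block share a latent polygenic factor) and variances are scaled
so var(QTL) + var(u) = h2_t and var(e) = 1 - h2_t, i.e. phenotypic variance
is ~1 net of contemporary-group effects.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .containers import GenotypeMatrix, PhenotypeTable
from .io import GeneModelSet

__all__ = [
    "SimConfig",
    "GroundTruth",
    "simulate_genotypes",
    "simulate_phenotypes",
    "make_gene_models",
    "make_term_annotation",
]


@dataclass
class SimConfig:
    """Study-design parameters for the synthetic population.

    Defaults describe a desk-scale version of a 2,110-head, 155-sire,
    54k-SNP design: 500 animals in ~13-offspring half-sib families, 5,000
    SNPs on 10 chromosomes, 10 traits with heritabilities spanning the
    0.17-0.67 range typical of carcass and meat-quality traits, and 24
    pleiotropic QTL each shared by a block of 4 traits.
    """

    n_animals: int = 500
    n_sires: int = 37
    n_snps: int = 5000
    n_chromosomes: int = 10
    maf_range: tuple[float, float] = (0.05, 0.5)
    n_traits: int = 10
    heritabilities: tuple[float, ...] | float | None = None  # None: spread over 0.17-0.67
    n_qtl: int = 12
    pleiotropy_block_size: int = 4
    qtl_effect_sd: float = 0.3
    qtl_maf_min: float = 0.15  # planted QTL are common variants
    n_contemporary_groups: int = 8
    cg_effect_sd: float = 0.5
    missing_pheno_rate: float = 0.02
    missing_geno_rate: float = 0.0
    block_polygenic_share: float = 0.5  # share of polygenic variance from the block factor
    snp_spacing_bp: int = 50_000
    seed: int = 0

    def __post_init__(self) -> None:
        lo, hi = self.maf_range
        if not (0.0 < lo <= hi <= 0.5):
            raise ValueError(f"maf_range must lie in (0, 0.5], got {self.maf_range}")
        if self.n_sires > self.n_animals:
            raise ValueError("n_sires cannot exceed n_animals")
        if self.n_qtl > self.n_snps:
            raise ValueError("n_qtl cannot exceed n_snps")
        h2 = self.heritability_vector()
        if np.any((h2 < 0) | (h2 > 1)):
            raise ValueError("heritabilities must lie in [0, 1]")
        if not (0 <= self.missing_pheno_rate < 1):
            raise ValueError("missing_pheno_rate must lie in [0, 1)")

    def heritability_vector(self) -> np.ndarray:
        h2 = self.heritabilities
        if h2 is None:
            # span the range typical of carcass/meat-quality panels
            return np.linspace(0.17, 0.67, self.n_traits)
        if np.isscalar(h2):
            return np.full(self.n_traits, float(h2))
        h2 = np.asarray(h2, dtype=float)
        if len(h2) != self.n_traits:
            raise ValueError("heritabilities length must equal n_traits")
        return h2

    @property
    def trait_names(self) -> list[str]:
        return [f"trait_{i + 1}" for i in range(self.n_traits)]

    @property
    def key_trait(self) -> str:
        # middle trait: covered by the most overlapping pleiotropy blocks
        return self.trait_names[self.n_traits // 2]


@dataclass
class GroundTruth:
    """Planted parameters for recovery scoring."""

    qtl_ids: list[str]
    qtl_trait_map: dict[str, set[str]]
    qtl_effects: pd.DataFrame  # QTL x trait betas
    true_h2: dict[str, float]
    cg_effects: pd.DataFrame  # group x trait
    sire_of: dict[str, str] = field(default_factory=dict)
    qtl_genes: dict[str, str] = field(default_factory=dict)  # filled by make_gene_models

    def __post_init__(self) -> None:
        if any(len(v) == 0 for v in self.qtl_trait_map.values()):
            raise ValueError("every planted QTL must affect at least one trait")

    def pleiotropic_key_qtl(self, key_trait: str, min_other: int = 2) -> list[str]:
        """QTL affecting the key trait plus >= min_other other traits —
        the planted signal the AWM selection rules can in principle keep."""
        out = []
        for q, traits in self.qtl_trait_map.items():
            if key_trait in traits and len(traits) - 1 >= min_other:
                out.append(q)
        return out


def _rng_for(config: SimConfig, stage: str) -> np.random.Generator:
    # deterministic per-stage stream: stable hash of the stage name spawned
    # off the single user seed
    tag = sum(ord(c) * 31**i for i, c in enumerate(stage)) % (2**31)
    return np.random.default_rng(np.random.SeedSequence((config.seed, tag)))


def simulate_genotypes(config: SimConfig) -> GenotypeMatrix:
    """Half-sib genotypes: sires drawn Binomial(2, MAF) per SNP; each
    offspring inherits one allele sampled from its sire's genotype and one
    from the population (dam pool at the population frequency)."""
    rng = _rng_for(config, "genotypes")
    m, n = config.n_snps, config.n_animals
    lo, hi = config.maf_range
    maf = rng.uniform(lo, hi, size=m) if hi > lo else np.full(m, lo)

    sire_geno = rng.binomial(2, maf, size=(config.n_sires, m)).astype(float)
    sire_assign = rng.integers(0, config.n_sires, size=n)
    # paternal allele: Bernoulli(sire dosage / 2); maternal: Bernoulli(maf)
    paternal = rng.random((n, m)) < (sire_geno[sire_assign] / 2.0)
    maternal = rng.random((n, m)) < maf
    geno = paternal.astype(float) + maternal.astype(float)

    if config.missing_geno_rate > 0:
        drop = rng.random((n, m)) < config.missing_geno_rate
        geno[drop] = np.nan

    chrom_of = np.repeat(
        np.arange(config.n_chromosomes), int(np.ceil(m / config.n_chromosomes))
    )[:m]
    pos_within = np.zeros(m, dtype=int)
    for c in range(config.n_chromosomes):
        idx = np.nonzero(chrom_of == c)[0]
        pos_within[idx] = (np.arange(len(idx)) + 1) * config.snp_spacing_bp
    mmap = pd.DataFrame(
        {
            "snp_id": [f"snp_{i + 1}" for i in range(m)],
            "chrom": [f"chr{c + 1}" for c in chrom_of],
            "pos": pos_within,
        }
    )
    sample_ids = [f"an_{i + 1}" for i in range(n)]
    gm = GenotypeMatrix(geno, sample_ids, mmap)
    gm.sire_of = {sample_ids[i]: f"sire_{sire_assign[i] + 1}" for i in range(n)}
    gm.true_maf = maf
    return gm


def _polygenic_factor(Z: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    """Unit-variance genetic factor from small effects at every SNP."""
    a = rng.normal(size=Z.shape[1])
    u = Z @ a
    sd = u.std()
    if sd == 0:
        return np.zeros(len(u))
    return u / sd


def simulate_phenotypes(
    genotypes: GenotypeMatrix, config: SimConfig
) -> tuple[PhenotypeTable, GroundTruth]:
    rng = _rng_for(config, "phenotypes")
    n, m = genotypes.n_animals, genotypes.n_snps
    h2 = config.heritability_vector()
    traits = config.trait_names

    G = genotypes.mean_imputed()
    p = G.mean(axis=0) / 2.0
    Z = G - 2.0 * p  # centered dosage

    # --- QTL placement: common variants (QC must not delete planted
    # truth), each QTL tied to one block of the disjoint trait partition
    eligible = np.nonzero(p * (1 - p) >= config.qtl_maf_min * (1 - config.qtl_maf_min))[0]
    if len(eligible) < config.n_qtl:
        eligible = np.arange(m)
    qtl_idx = np.sort(rng.choice(eligible, size=config.n_qtl, replace=False))
    qtl_ids = [genotypes.snp_ids[i] for i in qtl_idx]
    bs = min(config.pleiotropy_block_size, config.n_traits)
    n_blocks = int(np.ceil(config.n_traits / bs))
    blocks = [
        list(range(b * bs, min((b + 1) * bs, config.n_traits))) for b in range(n_blocks)
    ]
    block_of_qtl = rng.integers(0, n_blocks, size=config.n_qtl)
    beta = np.zeros((config.n_qtl, config.n_traits))
    trait_map: dict[str, set[str]] = {}
    # fixed-magnitude effects (uniform in a +/-20% band around
    # qtl_effect_sd) with one sign per QTL across its block: every planted
    # QTL carries a detectable, comparable signal with the coherent
    # direction structure expected of positively correlated traits, so
    # "truth recovery" is well defined
    for q in range(config.n_qtl):
        block = blocks[block_of_qtl[q]]
        sign = rng.choice((-1.0, 1.0))
        for t in block:
            if config.qtl_effect_sd > 0:
                beta[q, t] = sign * config.qtl_effect_sd * rng.uniform(0.8, 1.2)
        affected = {traits[t] for t in block} if config.qtl_effect_sd > 0 else {traits[block[0]]}
        trait_map[qtl_ids[q]] = affected

    # --- shared polygenic factors: one latent factor per trait block
    block_factor = {b: _polygenic_factor(Z, rng) for b in range(n_blocks)}
    trait_covered_by = {
        t: [b for b in range(n_blocks) if t in blocks[b]] for t in range(config.n_traits)
    }

    cg_labels = rng.integers(0, config.n_contemporary_groups, size=n)
    cg_eff = rng.normal(0.0, config.cg_effect_sd, size=(config.n_contemporary_groups, config.n_traits))

    Y = np.zeros((n, config.n_traits))
    realized_beta = beta.copy()
    for t in range(config.n_traits):
        qtl_part = Z[:, qtl_idx] @ beta[:, t]
        var_qtl = qtl_part.var()
        if var_qtl > h2[t] and var_qtl > 0:
            # planted effects exceed the heritability budget: shrink to fit,
            # leaving no polygenic variance
            scale = np.sqrt(h2[t] / var_qtl)
            warnings.warn(
                f"trait {traits[t]}: QTL variance {var_qtl:.3f} exceeds h2={h2[t]:.2f}; "
                "effects rescaled to fit"
            )
            qtl_part *= scale
            realized_beta[:, t] *= scale
            var_qtl = h2[t]
        var_u = h2[t] - var_qtl
        covering = trait_covered_by[t]
        if var_u > 0:
            own = _polygenic_factor(Z, rng)
            if covering:
                rho = config.block_polygenic_share
                shared = block_factor[covering[0]]
                u = np.sqrt(rho) * shared + np.sqrt(1.0 - rho) * own
                usd = u.std()
                u = u / usd if usd > 0 else u
            else:
                u = own
            u = u * np.sqrt(var_u)
        else:
            u = np.zeros(n)
        var_e = 1.0 - h2[t]
        if var_e <= 0 and h2[t] >= 1.0 and var_qtl == 0 and var_u == 0:
            raise ValueError(f"trait {traits[t]}: h2=1 with no genetic variance available")
        e = rng.normal(0.0, np.sqrt(max(var_e, 0.0)), size=n)
        Y[:, t] = cg_eff[cg_labels, t] + qtl_part + u + e

    if config.missing_pheno_rate > 0:
        drop = rng.random(Y.shape) < config.missing_pheno_rate
        Y[drop] = np.nan

    data = pd.DataFrame(Y, columns=traits)
    data.insert(0, "cg", [f"cg_{g + 1}" for g in cg_labels])
    data.insert(0, "animal_id", genotypes.sample_ids)
    pt = PhenotypeTable(data, traits)

    truth = GroundTruth(
        qtl_ids=qtl_ids,
        qtl_trait_map=trait_map,
        qtl_effects=pd.DataFrame(realized_beta, index=qtl_ids, columns=traits),
        true_h2={traits[t]: float(h2[t]) for t in range(config.n_traits)},
        cg_effects=pd.DataFrame(
            cg_eff,
            index=[f"cg_{g + 1}" for g in range(config.n_contemporary_groups)],
            columns=traits,
        ),
        sire_of=getattr(genotypes, "sire_of", {}),
    )
    return pt, truth


def make_gene_models(
    marker_map: pd.DataFrame,
    config: SimConfig,
    truth: GroundTruth | None = None,
    fraction_in_gene: float = 0.7,
    gene_halfwidth_bp: int = 2_000,
) -> GeneModelSet:
    """Place non-overlapping gene intervals so that ``fraction_in_gene`` of
    SNPs fall inside a gene; QTL SNPs are always given a host gene so
    downstream annotation can recover them.

    Genes are centred on their SNP with half-width < half the SNP spacing,
    so a gene never reaches within 2.5 kbp of a neighbouring SNP.
    """
    if len(marker_map) == 0:
        raise ValueError("marker map is empty")
    rng = _rng_for(config, "genes")
    snp_ids = list(marker_map["snp_id"])
    qtl_set = set(truth.qtl_ids) if truth is not None else set()

    n_genic = int(round(fraction_in_gene * len(snp_ids)))
    non_qtl = [i for i, s in enumerate(snp_ids) if s not in qtl_set]
    qtl_i = [i for i, s in enumerate(snp_ids) if s in qtl_set]
    genic = set(qtl_i[: n_genic] if fraction_in_gene > 0 else [])
    remaining = n_genic - len(genic)
    if remaining > 0:
        genic |= set(rng.choice(non_qtl, size=min(remaining, len(non_qtl)), replace=False).tolist())

    half_max = min(gene_halfwidth_bp, max((config.snp_spacing_bp - 2 * 2_500) // 2 - 1, 1))
    rows = []
    qtl_genes = {}
    for k, i in enumerate(sorted(genic)):
        chrom = marker_map["chrom"].iloc[i]
        pos = int(marker_map["pos"].iloc[i])
        half = int(rng.integers(half_max // 2 + 1, half_max + 1))
        start = max(1, pos - half)
        gid = f"gene_{k + 1:05d}"
        rows.append({"gene_id": gid, "chrom": chrom, "start": start, "end": pos + half})
        if snp_ids[i] in qtl_set:
            qtl_genes[snp_ids[i]] = gid
    if truth is not None:
        truth.qtl_genes = qtl_genes
    genes = pd.DataFrame(rows, columns=["gene_id", "chrom", "start", "end"])
    # guard against overlap (possible only if spacing is very tight)
    if len(genes):
        genes = genes.sort_values(["chrom", "start"]).reset_index(drop=True)
        keep = [True] * len(genes)
        for j in range(1, len(genes)):
            prev = genes.iloc[j - 1]
            cur = genes.iloc[j]
            if cur["chrom"] == prev["chrom"] and cur["start"] <= prev["end"]:
                keep[j] = False
        genes = genes[keep].reset_index(drop=True)
    return GeneModelSet(genes)


def make_term_annotation(
    models: GeneModelSet,
    config: SimConfig,
    truth: GroundTruth | None = None,
    n_terms: int = 30,
    term_size_range: tuple[int, int] = (5, 40),
) -> tuple[dict[str, list[str]], dict[str, str]]:
    """Random term -> gene sets of varied sizes plus one planted "causal"
    term holding the QTL-hosting genes (padded with random genes so its
    size is not a giveaway). Returns (terms, descriptions); empty terms
    are dropped."""
    genes = models.gene_ids
    if not genes:
        raise ValueError("no genes to annotate")
    rng = _rng_for(config, "terms")
    terms: dict[str, list[str]] = {}
    desc: dict[str, str] = {}
    lo, hi = term_size_range
    for k in range(n_terms):
        size = int(rng.integers(lo, min(hi, len(genes)) + 1))
        members = sorted(rng.choice(genes, size=size, replace=False).tolist())
        if members:
            terms[f"TERM:{k + 1:04d}"] = members
            desc[f"TERM:{k + 1:04d}"] = "random background term"
    causal_members = sorted(set((truth.qtl_genes or {}).values())) if truth is not None else []
    if causal_members:
        pad = [g for g in genes if g not in causal_members]
        n_pad = min(len(pad), max(0, int(rng.integers(2, 8))))
        extra = rng.choice(pad, size=n_pad, replace=False).tolist() if n_pad else []
        terms["TERM:causal"] = sorted(causal_members + extra)
        desc["TERM:causal"] = "planted causal process"
    return terms, desc
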