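# Methods

This note records the models, estimators and design choices behind
`awmnet`, and what the synthetic testbed does and does not establish.

## Mixed-model association (EMMAX)

Per trait the model is y = Xβ + g + e with g ~ N(0, σ²ₐK),
e ~ N(0, σ²ₑI); X carries an intercept plus contemporary-group dummies
(first level dropped, full rank enforced). K is the VanRaden method-1
genomic relationship matrix, K = ZZᵀ/(2Σpⱼ(1−pⱼ)), built from mean-imputed
dosages with observed allele frequencies; monomorphic SNPs are skipped. A
negative smallest eigenvalue (possible after subsetting) is repaired by
`grm.stabilize`, which shifts the diagonal just enough and records the
shift.

Variance components are estimated once per trait under the null. With
K = UDUᵀ the restricted likelihood (Harville form, including the
log|XᵀV⁻¹X| − log|XᵀX| terms, so it is the exact REML criterion, not an
approximation) is profiled in the single ratio δ = σ²ₑ/σ²ₐ. The search is
a 100-point grid on log δ ∈ [−10, 10] followed by bounded Brent
refinement in the best bracket; the grid guards against the multimodal
profiles that defeat pure local search. When the profile is flat (K = I:
σ²ₐ and σ²ₑ enter only through their sum) the result carries
`identifiable=False`. ML is available; REML is the default because fixed
effects are always present. Pseudo-heritability is σ²ₐ/(σ²ₐ+σ²ₑ).

The scan holds the fitted correlation structure K + δI fixed and fits
each SNP by GLS on [X | g] in the rotated basis. The residual variance is
re-estimated per SNP and the Wald statistic referred to t with
df = n − rank([X | g]). This scale-free convention makes p-values exactly
invariant to rescaling K or y, and reduces the scan to OLS as σ²ₐ → 0.
SNPs whose X-residualized variance is negligible relative to the
best-conditioned SNP (monomorphic or collinear with the design) are
flagged with effect 0, p 1, rather than tested. Animals missing a trait
are dropped for that trait and the variance components re-estimated on
the subset; traits below a minimum record count (default 30) are skipped
with a warning.

## AWM construction

The funnel is fixed and logged: key-phenotype filter (raw p below a
permissive threshold, default 0.05) → pleiotropy filter (p < 0.05 for at
least `min_other_traits` non-key traits, default 2) → gene proximity
(within a gene or ≤ 2,500 bp from one, 1-based inclusive intervals,
boundary inclusive on both sides; nearest gene breaks ties by distance
then lexicographic id). Effect columns are z-scored by default so traits
in different units contribute equally to row correlations; raw mode is
retained for sensitivity analysis. The key-trait column is included by
default and removable by flag. Both "at least two phenotypes" readings of
the pleiotropy rule are reachable through `min_other_traits`.

## PCIT

Edges start from the Pearson correlation of AWM rows across trait
columns (≥ 3 columns required; constant rows are excluded with a
warning). For every trio (x, y, z) the three first-order partials are
computed; the tolerance is the mean of the three partial/direct ratios;
edge (x, y) is flagged by z when |r_xy| ≤ |ε·r_xz| and |r_xy| ≤ |ε·r_yz|.
An edge survives iff no trio flags it. Trios containing a conditioning
correlation within 1e-12 of ±1, a zero direct correlation (ratio
undefined), or a non-finite tolerance are skipped. The production code
vectorizes over (x, y) per conditioning z; tests hold it exactly equal to
a deliberately naive scalar triple loop on hundreds of random correlation
matrices. Note the tolerance rule removes edges that are *weak relative
to the conditioning pair* — a large direct correlation whose partial is
exactly zero is still kept; this follows from the rule itself.

## MCODE

Vertex weight = k_max × density of the highest k-core of the closed
neighborhood. Clusters grow breadth-first from the highest-weight
unassigned seed, admitting neighbors with weight ≥ seed × (1 − vwp)
(vwp = 0.2 default); each vertex joins at most one cluster. Haircut is
iterative: vertices with fewer than two in-cluster links are removed
until stable — the single-pass variant leaves long chains alive, which
contradicts the algorithm's intent of returning dense cores. Optional
fluff adds boundary vertices whose closed-neighborhood density exceeds a
threshold. Clusters under 3 nodes are discarded; score = density × nodes
with the simple-graph maximum n(n−1)/2, no self-edges; all ties break
lexicographically, making output order deterministic.

A known, documented limitation: the seed-relative weight cutoff cannot
separate two statistically identical dense blocks that touch. Both
blocks' vertex weights are drawn from the same distribution, so once one
bridge edge is crossed the whole second block is admitted; tighter
cutoffs fragment a block rather than partition the graph. MCODE is a
dense-complex extractor, not a community-detection method — for
partition-type questions use a partitioner. The planted-structure tests
therefore check exact recovery of disjoint dense complexes (which MCODE
does cleanly) and record the merge behaviour on touching blocks.

## Annotation and enrichment

SNP-to-gene assignment is interval arithmetic on the GFF3 gene table
(vectorized searchsorted with a ±3-neighbor candidate window; exact
equality with a brute-force interval scan is a test invariant).
Categories: within_gene (distance 0; exon/intron resolved when exon
features exist), near_gene (0 < distance ≤ window, upstream/downstream by
side), intergenic. Enrichment is the upper-tail hypergeometric test per
term, restricted to the chosen universe — by default all genes hosting at
least one post-QC SNP, recorded in output headers since enrichment
results are only interpretable relative to their background — with
Benjamini–Hochberg FDR across tested terms. Functional grouping computes
Cohen's κ between term membership vectors over the analyzed gene list and
takes single-linkage components of the κ > 0.3 graph; the group
representative is the member with the smallest p and the group score is
−log₁₀ of the geometric-mean member p (1.3 ≙ mean p of 0.05). The full
iterative ClueGO merge procedure is simplified to single-linkage
components; only threshold semantics, not merge order, affect the
reported groups here.

## Synthetic testbed

`awmnet.sim` emulates the study design the pipeline targets: sire
half-sib families with a common dam pool, contemporary groups as additive
fixed shifts, a SNP panel with uniform MAF and even spacing (50 kb), and
a block of correlated traits. Per trait,

y = cg + Σ_q β_q·z_q + u + e,

where u is a polygenic term built from small effects at every SNP (traits
in the same pleiotropy block share a latent polygenic factor, default
50% of polygenic variance) and variances are scaled so genetic/total
variance equals the requested h² with total variance 1 net of group
effects. Defaults describe a desk-scale version of a ~2,000-head,
155-sire, 54k-SNP design: 500 animals / 37 sires, 5,000 SNPs on 10
chromosomes, 10 traits with h² spread over 0.17–0.67, 12 QTL each shared
by a disjoint block of 4 traits.

Planted QTL are meant to be *recoverable* ground truth, so three choices
depart from a fully diffuse architecture, all deliberate:

- QTL sit at common variants (MAF ≥ 0.15) so marker QC cannot silently
  delete the truth the tests score against.
- Effect magnitudes are uniform in ±20% around `qtl_effect_sd` (default
  0.3 phenotypic SD per allele) rather than Gaussian: Gaussian draws put
  much of their mass at effects undetectable at n = 500, which makes
  "fraction of truth recovered" ill-posed.
- Each QTL carries one sign across its trait block, the direction
  structure of positively correlated traits; independent signs would
  decorrelate the AWM rows of same-block QTL and erase the co-association
  signal PCIT is meant to find.

The generator does not model LD beyond family structure, genotype error,
sex chromosomes, dominance or imprinting. Consequently the tests
demonstrate internal correctness and recovery under the stated
architecture — clean planted signal, MCAR missingness, no LD — not
performance on real bovine data, where LD decay, assortative structure
and trait non-normality all bite. Gene models are non-overlapping
intervals centred on a configurable fraction of SNPs (QTL hosted first),
sized so a gene never reaches within 2.5 kb of a neighboring SNP, making
requested in/near-gene fractions exact. The term catalog contains random
terms of varied sizes plus one planted causal term holding the QTL host
genes padded with a few random genes.

Sire-offspring relatedness note: sires are latent parents (only offspring
are genotyped), so the testable relatedness invariant is mean GRM ≈ 0.25
among half-sib pairs against ≈ 0 for unrelated pairs — checked against
founder allele frequencies, since in-sample centering removes the shared
component of relatedness by construction.

## Numerical and reproducibility choices

- Single user seed; per-stage streams derived via `SeedSequence` with a
  stable stage tag — identical seeds give bit-identical outputs, and
  stages can be regenerated independently.
- HWE exact test sums Levene–Haldane probabilities ≤ that of the observed
  heterozygote count (tie tolerance 1e-12 in log space); monomorphic
  SNPs return p = 1. The exact and χ² versions agree within 0.02 only
  for samples in the tens of thousands — the discrete test is
  conservative by about half its p-value granularity — so the default
  panel-scale method choice (exact for QC runs, χ² inside the pipeline)
  is about speed, not accuracy.
- QC order: sample call rate → SNP call rate → MAF → HWE, so HWE sees the
  cleaned sample set. QC is idempotent away from call-rate boundaries;
  exactly at a boundary, removing SNPs can re-expose a sample on a second
  pass — inherent to cascade filters.
- Problem sizes in tests and the acceptance script (500–800 animals,
  2,000–5,000 SNPs, 10–20 seeds per claim) were chosen as the smallest
  sizes at which the tested quantities have stable expectations; the
  mixed-model calibration runs use 20 sires × 25 offspring to make the
  family-structure contrast (EMMAX λ ≈ 1 vs OLS λ > 1.2) unambiguous,
  while the pipeline default mirrors the ~13 offspring/sire ratio of the
  motivating design.
- Recovery scoring counts a planted QTL as recoverable when it affects
  the key trait and ≥ 2 others — the only QTL the AWM selection rules
  can in principle keep.
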