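"""Synthetic study generator.

Emulates the inputs of a summary-statistic TWAS so every downstream stage is
testable without external downloads:

* an LD reference panel of hard-call genotypes whose LD decays with distance
  (AR(1) latent Gaussians thresholded at the allele frequency),
* sparse cis-eQTL weight sets scaled to a stated cis-h2,
* GWAS z-scores built so that gene g's TWAS statistic has expectation
  ``lambda_g`` (its non-centrality) on top of LD-correlated MVN(0, V) noise,
* random gene sets with one optionally enriched set whose member genes get an
  additive shift on lambda.

Genes are laid on a single synthetic chromosome at fixed spacing (1 Mb apart
by default, SNPs within +/-250 kb of each gene's midpoint) so the 500-kb locus
merging and 5-Mb correlation-sparsification rules downstream are both
exercised. Seeds are explicit; fixed seed gives bit-identical output.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
from scipy.signal import lfilter
from scipy.stats import norm

from .datatypes import (
    GeneSetCollection,
    GenotypePanel,
    GwasSummary,
    SnpRecord,
    WeightSet,
)

import pandas as pd

GENE_SPACING_BP = 1_000_000
CIS_HALF_WINDOW_BP = 250_000
GENE_HALF_BODY_BP = 10_000


@dataclass
class SimulationConfig:
    """Study conditions for the synthetic TWAS.

    ``gene_ncp`` is the baseline per-gene TWAS non-centrality (0 = null gene);
    ``enrichment_shift`` is added to lambda for members of the planted set.
    """

    n_ref_individuals: int = 500
    n_genes: int = 200
    snps_per_gene: int = 10
    ld_decay_rho: float = 0.8
    maf_range: tuple[float, float] = (0.05, 0.5)
    n_causal_eqtl_per_gene: int = 3
    cis_h2: float = 0.2
    gene_ncp: float = 0.0
    n_sets: int = 40
    set_size_range: tuple[int, int] = (10, 50)
    enrichment_shift: float = 0.0
    seed: int = 0
    gwas_n: int = 100_000  # nominal sample size written to sumstats

    def __post_init__(self) -> None:
        for name in ("n_ref_individuals", "n_genes", "snps_per_gene",
                     "n_causal_eqtl_per_gene", "n_sets"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be >= 1")
        if not (0.0 <= self.ld_decay_rho < 1.0):
            raise ValueError("ld_decay_rho must be in [0, 1)")
        lo, hi = self.maf_range
        if not (0.0 < lo <= hi <= 0.5):
            raise ValueError("maf_range must lie within (0, 0.5]")
        if not (0.0 < self.cis_h2 <= 1.0):
            raise ValueError("cis_h2 must be in (0, 1]")
        if self.set_size_range[0] < 1 or self.set_size_range[0] > self.set_size_range[1]:
            raise ValueError("invalid set_size_range")
        if self.n_causal_eqtl_per_gene > self.snps_per_gene:
            raise ValueError("n_causal_eqtl_per_gene exceeds snps_per_gene")


@dataclass(frozen=True)
class GeneMeta:
    gene_id: str
    chrom: str
    start: int
    end: int
    snp_ids: tuple[str, ...]


def gene_layout(config: SimulationConfig, chrom: str = "1") -> list[GeneMeta]:
    """Deterministic gene/SNP placement on one synthetic chromosome."""
    genes = []
    m = config.snps_per_gene
    for g in range(config.n_genes):
        center = (g + 1) * GENE_SPACING_BP
        snp_ids = tuple(f"rs{g:05d}_{j:03d}" for j in range(m))
        genes.append(GeneMeta(
            gene_id=f"G{g:05d}",
            chrom=chrom,
            start=center - GENE_HALF_BODY_BP,
            end=center + GENE_HALF_BODY_BP,
            snp_ids=snp_ids,
        ))
    return genes


def _snp_positions(config: SimulationConfig, gene_index: int) -> np.ndarray:
    center = (gene_index + 1) * GENE_SPACING_BP
    m = config.snps_per_gene
    return center - CIS_HALF_WINDOW_BP + np.round(
        np.arange(m) * (2 * CIS_HALF_WINDOW_BP) / max(m - 1, 1)
    ).astype(int)


def simulate_reference_panel(
    config: SimulationConfig, seed: Optional[int] = None, chrom: str = "1"
) -> GenotypePanel:
    """Draw an LD-structured genotype panel.

    Two latent standard-normal AR(1) chains per individual (one per haplotype,
    correlation ``ld_decay_rho`` between adjacent SNPs) are thresholded at
    Phi^-1(maf) to give allele indicators; dosage is their sum, so genotypes
    are in Hardy-Weinberg proportions and empirical LD decays monotonically
    with SNP lag.
    """
    rng = np.random.default_rng(config.seed if seed is None else seed)
    genes = gene_layout(config, chrom)
    n_snps = config.n_genes * config.snps_per_gene
    if n_snps == 0:
        raise ValueError("degenerate config: zero SNPs")
    n_hap = 2 * config.n_ref_individuals
    rho = config.ld_decay_rho

    mafs = rng.uniform(config.maf_range[0], config.maf_range[1], size=n_snps)
    thresholds = norm.ppf(mafs)

    innov = rng.standard_normal((n_hap, n_snps))
    innov[:, 1:] *= np.sqrt(1.0 - rho * rho)
    # AR(1) recursion latent[j] = rho*latent[j-1] + innov[j] as an IIR filter
    latent = lfilter([1.0], [1.0, -rho], innov, axis=1)

    alleles = (latent < thresholds[None, :]).astype(np.int8)
    dosages = alleles[: config.n_ref_individuals] + alleles[config.n_ref_individuals:]

    # Guard monomorphic columns (possible at small n x low maf): make one het.
    mono = np.nonzero(dosages.std(axis=0) == 0)[0]
    for j in mono:
        dosages[0, j] = 1 if dosages[0, j] != 1 else 0

    records = []
    for g, gene in enumerate(genes):
        pos = _snp_positions(config, g)
        for j, snp_id in enumerate(gene.snp_ids):
            k = g * config.snps_per_gene + j
            records.append(SnpRecord(
                snp_id=snp_id, chrom=chrom, bp=int(pos[j]),
                a1="A", a2="G", maf=float(mafs[k]),
            ))
    return GenotypePanel(snps=records, dosages=dosages)


def simulate_weight_set(
    gene: GeneMeta,
    panel: GenotypePanel,
    config: SimulationConfig,
    seed: Optional[int] = None,
) -> WeightSet:
    """Sparse cis weight vector scaled so var(Xw) = cis_h2 in the panel.

    Also simulates one expression realisation y = Xw + e (var(e) = 1 - cis_h2)
    and records each SNP's marginal eQTL z-score in the panel, which fills the
    top-eQTL column of downstream result tables.
    """
    rng = np.random.default_rng(seed if seed is not None else config.seed)
    if len(gene.snp_ids) == 0:
        raise ValueError(f"{gene.gene_id}: cis window contains no SNPs")
    if len(gene.snp_ids) < config.n_causal_eqtl_per_gene:
        raise ValueError(f"{gene.gene_id}: fewer cis SNPs than causal eQTLs")

    X = panel.standardized(list(gene.snp_ids))
    m = X.shape[1]
    causal = np.sort(rng.choice(m, size=config.n_causal_eqtl_per_gene, replace=False))
    w = np.zeros(m)
    w[causal] = rng.standard_normal(config.n_causal_eqtl_per_gene)
    if not np.any(w != 0):  # degenerate draw of all-zero effects
        w[causal[0]] = 1.0
    g_hat = X @ w
    var_g = g_hat.var()
    w *= np.sqrt(config.cis_h2 / var_g)

    genetic = X @ w
    noise_sd = np.sqrt(max(1.0 - config.cis_h2, 0.0))
    y = genetic + noise_sd * rng.standard_normal(X.shape[0])
    y_sd = y.std()
    n = X.shape[0]
    with np.errstate(invalid="ignore", divide="ignore"):
        r = (X * (y - y.mean())[:, None]).mean(axis=0) / y_sd
        r = np.clip(r, -0.999999, 0.999999)
    eqtl_z = r * np.sqrt(n)

    return WeightSet(
        gene_id=gene.gene_id, chrom=gene.chrom, start=gene.start, end=gene.end,
        snp_ids=list(gene.snp_ids),
        a1=["A"] * m, a2=["G"] * m,
        w=w, cis_h2=config.cis_h2, eqtl_z=eqtl_z,
    )


def simulate_gwas_z(
    weight_sets: Sequence[WeightSet],
    panel: GenotypePanel,
    config: SimulationConfig,
    lam: Optional[np.ndarray] = None,
    seed: Optional[int] = None,
    ridge: float = 1e-6,
) -> GwasSummary:
    """GWAS z-scores carrying expression-mediated signal plus LD noise.

    z = sum_g lambda_g V w~_g + eps, with w~_g = w_g / sqrt(w_g' V w_g),
    eps ~ MVN(0, V) drawn through a Cholesky factor of V + ridge*I. Under this
    construction the TWAS statistic of gene g has expectation lambda_g exactly
    (when other genes are null) and variance 1.
    """
    rng = np.random.default_rng(seed if seed is not None else config.seed)
    if lam is None:
        lam = np.full(len(weight_sets), config.gene_ncp)
    lam = np.asarray(lam, dtype=float)
    if lam.size != len(weight_sets):
        raise ValueError("lambda vector length must match weight sets")

    snp_ids = panel.snp_ids
    Xs = panel.standardized(snp_ids)
    n = Xs.shape[0]
    V = (Xs.T @ Xs) / n

    mean = np.zeros(len(snp_ids))
    for ws, l in zip(weight_sets, lam):
        if l == 0.0:
            continue
        cols = np.array([panel.column(s) for s in ws.snp_ids])
        Vw = V[:, cols] @ ws.w
        denom = np.sqrt(ws.w @ Vw[cols])
        mean += l * Vw / denom

    L = np.linalg.cholesky(V + ridge * np.eye(V.shape[0]))
    z = mean + L @ rng.standard_normal(V.shape[0])

    table = pd.DataFrame({
        "snp": snp_ids,
        "a1": [rec.a1 for rec in panel.snps],
        "a2": [rec.a2 for rec in panel.snps],
        "z": z,
        "n": config.gwas_n,
    })
    return GwasSummary(table)


def simulate_gene_sets(
    gene_ids: Sequence[str],
    config: SimulationConfig,
    seed: Optional[int] = None,
) -> GeneSetCollection:
    """Random gene sets; the first is the designated (possibly enriched) set."""
    rng = np.random.default_rng(seed if seed is not None else config.seed)
    lo, hi = config.set_size_range
    if hi > len(gene_ids):
        raise ValueError("max set size exceeds number of genes")
    gene_ids = list(gene_ids)
    sets: dict[str, list[str]] = {}
    for k in range(config.n_sets):
        size = int(rng.integers(lo, hi + 1))
        members = sorted(rng.choice(gene_ids, size=size, replace=False).tolist())
        name = "set_enriched" if k == 0 else f"set_{k:04d}"
        sets[name] = members
    return GeneSetCollection(sets=sets, enriched_set="set_enriched")


@dataclass
class SimulatedStudy:
    config: SimulationConfig
    genes: list[GeneMeta]
    panel: GenotypePanel
    weight_sets: list[WeightSet]
    gene_sets: GeneSetCollection
    lam: np.ndarray
    gwas: GwasSummary


def simulate_study(config: SimulationConfig, seed: Optional[int] = None) -> SimulatedStudy:
    """Generate a complete synthetic study with a planted enrichment.

    lambda_g = gene_ncp + enrichment_shift * 1[g in planted set]; all stages
    are seeded from one SeedSequence so a fixed seed is fully reproducible.
    """
    root = np.random.SeedSequence(config.seed if seed is None else seed)
    s_panel, s_weights, s_sets, s_gwas = [
        int(s.generate_state(1)[0] % (2**31)) for s in root.spawn(4)
    ]
    genes = gene_layout(config)
    panel = simulate_reference_panel(config, seed=s_panel)
    wrng = np.random.default_rng(s_weights)
    weight_sets = [
        simulate_weight_set(g, panel, config, seed=int(wrng.integers(2**31)))
        for g in genes
    ]
    gene_sets = simulate_gene_sets([g.gene_id for g in genes], config, seed=s_sets)
    lam = np.full(config.n_genes, config.gene_ncp, dtype=float)
    if gene_sets.enriched_set is not None and config.enrichment_shift != 0.0:
        members = set(gene_sets.sets[gene_sets.enriched_set])
        for i, g in enumerate(genes):
            if g.gene_id in members:
                lam[i] += config.enrichment_shift
    gwas = simulate_gwas_z(weight_sets, panel, config, lam=lam, seed=s_gwas)
    return SimulatedStudy(
        config=config, genes=genes, panel=panel, weight_sets=weight_sets,
        gene_sets=gene_sets, lam=lam, gwas=gwas,
    )
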