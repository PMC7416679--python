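"""Locus aggregation, joint/conditional analysis and GWAS conditioning.

Significant genes within 500 kb of each other (boundary-to-boundary, chained
transitively) form a locus. Within a locus, conditionally independent signals
are found by backward elimination on the multivariate-normal conditional
z-score, using the gene x gene predicted-expression correlation Omega as the
covariance of the TWAS z-vector. Locus SNP statistics can then be conditioned
on the imputed expression of candidate genes: a locus is "explained" when its
sentinel SNP drops below genome-wide significance.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np

from .datatypes import (
    ConditionalResult,
    GeneCorrelation,
    GenotypePanel,
    GwasConditioned,
    Locus,
    TwasResult,
    WeightSet,
)
from .twas import predicted_expression, z_to_p, _chrom_key

logger = logging.getLogger(__name__)

GENOME_WIDE_P = 5e-8
LOCUS_WINDOW_BP = 500_000


def aggregate_loci(
    significant: Sequence[TwasResult], window: int = LOCUS_WINDOW_BP
) -> list[Locus]:
    """Merge significant genes within ``window`` bp into discrete loci.

    Chain merging (transitive closure): A-B and B-C within the window places
    A, B, C in one locus even if A-C is not. Gap is measured from gene end to
    the next gene start; different chromosomes never merge.
    """
    loci: list[Locus] = []
    ordered = sorted(significant, key=lambda r: (_chrom_key(r.chrom), r.start))
    cluster: list[TwasResult] = []

    def flush() -> None:
        if not cluster:
            return
        lead = max(cluster, key=lambda r: abs(r.twas_z))
        loci.append(Locus(
            locus_id=f"L{len(loci) + 1:03d}",
            chrom=cluster[0].chrom,
            start=min(r.start for r in cluster),
            end=max(r.end for r in cluster),
            members=[r.gene_id for r in cluster],
            lead_gene=lead.gene_id,
        ))
        cluster.clear()

    for r in ordered:
        if cluster and (
            r.chrom != cluster[-1].chrom
            or r.start - max(c.end for c in cluster) > window
        ):
            flush()
        cluster.append(r)
    flush()
    return loci


def predicted_expression_correlation(
    weight_sets: Sequence[WeightSet], panel: GenotypePanel
) -> GeneCorrelation:
    """Omega: correlation across panel individuals of predicted expressions."""
    gene_ids, expr, dropped = predicted_expression(weight_sets, panel)
    if dropped:
        raise ValueError(f"zero-variance predicted expression for gene {dropped[0]}")
    n = expr.shape[0]
    omega = (expr.T @ expr) / n
    omega = (omega + omega.T) / 2.0
    np.fill_diagonal(omega, 1.0)
    return GeneCorrelation(gene_ids=gene_ids, matrix=omega)


def conditional_z_score(
    z: np.ndarray, omega: np.ndarray, i: int, others: list[int],
    ridge: float = 0.0,
) -> float:
    """z_i conditioned on z[others] under z ~ MVN(shifts, Omega)."""
    if not others:
        return float(z[i])
    O = omega[np.ix_(others, others)]
    if ridge > 0.0:
        O = O + ridge * np.eye(len(others))
    rho = omega[i, others]
    sol = np.linalg.solve(O, z[others])
    var = 1.0 - float(rho @ np.linalg.solve(O, rho))
    if var <= 1e-8:
        return 0.0  # fully collinear with the conditioning genes
    return (float(z[i]) - float(rho @ sol)) / np.sqrt(var)


def conditional_twas(
    locus: Locus,
    twas_z: dict[str, float],
    omega: GeneCorrelation,
    alpha: float = 0.05,
    ridge: float = 1e-6,
) -> list[ConditionalResult]:
    """Backward elimination to the set of conditionally independent genes.

    Each gene is conditioned on the other retained locus members; while any
    retained gene has conditional p above the locus-wide threshold
    alpha / (2 * Ngenes) (pairwise-testing correction), the gene with the
    largest conditional p is dropped (ties: smaller |marginal z|, then
    lexicographic id). Survivors are flagged independent; dropped genes carry
    the conditional statistics they had when eliminated.
    """
    genes = locus.members
    n = len(genes)
    z = np.array([twas_z[g] for g in genes], dtype=float)
    threshold = alpha / (2 * n)
    O = omega.submatrix(genes)

    retained = list(range(n))
    results: dict[str, ConditionalResult] = {}
    while True:
        stats = {}
        for i in retained:
            others = [j for j in retained if j != i]
            cz = conditional_z_score(z, O, i, others, ridge)
            stats[i] = (cz, z_to_p(cz))
        failing = [i for i in retained if stats[i][1] > threshold]
        if not failing or len(retained) == 1:
            for i in retained:
                cz, cp = stats[i]
                results[genes[i]] = ConditionalResult(
                    gene_id=genes[i], marginal_z=float(z[i]),
                    conditional_z=cz, conditional_p=cp,
                    independent=cp <= threshold,
                )
            break
        drop = max(failing, key=lambda i: (stats[i][1], -abs(z[i]), genes[i]))
        cz, cp = stats[drop]
        results[genes[drop]] = ConditionalResult(
            gene_id=genes[drop], marginal_z=float(z[drop]),
            conditional_z=cz, conditional_p=cp, independent=False,
        )
        retained.remove(drop)
    return [results[g] for g in genes]


def condition_gwas_on_expression(
    snp_ids: Sequence[str],
    snp_z: np.ndarray,
    weight_sets: Sequence[WeightSet],
    ld: np.ndarray,
    omega: GeneCorrelation,
    twas_z: dict[str, float],
    gw_sig_p: float = GENOME_WIDE_P,
    ridge: float = 1e-6,
) -> tuple[list[GwasConditioned], bool]:
    """Condition locus SNP z-scores on the imputed expression of genes.

    For SNP s and gene g, rho_sg = (V w_g)_s / sqrt(w_g' V w_g) is the
    correlation between the SNP and the standardized predictor; conditioning
    on the gene TWAS z-vector gives

        z_s|expr = (z_s - rho_s' Omega^-1 z_twas) / sqrt(1 - rho_s' Omega^-1 rho_s).

    Returns per-SNP results plus an ``explained`` flag: True when the sentinel
    (max |marginal z|) SNP's conditional two-sided p is >= ``gw_sig_p``.
    SNPs collinear with the predictor space are flagged fully-explained and
    given conditional z = 0.
    """
    snp_ids = list(snp_ids)
    snp_z = np.asarray(snp_z, dtype=float)
    ld = np.asarray(ld, dtype=float)
    pos = {s: i for i, s in enumerate(snp_ids)}
    genes = [ws.gene_id for ws in weight_sets]
    zt = np.array([twas_z[g] for g in genes], dtype=float)
    O = omega.submatrix(genes)
    if ridge > 0.0:
        O = O + ridge * np.eye(len(genes))

    # rho matrix: n_snp x n_gene
    R = np.zeros((len(snp_ids), len(genes)))
    for k, ws in enumerate(weight_sets):
        idx = np.array([pos[s] for s in ws.snp_ids])
        Vw = ld[:, idx] @ ws.w
        R[:, k] = Vw / np.sqrt(ws.w @ Vw[idx])

    Oinv_zt = np.linalg.solve(O, zt)
    Oinv_R = np.linalg.solve(O, R.T)  # n_gene x n_snp
    num = snp_z - R @ Oinv_zt
    qs = np.einsum("sg,gs->s", R, Oinv_R)

    sentinel_idx = int(np.argmax(np.abs(snp_z)))
    out: list[GwasConditioned] = []
    for s in range(len(snp_ids)):
        if qs[s] >= 1.0 - 1e-8:
            out.append(GwasConditioned(
                snp_id=snp_ids[s], marginal_z=float(snp_z[s]),
                conditional_z=0.0, sentinel=(s == sentinel_idx),
                fully_explained_predictor=True,
            ))
        else:
            out.append(GwasConditioned(
                snp_id=snp_ids[s], marginal_z=float(snp_z[s]),
                conditional_z=float(num[s] / np.sqrt(1.0 - qs[s])),
                sentinel=(s == sentinel_idx),
            ))
    sent = out[sentinel_idx]
    if sent.fully_explained_predictor:
        explained = True
    else:
        explained = z_to_p(sent.conditional_z) >= gw_sig_p
    return out, explained


@dataclass
class LocusClassification:
    locus_id: str
    known: bool  # within window of a reported GWAS risk interval
    nearest_distance_bp: Optional[int] = None


def map_to_gwas_loci(
    loci: Sequence[Locus],
    gwas_intervals: Sequence[tuple[str, int, int]],
    window: int = LOCUS_WINDOW_BP,
) -> list[LocusClassification]:
    """Label each TWAS locus known (<= window bp from a GWAS interval) or novel.

    ``gwas_intervals`` are (chrom, start, end), 1-based inclusive.
    """
    out = []
    for locus in loci:
        best: Optional[int] = None
        for chrom, start, end in gwas_intervals:
            if str(chrom) != str(locus.chrom):
                continue
            d = max(0, start - locus.end, locus.start - end)
            best = d if best is None else min(best, d)
        out.append(LocusClassification(
            locus_id=locus.locus_id,
            known=(best is not None and best <= window),
            nearest_distance_bp=best,
        ))
    return out
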