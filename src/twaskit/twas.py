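"""Per-gene TWAS association from GWAS summary statistics.

The association statistic for a gene with harmonized cis-eQTL weights w, GWAS
z-scores z over the same SNPs, and reference-panel LD V is

    Z_twas = w'z / sqrt(w' V w)

(the FUSION-style imputed-expression association), with a two-sided normal
p-value. The transcriptome scan harmonizes every weight set against the panel
and GWAS, excludes genes overlapping the MHC, and applies a Bonferroni
threshold over the number of genes actually tested.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
from scipy.stats import norm

from .datatypes import (
    DegeneratePredictorError,
    GenotypePanel,
    GwasSummary,
    LdMatrix,
    MonomorphicSnpError,
    NoUsableSnpsError,
    TwasResult,
    WeightSet,
)

logger = logging.getLogger(__name__)

#: Extended MHC, hg19, 1-based inclusive — excluded from the scan by default
#: for its complex long-range LD.
MHC_REGION = ("6", 28_477_797, 33_448_354)

_AMBIGUOUS = {("A", "T"), ("T", "A"), ("C", "G"), ("G", "C")}


def is_strand_ambiguous(a1: str, a2: str) -> bool:
    return (a1.upper(), a2.upper()) in _AMBIGUOUS


@dataclass
class HarmonizedGene:
    """A weight set aligned to the panel's allele orientation with matched z."""

    weights: WeightSet
    z: np.ndarray
    panel_columns: np.ndarray
    n_dropped_missing: int = 0
    n_dropped_ambiguous: int = 0
    n_dropped_mismatch: int = 0


def harmonize_alleles(
    weights: WeightSet,
    gwas: GwasSummary,
    panel: GenotypePanel,
    drop_ambiguous: bool = True,
) -> HarmonizedGene:
    """Align weights and GWAS z to the panel's a1/a2 orientation.

    Sign-flips w and z where a1/a2 are swapped relative to the panel, drops
    strand-ambiguous (A/T, C/G) SNPs by default, and drops SNPs absent from
    the GWAS or the panel. Raises NoUsableSnpsError when nothing survives.
    """
    keep_ids, keep_a1, keep_a2, keep_w, keep_z, keep_eq, keep_cols = (
        [], [], [], [], [], [], []
    )
    n_missing = n_ambig = n_mismatch = 0
    for i, snp in enumerate(weights.snp_ids):
        if not panel.has_snp(snp) or not gwas.has_snp(snp):
            n_missing += 1
            continue
        col = panel.column(snp)
        rec = panel.snps[col]
        pa1, pa2 = rec.a1.upper(), rec.a2.upper()
        if drop_ambiguous and is_strand_ambiguous(pa1, pa2):
            n_ambig += 1
            continue
        wa = (weights.a1[i].upper(), weights.a2[i].upper())
        if wa == (pa1, pa2):
            sw = 1.0
        elif wa == (pa2, pa1):
            sw = -1.0
        else:
            n_mismatch += 1
            continue
        ga1, ga2, z, _ = gwas.record(snp)
        ga = (ga1.upper(), ga2.upper())
        if ga == (pa1, pa2):
            sz = 1.0
        elif ga == (pa2, pa1):
            sz = -1.0
        else:
            n_mismatch += 1
            continue
        keep_ids.append(snp)
        keep_a1.append(pa1)
        keep_a2.append(pa2)
        keep_w.append(sw * weights.w[i])
        keep_z.append(sz * z)
        if weights.eqtl_z is not None:
            keep_eq.append(sw * weights.eqtl_z[i])
        keep_cols.append(col)

    if not keep_ids or not np.any(np.asarray(keep_w) != 0):
        raise NoUsableSnpsError(f"{weights.gene_id}: no usable SNPs after harmonization")

    aligned = WeightSet(
        gene_id=weights.gene_id, chrom=weights.chrom,
        start=weights.start, end=weights.end,
        snp_ids=keep_ids, a1=keep_a1, a2=keep_a2,
        w=np.asarray(keep_w), cis_h2=weights.cis_h2,
        eqtl_z=np.asarray(keep_eq) if weights.eqtl_z is not None else None,
    )
    return HarmonizedGene(
        weights=aligned, z=np.asarray(keep_z), panel_columns=np.asarray(keep_cols),
        n_dropped_missing=n_missing, n_dropped_ambiguous=n_ambig,
        n_dropped_mismatch=n_mismatch,
    )


def compute_ld(panel: GenotypePanel, snp_ids: Sequence[str]) -> LdMatrix:
    """Pearson correlation of standardized dosages, PSD-repaired if needed."""
    Xs = panel.standardized(snp_ids)
    n = Xs.shape[0]
    V = (Xs.T @ Xs) / n
    V = (V + V.T) / 2.0
    np.fill_diagonal(V, 1.0)
    clipped = 0.0
    eigmin = np.linalg.eigvalsh(V)[0]
    if eigmin < -1e-8:
        vals, vecs = np.linalg.eigh(V)
        clipped = float(np.abs(vals[vals < 1e-8] - 1e-8).sum())
        vals = np.clip(vals, 1e-8, None)
        V = (vecs * vals) @ vecs.T
        V = (V + V.T) / 2.0
    return LdMatrix(snp_ids=list(snp_ids), V=V, clipped_eigenvalue_mass=clipped)


def twas_association(w: np.ndarray, z: np.ndarray, V: np.ndarray) -> tuple[float, float]:
    """TWAS statistic w'z / sqrt(w'Vw) and its two-sided normal p-value."""
    w = np.asarray(w, dtype=float)
    z = np.asarray(z, dtype=float)
    V = np.asarray(V, dtype=float)
    denom2 = float(w @ V @ w)
    if denom2 <= 1e-8:
        raise DegeneratePredictorError(
            f"predictor variance w'Vw = {denom2:.3g} <= 1e-8"
        )
    twas_z = float(w @ z) / np.sqrt(denom2)
    return twas_z, z_to_p(twas_z)


def z_to_p(z: float) -> float:
    """Two-sided standard-normal tail probability, underflow-safe.

    For |z| beyond ~38 the true tail underflows float64; the result is
    floored at the smallest positive subnormal so downstream -log10 and
    probit transforms stay finite.
    """
    if not np.isfinite(z):
        raise ValueError("z must be finite")
    p = float(2.0 * norm.sf(abs(z)))
    return p if p > 0.0 else 5e-324


def bonferroni_threshold(n_tests: int, alpha: float = 0.05) -> float:
    if n_tests < 1:
        raise ValueError("n_tests must be >= 1")
    return alpha / n_tests


def predicted_expression(
    weight_sets: Sequence[WeightSet], panel: GenotypePanel, standardize: bool = True
) -> tuple[list[str], np.ndarray, list[str]]:
    """Impute predicted expression X w_g for each gene into the panel.

    Returns (gene_ids, individuals x genes matrix, dropped_gene_ids); columns
    standardized to mean 0, variance 1 unless ``standardize`` is False.
    Zero-variance predictions are dropped with a log entry.
    """
    cols = []
    kept: list[str] = []
    dropped: list[str] = []
    for ws in weight_sets:
        X = panel.standardized(ws.snp_ids)
        g = X @ ws.w
        sd = g.std()
        if sd == 0.0:
            logger.warning("gene %s: zero-variance predicted expression, dropped",
                           ws.gene_id)
            dropped.append(ws.gene_id)
            continue
        if standardize:
            g = (g - g.mean()) / sd
        cols.append(g)
        kept.append(ws.gene_id)
    if not cols:
        raise NoUsableSnpsError("no gene with non-degenerate predicted expression")
    return kept, np.column_stack(cols), dropped


def gene_overlaps_region(
    ws: WeightSet, region: tuple[str, int, int]
) -> bool:
    chrom, start, end = region
    return str(ws.chrom) == str(chrom) and not (ws.end < start or ws.start > end)


@dataclass
class ScanResult:
    results: list[TwasResult]
    threshold: float
    alpha: float
    attrition: dict[str, int]
    harmonized: dict[str, HarmonizedGene] = field(default_factory=dict)

    @property
    def significant(self) -> list[TwasResult]:
        return [r for r in self.results if r.significant]


def _chrom_key(chrom: str):
    c = str(chrom)
    return (0, int(c)) if c.isdigit() else (1, c)


def run_transcriptome_scan(
    weight_sets: Sequence[WeightSet],
    gwas: GwasSummary,
    panel: GenotypePanel,
    mhc_region: Optional[tuple[str, int, int]] = MHC_REGION,
    alpha: float = 0.05,
    drop_ambiguous: bool = True,
) -> ScanResult:
    """TWAS over all genes; per-gene failures are logged skips, never aborts.

    The Bonferroni significance threshold uses the number of genes actually
    tested, and the attrition table records why each excluded gene fell out.
    """
    attrition = {
        "n_weight_sets": len(weight_sets),
        "mhc_excluded": 0,
        "no_usable_snps": 0,
        "monomorphic": 0,
        "degenerate_predictor": 0,
        "tested": 0,
    }
    results: list[TwasResult] = []
    harmonized: dict[str, HarmonizedGene] = {}

    for ws in sorted(weight_sets, key=lambda s: (_chrom_key(s.chrom), s.start)):
        if mhc_region is not None and gene_overlaps_region(ws, mhc_region):
            attrition["mhc_excluded"] += 1
            logger.info("gene %s excluded: overlaps MHC region", ws.gene_id)
            continue
        try:
            h = harmonize_alleles(ws, gwas, panel, drop_ambiguous=drop_ambiguous)
            ld = compute_ld(panel, h.weights.snp_ids)
            twas_z, twas_p = twas_association(h.weights.w, h.z, ld.V)
        except NoUsableSnpsError:
            attrition["no_usable_snps"] += 1
            logger.info("gene %s skipped: no usable SNPs", ws.gene_id)
            continue
        except MonomorphicSnpError as e:
            attrition["monomorphic"] += 1
            logger.info("gene %s skipped: %s", ws.gene_id, e)
            continue
        except DegeneratePredictorError:
            attrition["degenerate_predictor"] += 1
            logger.info("gene %s skipped: degenerate predictor", ws.gene_id)
            continue

        i_gwas = int(np.argmax(np.abs(h.z)))
        if h.weights.eqtl_z is not None:
            i_eqtl = int(np.argmax(np.abs(h.weights.eqtl_z)))
            top_eqtl_z = float(h.weights.eqtl_z[i_eqtl])
        else:
            i_eqtl = int(np.argmax(np.abs(h.weights.w)))
            top_eqtl_z = float("nan")
        results.append(TwasResult(
            gene_id=ws.gene_id, chrom=str(ws.chrom), start=ws.start, end=ws.end,
            twas_z=twas_z, twas_p=twas_p,
            top_gwas_snp=h.weights.snp_ids[i_gwas], top_gwas_z=float(h.z[i_gwas]),
            top_eqtl_snp=h.weights.snp_ids[i_eqtl], top_eqtl_z=top_eqtl_z,
            n_snps_used=h.weights.n_snps,
        ))
        harmonized[ws.gene_id] = h

    attrition["tested"] = len(results)
    if results:
        threshold = bonferroni_threshold(len(results), alpha)
        for r in results:
            r.significant = r.twas_p <= threshold
    else:
        threshold = float("nan")
    return ScanResult(results=results, threshold=threshold, alpha=alpha,
                      attrition=attrition, harmonized=harmonized)
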