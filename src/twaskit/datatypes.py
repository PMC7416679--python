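"""Core containers shared across the pipeline.

Coordinates are 1-based inclusive throughout (BED inputs are converted at the
boundary by :mod:`twaskit.io`). Alleles are stored uppercase; ``a1`` is the
counted/effect allele everywhere (weights predict expression per copy of a1,
GWAS z-scores refer to a1, panel dosages count a1).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd


class TwaskitError(Exception):
    """Base class for pipeline errors."""


class MonomorphicSnpError(TwaskitError):
    pass


class NoUsableSnpsError(TwaskitError):
    pass


class DegeneratePredictorError(TwaskitError):
    pass


@dataclass(frozen=True)
class SnpRecord:
    snp_id: str
    chrom: str
    bp: int
    a1: str
    a2: str
    maf: float


@dataclass
class GenotypePanel:
    """LD reference panel: additive dosages of a1 for each individual x SNP."""

    snps: list[SnpRecord]
    dosages: np.ndarray  # (n_individuals, n_snps), values in {0, 1, 2}
    _index: dict[str, int] = field(init=False, repr=False)

    def __post_init__(self) -> None:
        self.dosages = np.asarray(self.dosages)
        if self.dosages.ndim != 2 or self.dosages.shape[1] != len(self.snps):
            raise ValueError("dosage matrix does not match SNP records")
        vals = np.unique(self.dosages)
        if not np.isin(vals, [0, 1, 2]).all():
            raise ValueError("dosages must be in {0, 1, 2}")
        by_chrom: dict[str, int] = {}
        for rec in self.snps:
            last = by_chrom.get(rec.chrom)
            if last is not None and rec.bp <= last:
                raise ValueError("bp must be strictly increasing within chromosome")
            by_chrom[rec.chrom] = rec.bp
        self._index = {rec.snp_id: i for i, rec in enumerate(self.snps)}
        if len(self._index) != len(self.snps):
            raise ValueError("duplicate SNP ids in panel")

    @property
    def n_individuals(self) -> int:
        return self.dosages.shape[0]

    @property
    def n_snps(self) -> int:
        return self.dosages.shape[1]

    @property
    def snp_ids(self) -> list[str]:
        return [rec.snp_id for rec in self.snps]

    def column(self, snp_id: str) -> int:
        """Column index of a SNP, or KeyError."""
        return self._index[snp_id]

    def has_snp(self, snp_id: str) -> bool:
        return snp_id in self._index

    def standardized(self, snp_ids: Sequence[str]) -> np.ndarray:
        """Dosage submatrix standardized to mean 0, variance 1 (ddof=0).

        Raises MonomorphicSnpError naming the first zero-variance SNP.
        """
        cols = [self._index[s] for s in snp_ids]
        X = self.dosages[:, cols].astype(float)
        mu = X.mean(axis=0)
        sd = X.std(axis=0)
        bad = np.nonzero(sd == 0.0)[0]
        if bad.size:
            raise MonomorphicSnpError(
                f"monomorphic SNP in panel: {snp_ids[bad[0]]}"
            )
        return (X - mu) / sd


@dataclass
class WeightSet:
    """One gene's cis-eQTL expression predictor."""

    gene_id: str
    chrom: str
    start: int
    end: int
    snp_ids: list[str]
    a1: list[str]
    a2: list[str]
    w: np.ndarray
    cis_h2: float
    eqtl_z: Optional[np.ndarray] = None  # marginal SNP-expression z, if known

    def __post_init__(self) -> None:
        self.w = np.asarray(self.w, dtype=float)
        if not (len(self.snp_ids) == len(self.a1) == len(self.a2) == self.w.size >= 1):
            raise ValueError(f"{self.gene_id}: weight vector/SNP list mismatch or empty")
        if not np.any(self.w != 0):
            raise ValueError(f"{self.gene_id}: all weights zero")
        if self.eqtl_z is not None:
            self.eqtl_z = np.asarray(self.eqtl_z, dtype=float)
            if self.eqtl_z.size != self.w.size:
                raise ValueError(f"{self.gene_id}: eqtl_z length mismatch")

    @property
    def n_snps(self) -> int:
        return self.w.size

    @property
    def length_bp(self) -> int:
        return self.end - self.start + 1


@dataclass
class GwasSummary:
    """Per-SNP GWAS association scores on the standard-normal scale."""

    table: pd.DataFrame  # columns: snp, a1, a2, z, n
    _index: dict[str, int] = field(init=False, repr=False)

    def __post_init__(self) -> None:
        required = {"snp", "a1", "a2", "z"}
        missing = required - set(self.table.columns)
        if missing:
            raise ValueError(f"GWAS summary missing columns: {sorted(missing)}")
        if "n" not in self.table.columns:
            self.table = self.table.assign(n=np.nan)
        dup = self.table["snp"].duplicated()
        if dup.any():
            raise ValueError(
                f"duplicated SNP id in GWAS summary: {self.table['snp'][dup].iloc[0]}"
            )
        self.table = self.table.reset_index(drop=True)
        self._index = {s: i for i, s in enumerate(self.table["snp"])}

    def __len__(self) -> int:
        return len(self.table)

    def has_snp(self, snp_id: str) -> bool:
        return snp_id in self._index

    def record(self, snp_id: str) -> tuple[str, str, float, float]:
        """(a1, a2, z, n) for one SNP."""
        row = self.table.iloc[self._index[snp_id]]
        return row["a1"], row["a2"], float(row["z"]), float(row["n"])


@dataclass
class LdMatrix:
    """SNP x SNP Pearson correlation from a reference panel."""

    snp_ids: list[str]
    V: np.ndarray
    clipped_eigenvalue_mass: float = 0.0  # |sum of eigenvalues clipped to PSD|

    def __post_init__(self) -> None:
        self.V = np.asarray(self.V, dtype=float)
        if self.V.shape != (len(self.snp_ids), len(self.snp_ids)):
            raise ValueError("LD matrix shape does not match SNP ids")


@dataclass
class TwasResult:
    gene_id: str
    chrom: str
    start: int
    end: int
    twas_z: float
    twas_p: float
    top_gwas_snp: str
    top_gwas_z: float
    top_eqtl_snp: str
    top_eqtl_z: float
    n_snps_used: int
    significant: bool = False


@dataclass
class Locus:
    locus_id: str
    chrom: str
    start: int
    end: int
    members: list[str]  # gene ids, ordered by start
    lead_gene: str      # max |twas_z| member


@dataclass
class ConditionalResult:
    gene_id: str
    marginal_z: float
    conditional_z: float
    conditional_p: float
    independent: bool


@dataclass
class GwasConditioned:
    snp_id: str
    marginal_z: float
    conditional_z: float
    sentinel: bool
    fully_explained_predictor: bool = False  # SNP collinear with the predictor


@dataclass
class GeneCorrelation:
    """Gene x gene correlation of predicted expression.

    Dense (Omega, used in conditional analysis) or sparsified with PSD repair
    (K, the random-effect covariance of the enrichment model).
    """

    gene_ids: list[str]
    matrix: np.ndarray
    clipped_eigenvalue_mass: float = 0.0
    ridge_applied: float = 0.0

    def __post_init__(self) -> None:
        self.matrix = np.asarray(self.matrix, dtype=float)
        n = len(self.gene_ids)
        if self.matrix.shape != (n, n):
            raise ValueError("gene correlation shape mismatch")

    def submatrix(self, gene_ids: Sequence[str]) -> np.ndarray:
        pos = {g: i for i, g in enumerate(self.gene_ids)}
        idx = [pos[g] for g in gene_ids]
        return self.matrix[np.ix_(idx, idx)]


@dataclass
class GeneSetCollection:
    sets: dict[str, list[str]]  # set id -> member gene ids
    descriptions: dict[str, str] = field(default_factory=dict)
    enriched_set: Optional[str] = None  # planted-truth label from the simulator

    def __len__(self) -> int:
        return len(self.sets)


@dataclass
class GseaResult:
    set_id: str
    beta: float
    se: float
    p: float              # one-sided, competitive convention (beta > 0)
    p_two_sided: float
    fdr: float
    n_cis_h2_genes_in_set: int
    n_genes_in_set: int
    variance_ratio: float = np.nan  # REML sigma2_K / sigma2_e
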