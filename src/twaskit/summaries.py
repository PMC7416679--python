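"""Standalone summary statistics: sign test, paired z-score correlation with a
Fisher-z confidence interval, and the two-proportion chi-squared test."""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats


@dataclass
class ComparisonFrame:
    """Paired gene-level scores from two analyses, matched by gene id."""

    gene_ids: list[str]
    z_a: np.ndarray
    z_b: np.ndarray

    def __post_init__(self) -> None:
        self.z_a = np.asarray(self.z_a, dtype=float)
        self.z_b = np.asarray(self.z_b, dtype=float)
        if not (len(self.gene_ids) == self.z_a.size == self.z_b.size):
            raise ValueError("mismatched lengths")
        if self.z_a.size < 3:
            raise ValueError("need at least 3 paired genes")

    @classmethod
    def from_tables(cls, a: pd.DataFrame, b: pd.DataFrame,
                    gene_col: str = "gene", z_col: str = "twas_z") -> "ComparisonFrame":
        merged = a[[gene_col, z_col]].merge(
            b[[gene_col, z_col]], on=gene_col, suffixes=("_a", "_b"))
        return cls(gene_ids=merged[gene_col].tolist(),
                   z_a=merged[f"{z_col}_a"].to_numpy(),
                   z_b=merged[f"{z_col}_b"].to_numpy())


def sign_test(n_positive: int, n_total: int) -> float:
    """Exact two-sided binomial test of n_positive/n_total against 0.5.

    Two-sidedness by the minimum-likelihood rule (sums probabilities of all
    outcomes no more likely than the observed one).
    """
    if n_total < 1:
        raise ValueError("n_total must be >= 1")
    if not (0 <= n_positive <= n_total):
        raise ValueError("n_positive must be in [0, n_total]")
    return float(stats.binomtest(n_positive, n_total, 0.5).pvalue)


def pearson_correlation_test(
    frame: ComparisonFrame, method: str = "pearson", conf: float = 0.95
) -> tuple[float, float, float, float]:
    """Correlation of paired scores with a Fisher-z CI.

    Returns (r, ci_low, ci_high, p). p is two-sided from the t reference with
    n-2 degrees of freedom; the CI uses the Fisher z-transform with standard
    error 1/sqrt(n-3). ``method`` may be "pearson" or "spearman".
    """
    x, y = frame.z_a, frame.z_b
    n = x.size
    if n < 4:
        raise ValueError("need n >= 4 for a confidence interval")
    if x.std() == 0.0 or y.std() == 0.0:
        raise ValueError("zero-variance score vector")
    if method == "pearson":
        r, p = stats.pearsonr(x, y)
    elif method == "spearman":
        r, p = stats.spearmanr(x, y)
    else:
        raise ValueError(f"unknown method: {method}")
    r = float(r)
    if abs(r) >= 1.0:
        return r, r, r, float(p)
    zr = np.arctanh(r)
    half = stats.norm.ppf(0.5 + conf / 2) / np.sqrt(n - 3)
    return r, float(np.tanh(zr - half)), float(np.tanh(zr + half)), float(p)


def two_proportion_chisq(
    k1: int, n1: int, k2: int, n2: int, continuity: bool = False
) -> tuple[float, float]:
    """1-d.f. Pearson chi-squared on the 2x2 table k_i successes of n_i.

    Continuity (Yates) correction off by default. Returns (chi2, p).
    """
    for k, n in ((k1, n1), (k2, n2)):
        if n < 1 or not (0 <= k <= n):
            raise ValueError("counts must satisfy 0 <= k <= n, n >= 1")
    table = np.array([[k1, n1 - k1], [k2, n2 - k2]], dtype=float)
    if np.any(table.sum(axis=0) == 0):
        raise ValueError("empty margin in 2x2 table")
    if k1 * n2 == k2 * n1:  # identical proportions: chi2 exactly 0
        return 0.0, 1.0
    chi2, p, _, _ = stats.chi2_contingency(table, correction=continuity)
    return float(chi2), float(p)
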