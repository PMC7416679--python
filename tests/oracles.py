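"""Independent brute-force reference implementations used only by tests.

These deliberately avoid the library's code paths (explicit loops, direct
formulas) so that agreement with the package is a genuine cross-check.
"""

from __future__ import annotations

import math

import numpy as np
from scipy.stats import multivariate_normal, norm


def brute_twas_z(w, z, V) -> float:
    """w'z / sqrt(w'Vw) with explicit loops, no linear algebra calls."""
    num = 0.0
    for wi, zi in zip(w, z):
        num += wi * zi
    den = 0.0
    for i in range(len(w)):
        for j in range(len(w)):
            den += w[i] * V[i][j] * w[j]
    return num / math.sqrt(den)


def brute_conditional_z(z, omega, i, others) -> float:
    """MVN conditioning via the explicit partitioned-covariance formula."""
    others = list(others)
    if not others:
        return float(z[i])
    omega = np.asarray(omega, dtype=float)
    S11 = 1.0
    S12 = omega[i, others]
    S22 = omega[np.ix_(others, others)]
    S22_inv = np.linalg.inv(S22)
    mean = S12 @ S22_inv @ np.asarray(z, dtype=float)[others]
    var = S11 - S12 @ S22_inv @ S12
    return float((z[i] - mean) / math.sqrt(var))


def brute_bh(p) -> np.ndarray:
    """Benjamini-Hochberg step-up from its textbook definition."""
    p = np.asarray(p, dtype=float)
    m = p.size
    order = np.argsort(p, kind="stable")
    adj = np.empty(m)
    running_min = 1.0
    for rank in range(m, 0, -1):
        idx = order[rank - 1]
        running_min = min(running_min, p[idx] * m / rank)
        adj[idx] = running_min
    return adj


def ar1_threshold_dosage_corr(rho_latent: float, maf_i: float, maf_j: float) -> float:
    """Exact dosage correlation for thresholded latent Gaussians.

    Haplotype allele indicators are 1[x < Phi^-1(maf)] with latent correlation
    ``rho_latent``; dosages sum two independent haplotypes, so the dosage
    correlation equals the indicator correlation
    (P11 - q_i q_j) / sqrt(q_i(1-q_i) q_j(1-q_j)).
    """
    ti, tj = norm.ppf(maf_i), norm.ppf(maf_j)
    p11 = multivariate_normal.cdf(
        [ti, tj], mean=[0.0, 0.0], cov=[[1.0, rho_latent], [rho_latent, 1.0]])
    return (p11 - maf_i * maf_j) / math.sqrt(
        maf_i * (1 - maf_i) * maf_j * (1 - maf_j))


def brute_chisq_2x2(k1, n1, k2, n2) -> float:
    """Pearson chi-squared from expected counts, no continuity correction."""
    obs = [[k1, n1 - k1], [k2, n2 - k2]]
    row = [n1, n2]
    col = [k1 + k2, n1 + n2 - k1 - k2]
    total = n1 + n2
    chi2 = 0.0
    for i in range(2):
        for j in range(2):
            e = row[i] * col[j] / total
            chi2 += (obs[i][j] - e) ** 2 / e
    return chi2
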