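"""Weighted delete-one-block jackknife.

Standard errors for all f-statistics in this package come from the weighted
jackknife over contiguous genomic blocks (Busing, Meijer & van der Leeden
1999), the convention of the ADMIXTOOLS ecosystem.  Blocks are deleted one at
a time; with unequal block weights m_j (SNPs per block, n = sum m_j) the
pseudovalues are

    tau_j = h_j * theta_hat - (h_j - 1) * theta_j,      h_j = n / m_j

with jackknife estimate  theta_J = g*theta_hat - sum_j (1 - m_j/n) theta_j
and variance  (1/g) * sum_j (tau_j - theta_J)^2 / (h_j - 1).

For equal weights this reduces to the classic delete-one jackknife variance
((g-1)/g) * sum_j (theta_j - mean)^2.
"""

from __future__ import annotations

import numpy as np


def block_jackknife(per_block_values, per_block_weights, whole_estimate):
    """Combine delete-one-block estimates into (estimate, se).

    Parameters
    ----------
    per_block_values
        Delete-one estimates theta_j (statistic recomputed with block j
        removed), one per block.
    per_block_weights
        Positive block weights m_j (typically SNPs per block).
    whole_estimate
        The statistic computed on all blocks.

    Returns
    -------
    (estimate, se) : the bias-corrected jackknife estimate and its standard
    error; se is 0 when all delete-one estimates coincide.
    """
    theta = np.asarray(per_block_values, dtype=float)
    m = np.asarray(per_block_weights, dtype=float)
    if theta.ndim != 1 or theta.shape != m.shape:
        raise ValueError("values and weights must be 1-D and congruent")
    g = theta.size
    if g < 2:
        raise ValueError("insufficient blocks (need >= 2)")
    if (m <= 0).any():
        raise ValueError("block weights must be positive")
    n = m.sum()
    h = n / m
    est_j = g * whole_estimate - ((1.0 - m / n) * theta).sum()
    tau = h * whole_estimate - (h - 1.0) * theta
    var = ((tau - est_j) ** 2 / (h - 1.0)).sum() / g
    return float(est_j), float(np.sqrt(max(var, 0.0)))


def jackknife_covariance(loo_matrix: np.ndarray, weights, whole: np.ndarray
                         ) -> np.ndarray:
    """Weighted jackknife covariance of a vector statistic.

    Parameters
    ----------
    loo_matrix : (g, d) delete-one estimates of the d-vector.
    weights : (g,) positive block weights.
    whole : (d,) the full-data vector.

    Returns the (d, d) covariance, symmetrized.
    """
    theta = np.asarray(loo_matrix, dtype=float)
    m = np.asarray(weights, dtype=float)
    whole = np.asarray(whole, dtype=float)
    g, d = theta.shape
    if g < 2:
        raise ValueError("insufficient blocks (need >= 2)")
    n = m.sum()
    h = n / m
    est_j = g * whole - ((1.0 - m / n)[:, None] * theta).sum(axis=0)
    tau = h[:, None] * whole[None, :] - (h - 1.0)[:, None] * theta
    dev = tau - est_j[None, :]
    cov = (dev.T * (1.0 / (h - 1.0))) @ dev / g
    return (cov + cov.T) / 2.0


def loo_from_sums(block_sums: np.ndarray, block_counts: np.ndarray):
    """Delete-one means from per-block sums of per-SNP values.

    Returns (loo, whole, used) where ``used`` marks blocks with at least one
    contributing SNP anywhere; blocks whose removal leaves nothing yield NaN.
    """
    S, C = np.asarray(block_sums, float), np.asarray(block_counts, float)
    tot_s, tot_c = S.sum(), C.sum()
    if tot_c == 0:
        raise ValueError("no usable SNPs")
    whole = tot_s / tot_c
    with np.errstate(invalid="ignore", divide="ignore"):
        loo = (tot_s - S) / (tot_c - C)
    return loo, whole, C > 0
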