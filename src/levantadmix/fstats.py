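"""f-statistics for pseudo-haploid ancient-DNA data.

Estimators operate on per-population haploid allele counts (:class:`PopCounts`)
and report block-jackknife standard errors:

* ``f4_stat``:  mean over SNPs of (pA - pB)(pC - pD); zero expectation when
  (A, B) and (C, D) are clades relative to each other (treeness), so a
  significant deviation is evidence of gene flow.
* ``f3_stat``:  mean of (pX - pA)(pX - pB) minus the finite-sample bias
  correction pX(1-pX)/(nX - 1) (the "inbreed" correction appropriate for
  haploid calls); significantly negative values demonstrate that X is admixed
  between populations related to A and B.
* ``hudson_fst``:  Hudson's F_ST as a ratio of averages, with the same
  finite-sample corrections in the numerator.
* ``conditional_heterozygosity``:  mean of 2 d (n-d) / (n (n-1)), the
  probability that two random allele draws differ, meant to be computed on an
  externally ascertained (and transversion-filtered) SNP panel.

All estimates are frequency-convention safe: p is always the allele_b
(derived) frequency d/n from PopCounts.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .dataset import BlockPartition, PopCounts
from .jackknife import block_jackknife, loo_from_sums


@dataclass
class FStatResult:
    statistic: str
    pops: tuple[str, ...]
    estimate: float
    se: float
    z: float
    n_snps_used: int
    n_blocks: int
    per_block: list[tuple[float, float]]  # (delete-one value, block weight)

    def __str__(self) -> str:
        pops = ", ".join(self.pops)
        return (f"{self.statistic}({pops}) = {self.estimate:.6g} "
                f"± {self.se:.3g} (Z = {self.z:.2f}, "
                f"{self.n_snps_used} SNPs, {self.n_blocks} blocks)")


def _jackknife_result(statistic, pops, values, mask, partition: BlockPartition
                      ) -> FStatResult:
    """Mean-over-SNPs estimator with delete-one-block jackknife."""
    mask = np.asarray(mask, bool)
    n_used = int(mask.sum())
    if n_used == 0:
        raise ValueError(f"{statistic}: zero usable SNPs")
    v = np.where(mask, values, 0.0)
    sums = np.bincount(partition.block_id, weights=v,
                       minlength=partition.n_blocks)
    counts = np.bincount(partition.block_id, weights=mask.astype(float),
                         minlength=partition.n_blocks)
    loo, whole, used = loo_from_sums(sums, counts)
    loo, weights = loo[used], counts[used]
    if loo.size < 2:
        raise ValueError(f"{statistic}: insufficient blocks "
                         f"({loo.size}) for a standard error")
    _, se = block_jackknife(loo, weights, whole)
    est = float(whole)  # delete-one correction is exactly zero for a mean
    z = est / se if se > 0 else (0.0 if est == 0 else np.inf * np.sign(est))
    return FStatResult(statistic, tuple(pops), est, se, float(z), n_used,
                       int(loo.size), list(zip(loo.tolist(), weights.tolist())))


def f4_stat(counts: PopCounts, quad, partition: BlockPartition,
            allsnps: bool = True, batch_mask=None) -> FStatResult:
    """f4(A, B; C, D) with jackknife se.

    With ``allsnps`` (the default, matching the study's setting) the statistic
    uses every SNP covered in all four populations; otherwise ``batch_mask``
    (the intersection across a batch of statistics) restricts the SNP set.
    """
    a, b, c, d = quad
    pa, pb, pc, pd_ = (counts.freq(p) for p in quad)
    mask = ~(np.isnan(pa) | np.isnan(pb) | np.isnan(pc) | np.isnan(pd_))
    if not allsnps:
        if batch_mask is None:
            raise ValueError("allsnps=False requires a batch_mask "
                             "(global SNP intersection)")
        mask &= np.asarray(batch_mask, bool)
    vals = np.where(mask, (pa - pb) * (pc - pd_), 0.0)
    return _jackknife_result("f4", quad, vals, mask, partition)


def f3_stat(counts: PopCounts, target: str, a: str, b: str,
            partition: BlockPartition, inbreed: bool = True) -> FStatResult:
    """f3(X; A, B) with the haploid-call (inbreed) bias correction.

    SNPs where X has fewer than 2 haploid calls are excluded (the correction
    needs nX - 1 > 0).
    """
    px, pa, pb = counts.freq(target), counts.freq(a), counts.freq(b)
    nx = counts.total[counts.index(target)]
    mask = ~(np.isnan(px) | np.isnan(pa) | np.isnan(pb)) & (nx >= 2)
    with np.errstate(invalid="ignore", divide="ignore"):
        corr = px * (1.0 - px) / (nx - 1.0) if inbreed else 0.0
        vals = (px - pa) * (px - pb) - corr
    vals = np.where(mask, vals, 0.0)
    return _jackknife_result("f3", (target, a, b), vals, mask, partition)


def hudson_fst(counts: PopCounts, a: str, b: str, partition: BlockPartition
               ) -> FStatResult:
    """Hudson F_ST, ratio of summed numerators to summed denominators.

    num = (p1-p2)^2 - p1(1-p1)/(n1-1) - p2(1-p2)/(n2-1)
    den = p1(1-p2) + p2(1-p1)

    The ratio-of-averages form (sum over SNPs before dividing) is the
    recommended multi-locus combination; jackknife is applied to the ratio.
    """
    p1, p2 = counts.freq(a), counts.freq(b)
    n1 = counts.total[counts.index(a)]
    n2 = counts.total[counts.index(b)]
    mask = ~(np.isnan(p1) | np.isnan(p2)) & (n1 >= 2) & (n2 >= 2)
    with np.errstate(invalid="ignore", divide="ignore"):
        num = (p1 - p2) ** 2 - p1 * (1 - p1) / (n1 - 1.0) \
            - p2 * (1 - p2) / (n2 - 1.0)
        den = p1 * (1 - p2) + p2 * (1 - p1)
    num = np.where(mask, num, 0.0)
    den = np.where(mask, den, 0.0)
    n_used = int(mask.sum())
    if n_used == 0:
        raise ValueError("hudson_fst: zero usable SNPs")
    bid, nb = partition.block_id, partition.n_blocks
    num_s = np.bincount(bid, weights=num, minlength=nb)
    den_s = np.bincount(bid, weights=den, minlength=nb)
    cnt = np.bincount(bid, weights=mask.astype(float), minlength=nb)
    if den_s.sum() == 0:
        raise ValueError("hudson_fst: zero denominator sum")
    whole = num_s.sum() / den_s.sum()
    used = cnt > 0
    with np.errstate(invalid="ignore", divide="ignore"):
        loo = (num_s.sum() - num_s[used]) / (den_s.sum() - den_s[used])
    weights = cnt[used]
    if loo.size < 2:
        raise ValueError("hudson_fst: insufficient blocks")
    _, se = block_jackknife(loo, weights, whole)
    # report the plain ratio of sums; the jackknife provides only the se
    est = float(whole)
    z = est / se if se > 0 else 0.0
    return FStatResult("fst", (a, b), est, se, float(z), n_used,
                       int(loo.size), list(zip(loo.tolist(), weights.tolist())))


def conditional_heterozygosity(counts: PopCounts, pop: str,
                               partition: BlockPartition) -> FStatResult:
    """Mean of 2 d (n-d) / (n (n-1)) over SNPs with n >= 2 haploid calls.

    Callers wanting the ascertainment-safe variant apply ``filter_snps``
    (transversions, external ascertainment) before building counts.
    """
    i = counts.index(pop)
    d, n = counts.derived[i], counts.total[i].astype(float)
    mask = n >= 2
    if not mask.any():
        raise ValueError("conditional_heterozygosity: no SNP with n >= 2")
    with np.errstate(invalid="ignore", divide="ignore"):
        vals = 2.0 * d * (n - d) / (n * (n - 1.0))
    vals = np.where(mask, vals, 0.0)
    return _jackknife_result("het", (pop,), vals, mask, partition)
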