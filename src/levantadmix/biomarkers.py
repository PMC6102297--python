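"""Maximum-likelihood allele frequencies from raw read counts.

For low-coverage ancient samples, genotype calls at phenotypically relevant
SNPs are unreliable; instead the population reference-allele frequency p is
estimated directly from per-individual read counts.  Individual i contributes
R_i reads carrying the reference allele out of T_i total; marginalizing over
the unknown genotype,

    L(p) = prod_i [ p^2 B(R_i, T_i, 1-eps) + 2p(1-p) B(R_i, T_i, 1/2)
                    + (1-p)^2 B(R_i, T_i, eps) ]

with B the binomial pmf and eps a small per-read error rate (default 0.001).
The likelihood is maximized on [0, 1] by a 1001-point grid scan refined by
bounded one-dimensional minimization; maxima on the boundary are legal (a
fixed allele is a perfectly ordinary outcome).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import optimize, stats


@dataclass(frozen=True)
class SiteReadCounts:
    site_id: str
    ref_reads: tuple[int, ...]
    total_reads: tuple[int, ...]

    def __post_init__(self) -> None:
        r = np.asarray(self.ref_reads)
        t = np.asarray(self.total_reads)
        if r.shape != t.shape:
            raise ValueError("ref_reads and total_reads differ in length")
        if ((r < 0) | (r > t)).any():
            raise ValueError("need 0 <= R_i <= T_i")


@dataclass(frozen=True)
class FrequencyEstimate:
    site_id: str
    p_hat: float          # reference-allele frequency
    loglik: float
    epsilon: float
    n_individuals: int    # individuals with T_i > 0
    total_reads: int

    @property
    def alt_freq(self) -> float:
        """Alternative-allele frequency, the scale frequencies are quoted on."""
        return 1.0 - self.p_hat


def _loglik_factory(r: np.ndarray, t: np.ndarray, epsilon: float):
    b_hom_ref = stats.binom.pmf(r, t, 1.0 - epsilon)
    b_het = stats.binom.pmf(r, t, 0.5)
    b_hom_alt = stats.binom.pmf(r, t, epsilon)

    def loglik(p: float) -> float:
        mix = p * p * b_hom_ref + 2.0 * p * (1.0 - p) * b_het \
            + (1.0 - p) * (1.0 - p) * b_hom_alt
        with np.errstate(divide="ignore"):
            return float(np.log(np.maximum(mix, 1e-300)).sum())

    return loglik


def ml_allele_frequency(counts: SiteReadCounts, epsilon: float = 0.001
                        ) -> FrequencyEstimate:
    """Maximize the binomial-mixture likelihood of the reference frequency."""
    r = np.asarray(counts.ref_reads, dtype=np.int64)
    t = np.asarray(counts.total_reads, dtype=np.int64)
    keep = t > 0
    if not keep.any():
        raise ValueError(f"{counts.site_id}: no data (all T_i = 0)")
    r, t = r[keep], t[keep]
    loglik = _loglik_factory(r, t, epsilon)
    grid = np.linspace(0.0, 1.0, 1001)
    vals = np.array([loglik(p) for p in grid])
    i = int(vals.argmax())
    lo, hi = grid[max(i - 1, 0)], grid[min(i + 1, 1000)]
    res = optimize.minimize_scalar(lambda p: -loglik(p), bounds=(lo, hi),
                                   method="bounded",
                                   options={"xatol": 1e-7})
    p_hat, best = float(res.x), -float(res.fun)
    # keep the boundary/grid point if refinement did not beat it
    if vals[i] >= best:
        p_hat, best = float(grid[i]), float(vals[i])
    return FrequencyEstimate(counts.site_id, p_hat, best, epsilon,
                             int(keep.sum()), int(t.sum()))


def population_frequency_table(per_population_counts: dict[str, list[SiteReadCounts]],
                               epsilon: float = 0.001) -> pd.DataFrame:
    """Site x population table of ML frequencies.

    ``per_population_counts`` maps population -> SiteReadCounts per site.
    Populations with no usable reads at a site are emitted with NaN
    frequencies rather than dropped.
    """
    site_ids: list[str] = []
    for sites in per_population_counts.values():
        for s in sites:
            if s.site_id not in site_ids:
                site_ids.append(s.site_id)
    if not site_ids:
        raise ValueError("no sites provided")
    rows = []
    for sid in site_ids:
        for pop, sites in per_population_counts.items():
            match = [s for s in sites if s.site_id == sid]
            if match:
                try:
                    est = ml_allele_frequency(match[0], epsilon)
                    rows.append((sid, pop, est.p_hat, est.alt_freq,
                                 est.n_individuals, est.total_reads))
                    continue
                except ValueError:
                    pass
            rows.append((sid, pop, np.nan, np.nan, 0, 0))
    return pd.DataFrame(rows, columns=["site_id", "population", "ref_freq",
                                       "alt_freq", "n_individuals",
                                       "total_reads"])


def read_counts_table(path) -> dict[str, list[SiteReadCounts]]:
    """Load a TSV of (site_id, individual_id, population, ref_reads, total_reads)."""
    df = pd.read_csv(path, sep="\t")
    out: dict[str, list[SiteReadCounts]] = {}
    for (pop, sid), sub in df.groupby(["population", "site_id"]):
        out.setdefault(str(pop), []).append(
            SiteReadCounts(str(sid), tuple(sub["ref_reads"].astype(int)),
                           tuple(sub["total_reads"].astype(int))))
    return out
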