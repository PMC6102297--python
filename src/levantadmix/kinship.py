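"""Pairwise-mismatch-rate screen for close relatives.

Two pseudo-haploid call vectors from unrelated individuals of the same
population mismatch at a baseline rate set by the population's
heterozygosity; sharing chromosomes halves the expected mismatch rate in
proportion to kinship.  Normalizing each pair's mismatch rate (PMR) by the
cohort median — assuming most pairs are unrelated — puts the expectations at
0.5 (identical/twin), 0.75 (first degree), 0.875 (second degree) and 1
(unrelated), classified with midpoint cutoffs 0.625 / 0.8125 / 0.90625.

The screen feeds the exclusion rule used for building analysis sets: from
each related pair, keep the member covered at more SNPs.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass

import numpy as np

from .dataset import MISSING, BlockPartition, Dataset
from .jackknife import block_jackknife, loo_from_sums

#: Normalized-PMR upper cutoffs, midpoints between expected class values.
THRESH_IDENTICAL = 0.625
THRESH_FIRST_DEGREE = 0.8125
THRESH_SECOND_DEGREE = 0.90625


@dataclass
class PairMismatch:
    pair: tuple[str, str]
    n_overlap: int
    pmr: float
    se: float
    normalized: float | None = None
    insufficient: bool = False


@dataclass
class RelatednessCall:
    pair: tuple[str, str]
    relationship: str          # identical | first_degree | second_degree | unrelated
    normalized: float
    margin_se: float           # distance to the nearest cutoff in jackknife SEs


def pmr_matrix(dataset: Dataset, partition: BlockPartition,
               min_overlap: int = 5000) -> list[PairMismatch]:
    """Mismatch rate for every individual pair, with jackknife SEs.

    Pairs overlapping at fewer than ``min_overlap`` non-missing SNPs are
    flagged ``insufficient`` (their PMR is still reported when any overlap
    exists).
    """
    if dataset.n_individuals < 2:
        raise ValueError("need at least 2 individuals")
    geno = dataset.genotypes
    ids = dataset.individuals["individual_id"].tolist()
    out = []
    for i, j in itertools.combinations(range(len(ids)), 2):
        gi, gj = geno[i], geno[j]
        both = (gi != MISSING) & (gj != MISSING)
        n_ov = int(both.sum())
        if n_ov == 0:
            out.append(PairMismatch((ids[i], ids[j]), 0, np.nan, np.nan,
                                    insufficient=True))
            continue
        mm = both & (gi != gj)
        mm_sums = np.bincount(partition.block_id, weights=mm.astype(float),
                              minlength=partition.n_blocks)
        ov_sums = np.bincount(partition.block_id, weights=both.astype(float),
                              minlength=partition.n_blocks)
        loo, whole, used = loo_from_sums(mm_sums, ov_sums)
        if used.sum() >= 2:
            _, se = block_jackknife(loo[used], ov_sums[used], whole)
        else:
            se = np.nan
        out.append(PairMismatch((ids[i], ids[j]), n_ov, float(whole),
                                float(se), insufficient=n_ov < min_overlap))
    return out


def classify_relatives(pairs: list[PairMismatch],
                       coverage: dict[str, int] | None = None
                       ) -> tuple[list[RelatednessCall], list[str]]:
    """Classify pairs by median-normalized PMR; propose exclusions.

    Returns (calls, exclusion list).  The exclusion list removes, from each
    pair called identical/first-degree/second-degree, the member with lower
    SNP coverage (``coverage`` maps individual id -> n_snps_covered; without
    it the second member is dropped).  Detection beyond second degree is out
    of reach of the PMR statistic; such pairs are reported unrelated.
    """
    usable = [p for p in pairs if not p.insufficient and np.isfinite(p.pmr)]
    if len(usable) < 3:
        raise ValueError("need at least 3 pairs for median normalization")
    median = float(np.median([p.pmr for p in usable]))
    if median <= 0:
        raise ValueError("degenerate cohort: median PMR is zero "
                         "(all pairs identical?)")
    calls, excluded = [], []
    for p in usable:
        norm = p.pmr / median
        p.normalized = norm
        if norm < THRESH_IDENTICAL:
            rel = "identical"
        elif norm < THRESH_FIRST_DEGREE:
            rel = "first_degree"
        elif norm < THRESH_SECOND_DEGREE:
            rel = "second_degree"
        else:
            rel = "unrelated"
        cutoffs = (THRESH_IDENTICAL, THRESH_FIRST_DEGREE, THRESH_SECOND_DEGREE)
        margin = min(abs(norm - c) for c in cutoffs)
        margin_se = margin / (p.se / median) if p.se and p.se > 0 else np.inf
        calls.append(RelatednessCall(p.pair, rel, norm, float(margin_se)))
        if rel != "unrelated":
            a, b = p.pair
            if coverage is not None and coverage.get(a, 0) < coverage.get(b, 0):
                drop = a
            else:
                drop = b
            if drop not in excluded:
                excluded.append(drop)
    return calls, excluded
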