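"""Shared fixtures: hand-built datasets, allele counts and block partitions."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

from levantadmix.dataset import BlockPartition, Dataset, PopCounts


def snp_table(n: int, chrom: str = "1", spacing_m: float = 0.01) -> pd.DataFrame:
    """Minimal SNP table: transversion alleles, uniform genetic map."""
    return pd.DataFrame({
        "snp_id": [f"rs{i}" for i in range(n)],
        "chrom": chrom,
        "gpos": np.arange(n) * spacing_m,
        "ppos": (np.arange(n) + 1) * 1000,
        "allele_a": "A",
        "allele_b": "C",
    })


def make_counts(derived: dict[str, list], total: dict[str, list]) -> PopCounts:
    """PopCounts from per-population derived/total haploid call lists."""
    pops = list(derived)
    D = np.array([derived[p] for p in pops], dtype=float)
    N = np.array([total[p] for p in pops], dtype=np.int64)
    return PopCounts(pops, D, N, snp_table(D.shape[1]))


def per_snp_blocks(n: int) -> BlockPartition:
    """One jackknife block per SNP (for tiny hand-arithmetic fixtures)."""
    return BlockPartition(np.arange(n), n, 0.05)


@pytest.fixture
def toy_dataset() -> Dataset:
    """3 SNPs x 4 individuals: one diploid with a het call, three pseudo-haploid."""
    snps = pd.DataFrame({
        "snp_id": ["rs0", "rs1", "rs2"],
        "chrom": ["1", "1", "2"],
        "gpos": [0.0, 0.03, 0.0],
        "ppos": [1000, 2000, 1000],
        "allele_a": ["A", "C", "G"],
        "allele_b": ["G", "T", "C"],
    })
    individuals = pd.DataFrame({
        "individual_id": ["dip1", "ph1", "ph2", "ph3"],
        "sex": ["F", "M", "U", "M"],
        "group": ["Pop1", "Pop1", "Pop2", "Pop2"],
        "pseudo_haploid": [False, True, True, True],
    })
    geno = np.array([
        [1, 2, 0],
        [0, 2, 9],
        [2, 9, 9],
        [0, 0, 9],
    ], dtype=np.int8)
    return Dataset(snps, individuals, geno)


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(20260924)
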