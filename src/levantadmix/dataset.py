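"""EIGENSTRAT genotype data: containers, I/O, merging, filtering, counting.

The central container is :class:`Dataset`, holding a SNP table, an individual
table and a genotype matrix over {0, 1, 2, 9} where the value is the number of
copies of ``allele_a`` (the fifth .snp column) and 9 means missing.  Reported
allele frequencies throughout the package are for ``allele_b`` (the sixth
column, conventionally the derived/alternative allele), so a pseudo-haploid
derived call is stored as genotype 0.

Pseudo-haploid individuals (single randomly drawn sequence per site, the
standard representation for low-coverage ancient DNA) carry only {0, 2, 9}
and contribute a single haploid call to population allele counts; diploid
individuals contribute two.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

MISSING = 9

#: Transition allele pairs (purine<->purine, pyrimidine<->pyrimidine).
TRANSITION_PAIRS = ({"A", "G"}, {"C", "T"})

SNP_COLUMNS = ["snp_id", "chrom", "gpos", "ppos", "allele_a", "allele_b"]
IND_COLUMNS = ["individual_id", "sex", "group"]


class EigenstratParseError(ValueError):
    """Malformed EIGENSTRAT input (wrong row width, bad genotype symbol...)."""


def is_transition(allele_a: str, allele_b: str) -> bool:
    return {allele_a, allele_b} in TRANSITION_PAIRS


@dataclass(frozen=True)
class SnpRecord:
    snp_id: str
    chromosome: str
    genetic_pos: float  # Morgans
    physical_pos: int   # 1-based bp
    allele_a: str
    allele_b: str


@dataclass(frozen=True)
class IndividualRecord:
    individual_id: str
    sex: str            # M / F / U
    group: str
    n_snps_covered: int
    pseudo_haploid: bool = True


@dataclass
class Dataset:
    """SNP table + individual table + genotype matrix.

    ``snps`` columns: snp_id, chrom, gpos, ppos, allele_a, allele_b.
    ``individuals`` columns: individual_id, sex, group, pseudo_haploid.
    ``genotypes``: int8 array of shape (n_individuals, n_snps).
    """

    snps: pd.DataFrame
    individuals: pd.DataFrame
    genotypes: np.ndarray

    def __post_init__(self) -> None:
        self.snps = self.snps.reset_index(drop=True)
        self.individuals = self.individuals.reset_index(drop=True)
        self.genotypes = np.asarray(self.genotypes, dtype=np.int8)
        if self.genotypes.shape != (len(self.individuals), len(self.snps)):
            raise ValueError(
                f"genotype matrix shape {self.genotypes.shape} does not match "
                f"{len(self.individuals)} individuals x {len(self.snps)} SNPs"
            )
        if "pseudo_haploid" not in self.individuals.columns:
            # Ancient-DNA default: treat everything as pseudo-haploid unless told.
            self.individuals = self.individuals.assign(pseudo_haploid=True)
        self.validate()

    # -- invariants ------------------------------------------------------

    def validate(self) -> None:
        bad = ~np.isin(self.genotypes, (0, 1, 2, MISSING))
        if bad.any():
            raise ValueError(f"{bad.sum()} genotype values outside {{0,1,2,9}}")
        same = self.snps["allele_a"].to_numpy() == self.snps["allele_b"].to_numpy()
        if same.any():
            raise ValueError("allele_a == allele_b at some SNPs")
        if (self.snps["ppos"].to_numpy() < 0).any():
            raise ValueError("negative physical positions")
        ph = self.individuals["pseudo_haploid"].to_numpy(bool)
        if ph.any() and np.isin(self.genotypes[ph], 1).any():
            raise ValueError("pseudo-haploid individual carries a heterozygous call")
        if self.snps["snp_id"].duplicated().any():
            raise ValueError("duplicate snp_id in SNP table")
        for chrom, sub in self.snps.groupby("chrom", sort=False):
            g = sub["gpos"].to_numpy(float)
            if len(g) > 1 and (np.diff(g) < 0).any():
                warnings.warn(
                    f"genetic positions not non-decreasing on chromosome {chrom}",
                    stacklevel=2,
                )

    # -- conveniences ----------------------------------------------------

    @property
    def n_snps(self) -> int:
        return len(self.snps)

    @property
    def n_individuals(self) -> int:
        return len(self.individuals)

    def n_snps_covered(self) -> np.ndarray:
        """Non-missing genotype count per individual."""
        return (self.genotypes != MISSING).sum(axis=1)

    def snp_records(self) -> list[SnpRecord]:
        return [
            SnpRecord(r.snp_id, str(r.chrom), float(r.gpos), int(r.ppos),
                      r.allele_a, r.allele_b)
            for r in self.snps.itertuples(index=False)
        ]

    def individual_records(self) -> list[IndividualRecord]:
        cov = self.n_snps_covered()
        return [
            IndividualRecord(r.individual_id, r.sex, r.group, int(c),
                             bool(r.pseudo_haploid))
            for r, c in zip(self.individuals.itertuples(index=False), cov)
        ]

    def groups(self) -> dict[str, list[int]]:
        out: dict[str, list[int]] = {}
        for i, g in enumerate(self.individuals["group"]):
            out.setdefault(str(g), []).append(i)
        return out

    def take_snps(self, mask_or_index) -> "Dataset":
        idx = np.asarray(mask_or_index)
        if idx.dtype == bool:
            idx = np.flatnonzero(idx)
        return Dataset(
            self.snps.iloc[idx].reset_index(drop=True),
            self.individuals.reset_index(drop=True).copy(),
            self.genotypes[:, idx].copy(),
        )

    def take_individuals(self, mask_or_index) -> "Dataset":
        idx = np.asarray(mask_or_index)
        if idx.dtype == bool:
            idx = np.flatnonzero(idx)
        return Dataset(
            self.snps.reset_index(drop=True).copy(),
            self.individuals.iloc[idx].reset_index(drop=True),
            self.genotypes[idx, :].copy(),
        )

    def equals(self, other: "Dataset") -> bool:
        return (
            self.snps.reset_index(drop=True).equals(other.snps.reset_index(drop=True))
            and self.individuals.reset_index(drop=True).equals(
                other.individuals.reset_index(drop=True))
            and np.array_equal(self.genotypes, other.genotypes)
        )


@dataclass
class PopCounts:
    """Per-population haploid allele counts.

    ``derived[p, s]`` counts allele_b copies among non-missing haploid calls of
    population ``pops[p]`` at SNP ``s``; ``total[p, s]`` is the number of
    haploid calls (2 per non-missing diploid genotype, 1 per pseudo-haploid).
    """

    pops: list[str]
    derived: np.ndarray  # float64 (P, S)
    total: np.ndarray    # int64 (P, S)
    snps: pd.DataFrame = field(repr=False)

    def __post_init__(self) -> None:
        if (self.derived < 0).any() or (self.derived > self.total).any():
            raise ValueError("derived counts outside [0, total]")

    def index(self, pop: str) -> int:
        try:
            return self.pops.index(pop)
        except ValueError:
            raise KeyError(f"unknown population {pop!r}") from None

    def freq(self, pop: str) -> np.ndarray:
        """allele_b frequency per SNP (NaN where uncovered)."""
        i = self.index(pop)
        with np.errstate(invalid="ignore", divide="ignore"):
            return np.where(self.total[i] > 0, self.derived[i] / self.total[i], np.nan)

    @property
    def n_snps(self) -> int:
        return self.derived.shape[1]


@dataclass
class BlockPartition:
    """Contiguous genomic blocks for the weighted delete-one jackknife."""

    block_id: np.ndarray   # int per SNP
    n_blocks: int
    span: float            # target span (Morgans, or bp for physical fallback)
    unit: str = "morgans"

    def __post_init__(self) -> None:
        self.block_id = np.asarray(self.block_id, dtype=np.int64)
        if self.n_blocks and self.block_id.size:
            if self.block_id.min() < 0 or self.block_id.max() >= self.n_blocks:
                raise ValueError("block ids out of range")

    def weights(self) -> np.ndarray:
        """SNPs per block."""
        return np.bincount(self.block_id, minlength=self.n_blocks)


# ---------------------------------------------------------------------------
# EIGENSTRAT I/O
# ---------------------------------------------------------------------------

_PACKED_MAGIC = b"GENO"


def _read_snp(snp_path) -> pd.DataFrame:
    rows = []
    with open(snp_path) as fh:
        for lineno, line in enumerate(fh, 1):
            parts = line.split()
            if not parts:
                continue
            if len(parts) != 6:
                raise EigenstratParseError(
                    f"{snp_path}: line {lineno}: expected 6 columns, got {len(parts)}"
                )
            rows.append(
                (parts[0], str(parts[1]), float(parts[2]), int(parts[3]),
                 parts[4], parts[5])
            )
    return pd.DataFrame(rows, columns=SNP_COLUMNS)


def _read_ind(ind_path) -> pd.DataFrame:
    rows = []
    with open(ind_path) as fh:
        for lineno, line in enumerate(fh, 1):
            parts = line.split()
            if not parts:
                continue
            if len(parts) != 3:
                raise EigenstratParseError(
                    f"{ind_path}: line {lineno}: expected 3 columns, got {len(parts)}"
                )
            rows.append(tuple(parts))
    return pd.DataFrame(rows, columns=IND_COLUMNS)


def _geno_is_packed(geno_path) -> bool:
    with open(geno_path, "rb") as fh:
        return fh.read(4) == _PACKED_MAGIC


def _read_geno_ascii(geno_path, n_ind: int, n_snp: int) -> np.ndarray:
    if n_ind == 0:
        return np.empty((0, n_snp), dtype=np.int8)
    geno = np.empty((n_snp, n_ind), dtype=np.int8)
    row = 0
    with open(geno_path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.strip()
            if not line:
                continue
            if len(line) != n_ind:
                raise EigenstratParseError(
                    f"{geno_path}: line {lineno}: expected {n_ind} genotypes, "
                    f"got {len(line)}"
                )
            vals = np.frombuffer(line.encode(), dtype=np.uint8) - ord("0")
            if not np.isin(vals, (0, 1, 2, MISSING)).all():
                raise EigenstratParseError(
                    f"{geno_path}: line {lineno}: genotype symbol outside 0/1/2/9"
                )
            if row >= n_snp:
                raise EigenstratParseError(f"{geno_path}: more rows than SNPs")
            geno[row] = vals
            row += 1
    if row != n_snp:
        raise EigenstratParseError(
            f"{geno_path}: {row} genotype rows for {n_snp} SNPs"
        )
    return geno.T


def _read_geno_packed(geno_path, n_ind: int, n_snp: int) -> np.ndarray:
    with open(geno_path, "rb") as fh:
        data = fh.read()
    rlen = max(48, (n_ind + 3) // 4)
    header = data[:rlen].split(b"\x00")[0].split()
    if header[:1] != [_PACKED_MAGIC]:
        raise EigenstratParseError(f"{geno_path}: not a packed .geno file")
    h_ind, h_snp = int(header[1]), int(header[2])
    if (h_ind, h_snp) != (n_ind, n_snp):
        raise EigenstratParseError(
            f"{geno_path}: header says {h_ind} individuals x {h_snp} SNPs, "
            f".ind/.snp say {n_ind} x {n_snp}"
        )
    body = np.frombuffer(data[rlen:rlen + rlen * n_snp], dtype=np.uint8)
    if body.size < rlen * n_snp:
        raise EigenstratParseError(f"{geno_path}: truncated packed genotype body")
    body = body.reshape(n_snp, rlen)
    # 2 bits per individual, most significant pair first within each byte.
    shifts = np.array([6, 4, 2, 0], dtype=np.uint8)
    expanded = (body[:, :, None] >> shifts[None, None, :]) & 0b11
    geno = expanded.reshape(n_snp, rlen * 4)[:, :n_ind].astype(np.int8)
    geno[geno == 3] = MISSING
    return geno.T


def read_eigenstrat(geno_path, snp_path, ind_path) -> Dataset:
    """Read an EIGENSTRAT triplet; packed and ASCII .geno both accepted."""
    snps = _read_snp(snp_path)
    individuals = _read_ind(ind_path)
    if _geno_is_packed(geno_path):
        geno = _read_geno_packed(geno_path, len(individuals), len(snps))
    else:
        geno = _read_geno_ascii(geno_path, len(individuals), len(snps))
    individuals = individuals.assign(
        pseudo_haploid=~np.isin(geno, 1).any(axis=1)
    )
    return Dataset(snps, individuals, geno)


def write_eigenstrat(dataset: Dataset, prefix, packed: bool = False) -> None:
    """Write ``prefix``.geno/.snp/.ind; read∘write is the identity."""
    prefix = str(prefix)
    with open(prefix + ".snp", "w") as fh:
        for r in dataset.snps.itertuples(index=False):
            fh.write(f"{r.snp_id}\t{r.chrom}\t{r.gpos:.6f}\t{int(r.ppos)}"
                     f"\t{r.allele_a}\t{r.allele_b}\n")
    with open(prefix + ".ind", "w") as fh:
        for r in dataset.individuals.itertuples(index=False):
            fh.write(f"{r.individual_id}\t{r.sex}\t{r.group}\n")
    geno = dataset.genotypes.T  # (n_snp, n_ind)
    n_snp, n_ind = geno.shape
    if not packed:
        with open(prefix + ".geno", "w") as fh:
            for row in geno:
                fh.write("".join(map(str, row)) + "\n")
        return
    rlen = max(48, (n_ind + 3) // 4)
    header = f"GENO {n_ind} {n_snp} 0 0".encode().ljust(rlen, b"\x00")
    vals = geno.astype(np.uint8).copy()
    vals[vals == MISSING] = 3
    pad = (-n_ind) % 4
    if pad:
        vals = np.hstack([vals, np.full((n_snp, pad), 3, dtype=np.uint8)])
    vals = vals.reshape(n_snp, -1, 4)
    packed_bytes = (vals[:, :, 0] << 6) | (vals[:, :, 1] << 4) \
        | (vals[:, :, 2] << 2) | vals[:, :, 3]
    if packed_bytes.shape[1] < rlen:
        fill = np.zeros((n_snp, rlen - packed_bytes.shape[1]), dtype=np.uint8)
        packed_bytes = np.hstack([packed_bytes, fill])
    with open(prefix + ".geno", "wb") as fh:
        fh.write(header)
        fh.write(packed_bytes.astype(np.uint8).tobytes())


# ---------------------------------------------------------------------------
# Merge and filters
# ---------------------------------------------------------------------------

def merge_datasets(d1: Dataset, d2: Dataset) -> Dataset:
    """Intersect SNPs by id, align d2 alleles to d1, concatenate individuals.

    When d2's allele_a/allele_b are swapped relative to d1, d2's genotypes are
    flipped g -> 2-g.  SNPs with irreconcilable allele pairs or mismatching
    physical positions are dropped (count logged).  Strand-complement rescue is
    deliberately not attempted.
    """
    for d in (d1, d2):
        if d.snps["snp_id"].duplicated().any():
            raise ValueError("duplicate snp_id within one input")
    s1 = d1.snps.set_index("snp_id")
    s2 = d2.snps.set_index("snp_id")
    common = [sid for sid in d1.snps["snp_id"] if sid in s2.index]
    keep1, keep2, flip, dropped = [], [], [], 0
    for sid in common:
        r1, r2 = s1.loc[sid], s2.loc[sid]
        if int(r1.ppos) != int(r2.ppos) or str(r1.chrom) != str(r2.chrom):
            dropped += 1
            continue
        if (r1.allele_a, r1.allele_b) == (r2.allele_a, r2.allele_b):
            f = False
        elif (r1.allele_a, r1.allele_b) == (r2.allele_b, r2.allele_a):
            f = True
        else:
            dropped += 1
            continue
        keep1.append(d1.snps.index[d1.snps["snp_id"] == sid][0])
        keep2.append(d2.snps.index[d2.snps["snp_id"] == sid][0])
        flip.append(f)
    if dropped:
        logger.info("merge_datasets: dropped %d SNPs with irreconcilable "
                    "alleles or positions", dropped)
    g1 = d1.genotypes[:, keep1]
    g2 = d2.genotypes[:, keep2].copy()
    flip = np.asarray(flip, dtype=bool)
    if flip.any():
        cols = g2[:, flip]
        miss = cols == MISSING
        cols = 2 - cols
        cols[miss] = MISSING
        g2[:, flip] = cols
    snps = d1.snps.iloc[keep1].reset_index(drop=True)
    individuals = pd.concat(
        [d1.individuals, d2.individuals], ignore_index=True
    )
    return Dataset(snps, individuals, np.vstack([g1, g2]))


def filter_individuals(dataset: Dataset, min_snps: int = 5000) -> Dataset:
    """Drop individuals covered at fewer than ``min_snps`` sites (inclusive keep)."""
    keep = dataset.n_snps_covered() >= min_snps
    return dataset.take_individuals(keep)


def filter_snps(
    dataset: Dataset,
    transversions_only: bool = False,
    ascertainment_ids=None,
    autosomes_only: bool = False,
) -> Dataset:
    """SNP-panel filters: transversions, external ascertainment list, autosomes."""
    keep = np.ones(dataset.n_snps, dtype=bool)
    if transversions_only:
        ts = np.array([
            is_transition(a, b)
            for a, b in zip(dataset.snps["allele_a"], dataset.snps["allele_b"])
        ])
        keep &= ~ts
    if ascertainment_ids is not None:
        wanted = set(ascertainment_ids)
        present = set(dataset.snps["snp_id"])
        missing = wanted - present
        if missing:
            warnings.warn(
                f"{len(missing)} ascertainment ids absent from panel",
                stacklevel=2,
            )
        keep &= dataset.snps["snp_id"].isin(wanted).to_numpy()
    if autosomes_only:
        autosomes = {str(c) for c in range(1, 23)}
        keep &= dataset.snps["chrom"].astype(str).isin(autosomes).to_numpy()
    return dataset.take_snps(keep)


# ---------------------------------------------------------------------------
# Population counts and jackknife blocks
# ---------------------------------------------------------------------------

def compute_pop_counts(dataset: Dataset, grouping: dict[str, list[str]] | None = None
                       ) -> PopCounts:
    """Haploid allele_b counts per population per SNP.

    ``grouping`` maps population name -> individual ids; default groups by the
    .ind group column.  Diploid genotypes contribute 2 calls, pseudo-haploid 1.
    """
    ids = dataset.individuals["individual_id"].tolist()
    if grouping is None:
        grouping = {}
        for i, g in zip(ids, dataset.individuals["group"]):
            grouping.setdefault(str(g), []).append(i)
    id_to_row = {iid: i for i, iid in enumerate(ids)}
    seen: dict[str, str] = {}
    for pop, members in grouping.items():
        for iid in members:
            if iid in seen:
                raise ValueError(f"individual {iid!r} mapped to both "
                                 f"{seen[iid]!r} and {pop!r}")
            seen[iid] = pop
    ph = dataset.individuals["pseudo_haploid"].to_numpy(bool)
    geno = dataset.genotypes
    pops = list(grouping)
    D = np.zeros((len(pops), dataset.n_snps))
    N = np.zeros((len(pops), dataset.n_snps), dtype=np.int64)
    for p, pop in enumerate(pops):
        rows = [id_to_row[iid] for iid in grouping[pop]]
        if not rows:
            raise ValueError(f"population {pop!r} has zero individuals")
        for r in rows:
            g = geno[r]
            ok = g != MISSING
            if ph[r]:
                # one haploid call; genotype 0 = one allele_b copy
                N[p, ok] += 1
                D[p, ok] += (2 - g[ok]) / 2.0
            else:
                N[p, ok] += 2
                D[p, ok] += 2 - g[ok]
    return PopCounts(pops, D, N, dataset.snps.reset_index(drop=True))


def assign_blocks(snps: pd.DataFrame, block_size_morgans: float = 0.05,
                  physical_fallback_bp: int = 5_000_000) -> BlockPartition:
    """Greedy left-to-right contiguous blocks within chromosomes.

    A new block starts when the span from the block's first SNP would exceed
    the target size.  Falls back to physical windows when the genetic map is
    absent (all positions zero).
    """
    if len(snps) == 0:
        raise ValueError("empty SNP table")
    gpos = snps["gpos"].to_numpy(float)
    use_genetic = bool((gpos != 0).any())
    pos = gpos if use_genetic else snps["ppos"].to_numpy(float)
    size = block_size_morgans if use_genetic else float(physical_fallback_bp)
    block = np.empty(len(snps), dtype=np.int64)
    bid = -1
    prev_chrom = None
    start = 0.0
    for i, (chrom, x) in enumerate(zip(snps["chrom"].astype(str), pos)):
        if chrom != prev_chrom or x - start > size:
            bid += 1
            start = x
            prev_chrom = chrom
        block[i] = bid
    return BlockPartition(block, bid + 1, size,
                          "morgans" if use_genetic else "bp")
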