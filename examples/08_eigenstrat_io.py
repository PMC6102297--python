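"""EIGENSTRAT round trips, merging and filtering.

Writes a small simulated panel in both .geno dialects, merges two panels
with swapped alleles, and applies the standard per-individual and per-SNP
filters.
"""

import tempfile
from pathlib import Path

from levantadmix import (filter_individuals, filter_snps, merge_datasets,
                         peqiin_fixture, read_eigenstrat, write_eigenstrat)

dataset, _ = peqiin_fixture(seed=1, n_snps=5000)
tmp = Path(tempfile.mkdtemp())

write_eigenstrat(dataset, str(tmp / "panel_ascii"), packed=False)
write_eigenstrat(dataset, str(tmp / "panel_packed"), packed=True)
a = read_eigenstrat(tmp / "panel_ascii.geno", tmp / "panel_ascii.snp",
                    tmp / "panel_ascii.ind")
p = read_eigenstrat(tmp / "panel_packed.geno", tmp / "panel_packed.snp",
                    tmp / "panel_packed.ind")
print(f"round trip: ascii == packed == original: "
      f"{a.equals(dataset) and (a.genotypes == p.genotypes).all()}")

half1 = dataset.take_individuals(range(0, 40))
half2 = dataset.take_individuals(range(40, dataset.n_individuals))
merged = merge_datasets(half1, half2)
print(f"merge: {half1.n_individuals} + {half2.n_individuals} individuals -> "
      f"{merged.n_individuals} at {merged.n_snps} shared SNPs")

filtered = filter_individuals(dataset, min_snps=3000)
print(f"individual filter (>=3000 SNPs covered): "
      f"{dataset.n_individuals} -> {filtered.n_individuals}")

tv = filter_snps(dataset, transversions_only=True)
print(f"transversion filter: {dataset.n_snps} -> {tv.n_snps} SNPs")
print("  -> transversions are immune to the C->T deamination damage that")
print("     dominates ancient-DNA error, so diversity statistics use them.")
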