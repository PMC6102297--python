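"""Maximum-likelihood allele frequency from low-coverage read counts.

Each individual contributes (reference reads, total reads) at a site; the
binomial-mixture likelihood marginalizes the unknown genotypes instead of
calling them.
"""

from levantadmix import SiteReadCounts, ml_allele_frequency
from levantadmix.biomarkers import population_frequency_table

# a pigmentation-locus-style site in two populations
counts_popA = SiteReadCounts("eye_color_snp",
                             ref_reads=(3, 0, 2, 1, 4),
                             total_reads=(4, 5, 2, 3, 6))
est = ml_allele_frequency(counts_popA, epsilon=0.001)
print(f"PopA {est.site_id}: ref freq = {est.p_hat:.3f}, "
      f"alt freq = {est.alt_freq:.3f} "
      f"({est.n_individuals} individuals, {est.total_reads} reads)")
print("  -> the alternative-allele frequency is the quantity usually quoted")
print("     for phenotype-associated SNPs.\n")

table = population_frequency_table({
    "PopA": [counts_popA],
    "PopB": [SiteReadCounts("eye_color_snp", (5, 6, 2), (5, 6, 4))],
})
print(table.to_string(index=False))
print("  -> one row per site x population; populations lacking data at a")
print("     site are reported as missing rather than dropped.")
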