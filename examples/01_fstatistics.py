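"""Detect admixture with f-statistics on a simulated three-population cohort.

Builds a cohort where X is a 50/50 mixture of populations related to A and B,
then computes f3(X; A, B), Hudson F_ST and conditional heterozygosity.
"""

from levantadmix import (
    GraphNode, GraphSpec, SamplingSpec, assign_blocks, compute_pop_counts,
    conditional_heterozygosity, f3_stat, hudson_fst, sample_dataset,
    simulate_frequencies,
)

nodes = [
    GraphNode("root"),
    GraphNode("anc", ("root",), drift=0.02),
    GraphNode("pA", ("anc",), drift=0.10),
    GraphNode("pB", ("anc",), drift=0.10),
    GraphNode("A", ("pA",), drift=0.01),
    GraphNode("B", ("pB",), drift=0.01),
    GraphNode("X", ("pA", "pB"), drift=0.005, mix_weights=(0.5, 0.5)),
]
freqs = simulate_frequencies(GraphSpec(nodes), n_snps=50_000, seed=1)
plan = {p: (10, "pseudo_haploid", 0.1) for p in ("A", "B", "X")}
dataset = sample_dataset(freqs, SamplingSpec(plan), seed=2)

counts = compute_pop_counts(dataset)
blocks = assign_blocks(dataset.snps)

f3 = f3_stat(counts, "X", "A", "B", blocks)
print(f3)
print("  -> a significantly negative f3 (Z < -3) demonstrates that X's")
print("     allele frequencies are intermediate: X is admixed.\n")

fst = hudson_fst(counts, "A", "B", blocks)
print(fst)
print("  -> F_ST between the two source-related populations.\n")

for pop in ("A", "B", "X"):
    het = conditional_heterozygosity(counts, pop, blocks)
    print(f"het({pop}) = {het.estimate:.4f} ± {het.se:.4f}")
print("  -> the admixed population X is more heterozygous than either source.")
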