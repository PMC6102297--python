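"""Staged admixture-model enumeration with outgroup augmentation.

The target is a clade of candidate C1, but with only distant outgroups both
C1 and C2 look like acceptable single sources.  Adding an outgroup related
to C2's private ancestry eliminates the false model.
"""

from levantadmix import (GraphNode, GraphSpec, SamplingSpec, assign_blocks,
                         compute_pop_counts, model_search,
                         rank_outgroup_candidates, sample_dataset,
                         simulate_frequencies)

nodes = [
    GraphNode("B0"), GraphNode("Deep", ("B0",), pin=0.0),
    GraphNode("B1", ("B0",), drift=0.02), GraphNode("B2", ("B1",), drift=0.02),
    GraphNode("R1", ("B1",), drift=0.25), GraphNode("R2", ("B1",), drift=0.2),
    GraphNode("R3", ("B2",), drift=0.12),
    GraphNode("Par", ("B2",), drift=0.03),
    GraphNode("C1", ("Par",), drift=0.02),
    GraphNode("M", ("Par",), drift=0.02),
    GraphNode("C2", ("M",), drift=0.03),
    GraphNode("E", ("M",), drift=0.10),   # shares M's drift: informative
    GraphNode("T", ("C1",), drift=0.02),  # the target, truly a clade of C1
]
freqs = simulate_frequencies(GraphSpec(nodes), n_snps=50_000, seed=7)
plan = {p: (10, "pseudo_haploid", 0.1)
        for p in ("T", "C1", "C2", "E", "R1", "R2", "R3", "Deep")}
dataset = sample_dataset(freqs, SamplingSpec(plan), seed=8)
counts = compute_pop_counts(dataset)
blocks = assign_blocks(dataset.snps)

ranked = rank_outgroup_candidates(counts, ("C1", "C2"), ["E"], "Deep", blocks)
print("outgroup candidates ranked by |Z| of f4(C1, C2; A, Deep):", ranked)

ledger = model_search(counts, "T", ["C1", "C2"], ["C1", "C2"],
                      ["R1", "R2", "R3"], ["E"], blocks)
for row in ledger.rows:
    verdict = "plausible" if row.plausible else "rejected"
    print(f"{row.stage:12s} sources={'+'.join(row.sources):8s} "
          f"p={row.p:.3g}  {verdict}")
print("final survivors:", ["+".join(s) for s in ledger.final_survivors])
print("  -> both clade models pass with distant outgroups; appending the")
print("     informative outgroup E leaves only the true source C1.")
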