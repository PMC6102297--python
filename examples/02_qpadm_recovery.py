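"""Estimate three-way admixture proportions with qpAdm on the reference fixture.

The fixture's target is mixed from three source-related ancestors with known
weights (0.570 / 0.264 / 0.166); qpAdm should recover them within its
jackknife standard errors, with a non-rejecting model fit p-value.
"""

import numpy as np

from levantadmix import assign_blocks, compute_pop_counts, peqiin_fixture, qpadm

dataset, truth = peqiin_fixture(seed=1, n_snps=100_000)
print(f"cohort: {dataset.n_individuals} individuals x {dataset.n_snps} SNPs, "
      f"{len(truth['rights'])} right-set outgroups")

counts = compute_pop_counts(dataset)
blocks = assign_blocks(dataset.snps)

model = qpadm(counts, truth["target"], truth["sources"], truth["rights"],
              blocks)
print(model)
print("truth:", np.round(truth["weights"], 3))
print("  -> each weight should sit within ~2 standard errors of its truth")
print("     value, and p > 0.05 says the three-source model fits the f4")
print("     system relating target and sources to the outgroups.")
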