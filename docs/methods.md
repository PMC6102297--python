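# Methods

This note records the statistical models the package implements, the
conventions and numerical choices behind them, what the synthetic-data
generator does and does not emulate, and the limitations a user should
keep in mind.

## Data model and conventions

Genotypes live in an EIGENSTRAT-style matrix over {0, 1, 2, 9}. The value
counts copies of `allele_a` (the fifth `.snp` column); all reported allele
frequencies are for `allele_b`, so a pseudo-haploid derived call is stored
as 0. A single documented convention here prevents silent sign flips in
f-statistics. Pseudo-haploid individuals (the standard representation of
low-coverage ancient samples: one randomly drawn sequence per site) carry
only {0, 2, 9} and contribute **one** haploid call to population allele
counts, while diploid genotypes contribute two. This is the "inbreed"
counting convention: treating a pseudo-haploid sample's two identical
pseudo-alleles as independent would fabricate homozygosity and bias every
moment-based statistic.

Merging matches SNPs by id, verifies chromosome and physical position, and
flips genotypes g → 2−g when the allele pair is swapped. Strand-complement
rescue is deliberately not attempted: within one array family silent strand
flips are worse than the data loss from dropping ambiguous sites (dropped
counts are logged). Coordinates are 1-based; chromosome labels are strings.

Per-individual and per-SNP filters follow ancient-DNA practice: individuals
need at least 5,000 covered SNPs (inclusive threshold); diversity analyses
restrict to transversions (immune to postmortem C→T deamination) and may
apply an external ascertainment list so heterozygosity is comparable across
populations without discovery bias.

## Block jackknife

All standard errors come from the weighted delete-one-block jackknife
(Busing–Meijer–van der Leeden), with SNPs partitioned greedily into
contiguous blocks of at most 0.05 Morgans within chromosomes (5-Mb physical
windows when no genetic map is present). The block span is configurable;
0.05 M is the convention of the ADMIXTOOLS ecosystem this package
interoperates with. For mean-type statistics the jackknife point estimate
equals the plain mean, so the package reports the whole-data estimate and
uses the jackknife only for the standard error; for the F_ST ratio the same
convention is kept so that the printed estimate is exactly the ratio of
summed numerators to summed denominators.

## f-statistics

* `f4` — mean over usable SNPs of (p̂_A − p̂_B)(p̂_C − p̂_D). Unbiased under
  missingness and pseudo-haploidy; exactly antisymmetric and additive on a
  fixed SNP set.
* `f3` — mean of (p̂_X − p̂_A)(p̂_X − p̂_B) − p̂_X(1 − p̂_X)/(n_X − 1). The
  subtraction is the unbiased estimate of Var(p̂_X), the term that would
  otherwise make every f3 spuriously positive at small sample size. SNPs
  with fewer than 2 haploid calls in X are excluded.
* `hudson_fst` — ratio of averages:
  Σ[(p̂₁−p̂₂)² − p̂₁(1−p̂₁)/(n₁−1) − p̂₂(1−p̂₂)/(n₂−1)] / Σ[p̂₁(1−p̂₂) + p̂₂(1−p̂₁)].
  The ratio-of-averages combination is the stable multi-locus form; the
  jackknife is applied to the ratio. The estimator is symmetric in the two
  populations by construction.
* `conditional_heterozygosity` — mean of 2d(n−d)/(n(n−1)), the unbiased
  probability that two random haploid calls differ. The caller applies the
  ascertainment/transversion filter first.

Monomorphic SNPs are retained (they contribute zeros); averaged-estimator
conventions do not special-case zero-information sites. With `allsnps`
(default true) each statistic uses its own maximal SNP set; with it off, a
batch intersection mask must be supplied. Jackknife blocks are shared
either way.

## qpWave / qpAdm

The f4 matrix X[i,j] = f4(left₀, leftᵢ; right₀, rightⱼ) is assembled with a
per-entry SNP mask and per-block delete-one values; the covariance Q of
vec(X) is the weighted jackknife covariance over shared blocks. The rank-k
fit minimizes the Q-metric distance to the rank-k manifold by alternating
generalized least squares on the two factors, initialized from the SVD of X
plus 10 seeded random restarts (fixed default seed 42, relative tolerance
1e−9, cap 2000 iterations — the objective is non-convex and restarts guard
against local minima; determinism is needed for reproducible p-values).
The statistic is referred to χ² with (L−1−k)(R−1−k) degrees of freedom, the
rank-deficiency count of the saturated model; no small-sample multivariate
correction is applied. Q is inverted by Cholesky with an escalating ridge
of 10⁻¹²·trace(Q)/dim when ill-conditioned (jackknife covariances of large
f4 matrices are near-singular); the regularization is logged.

qpAdm weights solve the sum-to-one-constrained GLS system built from the
rows Fᵢⱼ = f4(sourceᵢ, target; right₀, rightⱼ): minimize wᵀ(F W Fᵀ)w
subject to Σw = 1, where W is the inverse jackknife covariance of the model
residual e(w) = −Fᵀw, iterated to a fixed point. Because e(w) is invariant
to which source would serve as a GLS base (the constraint makes the
residual a pure contrast), the estimated weights are symmetric in the
sources and base-free by construction. Standard errors come from
re-solving the system with each block deleted and combining with the
weighted jackknife; the model p-value is the rank test at k = |sources|−1
on left = {target} ∪ sources, so the two agree by construction. Weights
are *not* constrained to [0,1]: infeasible weights are reported and flagged,
and a model is "plausible" when p > 0.05 and all weights lie in [0,1].

`qpwave_min_streams` tests ranks upward from 0 and reports the smallest
accepted rank plus one. When only the saturated full-rank model fits
(df = 0, χ² = 0, p = 1), the count is returned with a saturation flag: the
data establish a lower bound on the number of streams but cannot bound it
above.

`model_search` reproduces the staged enumeration style of admixture-model
selection: all 1-source models (clade tests), then pairs containing at
least one designated core source, then triplets containing at least two;
the first stage with plausible models ends the enumeration (parsimony).
Augmenting outgroups are then appended to the right set one at a time and
survivors re-tested until at most one remains — appending an outgroup can
only shrink the survivor set, never grow it, since survivors alone are
re-tested. An empty survivor set is a valid, recorded outcome.
`rank_outgroup_candidates` orders candidate outgroups by |Z| of
f4(P, Q; A, deep-outgroup), i.e. by how asymmetrically each candidate is
related to the model pair being discriminated.

## Allele frequencies from read counts

The likelihood marginalizes each individual's unknown genotype over
Hardy–Weinberg priors with a per-read error rate ε = 0.001 (default).
Maximization is a 1001-point grid scan refined by bounded one-dimensional
minimization to 1e−6, in log space; the grid-plus-refine design is used
instead of derivative methods because boundary maxima (fixed alleles) are
common and legal. The reported `alt_freq` is 1 − p̂, the scale on which
phenotype-associated allele frequencies are normally quoted. External
reference frequencies (e.g. continental panels) are accepted as
user-supplied tables, never fetched.

## Y-haplogroup scoring

Candidate haplogroups are scored by weighted mismatches between observed
calls and the derived/ancestral states expected on the root-to-node path:
off-path observed derived alleles always count, on-path observed ancestral
alleles count when `penalize_ancestral` is on (default — without it,
sparse data trivially favors the deepest lineages, so the toggle is a
documented extension of pure derived-mismatch counting). Derived
transitions weigh 1/3 of a transversion, reflecting deamination damage.
Ties break deterministically by (score, more matched derived, deeper node,
lexicographic name); the breadth-first traversal is an ordering, not a
pruning, so the result equals the exhaustive minimum. Samples covered at
fewer than 100,000 SNPs genome-wide are flagged, never refused. Parentage
in ISOGG-style tables is lexical (longest proper prefix) unless an explicit
parent column is given.

## Kinship screen

The pairwise mismatch rate (PMR) between two pseudo-haploid call vectors,
normalized by the cohort median (assuming most pairs unrelated), has
expectations 0.5 / 0.75 / 0.875 / 1 for identical, first-degree,
second-degree and unrelated pairs; classification uses the midpoint cutoffs
0.625 / 0.8125 / 0.90625. From each related pair the lower-coverage member
is proposed for exclusion. Because the baseline is a within-cohort median,
the pipeline applies the screen separately per population group; a
monomorphic group (zero median) is skipped with a log message. The PMR
statistic cannot resolve third-degree relatives; anything beyond the
second-degree cutoff is reported as unrelated.

## Synthetic data generator

Allele frequencies evolve down an acyclic admixture graph under
Balding–Nichols drift: child ~ Beta(p(1−F)/F, (1−p)(1−F)/F) with mean p and
variance F·p(1−p); F = 0 is an exact pass-through and fixed frequencies
(0 or 1) stay fixed. Admixture nodes mix parent frequencies with fixed
weights and then apply their own drift edge (mixture-then-drift — the
order matters for f-statistic expectations and is therefore fixed and
documented). Root frequencies are Uniform(0.05, 0.95), a generic
common-SNP ascertainment profile; outgroup nodes may pin the derived
frequency to 0, making them polarity anchors for f4(...; A, outgroup)
statistics.

Sampling draws diploid genotypes Binomial(2, p) or pseudo-haploid calls
Binomial(1, p), with i.i.d. missingness, onto a panel spread over 22
autosomes with a uniform genetic map (0.03 cM between adjacent SNPs, so a
100k-SNP panel yields roughly 600 jackknife blocks of 0.05 M).

The reference fixture emulates the shape of a merged ancient-DNA cohort:
one deep pinned outgroup, eleven right-set populations branching at drift
depths 0.05–0.30, three admixture sources (post-split drift ≈ 0.03), and a
target mixed with weights 0.570/0.264/0.166 (the printed three-way model
proportions normalized to sum to 1) plus post-admixture drift 0.005;
20 pseudo-haploid target individuals, 10 per source, 5 per outgroup, 30%
missing calls. The right-set drift depths are calibration choices recorded
in the fixture's truth record.

What the generator does **not** emulate: linkage disequilibrium (SNPs are
independent; blocks exist to exercise the jackknife machinery, not to model
LD), reference bias, damage-driven genotype error, contamination, and
non-equilibrium demography (bottleneck timing, growth). Tests passing on
this generator therefore validate the estimators and their calibration
under the assumed sampling model, not robustness to those real-data
artifacts.

Desk-scale problem sizes used by the test suite and the reference
experiment — 100k SNPs for weight recovery and admixture signatures, 20k
SNPs and 200 replicates for rank-test calibration, 20 seeds for stream
counting — were chosen so each check resolves its effect with comfortable
statistical margin while the whole battery runs in minutes on one CPU.

## Known limitations

* The rank-test null uses the plain χ² reference; with few blocks relative
  to the f4-matrix dimension the jackknife covariance is noisy and the test
  can become anticonservative. The simulation layouts here keep blocks ≳
  20× the matrix dimension.
* qpAdm standard errors treat the residual-covariance weighting matrix as
  fixed across delete-one re-estimates; this is the usual practice and
  slightly understates weight uncertainty in extreme cases.
* The packed-EIGENSTRAT writer emits zero header hashes (readers that
  verify hashes against the .ind/.snp content will warn).
* The kinship classifier assumes a cohort dominated by unrelated pairs;
  in small heavily related cohorts the median normalization breaks down
  (reported as an error rather than guessed around).
* Real-data reproduction of published tables requires the corresponding
  deposited genotype datasets; the pipeline accepts them as EIGENSTRAT
  input but no download is performed.
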