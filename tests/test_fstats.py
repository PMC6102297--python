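"""f4/f3/F_ST/heterozygosity estimators: hand oracles, identities, simulations."""

import numpy as np
import pytest

from levantadmix import (
    GraphNode, GraphSpec, SamplingSpec, assign_blocks, compute_pop_counts,
    conditional_heterozygosity, f3_stat, f4_stat, hudson_fst, sample_dataset,
    simulate_frequencies,
)

from conftest import make_counts, per_snp_blocks


# ---------------------------------------------------------------------------
# Hand-arithmetic oracles (tiny fixtures, expectations computed by hand)
# ---------------------------------------------------------------------------

def test_f4_matches_hand_arithmetic():
    counts = make_counts(
        derived={"A": [1, 1], "B": [0, 1], "C": [2, 0], "D": [1, 1]},
        total={"A": [2, 4], "B": [2, 2], "C": [2, 2], "D": [2, 2]},
    )
    # SNP1: (0.5-0)(1-0.5) = 0.25 ; SNP2: (0.25-0.5)(0-0.5) = 0.125
    res = f4_stat(counts, ("A", "B", "C", "D"), per_snp_blocks(2))
    assert res.estimate == pytest.approx((0.25 + 0.125) / 2)
    assert res.n_snps_used == 2


def test_f3_matches_hand_arithmetic_with_correction():
    counts = make_counts(
        derived={"X": [1, 2], "A": [0, 1], "B": [2, 2]},
        total={"X": [2, 4], "A": [2, 2], "B": [2, 4]},
    )
    # SNP1: (0.5-0)(0.5-1) - 0.25/1 = -0.5
    # SNP2: (0.5-0.5)(0.5-0.5) - 0.25/3 = -1/12
    expected = (-0.5 - 0.25 / 3) / 2
    res = f3_stat(counts, "X", "A", "B", per_snp_blocks(2))
    assert res.estimate == pytest.approx(expected)


def test_f3_excludes_snps_with_single_call():
    counts = make_counts(
        derived={"X": [1, 1, 1], "A": [0, 0, 0], "B": [2, 2, 2]},
        total={"X": [2, 1, 2], "A": [2, 2, 2], "B": [2, 2, 2]},
    )
    res = f3_stat(counts, "X", "A", "B", per_snp_blocks(3))
    assert res.n_snps_used == 2


def test_fst_matches_hand_arithmetic():
    counts = make_counts(
        derived={"A": [1, 2], "B": [0, 1]},
        total={"A": [2, 2], "B": [2, 4]},
    )
    # SNP1: num = 0.25 - 0.25/1 - 0 = 0 ; den = 0.5
    # SNP2: num = 0.75^2 - 0 - 0.25*0.75/3 = 0.5 ; den = 0.75
    res = hudson_fst(counts, "A", "B", per_snp_blocks(2))
    assert res.estimate == pytest.approx(0.5 / 1.25)


def test_fst_is_symmetric():
    counts = make_counts(
        derived={"A": [1, 2, 0], "B": [0, 1, 2]},
        total={"A": [2, 2, 3], "B": [2, 4, 4]},
    )
    part = per_snp_blocks(3)
    ab = hudson_fst(counts, "A", "B", part)
    ba = hudson_fst(counts, "B", "A", part)
    assert ab.estimate == ba.estimate
    assert ab.se == ba.se


def test_heterozygosity_hand_values():
    part = per_snp_blocks(3)
    # d=1,n=2 at every SNP: estimate 1 (two calls always differ)
    c1 = make_counts(derived={"P": [1, 1, 1]}, total={"P": [2, 2, 2]})
    assert conditional_heterozygosity(c1, "P", part).estimate == pytest.approx(1.0)
    # monomorphic: 0
    c2 = make_counts(derived={"P": [0, 0, 0]}, total={"P": [3, 4, 2]})
    assert conditional_heterozygosity(c2, "P", part).estimate == 0.0
    # mixed: (2*1*1/(2*1) + 2*2*2/(4*3) + 0) / 3
    c3 = make_counts(derived={"P": [1, 2, 0]}, total={"P": [2, 4, 3]})
    expected = (1.0 + 8.0 / 12.0 + 0.0) / 3.0
    assert conditional_heterozygosity(c3, "P", part).estimate == pytest.approx(expected)


# ---------------------------------------------------------------------------
# Exact structural identities
# ---------------------------------------------------------------------------

@pytest.fixture
def random_counts(rng):
    n = 40
    pops = ["A", "B", "C", "D", "E"]
    total = {p: rng.integers(4, 12, size=n).tolist() for p in pops}
    derived = {p: [int(rng.integers(0, t + 1)) for t in total[p]] for p in pops}
    return make_counts(derived, total)


def test_f4_duplicate_right_pair_is_exactly_zero(random_counts):
    part = per_snp_blocks(random_counts.n_snps)
    res = f4_stat(random_counts, ("A", "B", "C", "C"), part)
    assert res.estimate == 0.0
    assert res.se == 0.0


def test_f4_antisymmetry(random_counts):
    part = per_snp_blocks(random_counts.n_snps)
    base = f4_stat(random_counts, ("A", "B", "C", "D"), part)
    swapped_left = f4_stat(random_counts, ("B", "A", "C", "D"), part)
    swapped_right = f4_stat(random_counts, ("A", "B", "D", "C"), part)
    assert base.estimate == -swapped_left.estimate
    assert base.estimate == -swapped_right.estimate


def test_f4_pair_exchange_symmetry(random_counts):
    part = per_snp_blocks(random_counts.n_snps)
    a = f4_stat(random_counts, ("A", "B", "C", "D"), part)
    b = f4_stat(random_counts, ("C", "D", "A", "B"), part)
    assert a.estimate == pytest.approx(b.estimate, abs=1e-15)


def test_f4_additivity_on_fixed_snp_set(random_counts):
    part = per_snp_blocks(random_counts.n_snps)
    ce = f4_stat(random_counts, ("A", "B", "C", "E"), part).estimate
    cd = f4_stat(random_counts, ("A", "B", "C", "D"), part).estimate
    de = f4_stat(random_counts, ("A", "B", "D", "E"), part).estimate
    assert ce == pytest.approx(cd + de, abs=1e-15)


def test_estimates_invariant_to_snp_order_and_block_relabeling(random_counts, rng):
    from levantadmix.dataset import BlockPartition
    n = random_counts.n_snps
    part = BlockPartition(np.repeat(np.arange(8), n // 8), 8, 0.05)
    base = f4_stat(random_counts, ("A", "B", "C", "D"), part)
    perm = rng.permutation(n)
    shuffled = make_counts(
        {p: random_counts.derived[i][perm].tolist()
         for i, p in enumerate(random_counts.pops)},
        {p: random_counts.total[i][perm].tolist()
         for i, p in enumerate(random_counts.pops)},
    )
    part_perm = BlockPartition(part.block_id[perm], 8, 0.05)
    res = f4_stat(shuffled, ("A", "B", "C", "D"), part_perm)
    assert res.estimate == pytest.approx(base.estimate, abs=1e-15)
    assert res.se == pytest.approx(base.se, rel=1e-12)
    # relabel blocks
    relabel = rng.permutation(8)
    part_rel = BlockPartition(relabel[part.block_id], 8, 0.05)
    res2 = f4_stat(random_counts, ("A", "B", "C", "D"), part_rel)
    assert res2.se == pytest.approx(base.se, rel=1e-12)


def test_zero_usable_snps_errors():
    counts = make_counts(derived={"A": [0], "B": [0], "C": [0], "D": [0]},
                         total={"A": [0], "B": [2], "C": [2], "D": [2]})
    with pytest.raises(ValueError, match="zero usable"):
        f4_stat(counts, ("A", "B", "C", "D"), per_snp_blocks(1))


# ---------------------------------------------------------------------------
# Simulation-backed behavior
# ---------------------------------------------------------------------------

def _admixed_trio(seed: int, n_snps: int, w: float = 0.5):
    """Sources A, B drifted apart; X = w*A + (1-w)*B with slight own drift."""
    nodes = [GraphNode("root"), GraphNode("anc", ("root",), drift=0.02),
             GraphNode("pA", ("anc",), drift=0.10),
             GraphNode("pB", ("anc",), drift=0.10),
             GraphNode("A", ("pA",), drift=0.01),
             GraphNode("B", ("pB",), drift=0.01),
             GraphNode("X", ("pA", "pB"), drift=0.005, mix_weights=(w, 1 - w))]
    freqs = simulate_frequencies(GraphSpec(nodes), n_snps, seed)
    plan = {p: (10, "pseudo_haploid", 0.1) for p in ("A", "B", "X")}
    return sample_dataset(freqs, SamplingSpec(plan), seed + 1)


def test_f4_clade_pair_is_consistent_with_zero():
    # (A, B) form a clade against (C, outgroup): f4 should be within noise of 0
    nodes = [GraphNode("root"), GraphNode("out", ("root",), drift=0.2),
             GraphNode("anc", ("root",), drift=0.05),
             GraphNode("C", ("anc",), drift=0.1),
             GraphNode("ab", ("anc",), drift=0.05),
             GraphNode("A", ("ab",), drift=0.05),
             GraphNode("B", ("ab",), drift=0.05)]
    freqs = simulate_frequencies(GraphSpec(nodes), 50_000, 101)
    plan = {p: (10, "pseudo_haploid", 0.1) for p in ("A", "B", "C", "out")}
    ds = sample_dataset(freqs, SamplingSpec(plan), 102)
    counts = compute_pop_counts(ds)
    res = f4_stat(counts, ("A", "B", "C", "out"), assign_blocks(ds.snps))
    assert abs(res.z) < 3


def test_f3_detects_admixture():
    ds = _admixed_trio(201, 30_000)
    counts = compute_pop_counts(ds)
    res = f3_stat(counts, "X", "A", "B", assign_blocks(ds.snps))
    assert res.estimate < 0
    assert res.z < -3


def test_f3_positive_for_unadmixed_sister():
    # X a pure sister of A: no admixture signal, f3 stays positive
    nodes = [GraphNode("root"), GraphNode("anc", ("root",), drift=0.02),
             GraphNode("pA", ("anc",), drift=0.10),
             GraphNode("B", ("anc",), drift=0.11),
             GraphNode("A", ("pA",), drift=0.01),
             GraphNode("X", ("pA",), drift=0.01)]
    freqs = simulate_frequencies(GraphSpec(nodes), 30_000, 301)
    plan = {p: (10, "pseudo_haploid", 0.1) for p in ("A", "B", "X")}
    ds = sample_dataset(freqs, SamplingSpec(plan), 302)
    counts = compute_pop_counts(ds)
    res = f3_stat(counts, "X", "A", "B", assign_blocks(ds.snps))
    assert res.estimate > 0


def test_admixed_population_heterozygosity_exceeds_sources():
    ds = _admixed_trio(401, 50_000)
    counts = compute_pop_counts(ds)
    part = assign_blocks(ds.snps)
    hx = conditional_heterozygosity(counts, "X", part).estimate
    ha = conditional_heterozygosity(counts, "A", part).estimate
    hb = conditional_heterozygosity(counts, "B", part).estimate
    assert hx > ha and hx > hb


def test_fst_null_for_identical_populations():
    nodes = [GraphNode("root"), GraphNode("P", ("root",), drift=0.05)]
    freqs = dict(simulate_frequencies(GraphSpec(nodes), 30_000, 501))
    freqs["Q"] = freqs["P"]
    plan = {p: (10, "pseudo_haploid", 0.1) for p in ("P", "Q")}
    ds = sample_dataset(freqs, SamplingSpec(plan), 502)
    counts = compute_pop_counts(ds)
    res = hudson_fst(counts, "P", "Q", assign_blocks(ds.snps))
    assert abs(res.z) < 3


def test_fst_matches_large_sample_estimator_oracle():
    """Two-leaf graph, F = 0.05 per branch, vs an independent brute-force
    oracle: the per-SNP Hudson estimator averaged over 10^6 simulated SNPs."""
    nodes = [GraphNode("root"),
             GraphNode("P", ("root",), drift=0.05),
             GraphNode("Q", ("root",), drift=0.05)]
    spec = GraphSpec(nodes)

    # oracle: direct numpy arithmetic on 10^6 SNPs, 10 haploid calls per pop
    rng = np.random.default_rng(601)
    f = simulate_frequencies(spec, 1_000_000, 602)
    n = 10
    d1 = rng.binomial(n, f["P"])
    d2 = rng.binomial(n, f["Q"])
    p1, p2 = d1 / n, d2 / n
    num = (p1 - p2) ** 2 - p1 * (1 - p1) / (n - 1) - p2 * (1 - p2) / (n - 1)
    den = p1 * (1 - p2) + p2 * (1 - p1)
    oracle = num.sum() / den.sum()

    freqs = simulate_frequencies(spec, 100_000, 603)
    plan = {p: (5, "pseudo_haploid", 0.0) for p in ("P", "Q")}
    ds = sample_dataset(freqs, SamplingSpec(plan), 604)
    counts = compute_pop_counts(ds)
    res = hudson_fst(counts, "P", "Q", assign_blocks(ds.snps))
    assert res.estimate == pytest.approx(oracle, abs=3 * res.se)


def test_jackknife_se_tracks_replicate_scatter():
    """Across independent replicates the claimed se matches the empirical
    SD of the estimates within a factor of 1.3."""
    nodes = [GraphNode("B0"), GraphNode("B1", ("B0",), drift=0.05),
             GraphNode("A", ("B1",), drift=0.05),
             GraphNode("B", ("B1",), drift=0.05),
             GraphNode("C", ("B0",), drift=0.10),
             GraphNode("D", ("B0",), drift=0.15)]
    spec = GraphSpec(nodes)
    ests, ses = [], []
    for rep in range(120):
        freqs = simulate_frequencies(spec, 4000, 9000 + rep)
        plan = {p: (8, "pseudo_haploid", 0.1) for p in "ABCD"}
        ds = sample_dataset(freqs, SamplingSpec(plan), 9500 + rep)
        counts = compute_pop_counts(ds)
        res = f4_stat(counts, ("A", "B", "C", "D"), assign_blocks(ds.snps))
        ests.append(res.estimate)
        ses.append(res.se)
    ratio = np.mean(ses) / np.std(ests)
    assert 1 / 1.3 < ratio < 1.3
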