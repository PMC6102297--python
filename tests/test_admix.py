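"""f4 matrices, rank tests, qpAdm weights, qpWave stream counts, model search."""

import numpy as np
import pytest

from levantadmix import (
    GraphNode, GraphSpec, SamplingSpec, assign_blocks, build_f4_matrix,
    compute_pop_counts, model_search, qpadm, qpwave_min_streams,
    rank_outgroup_candidates, rank_test, resampled_copies_fixture,
    sample_dataset, simulate_frequencies, three_stream_fixture,
    two_stream_fixture,
)

from conftest import make_counts, per_snp_blocks


def _counts_and_blocks(ds):
    return compute_pop_counts(ds), assign_blocks(ds.snps)


# ---------------------------------------------------------------------------
# F4 matrix construction
# ---------------------------------------------------------------------------

def test_f4_matrix_entries_match_direct_arithmetic():
    from levantadmix import f4_stat
    counts = make_counts(
        derived={"L0": [1, 2], "L1": [0, 1], "R0": [2, 0], "R1": [1, 1],
                 "R2": [0, 2]},
        total={p: [2, 2] for p in ("L0", "L1", "R0", "R1", "R2")},
    )
    part = per_snp_blocks(2)
    m = build_f4_matrix(counts, ("L0", "L1"), ("R0", "R1", "R2"), part)
    assert m.shape == (1, 2)
    for j, rj in enumerate(("R1", "R2")):
        direct = f4_stat(counts, ("L0", "L1", "R0", rj), part).estimate
        assert m.X[0, j] == pytest.approx(direct, abs=1e-15)


def test_f4_matrix_zero_for_relabeled_copy_left():
    ds, info = resampled_copies_fixture(seed=11, n_snps=5000)
    counts, part = _counts_and_blocks(ds)
    m = build_f4_matrix(counts, ("C1", "C2"), info["right"], part)
    assert np.allclose(m.X, 0.0)


def test_f4_matrix_right_permutation_permutes_columns():
    ds, info = two_stream_fixture(seed=13, n_snps=5000)
    counts, part = _counts_and_blocks(ds)
    r = info["right"]
    m = build_f4_matrix(counts, info["left"], r, part)
    perm = [r[0], r[3], r[1], r[4], r[2]]
    m2 = build_f4_matrix(counts, info["left"], perm, part)
    # columns follow the non-base right populations
    lookup = {p: j for j, p in enumerate(r[1:])}
    for j2, p in enumerate(perm[1:]):
        assert np.allclose(m2.X[:, j2], m.X[:, lookup[p]])


def test_f4_matrix_rejects_left_right_overlap():
    ds, info = two_stream_fixture(seed=13, n_snps=2000)
    counts, part = _counts_and_blocks(ds)
    with pytest.raises(ValueError, match="shared"):
        build_f4_matrix(counts, ("L1", "R1"), info["right"], part)


# ---------------------------------------------------------------------------
# Rank test
# ---------------------------------------------------------------------------

def test_full_rank_is_saturated_chisq_zero():
    ds, info = two_stream_fixture(seed=17, n_snps=5000)
    counts, part = _counts_and_blocks(ds)
    m = build_f4_matrix(counts, info["left"], info["right"], part)
    res = rank_test(m, min(m.shape))
    assert res.chisq == 0.0
    assert res.df == 0
    assert res.p == 1.0


def test_rank_zero_rejected_on_two_stream_data():
    ds, info = two_stream_fixture(seed=19)
    counts, part = _counts_and_blocks(ds)
    m = build_f4_matrix(counts, info["left"], info["right"], part)
    assert rank_test(m, 0).p < 0.05


def test_rank_one_accepted_on_two_stream_data():
    ds, info = two_stream_fixture(seed=19)
    counts, part = _counts_and_blocks(ds)
    m = build_f4_matrix(counts, info["left"], info["right"], part)
    res = rank_test(m, 1)
    assert res.df == (3 - 1 - 1) * (5 - 1 - 1)
    assert res.p > 0.05


def test_rank_out_of_range_errors():
    ds, info = two_stream_fixture(seed=13, n_snps=2000)
    counts, part = _counts_and_blocks(ds)
    m = build_f4_matrix(counts, info["left"], info["right"], part)
    with pytest.raises(ValueError, match="outside"):
        rank_test(m, 5)


# ---------------------------------------------------------------------------
# qpAdm
# ---------------------------------------------------------------------------

def _two_way_dataset(seed, n_snps=100_000, w=0.7):
    nodes = [GraphNode("B0"), GraphNode("B1", ("B0",), drift=0.02),
             GraphNode("B2", ("B1",), drift=0.04),
             GraphNode("B3", ("B2",), drift=0.04)]
    for i, (at, F) in enumerate(zip(("B1", "B1", "B2", "B2", "B3"),
                                    (0.25, 0.2, 0.15, 0.12, 0.08)), 1):
        nodes.append(GraphNode(f"R{i}", (at,), drift=F))
    nodes.append(GraphNode("pA", ("B2",), drift=0.04))
    nodes.append(GraphNode("pB", ("B3",), drift=0.04))
    nodes.append(GraphNode("SA", ("pA",), drift=0.03))
    nodes.append(GraphNode("SB", ("pB",), drift=0.03))
    nodes.append(GraphNode("T", ("pA", "pB"), drift=0.005,
                           mix_weights=(w, 1 - w)))
    freqs = simulate_frequencies(GraphSpec(nodes), n_snps, seed)
    plan = {"T": (20, "pseudo_haploid", 0.3), "SA": (10, "pseudo_haploid", 0.3),
            "SB": (10, "pseudo_haploid", 0.3)}
    plan.update({f"R{i}": (5, "pseudo_haploid", 0.3) for i in range(1, 6)})
    return sample_dataset(freqs, SamplingSpec(plan), seed + 1)


RIGHTS5 = [f"R{i}" for i in range(1, 6)]


def test_qpadm_identity_case():
    # target resampled from the same population as source 1
    nodes = [GraphNode("B0"), GraphNode("B1", ("B0",), drift=0.03),
             GraphNode("R1", ("B0",), drift=0.2),
             GraphNode("R2", ("B0",), drift=0.15),
             GraphNode("R3", ("B1",), drift=0.1),
             GraphNode("S1", ("B1",), drift=0.05),
             GraphNode("S2", ("B0",), drift=0.08)]
    freqs = dict(simulate_frequencies(GraphSpec(nodes), 50_000, 23))
    freqs["T"] = freqs["S1"]
    plan = {p: (10, "pseudo_haploid", 0.2)
            for p in ("T", "S1", "S2", "R1", "R2", "R3")}
    ds = sample_dataset(freqs, SamplingSpec(plan), 24)
    counts, part = _counts_and_blocks(ds)
    model = qpadm(counts, "T", ["S1", "S2"], ["R1", "R2", "R3"], part)
    assert abs(model.weights[0] - 1.0) <= 2 * model.ses[0]
    assert abs(model.weights[1] - 0.0) <= 2 * model.ses[1]


def test_qpadm_two_way_recovery():
    ds = _two_way_dataset(29)
    counts, part = _counts_and_blocks(ds)
    model = qpadm(counts, "T", ["SA", "SB"], RIGHTS5, part)
    assert model.plausible
    assert abs(model.weights[0] - 0.7) <= 2 * model.ses[0]
    assert abs(model.weights[1] - 0.3) <= 2 * model.ses[1]


def test_qpadm_weights_sum_to_one_exactly():
    ds = _two_way_dataset(31, n_snps=20_000)
    counts, part = _counts_and_blocks(ds)
    model = qpadm(counts, "T", ["SA", "SB"], RIGHTS5, part)
    assert model.weights.sum() == pytest.approx(1.0, abs=1e-12)


def test_qpadm_invariant_to_source_order():
    ds = _two_way_dataset(37, n_snps=20_000)
    counts, part = _counts_and_blocks(ds)
    a = qpadm(counts, "T", ["SA", "SB"], RIGHTS5, part)
    b = qpadm(counts, "T", ["SB", "SA"], RIGHTS5, part)
    assert np.abs(a.weights - b.weights[::-1]).max() < 1e-6
    assert np.abs(a.ses - b.ses[::-1]).max() < 1e-6
    assert a.p == pytest.approx(b.p, rel=1e-9)


def test_qpadm_p_equals_rank_test_on_left_set():
    ds = _two_way_dataset(41, n_snps=20_000)
    counts, part = _counts_and_blocks(ds)
    model = qpadm(counts, "T", ["SA", "SB"], RIGHTS5, part)
    m = build_f4_matrix(counts, ("T", "SA", "SB"), RIGHTS5, part)
    assert model.p == rank_test(m, 1).p


def test_qpadm_argument_validation():
    ds = _two_way_dataset(43, n_snps=5000)
    counts, part = _counts_and_blocks(ds)
    with pytest.raises(ValueError, match="underdetermined"):
        qpadm(counts, "T", ["SA", "SB", "R1", "R2", "R3"],
              ["R4", "R5"], part)
    with pytest.raises(ValueError, match="target"):
        qpadm(counts, "T", ["T", "SA"], RIGHTS5, part)


# ---------------------------------------------------------------------------
# qpWave
# ---------------------------------------------------------------------------

def test_min_streams_one_for_relabeled_copies():
    ds, info = resampled_copies_fixture(seed=47)
    counts, part = _counts_and_blocks(ds)
    n, ranks, saturated = qpwave_min_streams(counts, info["left"],
                                             info["right"], part)
    assert n == 1
    assert not saturated


def test_min_streams_three_for_independent_streams():
    ds, info = three_stream_fixture(seed=53)
    counts, part = _counts_and_blocks(ds)
    n, ranks, saturated = qpwave_min_streams(counts, info["left"],
                                             info["right"], part)
    assert n == 3
    assert saturated       # only the df=0 saturated rank fits
    assert ranks[0].p < 0.05 and ranks[1].p < 0.05


def test_min_streams_two_for_two_stream_left():
    ds, info = two_stream_fixture(seed=59)
    counts, part = _counts_and_blocks(ds)
    n, ranks, saturated = qpwave_min_streams(counts, info["left"],
                                             info["right"], part)
    assert n == 2
    assert not saturated


# ---------------------------------------------------------------------------
# Outgroup ranking and model search
# ---------------------------------------------------------------------------

def _clade_dataset(seed, n_snps=50_000):
    """Target T cladal with C1; E sees C2's private branch; S symmetric."""
    nodes = [GraphNode("B0"), GraphNode("Deep", ("B0",), pin=0.0),
             GraphNode("B1", ("B0",), drift=0.02),
             GraphNode("B2", ("B1",), drift=0.02),
             GraphNode("R1", ("B1",), drift=0.25),
             GraphNode("R2", ("B1",), drift=0.2),
             GraphNode("R3", ("B2",), drift=0.12),
             GraphNode("Par", ("B2",), drift=0.03),
             GraphNode("C1", ("Par",), drift=0.02),
             GraphNode("M", ("Par",), drift=0.02),
             GraphNode("C2", ("M",), drift=0.03),
             GraphNode("E", ("M",), drift=0.10),
             GraphNode("S", ("B2",), drift=0.10),
             GraphNode("T", ("C1",), drift=0.02)]
    freqs = simulate_frequencies(GraphSpec(nodes), n_snps, seed)
    plan = {p: (10, "pseudo_haploid", 0.1)
            for p in ("T", "C1", "C2", "E", "S", "R1", "R2", "R3", "Deep")}
    return sample_dataset(freqs, SamplingSpec(plan), seed + 1)


def test_outgroup_ranking_orders_by_informativeness():
    ds = _clade_dataset(61)
    counts, part = _counts_and_blocks(ds)
    ranked = rank_outgroup_candidates(counts, ("C1", "C2"), ["S", "E"],
                                      "Deep", part)
    assert ranked[0][0] == "E"
    assert ranked[0][1] > 3          # cladal with C2: strongly asymmetric
    assert ranked[-1][0] == "S"
    assert ranked[-1][1] < 3         # symmetric by construction
    # invariant to candidate input order
    assert ranked == rank_outgroup_candidates(counts, ("C1", "C2"),
                                              ["E", "S"], "Deep", part)


def test_outgroup_ranking_validates_inputs():
    ds = _clade_dataset(61, n_snps=5000)
    counts, part = _counts_and_blocks(ds)
    with pytest.raises(ValueError, match="empty"):
        rank_outgroup_candidates(counts, ("C1", "C2"), [], "Deep", part)
    with pytest.raises(ValueError, match="overlap"):
        rank_outgroup_candidates(counts, ("C1", "C2"), ["C1"], "Deep", part)


def test_model_search_clade_resolved_at_stage_one():
    ds = _clade_dataset(67)
    counts, part = _counts_and_blocks(ds)
    ledger = model_search(counts, "T", ["C1", "C2"], ["C1", "C2"],
                          ["R1", "R2", "R3"], ["E"], part)
    assert ledger.final_survivors == [("C1",)]
    stages = {r.stage for r in ledger.rows}
    assert "2-source" not in stages  # stage 1 succeeded, enumeration stopped


def test_model_search_augmentation_eliminates_false_clade():
    ds = _clade_dataset(67)
    counts, part = _counts_and_blocks(ds)
    ledger = model_search(counts, "T", ["C1", "C2"], ["C1", "C2"],
                          ["R1", "R2", "R3"], ["E"], part)
    # before augmentation both clade models pass; E kills the C2 model
    first_round = ledger.survivors_history[0]
    assert set(first_round) == {("C1",), ("C2",)}
    assert ledger.survivors_history[-1] == [("C1",)]


def test_model_search_survivors_monotone_nonincreasing():
    ds = _clade_dataset(71)
    counts, part = _counts_and_blocks(ds)
    ledger = model_search(counts, "T", ["C1", "C2"], ["C1", "C2"],
                          ["R1", "R2", "R3"], ["E"], part)
    sizes = [len(s) for s in ledger.survivors_history]
    assert all(a >= b for a, b in zip(sizes, sizes[1:]))


def test_model_search_hidden_source_leaves_no_survivors():
    from levantadmix import peqiin_fixture
    ds, truth = peqiin_fixture(seed=5, n_snps=60_000)
    counts, part = _counts_and_blocks(ds)
    pool = ["Levant_N", "Anatolia_N"]   # Iran-related source missing
    ledger = model_search(counts, truth["target"], pool, pool,
                          truth["rights"], [], part)
    assert ledger.final_survivors == []


def test_model_search_finds_true_triplet():
    from levantadmix import peqiin_fixture
    ds, truth = peqiin_fixture(seed=5, n_snps=100_000)
    counts, part = _counts_and_blocks(ds)
    pool = list(truth["sources"])
    ledger = model_search(counts, truth["target"], pool, pool,
                          truth["rights"], [], part)
    assert ledger.final_survivors == [tuple(truth["sources"])]
    # stages 1 and 2 must have been exhausted first
    stages = [r.stage for r in ledger.rows]
    assert "1-source" in stages and "2-source" in stages
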