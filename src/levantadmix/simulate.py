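"""Admixture-graph simulation of allele frequencies and genotype panels.

Allele frequencies evolve down a user-specified acyclic graph under the
Balding-Nichols model: along an edge with drift parameter F, a child
frequency is drawn from Beta(p(1-F)/F, (1-p)(1-F)/F) around the parent
frequency p (mean p, variance F p(1-p)).  Admixture nodes first mix their
parents' frequencies with fixed weights, then apply their own drift edge
(mixture-then-drift; f-statistic expectations depend on this order).
Outgroup nodes may pin the derived frequency to 0, which makes them usable
as allele-polarity anchors in f4(...; A, Outgroup) statistics.

Sampled genotype panels emulate a merged ancient-DNA dataset: per-population
sample sizes, diploid or pseudo-haploid calls, i.i.d. missingness, an
EIGENSTRAT-writable :class:`~levantadmix.dataset.Dataset` with SNPs spread
over 22 autosomes carrying a uniform genetic map (so jackknife blocks are
well defined).  SNPs are simulated without linkage.

``peqiin_fixture`` builds the package's reference scenario: a deep pinned
outgroup, eleven early-branching right-set populations, three admixture
sources and a target mixed with weights configured to the three-way model of
the Chalcolithic Levant study (Levant_N-like 0.570, Anatolia_N-like 0.264,
Iran_ChL-like 0.166 after normalization), with post-admixture drift,
pseudo-haploid sampling and 30% missingness.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .dataset import Dataset

#: Three-way truth weights, normalized to sum to 1 (printed values 0.571 /
#: 0.264 / 0.166 sum to 1.001 from rounding).
PEQIIN_TRUTH_WEIGHTS = (0.571 / 1.001, 0.264 / 1.001, 0.166 / 1.001)
PEQIIN_SOURCES = ("Levant_N", "Anatolia_N", "Iran_ChL")
PEQIIN_TARGET = "Levant_ChL"


@dataclass(frozen=True)
class GraphNode:
    name: str
    parents: tuple[str, ...] = ()          # () = root
    drift: float = 0.0                      # F of the node's incoming edge
    mix_weights: tuple[float, ...] = ()     # required when len(parents) >= 2
    pin: float | None = None                # pin frequency (e.g. 0 for outgroup)


@dataclass
class GraphSpec:
    nodes: list[GraphNode]
    root_low: float = 0.05
    root_high: float = 0.95

    def __post_init__(self) -> None:
        names = [n.name for n in self.nodes]
        if len(set(names)) != len(names):
            raise ValueError("duplicate node names")
        known = set()
        for n in self.nodes:  # nodes must be listed parents-first (topological)
            for p in n.parents:
                if p not in known:
                    raise ValueError(
                        f"node {n.name!r}: parent {p!r} not defined earlier "
                        "(graph must be acyclic, listed in topological order)")
            if not 0.0 <= n.drift < 1.0:
                raise ValueError(f"node {n.name!r}: drift F must be in [0, 1)")
            if len(n.parents) >= 2:
                if len(n.mix_weights) != len(n.parents):
                    raise ValueError(f"node {n.name!r}: mixture weights must "
                                     "match parent count")
                if abs(sum(n.mix_weights) - 1.0) > 1e-12:
                    raise ValueError(f"node {n.name!r}: mixture weights must "
                                     "sum to 1")
            known.add(n.name)

    @classmethod
    def from_dict(cls, spec: dict) -> "GraphSpec":
        """Build from a YAML-style mapping {nodes: [{name, parents, ...}]}."""
        nodes = [
            GraphNode(
                name=d["name"],
                parents=tuple(d.get("parents", ())),
                drift=float(d.get("drift", 0.0)),
                mix_weights=tuple(d.get("mix_weights", ())),
                pin=d.get("pin"),
            )
            for d in spec["nodes"]
        ]
        root = spec.get("root_frequency", {})
        return cls(nodes, root.get("low", 0.05), root.get("high", 0.95))


@dataclass
class SamplingSpec:
    """Per-population sampling plan: (n individuals, ploidy, missing rate)."""
    populations: dict[str, tuple[int, str, float]]

    def __post_init__(self) -> None:
        for pop, (n, mode, miss) in self.populations.items():
            if n < 1:
                raise ValueError(f"{pop}: need n >= 1")
            if mode not in ("diploid", "pseudo_haploid"):
                raise ValueError(f"{pop}: unknown ploidy mode {mode!r}")
            if not 0.0 <= miss <= 1.0:
                raise ValueError(f"{pop}: missing rate outside [0, 1]")


def _bn_draw(rng: np.random.Generator, p: np.ndarray, F: float) -> np.ndarray:
    """Balding-Nichols drift; F = 0 is identity, fixed frequencies stay fixed."""
    if F == 0.0:
        return p.copy()
    out = p.copy()
    interior = (p > 0.0) & (p < 1.0)
    if interior.any():
        a = p[interior] * (1.0 - F) / F
        b = (1.0 - p[interior]) * (1.0 - F) / F
        out[interior] = rng.beta(a, b)
    return out


def simulate_frequencies(spec: GraphSpec, n_snps: int, seed: int
                         ) -> dict[str, np.ndarray]:
    """Derived-allele frequency per node per SNP."""
    rng = np.random.default_rng(seed)
    freqs: dict[str, np.ndarray] = {}
    for node in spec.nodes:
        if node.pin is not None:
            freqs[node.name] = np.full(n_snps, float(node.pin))
            continue
        if not node.parents:
            base = rng.uniform(spec.root_low, spec.root_high, n_snps)
        elif len(node.parents) == 1:
            base = freqs[node.parents[0]]
        else:
            w = np.asarray(node.mix_weights)
            base = sum(wi * freqs[p] for wi, p in zip(w, node.parents))
        freqs[node.name] = _bn_draw(rng, np.asarray(base, float), node.drift)
    return freqs


def _snp_table(n_snps: int, cm_per_snp: float = 0.03) -> pd.DataFrame:
    """SNPs spread over 22 autosomes with a uniform genetic map.

    ``cm_per_snp`` sets the map density (default 0.03 cM between adjacent
    SNPs), which controls how many 0.05 M jackknife blocks the panel yields.
    """
    chroms = np.array_split(np.arange(n_snps), 22)
    rows = []
    # alternating transversion/transition allele pairs, deterministic
    pairs = [("A", "T"), ("A", "G"), ("C", "G"), ("C", "T")]
    i = 0
    for ci, idx in enumerate(chroms, start=1):
        for j in range(len(idx)):
            a, b = pairs[i % 4]
            rows.append((f"snp{i}", str(ci), j * cm_per_snp / 100.0,
                         10_000 * (j + 1), a, b))
            i += 1
    return pd.DataFrame(rows, columns=["snp_id", "chrom", "gpos", "ppos",
                                       "allele_a", "allele_b"])


def sample_dataset(frequencies: dict[str, np.ndarray], sampling: SamplingSpec,
                   seed: int, snps: pd.DataFrame | None = None) -> Dataset:
    """Draw a genotype Dataset from per-population derived frequencies.

    Diploid genotypes are Binomial(2, p) derived copies stored as 2 - copies
    of the derived allele (the genotype value counts allele_a); pseudo-haploid
    calls draw a single allele and store it as 0 (derived) or 2 (ancestral).
    Missingness is i.i.d. per call.
    """
    unknown = set(sampling.populations) - set(frequencies)
    if unknown:
        raise ValueError(f"unknown populations in sampling spec: {unknown}")
    rng = np.random.default_rng(seed)
    n_snps = len(next(iter(frequencies.values())))
    if snps is None:
        snps = _snp_table(n_snps)
    geno_rows, ind_rows = [], []
    for pop, (n, mode, miss) in sampling.populations.items():
        p = frequencies[pop]
        if mode == "diploid":
            derived = rng.binomial(2, p, size=(n, n_snps))
        else:
            derived = 2 * rng.binomial(1, p, size=(n, n_snps))
        g = (2 - derived).astype(np.int8)
        if miss > 0:
            g[rng.random((n, n_snps)) < miss] = 9
        geno_rows.append(g)
        ind_rows += [(f"{pop}_{i}", "U", pop, mode == "pseudo_haploid")
                     for i in range(n)]
    individuals = pd.DataFrame(
        ind_rows, columns=["individual_id", "sex", "group", "pseudo_haploid"])
    return Dataset(snps.reset_index(drop=True), individuals,
                   np.vstack(geno_rows))


# ---------------------------------------------------------------------------
# Reference fixture
# ---------------------------------------------------------------------------

#: Right-set drift depths (calibration choices, recorded in the truth record).
_RIGHT_DRIFTS = (0.30, 0.28, 0.26, 0.24, 0.22, 0.20, 0.18, 0.16, 0.12, 0.08, 0.05)
_RIGHT_ATTACH = ("B1", "B1", "B2", "B2", "B3", "B3", "B4", "B4", "B5", "B6", "B7")


def peqiin_graph() -> GraphSpec:
    """The fixture's admixture graph (deep outgroup, 11 rights, 3 sources)."""
    nodes = [GraphNode("B0")]
    nodes.append(GraphNode("Chimp", ("B0",), pin=0.0))
    for i in range(1, 8):  # backbone chain, modest shared drift per segment
        nodes.append(GraphNode(f"B{i}", (f"B{i-1}",), drift=0.02))
    for i, (F, at) in enumerate(zip(_RIGHT_DRIFTS, _RIGHT_ATTACH), start=1):
        nodes.append(GraphNode(f"Right{i:02d}", (at,), drift=F))
    nodes.append(GraphNode("pLevant", ("B7",), drift=0.04))
    nodes.append(GraphNode("pAnatolia", ("B5",), drift=0.05))
    nodes.append(GraphNode("pIran", ("B3",), drift=0.06))
    nodes.append(GraphNode("Levant_N", ("pLevant",), drift=0.03))
    nodes.append(GraphNode("Anatolia_N", ("pAnatolia",), drift=0.03))
    nodes.append(GraphNode("Iran_ChL", ("pIran",), drift=0.03))
    nodes.append(GraphNode(PEQIIN_TARGET, ("pLevant", "pAnatolia", "pIran"),
                           drift=0.005, mix_weights=PEQIIN_TRUTH_WEIGHTS))
    return GraphSpec(nodes)


def two_stream_fixture(seed: int, n_snps: int = 20_000
                       ) -> tuple[Dataset, dict]:
    """Three left populations deriving from exactly two ancestry streams.

    L1 and L2 descend from separate streams P and Q; L3 is a 50/50 mixture.
    The f4 matrix of (L1, L2, L3) against the five rights therefore has true
    rank 1, the null scenario for rank-test calibration.  The stream
    separation (P and Q split across a 0.02-drift backbone segment seen by
    the deepest right) keeps the rank-1 component well resolved at 20k SNPs.
    """
    nodes = [GraphNode("B0")]
    nodes += [GraphNode(f"B{i}", (f"B{i-1}",), drift=0.02) for i in (1, 2, 3)]
    for i, (at, F) in enumerate(zip(("B1", "B1", "B2", "B2", "B3"),
                                    (0.25, 0.20, 0.15, 0.12, 0.08)), 1):
        nodes.append(GraphNode(f"R{i}", (at,), drift=F))
    nodes.append(GraphNode("P", ("B2",), drift=0.10))
    nodes.append(GraphNode("Q", ("B3",), drift=0.10))
    nodes.append(GraphNode("L1", ("P",), drift=0.02))
    nodes.append(GraphNode("L2", ("Q",), drift=0.02))
    nodes.append(GraphNode("L3", ("P", "Q"), drift=0.02,
                           mix_weights=(0.5, 0.5)))
    freqs = simulate_frequencies(GraphSpec(nodes), n_snps, seed)
    pops = ["L1", "L2", "L3", "R1", "R2", "R3", "R4", "R5"]
    plan = {p: (10, "pseudo_haploid", 0.1) for p in pops}
    dataset = sample_dataset(freqs, SamplingSpec(plan), seed + 1)
    info = {"left": ["L1", "L2", "L3"], "right": ["R1", "R2", "R3", "R4", "R5"],
            "true_rank": 1, "n_snps": n_snps, "seed": seed}
    return dataset, info


def three_stream_fixture(seed: int, n_snps: int = 20_000
                         ) -> tuple[Dataset, dict]:
    """Three left populations from three independent ancestry streams.

    Lefts branch from successive backbone nodes separated by 0.06-drift
    segments, and rights branch both between and below the left attachment
    points, so every stream separation is visible to the right set: the
    2 x (R-1) f4 matrix has full rank 2 and the minimum stream count is 3.
    """
    nodes = [GraphNode("B0"), GraphNode("B1", ("B0",), drift=0.02)]
    nodes += [GraphNode(f"B{i}", (f"B{i-1}",), drift=0.06) for i in (2, 3)]
    attach = ("B1", "B1", "B2", "B2", "B3", "B3")
    drifts = (0.25, 0.20, 0.15, 0.12, 0.10, 0.08)
    for i, (at, F) in enumerate(zip(attach, drifts), 1):
        nodes.append(GraphNode(f"R{i}", (at,), drift=F))
    nodes.append(GraphNode("L1", ("B1",), drift=0.10))
    nodes.append(GraphNode("L2", ("B2",), drift=0.10))
    nodes.append(GraphNode("L3", ("B3",), drift=0.10))
    freqs = simulate_frequencies(GraphSpec(nodes), n_snps, seed)
    pops = ["L1", "L2", "L3"] + [f"R{i}" for i in range(1, 7)]
    plan = {p: (10, "pseudo_haploid", 0.1) for p in pops}
    dataset = sample_dataset(freqs, SamplingSpec(plan), seed + 1)
    info = {"left": ["L1", "L2", "L3"],
            "right": [f"R{i}" for i in range(1, 7)],
            "true_rank": 2, "n_snps": n_snps, "seed": seed}
    return dataset, info


def resampled_copies_fixture(seed: int, n_snps: int = 20_000
                             ) -> tuple[Dataset, dict]:
    """Left set of three relabeled copies of one population (one stream).

    The same sampled individuals appear under three group labels C1/C2/C3,
    so the per-SNP allele frequencies of the copies are identical and the f4
    matrix is exactly zero: the minimal single-stream scenario.
    """
    nodes = [GraphNode("B0")]
    nodes += [GraphNode(f"B{i}", (f"B{i-1}",), drift=0.02) for i in (1, 2, 3)]
    for i, (at, F) in enumerate(zip(("B1", "B1", "B2", "B2", "B3"),
                                    (0.25, 0.20, 0.15, 0.12, 0.08)), 1):
        nodes.append(GraphNode(f"R{i}", (at,), drift=F))
    nodes.append(GraphNode("P", ("B3",), drift=0.05))
    freqs = simulate_frequencies(GraphSpec(nodes), n_snps, seed)
    plan = {p: (8, "pseudo_haploid", 0.1)
            for p in ["P", "R1", "R2", "R3", "R4", "R5"]}
    base = sample_dataset(freqs, SamplingSpec(plan), seed + 1)
    p_rows = np.flatnonzero(base.individuals["group"] == "P")
    copies, geno = [], [base.genotypes]
    for label in ("C1", "C2", "C3"):
        sub = base.individuals.iloc[p_rows].copy()
        sub["group"] = label
        sub["individual_id"] = [f"{label}_{i}" for i in range(len(sub))]
        copies.append(sub)
        geno.append(base.genotypes[p_rows])
    individuals = pd.concat([base.individuals, *copies], ignore_index=True)
    dataset = Dataset(base.snps, individuals, np.vstack(geno))
    info = {"left": ["C1", "C2", "C3"],
            "right": ["R1", "R2", "R3", "R4", "R5"],
            "true_rank": 0, "n_snps": n_snps, "seed": seed}
    return dataset, info


def peqiin_fixture(seed: int, n_snps: int = 100_000
                   ) -> tuple[Dataset, dict]:
    """Reference synthetic cohort plus a truth record.

    20 pseudo-haploid target individuals, 10 per source, 5 per outgroup,
    30% missing calls, mirroring the shape of the study cohort.
    """
    if n_snps < 1000:
        raise ValueError("need at least 1000 SNPs")
    spec = peqiin_graph()
    freqs = simulate_frequencies(spec, n_snps, seed)
    rights = [f"Right{i:02d}" for i in range(1, 12)]
    plan = {PEQIIN_TARGET: (20, "pseudo_haploid", 0.3)}
    for s in PEQIIN_SOURCES:
        plan[s] = (10, "pseudo_haploid", 0.3)
    for r in ["Chimp"] + rights:
        plan[r] = (5, "pseudo_haploid", 0.3)
    dataset = sample_dataset(freqs, SamplingSpec(plan), seed + 1)
    truth = {
        "target": PEQIIN_TARGET,
        "sources": list(PEQIIN_SOURCES),
        "weights": list(PEQIIN_TRUTH_WEIGHTS),
        "rights": ["Chimp"] + rights,
        "right_drifts": list(_RIGHT_DRIFTS),
        "post_admixture_drift": 0.005,
        "seed": seed,
        "n_snps": n_snps,
    }
    return dataset, truth
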