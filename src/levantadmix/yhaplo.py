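"""Y-chromosome haplogroup assignment on an ISOGG-style tree.

Ancient samples yield sparse, damage-prone Y calls, so assignment is scored
rather than deterministic: every haplogroup is evaluated by breadth-first
traversal, counting weighted mismatches between the observed calls and the
derived/ancestral state expected on the path from the root to that node.
Derived mutations that are transitions (A<->G, C<->T) — the classes inflated
by postmortem cytosine deamination — are down-weighted to 1/3 of a
transversion.  The best haplogroup minimizes the mismatch score; samples
covered at fewer than 100,000 SNPs genome-wide get a low-data warning flag
(never a refusal).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import pandas as pd

from .dataset import is_transition

logger = logging.getLogger(__name__)

TRANSITION_WEIGHT = 1.0 / 3.0
LOW_DATA_SNPS = 100_000


@dataclass
class HaplotreeNode:
    name: str
    parent: str | None
    #: (position, ancestral, derived, is_transition)
    variants: list[tuple[int, str, str, bool]] = field(default_factory=list)
    children: list[str] = field(default_factory=list)
    depth: int = 0


@dataclass
class Haplotree:
    nodes: dict[str, HaplotreeNode]
    roots: list[str]

    def path_positions(self, name: str) -> dict[int, tuple[str, str, bool]]:
        """position -> (ancestral, derived, is_transition) on root->name path."""
        out: dict[int, tuple[str, str, bool]] = {}
        node = self.nodes[name]
        chain = []
        while node is not None:
            chain.append(node)
            node = self.nodes[node.parent] if node.parent else None
        for n in reversed(chain):
            for pos, anc, der, ts in n.variants:
                out[pos] = (anc, der, ts)
        return out

    def all_positions(self) -> dict[int, tuple[str, str, bool]]:
        out: dict[int, tuple[str, str, bool]] = {}
        for n in self.nodes.values():
            for pos, anc, der, ts in n.variants:
                out[pos] = (anc, der, ts)
        return out

    def bfs_order(self) -> list[str]:
        order, queue = [], list(self.roots)
        while queue:
            name = queue.pop(0)
            order.append(name)
            queue.extend(sorted(self.nodes[name].children))
        return order


@dataclass
class YCallResult:
    haplogroup: str
    score: float
    matched_derived: int
    mismatched: int
    covered_informative: int
    low_data: bool


def load_haplotree(table: pd.DataFrame | str) -> Haplotree:
    """Build a tree from rows of (haplogroup, position, ancestral, derived).

    Parentage is taken from an explicit ``parent`` column when present,
    otherwise from the ISOGG naming convention: the parent is the longest
    proper prefix of the name that is itself a haplogroup in the table
    (single-letter haplogroups are roots).  Duplicate (haplogroup, position)
    rows are deduplicated with a logged count.
    """
    if not isinstance(table, pd.DataFrame):
        table = pd.read_csv(table, sep="\t", dtype={"haplogroup": str})
    required = {"haplogroup", "position", "ancestral", "derived"}
    missing = required - set(table.columns)
    if missing:
        raise ValueError(f"haplotree table missing columns: {missing}")
    before = len(table)
    table = table.drop_duplicates(subset=["haplogroup", "position"])
    dropped = before - len(table)
    if dropped:
        logger.warning("load_haplotree: deduplicated %d repeated "
                       "(haplogroup, position) rows", dropped)
    names = sorted(set(table["haplogroup"]))
    explicit = "parent" in table.columns
    parent_of: dict[str, str | None] = {}
    for name in names:
        if explicit:
            p = table.loc[table["haplogroup"] == name, "parent"].iloc[0]
            parent_of[name] = None if pd.isna(p) or p == "" else str(p)
            if parent_of[name] is not None and parent_of[name] not in names:
                raise ValueError(f"haplogroup {name!r}: parent "
                                 f"{parent_of[name]!r} not in table")
            continue
        cands = [o for o in names if o != name and name.startswith(o)]
        if cands:
            parent_of[name] = max(cands, key=len)
        elif len(name) == 1:
            parent_of[name] = None
        else:
            raise ValueError(f"haplogroup {name!r} has no lexical parent in "
                             "the table and no explicit parent column")
    nodes = {name: HaplotreeNode(name, parent_of[name]) for name in names}
    for name, parent in parent_of.items():
        if parent is not None:
            nodes[parent].children.append(name)
    for r in table.itertuples(index=False):
        anc, der = str(r.ancestral), str(r.derived)
        nodes[str(r.haplogroup)].variants.append(
            (int(r.position), anc, der, is_transition(anc, der)))
    roots = sorted(n for n, p in parent_of.items() if p is None)

    def set_depth(name: str, d: int) -> None:
        nodes[name].depth = d
        for c in nodes[name].children:
            set_depth(c, d + 1)

    for root in roots:
        set_depth(root, 0)
    return Haplotree(nodes, roots)


def score_haplogroup(calls: dict[int, str], tree: Haplotree, name: str,
                     penalize_ancestral: bool = True) -> tuple[float, int, int]:
    """(score, matched_derived, mismatches) of one haplogroup for a sample.

    Off-path observed derived alleles always mismatch; on-path observed
    ancestral alleles mismatch when ``penalize_ancestral`` (default: without
    it, sparse data trivially favors the deepest lineages).  Transitions
    weigh 1/3, transversions 1.
    """
    on_path = tree.path_positions(name)
    informative = tree.all_positions()
    score, matched, mismatched = 0.0, 0, 0
    for pos, obs in calls.items():
        info = informative.get(pos)
        if info is None:
            continue
        anc, der, ts = info
        w = TRANSITION_WEIGHT if ts else 1.0
        if pos in on_path:
            if obs == der:
                matched += 1
            elif obs == anc and penalize_ancestral:
                score += w
                mismatched += 1
        else:
            if obs == der:
                score += w
                mismatched += 1
    return score, matched, mismatched


def call_y_haplogroup(calls: dict[int, str], tree: Haplotree,
                      n_snps_covered: int | None = None,
                      penalize_ancestral: bool = True) -> YCallResult:
    """Assign the haplogroup minimizing the weighted mismatch score.

    Ties break by more matched derived alleles, then deeper node, then
    lexicographic name.  The traversal is breadth-first but scores every
    node — it is an ordering, not a pruning — so the result equals the
    exhaustive minimum.
    """
    informative = tree.all_positions()
    covered = sum(1 for pos in calls if pos in informative)
    if covered == 0:
        raise ValueError("uncallable: zero covered informative positions")
    best = None
    for name in tree.bfs_order():
        score, matched, mism = score_haplogroup(calls, tree, name,
                                                penalize_ancestral)
        key = (score, -matched, -tree.nodes[name].depth, name)
        if best is None or key < best[0]:
            best = (key, name, score, matched, mism)
    _, name, score, matched, mism = best
    low = n_snps_covered is not None and n_snps_covered < LOW_DATA_SNPS
    return YCallResult(name, score, matched, mism, covered, low)


def read_calls(path) -> dict[int, str]:
    """Load a per-sample calls TSV of (position, allele)."""
    df = pd.read_csv(path, sep="\t")
    return {int(r.position): str(r.allele) for r in df.itertuples(index=False)}
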