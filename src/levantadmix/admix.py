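"""Rank-based admixture modeling: f4 matrices, qpWave rank tests, qpAdm.

The machinery follows the qpWave/qpAdm methodology: all f4-statistics of the
form f4(left_0, left_i; right_0, right_j) are collected into an
(L-1) x (R-1) matrix X with a block-jackknife covariance Q of vec(X).  If the
left populations descend from k+1 ancestry streams (relative to the rights),
X has rank k; the fit of a rank-k hypothesis is

    chisq = min_{rank(Y)=k} (vec(X) - vec(Y))' Q^{-1} (vec(X) - vec(Y))

referred to a chi-squared distribution with (L-1-k)(R-1-k) degrees of
freedom.  qpAdm augments the rank test with a generalized-least-squares
estimate of the mixture weights of a target population from proposed sources,
constrained to sum to 1, with delete-one-block jackknife standard errors.

The model-selection driver reproduces the study design: enumerate 1-, 2- and
3-source models (with core-source restrictions), keep models with p > 0.05
and weights in [0, 1], then append additional right-set outgroups one at a
time, re-testing survivors until at most one remains.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass, field

import numpy as np
from scipy import linalg, stats

from .dataset import BlockPartition, PopCounts
from .jackknife import block_jackknife, jackknife_covariance

logger = logging.getLogger(__name__)

P_PLAUSIBLE = 0.05


# ---------------------------------------------------------------------------
# f4 matrix with jackknife covariance
# ---------------------------------------------------------------------------

@dataclass
class F4Matrix:
    left: tuple[str, ...]
    right: tuple[str, ...]
    X: np.ndarray                 # (L-1, R-1)
    Q: np.ndarray                 # (d, d), d = (L-1)(R-1)
    loo: np.ndarray = field(repr=False)      # (g, d) delete-one vec(X)
    block_weights: np.ndarray = field(repr=False)  # (g,)
    n_snps_used: np.ndarray = field(repr=False)    # per-entry counts, (L-1, R-1)

    @property
    def shape(self) -> tuple[int, int]:
        return self.X.shape


def _f4_entry_sums(counts: PopCounts, a: str, b: str, c: str, d: str,
                   partition: BlockPartition, extra_mask=None):
    """Per-block sums/counts of the per-SNP f4 product for one quadruple."""
    pa, pb, pc, pd_ = (counts.freq(p) for p in (a, b, c, d))
    mask = ~(np.isnan(pa) | np.isnan(pb) | np.isnan(pc) | np.isnan(pd_))
    if extra_mask is not None:
        mask &= extra_mask
    vals = np.where(mask, (pa - pb) * (pc - pd_), 0.0)
    sums = np.bincount(partition.block_id, weights=vals,
                       minlength=partition.n_blocks)
    cnts = np.bincount(partition.block_id, weights=mask.astype(float),
                       minlength=partition.n_blocks)
    return sums, cnts, int(mask.sum())


def _assemble(entries, partition: BlockPartition):
    """Whole-data means, delete-one means and block weights for many entries.

    ``entries`` is a list of (sums, counts, n_used).  Blocks are shared:
    a block enters the jackknife when any entry has SNPs in it; entries
    untouched by a deleted block keep their whole-data value.
    """
    S = np.stack([e[0] for e in entries])      # (d, g)
    C = np.stack([e[1] for e in entries])
    tot_s, tot_c = S.sum(axis=1), C.sum(axis=1)
    if (tot_c == 0).any():
        raise ValueError("an f4 entry has zero usable SNPs")
    whole = tot_s / tot_c
    denom = tot_c[:, None] - C
    with np.errstate(invalid="ignore", divide="ignore"):
        loo = (tot_s[:, None] - S) / denom
    loo = np.where(denom > 0, loo, whole[:, None])   # block held all SNPs
    union = C.sum(axis=0) > 0
    weights = C.sum(axis=0)[union] / len(entries)
    if union.sum() < 2:
        raise ValueError("fewer than 2 jackknife blocks with data")
    return whole, loo[:, union].T, weights           # loo -> (g, d)


def build_f4_matrix(counts: PopCounts, left, right,
                    partition: BlockPartition, allsnps: bool = True
                    ) -> F4Matrix:
    """X[i-1, j-1] = f4(left_0, left_i; right_0, right_j) with covariance Q."""
    left, right = tuple(left), tuple(right)
    if len(left) < 2 or len(right) < 2:
        raise ValueError("need at least 2 left and 2 right populations")
    overlap = set(left) & set(right)
    if overlap:
        raise ValueError(f"populations shared between left and right: {overlap}")
    extra = None
    if not allsnps:
        extra = np.ones(counts.n_snps, dtype=bool)
        for p in (*left, *right):
            extra &= counts.total[counts.index(p)] > 0
    entries, n_used = [], []
    for li in left[1:]:
        for rj in right[1:]:
            e = _f4_entry_sums(counts, left[0], li, right[0], rj,
                               partition, extra)
            entries.append(e)
            n_used.append(e[2])
    whole, loo, weights = _assemble(entries, partition)
    Q = jackknife_covariance(loo, weights, whole)
    L1, R1 = len(left) - 1, len(right) - 1
    return F4Matrix(left, right, whole.reshape(L1, R1), Q, loo, weights,
                    np.array(n_used).reshape(L1, R1))


# ---------------------------------------------------------------------------
# Rank test
# ---------------------------------------------------------------------------

@dataclass
class RankTestResult:
    k: int
    chisq: float
    df: int
    p: float

    def __str__(self) -> str:
        return f"rank {self.k}: chisq = {self.chisq:.3f}, df = {self.df}, p = {self.p:.4g}"


def _robust_inverse(Q: np.ndarray) -> np.ndarray:
    """Inverse of a jackknife covariance, ridge-regularized when needed."""
    d = Q.shape[0]
    eps = 0.0
    for _ in range(12):
        try:
            c, low = linalg.cho_factor(Q + eps * np.eye(d), lower=True)
            return linalg.cho_solve((c, low), np.eye(d))
        except linalg.LinAlgError:
            eps = max(eps * 10.0, 1e-12 * np.trace(Q) / d)
            logger.info("rank_test: ridge-regularizing covariance, eps=%.3g", eps)
    return linalg.pinvh(Q)


def _gls_solve(K: np.ndarray, Qi: np.ndarray, x: np.ndarray) -> np.ndarray:
    M = K.T @ Qi @ K
    rhs = K.T @ Qi @ x
    return np.linalg.lstsq(M, rhs, rcond=None)[0]


def rank_test(m: F4Matrix, k: int, n_restarts: int = 10, tol: float = 1e-9,
              max_iter: int = 2000, seed: int = 42) -> RankTestResult:
    """Chi-squared fit of a rank-k hypothesis for the f4 matrix.

    The best rank-k approximation in the Q-metric is found by alternating
    generalized least squares on the factors (fix A solve B, fix B solve A),
    initialized from the SVD of X plus seeded random restarts.
    """
    L1, R1 = m.shape
    kmax = min(L1, R1)
    if not 0 <= k <= kmax:
        raise ValueError(f"rank {k} outside [0, {kmax}]")
    df = (L1 - k) * (R1 - k)
    if df == 0:
        return RankTestResult(k, 0.0, 0, 1.0)
    x = m.X.reshape(-1)
    Qi = _robust_inverse(m.Q)
    if k == 0:
        chisq = float(x @ Qi @ x)
        return RankTestResult(k, chisq, df, float(stats.chi2.sf(chisq, df)))

    U, s, Vt = np.linalg.svd(m.X, full_matrices=False)
    inits = [U[:, :k] * s[:k]]
    rng = np.random.default_rng(seed)
    scale = np.abs(m.X).mean() or 1.0
    inits += [rng.normal(scale=scale, size=(L1, k))
              for _ in range(n_restarts)]
    I_L, I_R = np.eye(L1), np.eye(R1)
    best = np.inf
    for A in inits:
        A = A.copy()
        obj_prev = np.inf
        for _ in range(max_iter):
            b = _gls_solve(np.kron(A, I_R), Qi, x)
            B = b.reshape(k, R1)
            a = _gls_solve(np.kron(I_L, B.T), Qi, x)
            A = a.reshape(L1, k)
            r = x - (A @ B).reshape(-1)
            obj = float(r @ Qi @ r)
            if obj_prev - obj <= tol * max(obj, 1.0):
                break
            obj_prev = obj
        else:
            raise RuntimeError("rank_test: alternating GLS did not converge")
        best = min(best, obj)
    chisq = max(best, 0.0)
    return RankTestResult(k, chisq, df, float(stats.chi2.sf(chisq, df)))


# ---------------------------------------------------------------------------
# qpAdm
# ---------------------------------------------------------------------------

@dataclass
class AdmixtureModel:
    target: str
    sources: tuple[str, ...]
    right: tuple[str, ...]
    weights: np.ndarray
    ses: np.ndarray
    p: float
    rank: RankTestResult
    feasible: bool
    plausible: bool
    n_blocks: int

    def __str__(self) -> str:
        ws = ", ".join(f"{s}={w:.3f}±{e:.3f}"
                       for s, w, e in zip(self.sources, self.weights, self.ses))
        tag = "plausible" if self.plausible else (
            "infeasible" if not self.feasible else "rejected")
        return (f"qpAdm {self.target} = [{ws}]  p = {self.p:.4g}  ({tag})")


def _source_system(counts: PopCounts, target: str, sources, right,
                   partition: BlockPartition):
    """Whole-data and delete-one G matrices, G[i, j] = f4(s_i, target; r0, r_j)."""
    entries = []
    for s in sources:
        for rj in right[1:]:
            entries.append(_f4_entry_sums(counts, s, target, right[0], rj,
                                          partition))
    whole, loo, weights = _assemble(entries, partition)
    K, R1 = len(sources), len(right) - 1
    return whole.reshape(K, R1), loo.reshape(len(weights), K, R1), weights


def _constrained_gls(G: np.ndarray, W: np.ndarray) -> np.ndarray:
    """argmin w' (G W G') w  subject to  sum(w) = 1."""
    H = G @ W @ G.T
    ones = np.ones(H.shape[0])
    u = np.linalg.lstsq(H, ones, rcond=None)[0]
    tot = u.sum()
    if abs(tot) < 1e-30:
        raise ValueError("qpadm: degenerate source system")
    return u / tot


def qpadm(counts: PopCounts, target: str, sources, right,
          partition: BlockPartition, allsnps: bool = True) -> AdmixtureModel:
    """Estimate mixture weights of ``target`` from ``sources`` vs ``right``.

    Weights solve the sum-to-one-constrained GLS system built from
    f4(source_i, target; right_0, right_j) rows, weighted by the inverse
    block-jackknife covariance of the model residual (iterated to a fixed
    point, which makes the solution invariant to source ordering and to the
    choice of a GLS base).  Standard errors come from delete-one-block
    re-estimation; the model p-value is the rank test at k = |sources| - 1 on
    left = {target} + sources.
    """
    sources, right = tuple(sources), tuple(right)
    if len(sources) < 1:
        raise ValueError("need at least one source")
    if target in sources or target in right:
        raise ValueError("target must not appear among sources or rights")
    if len(sources) >= len(right):
        raise ValueError("underdetermined: need more right populations "
                         "than sources")
    if not allsnps:
        logger.info("qpadm: allsnps=False restricts every f4 to the global "
                    "left+right intersection")
    fit = rank_test(build_f4_matrix(counts, (target, *sources), right,
                                    partition, allsnps=allsnps),
                    k=len(sources) - 1)
    K = len(sources)
    if K == 1:
        w = np.array([1.0])
        ses = np.array([0.0])
        g = 2
    else:
        G, loo_G, bw = _source_system(counts, target, sources, right, partition)
        g = len(bw)
        w = np.full(K, 1.0 / K)
        W = np.eye(len(right) - 1)
        for _ in range(60):
            w_new = _constrained_gls(G, W)
            e_loo = -np.einsum("i,gij->gj", w_new, loo_G)
            cov_e = jackknife_covariance(e_loo, bw, -G.T @ w_new)
            W = linalg.pinvh(cov_e)
            if np.abs(w_new - w).max() < 1e-12:
                w = w_new
                break
            w = w_new
        loo_w = np.stack([_constrained_gls(loo_G[b], W) for b in range(g)])
        ses = np.array([
            block_jackknife(loo_w[:, i], bw, w[i])[1] for i in range(K)
        ])
    feasible = bool(np.all((w >= 0.0) & (w <= 1.0)))
    plausible = feasible and fit.p > P_PLAUSIBLE
    return AdmixtureModel(target, sources, right, w, ses, fit.p, fit,
                          feasible, plausible, g)


# ---------------------------------------------------------------------------
# qpWave
# ---------------------------------------------------------------------------

def qpwave_min_streams(counts: PopCounts, left, right,
                       partition: BlockPartition, allsnps: bool = True,
                       p_threshold: float = P_PLAUSIBLE
                       ) -> tuple[int, list[RankTestResult], bool]:
    """Minimum number of ancestry streams relating left to right populations.

    Tests ranks k = 0, 1, ... in order; the minimum number of streams is the
    smallest accepted k plus 1.  If only the saturated full-rank model (df 0,
    p = 1) is accepted the result carries ``saturated=True``: the data demand
    at least that many streams but cannot bound the number above.
    """
    m = build_f4_matrix(counts, left, right, partition, allsnps=allsnps)
    kmax = min(m.shape)
    results = []
    for k in range(kmax + 1):
        res = rank_test(m, k)
        results.append(res)
        if res.df > 0 and res.p > p_threshold:
            return k + 1, results, False
    return kmax + 1, results, True


# ---------------------------------------------------------------------------
# Outgroup ranking and model search
# ---------------------------------------------------------------------------

def rank_outgroup_candidates(counts: PopCounts, pair, candidates,
                             deep_outgroup: str, partition: BlockPartition
                             ) -> list[tuple[str, float]]:
    """Sort candidate outgroups by |Z| of f4(P, Q; A, deep_outgroup).

    A large |Z| means the candidate A is asymmetrically related to the pair
    (P, Q) and will help discriminate admixture models involving them.
    """
    from .fstats import f4_stat
    P, Q = pair
    if not candidates:
        raise ValueError("empty candidate list")
    forbidden = {P, Q, deep_outgroup}
    bad = forbidden & set(candidates)
    if bad:
        raise ValueError(f"candidates overlap the tested pair/outgroup: {bad}")
    scored = []
    for cand in candidates:
        res = f4_stat(counts, (P, Q, cand, deep_outgroup), partition)
        scored.append((cand, abs(res.z)))
    scored.sort(key=lambda t: (-t[1], t[0]))
    return scored


@dataclass
class LedgerRow:
    stage: str
    target: str
    sources: tuple[str, ...]
    right: tuple[str, ...]
    p: float
    weights: np.ndarray
    ses: np.ndarray
    feasible: bool
    plausible: bool


@dataclass
class ModelSelectionLedger:
    rows: list[LedgerRow]
    survivors_history: list[list[tuple[str, ...]]]

    @property
    def final_survivors(self) -> list[tuple[str, ...]]:
        return self.survivors_history[-1] if self.survivors_history else []


def _fit_models(counts, target, models, right, partition, allsnps, stage,
                rows) -> list[tuple[str, ...]]:
    survivors = []
    for srcs in models:
        try:
            model = qpadm(counts, target, srcs, right, partition,
                          allsnps=allsnps)
        except ValueError as exc:
            logger.info("model_search: skipping %s (%s)", srcs, exc)
            continue
        rows.append(LedgerRow(stage, target, tuple(srcs), tuple(right),
                              model.p, model.weights, model.ses,
                              model.feasible, model.plausible))
        if model.plausible:
            survivors.append(tuple(srcs))
    return survivors


def model_search(counts: PopCounts, target: str, candidate_pool,
                 core_sources, right_base, augmenting_outgroups,
                 partition: BlockPartition, allsnps: bool = True
                 ) -> ModelSelectionLedger:
    """Staged enumeration of admixture models with outgroup augmentation.

    Stage 1 tests every 1-source model (clade tests); stage 2 every pair with
    at least one core source; stage 3 every triplet with at least two core
    sources.  The first stage producing plausible models ends the enumeration
    (parsimony).  Augmenting outgroups are then appended to the right set one
    at a time, survivors re-tested, until at most one model survives or the
    outgroups are exhausted.  An empty survivor set is a valid outcome.
    """
    candidate_pool = list(candidate_pool)
    core = set(core_sources)
    if not core <= set(candidate_pool):
        raise ValueError("core_sources must be a subset of candidate_pool")
    rows: list[LedgerRow] = []
    history: list[list[tuple[str, ...]]] = []

    stages = [
        ("1-source", [(c,) for c in candidate_pool]),
        ("2-source", [p for p in itertools.combinations(candidate_pool, 2)
                      if core & set(p)]),
        ("3-source", [t for t in itertools.combinations(candidate_pool, 3)
                      if len(core & set(t)) >= 2]),
    ]
    survivors: list[tuple[str, ...]] = []
    for stage_name, models in stages:
        survivors = _fit_models(counts, target, models, tuple(right_base),
                                partition, allsnps, stage_name, rows)
        history.append(list(survivors))
        if survivors:
            break

    right = list(right_base)
    for og in augmenting_outgroups:
        if len(survivors) <= 1:
            break
        if og in right or og == target:
            continue
        right.append(og)
        survivors = _fit_models(
            counts, target, survivors, tuple(right), partition, allsnps,
            f"augment+{og}", rows)
        history.append(list(survivors))
    return ModelSelectionLedger(rows, history)
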