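"""Reproducibility-optimized test statistic for two-group designs.

The per-gene statistic family is ``d(g) = |mean1 - mean2| / (a1 + a2 * s_g)``
with ``a1 >= 0``, ``a2 in {0, 1}`` and ``s_g`` the pooled two-group standard
error.  The free parameters ``(a1, a2)`` and a top-list size ``k`` are chosen
to maximize a z-type reproducibility score: the mean overlap of top-k gene
lists across pairs of within-group bootstrap datasets, standardized against
the overlap obtained under random permutation of the group labels.

Significance is assessed by a permutation FDR at the selected statistic.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from .io_counts import CountMatrix, GroupDesign
from .normalize import (
    ExpressionMatrix,
    drop_zero_genes,
    logcpm_transform,
    tmm_factors,
    unit_factors,
)

logger = logging.getLogger(__name__)

__all__ = [
    "AlphaPair",
    "GroupSummaries",
    "ResamplePlan",
    "OverlapCurves",
    "RotsFit",
    "default_alpha_grid",
    "default_k_grid",
    "group_summaries",
    "d_stat",
    "rank_genes",
    "topk_overlap",
    "make_bootstrap_pairs",
    "make_null_pairs",
    "reproducibility_curves",
    "optimize",
    "estimate_fdr",
    "run_rots",
]

#: Reproducibility z-scores below this value signal that the data or the
#: statistic are insufficient for reliable detection (rule of thumb).
Z_RELIABILITY_THRESHOLD = 2.0


@dataclass(frozen=True)
class AlphaPair:
    """Regularization parameters of the statistic family.

    ``a1`` is a non-negative additive stabilizer; ``a2`` switches the pooled
    standard error in or out of the denominator.  ``(0, 1)`` is the ordinary
    pooled t-statistic, ``(1, 0)`` the absolute signal log-ratio.
    """

    a1: float
    a2: int

    def __post_init__(self) -> None:
        if self.a1 < 0:
            raise ValueError("a1 must be >= 0")
        if self.a2 not in (0, 1):
            raise ValueError("a2 must be 0 or 1")
        if self.a1 == 0 and self.a2 == 0:
            raise ValueError("a1 and a2 cannot both be 0")


@dataclass
class GroupSummaries:
    """Per-gene group means, unbiased variances, and the pooled SE."""

    mean1: np.ndarray
    mean2: np.ndarray
    var1: np.ndarray
    var2: np.ndarray
    pooled_se: np.ndarray
    n1: int
    n2: int


@dataclass
class ResamplePlan:
    """Pre-drawn column resamples shared across the parameter lattice.

    ``indices`` has shape (B, 2, n1+n2): B pairs of datasets, each a vector
    of source-column indices whose position ``p`` carries the group label
    ``labels[p]``.  Bootstrap plans draw each position's index from its own
    group's columns with replacement; null plans use a fresh uniform
    permutation of all columns per dataset.
    """

    kind: str  # "bootstrap" | "null"
    B: int
    indices: np.ndarray
    labels: np.ndarray
    seed: int

    def __post_init__(self) -> None:
        if self.kind not in ("bootstrap", "null"):
            raise ValueError(f"unknown plan kind {self.kind!r}")
        if self.indices.shape != (self.B, 2, self.labels.size):
            raise ValueError("indices shape must be (B, 2, n1+n2)")


@dataclass
class OverlapCurves:
    """Mean/SD bootstrap overlaps and null overlaps over the (alpha, k) lattice.

    Arrays are indexed ``[alpha, k]``.  ``Z`` is NaN where the bootstrap SD
    is zero (score undefined there).
    """

    alpha_grid: list[AlphaPair]
    k_grid: np.ndarray
    R: np.ndarray
    s: np.ndarray
    R0: np.ndarray
    Z: np.ndarray


@dataclass
class RotsFit:
    """Complete result of a run: per-gene outputs plus the selected optimum."""

    gene_ids: list[str]
    statistic: np.ndarray
    logfc: np.ndarray
    fdr: np.ndarray
    alpha: AlphaPair
    k_opt: int
    R_opt: float
    Z_opt: float
    B: int
    P: int
    seed: int
    dropped_gene_ids: list[str] = field(default_factory=list)


# ---------------------------------------------------------------------------
# parameter lattice defaults

_K_BASE = (
    5, 10, 25, 50, 100, 200, 350, 500, 750, 1000, 1500, 2000, 3000, 5000,
    7500, 10000, 15000, 20000, 30000, 50000, 75000, 100000,
)


def default_alpha_grid() -> list[AlphaPair]:
    """Dense lattice of (a1, a2) pairs.

    a2=1 with a1 on {0, 0.01, ..., 1} ∪ {1.1, ..., 5} (dense near zero where
    the statistic is most sensitive to regularization), plus the single
    signal-log-ratio point (1, 0).
    """
    fine = np.round(np.arange(0, 101) * 0.01, 10)
    coarse = np.round(np.arange(11, 51) * 0.1, 10)
    grid = [AlphaPair(float(a), 1) for a in np.concatenate([fine, coarse])]
    grid.append(AlphaPair(1.0, 0))
    return grid


def default_k_grid(n_genes: int) -> np.ndarray:
    """Increasing top-list sizes in [5, G], always including G."""
    ks = sorted({k for k in _K_BASE if 5 <= k <= n_genes} | {n_genes})
    return np.array(ks, dtype=np.int64)


# ---------------------------------------------------------------------------
# statistic family

def _group_columns(
    X: ExpressionMatrix, design: GroupDesign
) -> tuple[np.ndarray, np.ndarray]:
    """Column index arrays of group 1 and group 2 in X's column order."""
    design = design.reordered(X.sample_ids)
    return np.flatnonzero(design.groups == 1), np.flatnonzero(design.groups == 2)


def _pooled_stats(
    V1: np.ndarray, V2: np.ndarray
) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    n1 = V1.shape[1]
    n2 = V2.shape[1]
    m1 = V1.mean(axis=1)
    m2 = V2.mean(axis=1)
    v1 = V1.var(axis=1, ddof=1)
    v2 = V2.var(axis=1, ddof=1)
    pooled = np.sqrt(
        (1.0 / n1 + 1.0 / n2)
        * ((n1 - 1) * v1 + (n2 - 1) * v2)
        / (n1 + n2 - 2)
    )
    return m1, m2, v1, v2, pooled


def group_summaries(X: ExpressionMatrix, design: GroupDesign) -> GroupSummaries:
    """Sample means, unbiased variances, and pooled SE per gene and group."""
    idx1, idx2 = _group_columns(X, design)
    m1, m2, v1, v2, pooled = _pooled_stats(X.values[:, idx1], X.values[:, idx2])
    return GroupSummaries(m1, m2, v1, v2, pooled, idx1.size, idx2.size)


def _d_matrix(
    V1: np.ndarray, V2: np.ndarray, a1: np.ndarray, a2: np.ndarray
) -> np.ndarray:
    """Statistic for every gene (rows) and every alpha pair (columns).

    Zero-denominator convention: 0 where the numerator is also 0, +inf
    otherwise (+inf ranks above all finite values).
    """
    m1, m2, _, _, pooled = _pooled_stats(V1, V2)
    num = np.abs(m1 - m2)
    denom = a1[None, :] + a2[None, :] * pooled[:, None]
    with np.errstate(divide="ignore", invalid="ignore"):
        d = num[:, None] / denom
    return np.where(np.isnan(d), 0.0, d)


def d_stat(
    X: ExpressionMatrix, design: GroupDesign, alpha: AlphaPair
) -> np.ndarray:
    """Per-gene statistic ``|mean1 - mean2| / (a1 + a2 * s_g)``."""
    idx1, idx2 = _group_columns(X, design)
    a1 = np.array([alpha.a1])
    a2 = np.array([float(alpha.a2)])
    return _d_matrix(X.values[:, idx1], X.values[:, idx2], a1, a2)[:, 0]


def rank_genes(d: np.ndarray) -> np.ndarray:
    """Gene indices sorted by statistic, descending; ties by ascending index."""
    return np.argsort(-np.asarray(d, dtype=np.float64), kind="stable")


def topk_overlap(order_a: np.ndarray, order_b: np.ndarray, k: int) -> float:
    """Fraction of genes shared by the two top-k lists."""
    n = len(order_a)
    if not 1 <= k <= n:
        raise ValueError(f"k={k} out of range [1, {n}]")
    return np.intersect1d(order_a[:k], order_b[:k]).size / k


# ---------------------------------------------------------------------------
# resampling plans

def make_bootstrap_pairs(design: GroupDesign, B: int, seed: int) -> ResamplePlan:
    """B pairs of within-group bootstrap datasets, reproducible from seed.

    Each dataset keeps the original group sizes and labels; the index at a
    group-j position is drawn with replacement from group j's columns only.
    The RNG stream is consumed in a fixed order (per pair: dataset 1 group 1,
    dataset 1 group 2, dataset 2 group 1, dataset 2 group 2).
    """
    if B < 2:
        raise ValueError("B must be >= 2")
    rng = np.random.default_rng(seed)
    g = design.groups
    n = g.size
    cols1 = np.flatnonzero(g == 1)
    cols2 = np.flatnonzero(g == 2)
    indices = np.empty((B, 2, n), dtype=np.intp)
    for b in range(B):
        for m in range(2):
            vec = np.empty(n, dtype=np.intp)
            vec[g == 1] = rng.choice(cols1, size=cols1.size, replace=True)
            vec[g == 2] = rng.choice(cols2, size=cols2.size, replace=True)
            indices[b, m] = vec
    return ResamplePlan("bootstrap", B, indices, g.copy(), seed)


def make_null_pairs(design: GroupDesign, B: int, seed: int) -> ResamplePlan:
    """B pairs of label-permuted datasets, reproducible from seed.

    Each dataset is an independent uniform permutation of all columns into
    two pseudo-groups of the original sizes.
    """
    if B < 2:
        raise ValueError("B must be >= 2")
    rng = np.random.default_rng(seed)
    g = design.groups
    n = g.size
    indices = np.empty((B, 2, n), dtype=np.intp)
    for b in range(B):
        for m in range(2):
            indices[b, m] = rng.permutation(n)
    return ResamplePlan("null", B, indices, g.copy(), seed)


# ---------------------------------------------------------------------------
# reproducibility curves and optimization

def _ranking_positions(
    V: np.ndarray, vec: np.ndarray, labels: np.ndarray, a1: np.ndarray, a2: np.ndarray
) -> np.ndarray:
    """Rank position of each gene (rows) per alpha (columns) in one dataset."""
    V1 = V[:, vec[labels == 1]]
    V2 = V[:, vec[labels == 2]]
    d = _d_matrix(V1, V2, a1, a2)
    order = np.argsort(-d, axis=0, kind="stable")
    pos = np.empty_like(order)
    np.put_along_axis(pos, order, np.arange(order.shape[0])[:, None], axis=0)
    return pos


def _plan_overlaps(
    V: np.ndarray,
    plan: ResamplePlan,
    a1: np.ndarray,
    a2: np.ndarray,
    k_grid: np.ndarray,
) -> np.ndarray:
    """Top-k overlaps for every (pair, alpha, k) of a resampling plan.

    A gene is in both top-k lists of a pair iff its worse rank position is
    below k, so per-pair overlaps for the whole k grid reduce to threshold
    counts on the elementwise max of the two position arrays.
    """
    out = np.empty((plan.B, a1.size, k_grid.size))
    for b in range(plan.B):
        pos_a = _ranking_positions(V, plan.indices[b, 0], plan.labels, a1, a2)
        pos_b = _ranking_positions(V, plan.indices[b, 1], plan.labels, a1, a2)
        worst = np.maximum(pos_a, pos_b)
        for j, k in enumerate(k_grid):
            out[b, :, j] = (worst < k).sum(axis=0) / k
    return out


def reproducibility_curves(
    X: ExpressionMatrix,
    design: GroupDesign,
    boot: ResamplePlan,
    null: ResamplePlan,
    alpha_grid: list[AlphaPair],
    k_grid: np.ndarray,
) -> OverlapCurves:
    """Mean/SD bootstrap overlap, null overlap, and z-score per lattice point.

    For each pair and alpha the statistic is computed on both resampled
    datasets and the top-k overlap recorded for every k; R is the mean and s
    the (n-1) SD over bootstrap pairs, R0 the mean over null pairs, and
    ``Z = (R - R0) / s`` (NaN where s = 0).
    """
    if len(alpha_grid) == 0 or len(k_grid) == 0:
        raise ValueError("alpha and k grids must be non-empty")
    k_grid = np.asarray(k_grid, dtype=np.int64)
    G = X.values.shape[0]
    if (k_grid < 1).any() or (k_grid > G).any():
        raise ValueError(f"k grid must lie in [1, {G}]")
    design = design.reordered(X.sample_ids)
    V = X.values
    a1 = np.array([a.a1 for a in alpha_grid])
    a2 = np.array([float(a.a2) for a in alpha_grid])
    boot_ov = _plan_overlaps(V, boot, a1, a2, k_grid)
    null_ov = _plan_overlaps(V, null, a1, a2, k_grid)
    R = boot_ov.mean(axis=0)
    s = boot_ov.std(axis=0, ddof=1)
    R0 = null_ov.mean(axis=0)
    with np.errstate(divide="ignore", invalid="ignore"):
        Z = np.where(s > 0, (R - R0) / s, np.nan)
    return OverlapCurves(list(alpha_grid), k_grid, R, s, R0, Z)


def optimize(curves: OverlapCurves) -> tuple[AlphaPair, int, float, float]:
    """Lattice point with maximal Z.

    Ties are broken by larger k, then smaller a1, then larger a2.
    """
    finite = np.isfinite(curves.Z)
    if not finite.any():
        raise ValueError("data insufficient for optimization: no defined Z")
    z_max = curves.Z[finite].max()
    cand = np.argwhere(finite & (curves.Z == z_max))
    i, j = max(
        (tuple(c) for c in cand),
        key=lambda ij: (
            curves.k_grid[ij[1]],
            -curves.alpha_grid[ij[0]].a1,
            curves.alpha_grid[ij[0]].a2,
        ),
    )
    return (
        curves.alpha_grid[i],
        int(curves.k_grid[j]),
        float(curves.R[i, j]),
        float(z_max),
    )


# ---------------------------------------------------------------------------
# permutation FDR

def _fdr_from_perm_stats(d_obs: np.ndarray, d_perm: np.ndarray) -> np.ndarray:
    """FDR from observed statistics and a (P, G) matrix of permuted ones.

    raw(g) = [(1/P) * #{permuted >= d(g)}] / #{observed >= d(g)}, clipped to
    [0, 1]; the monotone step-up adjustment takes, for each gene, the minimum
    raw value over all genes with statistic <= d(g), so FDR is non-decreasing
    as the statistic decreases.
    """
    d_obs = np.asarray(d_obs, dtype=np.float64)
    P, G = d_perm.shape
    pooled = np.sort(d_perm.ravel())
    obs_sorted = np.sort(d_obs)
    num = (pooled.size - np.searchsorted(pooled, d_obs, side="left")) / P
    den = G - np.searchsorted(obs_sorted, d_obs, side="left")
    raw = np.clip(num / den, 0.0, 1.0)
    order = np.argsort(d_obs, kind="stable")  # ascending
    cm = np.minimum.accumulate(raw[order])
    dv = d_obs[order]
    block_end = np.r_[np.flatnonzero(np.diff(dv) != 0), G - 1]
    block_of = np.searchsorted(block_end, np.arange(G), side="left")
    fdr = np.empty(G)
    fdr[order] = cm[block_end[block_of]]
    return fdr


def estimate_fdr(
    X: ExpressionMatrix,
    design: GroupDesign,
    alpha: AlphaPair,
    P: int,
    seed: int,
) -> np.ndarray:
    """Permutation FDR for the statistic at a fixed alpha.

    Draws P whole-dataset label permutations (group sizes preserved),
    recomputes the statistic on each, and applies the estimator of
    :func:`_fdr_from_perm_stats`.
    """
    if P < 1:
        raise ValueError("P must be >= 1")
    design = design.reordered(X.sample_ids)
    d_obs = d_stat(X, design, alpha)
    rng = np.random.default_rng(seed)
    g = design.groups
    n = g.size
    V = X.values
    a1 = np.array([alpha.a1])
    a2 = np.array([float(alpha.a2)])
    d_perm = np.empty((P, d_obs.size))
    for p in range(P):
        perm = rng.permutation(n)
        d_perm[p] = _d_matrix(
            V[:, perm[g == 1]], V[:, perm[g == 2]], a1, a2
        )[:, 0]
    return _fdr_from_perm_stats(d_obs, d_perm)


# ---------------------------------------------------------------------------
# end-to-end driver

def run_rots(
    counts: CountMatrix,
    design: GroupDesign,
    *,
    B: int = 1000,
    seed: int = 0,
    alpha_grid: list[AlphaPair] | None = None,
    k_grid: np.ndarray | None = None,
    normalize: bool = True,
    P: int | None = None,
    prior: float = 0.5,
) -> RotsFit:
    """Full pipeline: filter, normalize, optimize the statistic, score genes.

    All-zero genes are dropped; counts are scaled (unless ``normalize`` is
    False) and log-CPM transformed; bootstrap and null resampling plans of
    size B are drawn; the (alpha, k) lattice is scanned for the maximal
    reproducibility z-score; the statistic at the optimum is computed on the
    original data and a permutation FDR with P permutations (default B) is
    attached.  Fully deterministic given the seed: the bootstrap, null, and
    permutation streams use the three spawned children of the seed, in that
    order.
    """
    design = design.reordered(counts.sample_ids)
    kept, dropped = drop_zero_genes(counts)
    G = kept.n_genes
    if G < 2:
        raise ValueError(f"only {G} non-zero gene(s); nothing to rank")
    factors = tmm_factors(kept) if normalize else unit_factors(kept)
    X = logcpm_transform(kept, factors, prior=prior)
    if alpha_grid is None:
        alpha_grid = default_alpha_grid()
    if k_grid is None:
        k_grid = default_k_grid(G)
    seed_boot, seed_null, seed_fdr = (
        int(s.generate_state(1)[0]) for s in np.random.SeedSequence(seed).spawn(3)
    )
    logger.info("G=%d genes (%d dropped), B=%d, |alpha|=%d, |k|=%d",
                G, len(dropped), B, len(alpha_grid), len(k_grid))
    boot = make_bootstrap_pairs(design, B, seed_boot)
    null = make_null_pairs(design, B, seed_null)
    curves = reproducibility_curves(X, design, boot, null, alpha_grid, k_grid)
    alpha, k_opt, R_opt, Z_opt = optimize(curves)
    logger.info("optimum: alpha=(%g, %d), k=%d, R=%.4f, Z=%.3f",
                alpha.a1, alpha.a2, k_opt, R_opt, Z_opt)
    if Z_opt < Z_RELIABILITY_THRESHOLD:
        logger.warning(
            "reproducibility z-score %.3f is below %.1f: the data or the "
            "statistic may be insufficient for reliable detection",
            Z_opt, Z_RELIABILITY_THRESHOLD,
        )
    d = d_stat(X, design, alpha)
    summ = group_summaries(X, design)
    logfc = summ.mean2 - summ.mean1
    n_perm = B if P is None else P
    fdr = estimate_fdr(X, design, alpha, n_perm, seed_fdr)
    return RotsFit(
        gene_ids=list(kept.gene_ids),
        statistic=d,
        logfc=logfc,
        fdr=fdr,
        alpha=alpha,
        k_opt=k_opt,
        R_opt=R_opt,
        Z_opt=Z_opt,
        B=B,
        P=n_perm,
        seed=seed,
        dropped_gene_ids=dropped,
    )
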