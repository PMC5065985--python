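"""Network topology dynamics: metric matrices, similarity, modular states.

A sequence of windowed HFNs yields, for each nodal graph metric, a nodes x
windows matrix (580 x 81 at the default geometry).  Pearson correlation
between its columns gives the *temporal* similarity matrix (windows x
windows); between its rows the *nodal* similarity matrix (nodes x nodes).
Modularity optimization on the temporal matrix groups windows into dynamic
*states*; signed community detection on the nodal matrix groups nodes into
*communities* with similar metric time courses.

Modularity of a partition is always evaluated exactly as

    Q = (1/l) * sum_ij [w_ij - k_i k_j / l] * delta(m_i, m_j)

with l the total weight and k the weighted degrees (self-similarity diagonal
excluded).  Q is 0 for the single-module partition by construction.  The
temporal matrix is clipped to its positive part before optimization (clipped
mass is logged); the nodal matrix keeps its signs and is partitioned with a
signed quality function in which positive weights reward and negative
weights penalize co-assignment.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

from .graph_metrics import METRIC_NAMES, nodal_metrics

__all__ = [
    "MetricDynamicsMatrix",
    "SimilarityMatrix",
    "PartitionResult",
    "metric_dynamics",
    "summarize_dynamics",
    "similarity",
    "modularity_q",
    "modularity_partition",
    "louvain_signed_partition",
    "state_statistics",
    "modularity_null",
]

logger = logging.getLogger(__name__)


@dataclass
class MetricDynamicsMatrix:
    """values[node, window] of one nodal graph metric across sliding windows."""

    values: np.ndarray
    metric: str
    node_index: Optional[Sequence] = None

    @property
    def n_nodes(self) -> int:
        return self.values.shape[0]

    @property
    def n_windows(self) -> int:
        return self.values.shape[1]


def metric_dynamics(graphs: Sequence, metric: str, distance: str = "inv") -> MetricDynamicsMatrix:
    """Stack one nodal metric over a window-ordered sequence of HFNs."""
    if metric not in METRIC_NAMES:
        raise ValueError(f"unknown metric {metric!r}; choose from {METRIC_NAMES}")
    n_nodes = {getattr(g, "adjacency", g).shape[0] for g in graphs}
    if len(n_nodes) != 1:
        raise ValueError("all graphs must share one node set")
    cols = [nodal_metrics(g, distance=distance).by_name(metric) for g in graphs]
    values = np.column_stack(cols)
    nodes = getattr(graphs[0], "nodes", None)
    return MetricDynamicsMatrix(values=values, metric=metric, node_index=nodes)


def summarize_dynamics(m: MetricDynamicsMatrix) -> dict[str, float]:
    """Grand mean and the two averaging orders of the SD.

    ``sd_across_nodes`` is the population SD over nodes within each window,
    averaged over windows; ``sd_across_time`` the SD over windows within each
    node, averaged over nodes.  The grand mean is identical for both orders.
    """
    v = m.values
    return {
        "grand_mean": float(np.nanmean(v)),
        "sd_across_nodes": float(np.nanmean(np.nanstd(v, axis=0))),
        "sd_across_time": float(np.nanmean(np.nanstd(v, axis=1))),
    }


@dataclass
class SimilarityMatrix:
    """Square symmetric Pearson-correlation matrix with unit diagonal.

    ``axis`` is "temporal" (windows x windows) or "nodal" (nodes x nodes).
    ``excluded`` flags zero-variance elements whose correlations are
    undefined; their rows/columns are NaN and they are left out of
    modularity optimization.
    """

    values: np.ndarray
    axis: str
    excluded: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        if self.excluded is None:
            self.excluded = np.zeros(self.values.shape[0], dtype=bool)


def similarity(m: MetricDynamicsMatrix, axis: str) -> SimilarityMatrix:
    """Pearson correlation across windows ("temporal") or nodes ("nodal")."""
    if axis == "temporal":
        x = m.values.T  # rows = windows
    elif axis == "nodal":
        x = m.values  # rows = nodes
    else:
        raise ValueError("axis must be 'temporal' or 'nodal'")
    if x.shape[0] < 2:
        raise ValueError("need at least two elements on the chosen axis")
    sd = x.std(axis=1)
    excluded = sd == 0
    if excluded.any():
        warnings.warn(
            f"{int(excluded.sum())} zero-variance element(s) excluded from "
            f"{axis} similarity"
        )
    with np.errstate(invalid="ignore", divide="ignore"):
        c = np.corrcoef(x)
    c[excluded, :] = np.nan
    c[:, excluded] = np.nan
    keep = ~excluded
    np.fill_diagonal(c, np.where(keep, 1.0, np.nan))
    c_keep = c[np.ix_(keep, keep)]
    c[np.ix_(keep, keep)] = (c_keep + c_keep.T) / 2.0  # enforce exact symmetry
    return SimilarityMatrix(values=c, axis=axis, excluded=excluded)


@dataclass
class PartitionResult:
    """A hard partition with its exactly evaluated modularity.

    ``assignment`` holds a module id (0..n_modules-1) per element, -1 for
    elements excluded from the optimization (zero-variance rows).
    """

    assignment: np.ndarray
    q: float
    n_modules: int
    element_counts: np.ndarray
    axis: Optional[str] = None
    q_signed: Optional[float] = None

    @property
    def durations(self) -> np.ndarray:
        """Per-module element counts (windows per state on the temporal axis)."""
        return self.element_counts


def modularity_q(w: np.ndarray, assignment: np.ndarray) -> float:
    """Newman weighted modularity of a given assignment (diagonal ignored).

    Q = (1/l) sum_ij (w_ij - k_i k_j / l) delta(m_i, m_j), with l the total
    weight of the (symmetric, possibly signed) matrix and k_i its weighted
    degrees.  Elements assigned -1 are excluded.
    """
    w = np.asarray(w, dtype=float).copy()
    assignment = np.asarray(assignment)
    keep = assignment >= 0
    w = w[np.ix_(keep, keep)]
    a = assignment[keep]
    np.fill_diagonal(w, 0.0)
    w = np.nan_to_num(w)
    l = w.sum()
    if l == 0:
        return 0.0
    k = w.sum(axis=1)
    same = a[:, None] == a[None, :]
    return float(np.sum((w - np.outer(k, k) / l)[same]) / l)


def _signed_q(w: np.ndarray, assignment: np.ndarray) -> float:
    """Asymmetric signed modularity: Q+ minus the negatively-weighted Q-."""
    w = np.asarray(w, dtype=float).copy()
    np.fill_diagonal(w, 0.0)
    w = np.nan_to_num(w)
    pos = np.clip(w, 0.0, None)
    neg = np.clip(-w, 0.0, None)
    lp, ln = pos.sum(), neg.sum()
    same = assignment[:, None] == assignment[None, :]
    q = 0.0
    if lp > 0:
        kp = pos.sum(axis=1)
        q += np.sum((pos - np.outer(kp, kp) / lp)[same]) / lp
    if ln > 0:
        kn = neg.sum(axis=1)
        q -= np.sum((neg - np.outer(kn, kn) / ln)[same]) / (lp + ln)
    return float(q)


def _relabel(assignment: np.ndarray) -> np.ndarray:
    """Renumber modules 0..K-1 in order of first appearance (-1 preserved)."""
    out = np.full(assignment.shape, -1, dtype=int)
    nxt = 0
    seen: dict[int, int] = {}
    for i, m in enumerate(assignment):
        if m < 0:
            continue
        if m not in seen:
            seen[m] = nxt
            nxt += 1
        out[i] = seen[m]
    return out


def _partition_result(
    w: np.ndarray, assignment: np.ndarray, axis: Optional[str], signed: bool
) -> PartitionResult:
    assignment = _relabel(assignment)
    counts = np.bincount(assignment[assignment >= 0]) if (assignment >= 0).any() else np.array([], int)
    q = modularity_q(w, assignment)
    return PartitionResult(
        assignment=assignment,
        q=q,
        n_modules=int(counts.size),
        element_counts=counts,
        axis=axis,
        q_signed=_signed_q(w, assignment) if signed else None,
    )


def _igraph_from(w: np.ndarray):
    import igraph as ig

    src, dst = np.nonzero(np.triu(w, k=1))
    g = ig.Graph(n=w.shape[0], edges=list(zip(src.tolist(), dst.tolist())))
    g.es["weight"] = w[src, dst].tolist()
    return g


def modularity_partition(
    s: SimilarityMatrix, seed: int = 0, n_restarts: int = 10
) -> PartitionResult:
    """Newman-style modularity partition of a (temporal) similarity matrix.

    Negative correlations are clipped to zero before optimization (their
    total magnitude is logged); the returned Q is evaluated exactly on the
    clipped matrix for the best of ``n_restarts`` optimizer runs.
    """
    import leidenalg as la

    w = np.nan_to_num(np.asarray(s.values, dtype=float).copy())
    np.fill_diagonal(w, 0.0)
    neg_mass = float(np.clip(-w, 0.0, None).sum())
    if neg_mass > 0:
        logger.info("clipped negative similarity mass %.3f before modularity", neg_mass)
    w = np.clip(w, 0.0, None)
    keep = ~s.excluded
    sub = w[np.ix_(keep, keep)]
    g = _igraph_from(sub)
    best = None
    for r in range(n_restarts):
        part = la.find_partition(
            g,
            la.ModularityVertexPartition,
            weights="weight",
            seed=seed + r,
        )
        memb = np.asarray(part.membership)
        full = np.full(w.shape[0], -1, dtype=int)
        full[keep] = memb
        q = modularity_q(w, full)
        if best is None or q > best[0]:
            best = (q, full)
    return _partition_result(w, best[1], s.axis, signed=False)


def louvain_signed_partition(
    s: SimilarityMatrix, seed: int = 0, n_restarts: int = 10
) -> PartitionResult:
    """Signed community detection on a (nodal) correlation matrix.

    Positive and negative correlations form two weight layers optimized
    jointly with layer weights +1 and -1 (Louvain-family local moving with
    Leiden refinement), so positive similarity rewards and negative
    similarity penalizes co-assignment.  Q (Eq.-style, on the signed matrix)
    and the asymmetric signed quality are both reported.
    """
    import leidenalg as la

    w = np.nan_to_num(np.asarray(s.values, dtype=float).copy())
    np.fill_diagonal(w, 0.0)
    if np.nanmax(np.abs(w), initial=0.0) > 1.0 + 1e-9:
        raise ValueError("similarity entries must lie in [-1, 1]")
    keep = ~s.excluded
    sub = w[np.ix_(keep, keep)]
    g_pos = _igraph_from(np.clip(sub, 0.0, None))
    g_neg = _igraph_from(np.clip(-sub, 0.0, None))
    best = None
    for r in range(n_restarts):
        p_pos = la.ModularityVertexPartition(g_pos, weights="weight")
        p_neg = la.ModularityVertexPartition(g_neg, weights="weight")
        opt = la.Optimiser()
        opt.set_rng_seed(seed + r)
        opt.optimise_partition_multiplex([p_pos, p_neg], layer_weights=[1, -1])
        memb = np.asarray(p_pos.membership)
        full = np.full(w.shape[0], -1, dtype=int)
        full[keep] = memb
        q = _signed_q(sub, memb)
        if best is None or q > best[0]:
            best = (q, full)
    return _partition_result(w, best[1], s.axis, signed=True)


@dataclass
class StateStatistics:
    """Counts and extremes of a partition's modules.

    On the temporal axis modules are dynamic states and sizes are window
    counts ("durations"); contiguous-run statistics are reported alongside,
    since states need not occupy contiguous windows.  On the nodal axis
    modules are node communities.
    """

    n_modules: int
    min_size: int
    max_size: int
    n_runs: Optional[int] = None
    min_run: Optional[int] = None
    max_run: Optional[int] = None


def state_statistics(p: PartitionResult, axis: Optional[str] = None) -> StateStatistics:
    """Number of modules and min/max module size (plus runs when temporal)."""
    axis = axis or p.axis
    if p.n_modules == 0:
        raise ValueError("partition has no assigned elements")
    sizes = p.element_counts
    stats = StateStatistics(
        n_modules=p.n_modules,
        min_size=int(sizes.min()),
        max_size=int(sizes.max()),
    )
    if axis == "temporal":
        a = p.assignment[p.assignment >= 0]
        boundaries = np.flatnonzero(np.diff(a) != 0)
        run_lengths = np.diff(np.concatenate(([0], boundaries + 1, [a.size])))
        stats.n_runs = int(run_lengths.size)
        stats.min_run = int(run_lengths.min())
        stats.max_run = int(run_lengths.max())
    return stats


def _shuffled_similarity(
    values: np.ndarray, rng: np.random.Generator
) -> np.ndarray:
    """Symmetric null matrix: off-diagonal entries permuted, diagonal kept."""
    n = values.shape[0]
    iu = np.triu_indices(n, k=1)
    shuffled = rng.permutation(values[iu])
    out = np.zeros_like(values)
    out[iu] = shuffled
    out = out + out.T
    np.fill_diagonal(out, np.diagonal(values))
    return out


def modularity_null(
    s: SimilarityMatrix,
    n: int = 100,
    seed: Optional[int] = None,
    signed: Optional[bool] = None,
    n_restarts: int = 3,
) -> dict:
    """Null modularity distribution from edge-shuffled similarity matrices.

    Each of the ``n`` null matrices permutes the observed off-diagonal
    similarities (preserving symmetry, size and value multiset), is
    partitioned with the same algorithm as the observation, and contributes
    its Q.  Returns the observed Q, the null sample and the empirical
    p-value P(Q_null >= Q_obs).
    """
    if n < 1:
        raise ValueError("n must be at least 1")
    rng = np.random.default_rng(seed)
    if signed is None:
        signed = s.axis == "nodal"
    partition = louvain_signed_partition if signed else modularity_partition
    observed = partition(s, seed=int(rng.integers(2**31)), n_restarts=n_restarts)
    q_obs = observed.q_signed if signed else observed.q
    null = np.empty(n)
    base = np.nan_to_num(s.values)
    for i in range(n):
        null_s = SimilarityMatrix(
            values=_shuffled_similarity(base, rng), axis=s.axis,
            excluded=np.zeros(base.shape[0], dtype=bool),
        )
        p = partition(null_s, seed=int(rng.integers(2**31)), n_restarts=n_restarts)
        null[i] = p.q_signed if signed else p.q
    p_value = float((np.count_nonzero(null >= q_obs) + 1) / (n + 1))
    return {
        "q_observed": float(q_obs),
        "null": null,
        "p_value": p_value,
        "partition": observed,
    }
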