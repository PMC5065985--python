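"""Weighted-directed nodal graph metrics and small-world assessment.

All metrics operate on a nonnegative weighted directed adjacency matrix with
zero diagonal (weights in [0, 1], as produced by ICI-based networks):

* in/out strengths -- weighted degrees, column/row sums;
* clustering coefficient -- Fagiolo's weighted-directed form, cube-root
  weight products over both triangle orientations, normalized by
  (k_in + k_out)(k_in + k_out - 1) - 2 * #bilateral;
* characteristic path length and global efficiency -- directed shortest
  paths on edge lengths 1/w (or 1 - w); CPL_i averages distances over
  *reachable* targets (unreachable pairs are counted and reported), while
  global efficiency averages inverse distances with unreachable pairs
  contributing zero;
* local efficiency -- weighted-directed form over each node's in-or-out
  neighborhood, cube-root weight products with inverse neighbor-subgraph
  distances computed on cube-root lengths, normalized by k(k-1);
* lattice and random reference graphs -- the random reference repositions
  the existing weighted edges onto uniformly random off-diagonal slots; the
  lattice reference additionally sorts each column's weights toward the
  diagonal, concentrating strong edges near it.  Both preserve node count,
  edge count and the weight multiset exactly.
* small-world coefficients -- sigma = (CC/CC_rand)/(CPL/CPL_rand) (> 1 for
  small-world graphs), omega = CPL_rand/CPL - CC/CC_latt (near 0 for
  small-world, positive toward random, negative toward lattice), and their
  efficiency-based analogues sigma_E, omega_E.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Optional, Sequence, Union

import numpy as np
from scipy.sparse import csr_matrix
from scipy.sparse.csgraph import dijkstra

__all__ = [
    "NodalMetrics",
    "SmallWorldMetrics",
    "strengths",
    "degrees",
    "clustering_wd",
    "shortest_path_metrics",
    "local_efficiency",
    "nodal_metrics",
    "lattice_reference",
    "random_reference",
    "graph_means",
    "small_world_coefficients",
]

AdjLike = Union[np.ndarray, "object"]


def _adj(g: AdjLike) -> np.ndarray:
    a = getattr(g, "adjacency", g)
    a = np.asarray(a, dtype=float)
    if a.ndim != 2 or a.shape[0] != a.shape[1]:
        raise ValueError("adjacency must be a square matrix")
    if np.any(a < 0):
        raise ValueError("weights must be nonnegative")
    return a


def _lengths(w: np.ndarray, distance: str) -> np.ndarray:
    """Edge lengths from weights; zero weight means no edge (inf length)."""
    with np.errstate(divide="ignore"):
        if distance == "inv":
            L = np.where(w > 0, 1.0 / w, np.inf)
        elif distance == "one-minus":
            L = np.where(w > 0, 1.0 - w, np.inf)
        else:
            raise ValueError("distance must be 'inv' or 'one-minus'")
    np.fill_diagonal(L, np.inf)
    return L


def _distance_matrix(lengths: np.ndarray) -> np.ndarray:
    finite = np.isfinite(lengths)
    graph = csr_matrix(
        (lengths[finite], np.nonzero(finite)), shape=lengths.shape
    )
    return dijkstra(graph, directed=True)


def strengths(g: AdjLike) -> tuple[np.ndarray, np.ndarray]:
    """(s_in, s_out): summed incoming and outgoing edge weights per node."""
    w = _adj(g)
    return w.sum(axis=0), w.sum(axis=1)


def degrees(g: AdjLike) -> tuple[np.ndarray, np.ndarray]:
    """(k_in, k_out): counts of incoming and outgoing edges per node."""
    a = _adj(g) > 0
    return a.sum(axis=0).astype(float), a.sum(axis=1).astype(float)


def clustering_wd(g: AdjLike, rescale: bool = False) -> np.ndarray:
    """Fagiolo weighted-directed clustering coefficient per node.

    t_i = ((W^(1/3) + W^T^(1/3))^3)_ii / 2 counts weighted directed triangles
    over both orientations; the denominator is the number of possible
    triangles, (k_in + k_out)(k_in + k_out - 1) - 2 * (A^2)_ii.  Nodes with
    no possible triangle get 0.
    """
    w = _adj(g)
    if w.max(initial=0.0) > 1.0:
        if not rescale:
            raise ValueError("weights must lie in [0, 1]; pass rescale=True")
        w = w / w.max()
    wr = np.cbrt(w)
    s = wr + wr.T
    t = np.diagonal(s @ s @ s) / 2.0
    a = (w > 0).astype(float)
    k_tot = a.sum(axis=0) + a.sum(axis=1)
    k_bi = np.diagonal(a @ a)
    denom = k_tot * (k_tot - 1.0) - 2.0 * k_bi
    with np.errstate(divide="ignore", invalid="ignore"):
        cc = t / denom
    return np.where(denom > 0, cc, 0.0)


def shortest_path_metrics(
    g: AdjLike, distance: str = "inv"
) -> tuple[np.ndarray, np.ndarray, int]:
    """Per-node (cpl_i, eglob_i) on directed shortest paths.

    cpl_i is the mean distance from i to its *reachable* targets (NaN when
    none is reachable); eglob_i is the mean of 1/d over all targets with
    unreachable pairs contributing 0.  Also returns the number of unreachable
    ordered pairs.
    """
    w = _adj(g)
    n = w.shape[0]
    if n < 2:
        return np.full(n, np.nan), np.zeros(n), 0
    d = _distance_matrix(_lengths(w, distance))
    off = ~np.eye(n, dtype=bool)
    reach = np.isfinite(d) & off
    n_unreachable = int(np.count_nonzero(off & ~reach))
    with np.errstate(invalid="ignore"):
        cpl = np.where(
            reach.sum(axis=1) > 0,
            np.nansum(np.where(reach, d, np.nan), axis=1) / reach.sum(axis=1),
            np.nan,
        )
    inv = np.where(reach, 1.0 / np.where(reach, d, np.inf), 0.0)
    eglob = inv.sum(axis=1) / (n - 1)
    return cpl, eglob, n_unreachable


def local_efficiency(g: AdjLike, rescale: bool = False) -> np.ndarray:
    """Weighted-directed local efficiency per node.

    For each node u with neighborhood N_u (union of in- and out-neighbors),
    efficiency pairs the cube roots of the edge weights linking u to j and h
    with the inverse shortest-path distances between j and h inside N_u,
    computed on cube-root edge lengths; normalization is by the number of
    neighbor pairs counted with edge multiplicity, (sum_a)^2 - sum_a^2 with
    a_v = A(u,v) + A(v,u).  Nodes with fewer than two neighbors get 0.
    """
    w = _adj(g)
    if w.max(initial=0.0) > 1.0:
        if not rescale:
            raise ValueError("weights must lie in [0, 1]; pass rescale=True")
        w = w / w.max()
    n = w.shape[0]
    a = (w > 0).astype(float)
    lengths = np.cbrt(_lengths(w, "inv"))
    e = np.zeros(n)
    for u in range(n):
        nbrs = np.flatnonzero((a[u] + a[:, u]) > 0)
        if nbrs.size < 2:
            continue
        sub = lengths[np.ix_(nbrs, nbrs)]
        d = _distance_matrix(sub)
        with np.errstate(divide="ignore"):
            di = np.where(np.isfinite(d) & (d > 0), 1.0 / d, 0.0)
        se = di + di.T
        sw = np.cbrt(w[u, nbrs]) + np.cbrt(w[nbrs, u])
        numer = float(np.sum(np.outer(sw, sw) * se)) / 2.0
        if numer == 0.0:
            continue
        sa = a[u, nbrs] + a[nbrs, u]
        denom = sa.sum() ** 2 - np.sum(sa**2)
        e[u] = numer / denom
    return e


@dataclass
class NodalMetrics:
    """All six nodal metrics of one graph plus bookkeeping."""

    s_in: np.ndarray
    s_out: np.ndarray
    cc: np.ndarray
    cpl: np.ndarray
    eloc: np.ndarray
    eglob: np.ndarray
    n_unreachable_pairs: int = 0

    def by_name(self, name: str) -> np.ndarray:
        return getattr(self, name)


METRIC_NAMES = ("s_in", "s_out", "cc", "cpl", "eloc", "eglob")


def nodal_metrics(g: AdjLike, distance: str = "inv") -> NodalMetrics:
    """Compute all nodal metrics of one graph."""
    s_in, s_out = strengths(g)
    cc = clustering_wd(g)
    cpl, eglob, n_unreach = shortest_path_metrics(g, distance=distance)
    eloc = local_efficiency(g)
    return NodalMetrics(
        s_in=s_in,
        s_out=s_out,
        cc=cc,
        cpl=cpl,
        eloc=eloc,
        eglob=eglob,
        n_unreachable_pairs=n_unreach,
    )


def _random_positions(
    n: int, m: int, rng: np.random.Generator
) -> tuple[np.ndarray, np.ndarray]:
    """m distinct off-diagonal ordered positions of an n x n matrix."""
    total = n * (n - 1)
    flat = rng.choice(total, size=m, replace=False)
    row = flat // (n - 1)
    col = flat % (n - 1)
    col = np.where(col >= row, col + 1, col)  # skip the diagonal slot
    return row, col


def random_reference(
    g: AdjLike, n_realizations: int = 10, seed: Optional[int] = None
) -> list[np.ndarray]:
    """Edge-repositioned random references.

    The existing weighted edges are reassigned to uniformly random distinct
    off-diagonal ordered positions; node count, edge count and the weight
    multiset are preserved exactly.  The degree sequence is *not* preserved
    (plain repositioning, not degree-preserving rewiring).
    """
    w = _adj(g)
    n = w.shape[0]
    weights = w[w > 0]
    rng = np.random.default_rng(seed)
    out = []
    for _ in range(n_realizations):
        r = np.zeros_like(w)
        if weights.size:
            row, col = _random_positions(n, weights.size, rng)
            r[row, col] = rng.permutation(weights)
        out.append(r)
    return out


def _ring_offsets(n: int) -> np.ndarray:
    """Row offsets from the diagonal ordered by circular distance."""
    offs: list[int] = []
    for d in range(1, (n - 1) // 2 + 1):
        offs += [d, -d]
    if n % 2 == 0:
        offs.append(n // 2)
    return np.asarray(offs)


def _latticize(w: np.ndarray, wrap: bool = True) -> np.ndarray:
    """Sort each column's weights by descending size toward the diagonal.

    With ``wrap=True`` (default) "toward the diagonal" means circular
    distance, so every column becomes a band that wraps at the matrix corners
    and the result is a true ring lattice.  With ``wrap=False`` the column is
    split at the diagonal element and each part sorted independently toward
    it (no wraparound; corner columns pile up on one side).
    """
    n = w.shape[0]
    out = np.zeros_like(w)
    if wrap:
        offsets = _ring_offsets(n)
        for j in range(n):
            vals = np.delete(w[:, j], j)
            order = np.argsort(-vals, kind="stable")
            pos = (j + offsets) % n
            out[pos, j] = vals[order]
    else:
        for j in range(n):
            col = w[:, j]
            above = np.sort(col[:j])[::-1] if j else np.empty(0)
            below = np.sort(col[j + 1 :])[::-1]
            # largest weights closest to the diagonal element
            out[:j, j] = above[::-1]
            out[j + 1 :, j] = below
    return out


def lattice_reference(
    g: AdjLike,
    n_realizations: int = 10,
    seed: Optional[int] = None,
    wrap: bool = True,
) -> list[np.ndarray]:
    """Lattice references: random repositioning, then per-column sorting.

    After an initial random edge permutation, each adjacency column's weights
    are sorted so the largest sit next to the diagonal, yielding a banded
    nearest-neighbor (ring-lattice) topology with the exact node count, edge
    count and weight multiset of the input.  ``wrap`` selects circular
    (default, true ring) versus split-at-the-diagonal (no wraparound)
    placement.
    """
    rng = np.random.default_rng(seed)
    randoms = random_reference(g, n_realizations=n_realizations, seed=rng)
    return [_latticize(r, wrap=wrap) for r in randoms]


@dataclass
class GraphMeans:
    """Graph-level means of the four topology metrics."""

    cc: float
    cpl: float
    eloc: float
    eglob: float


def graph_means(g: AdjLike, distance: str = "inv") -> GraphMeans:
    """Node-averaged CC, CPL, local and global efficiency of one graph."""
    cc = clustering_wd(g)
    cpl, eglob, _ = shortest_path_metrics(g, distance=distance)
    eloc = local_efficiency(g)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        mean_cpl = float(np.nanmean(cpl))
    return GraphMeans(
        cc=float(np.mean(cc)),
        cpl=mean_cpl,
        eloc=float(np.mean(eloc)),
        eglob=float(np.mean(eglob)),
    )


def _mean_over(graphs: Sequence[AdjLike], distance: str) -> GraphMeans:
    ms = [graph_means(a, distance=distance) for a in graphs]
    return GraphMeans(
        cc=float(np.mean([m.cc for m in ms])),
        cpl=float(np.mean([m.cpl for m in ms])),
        eloc=float(np.mean([m.eloc for m in ms])),
        eglob=float(np.mean([m.eglob for m in ms])),
    )


@dataclass
class SmallWorldMetrics:
    """Small-world coefficients against random and lattice references.

    gamma = CC/CC_rand, lam = CPL/CPL_rand, sigma = gamma/lam;
    omega = CPL_rand/CPL - CC/CC_latt;
    gamma_e = Eloc/Eloc_rand, lambda_e = Eglob_rand/Eglob,
    sigma_e = gamma_e/lambda_e; omega_e = Eglob/Eglob_rand - Eloc/Eloc_latt.
    """

    gamma: float
    lam: float
    sigma: float
    omega: float
    gamma_e: float
    lambda_e: float
    sigma_e: float
    omega_e: float
    real: GraphMeans
    random: GraphMeans
    lattice: GraphMeans


def _ratio(a: float, b: float, label: str) -> float:
    if b == 0 or not np.isfinite(b):
        warnings.warn(f"undefined small-world ratio: {label} denominator is {b}")
        return np.nan
    return a / b


def small_world_coefficients(
    real: AdjLike,
    rand: Union[AdjLike, Sequence[np.ndarray], None] = None,
    latt: Union[AdjLike, Sequence[np.ndarray], None] = None,
    n_realizations: int = 10,
    seed: Optional[int] = None,
    distance: str = "inv",
) -> SmallWorldMetrics:
    """Small-world coefficients of a graph vs its reference ensembles.

    ``rand``/``latt`` may be single adjacencies, lists of realizations, or
    omitted (references are then generated here, ``n_realizations`` each).
    Reference metrics are averaged over realizations before forming ratios.
    """
    w = _adj(real)
    rng = np.random.default_rng(seed)
    if rand is None:
        rand = random_reference(w, n_realizations, seed=int(rng.integers(2**31)))
    if latt is None:
        latt = lattice_reference(w, n_realizations, seed=int(rng.integers(2**31)))
    rand_list = rand if isinstance(rand, (list, tuple)) else [rand]
    latt_list = latt if isinstance(latt, (list, tuple)) else [latt]
    m_real = graph_means(w, distance)
    m_rand = _mean_over(rand_list, distance)
    m_latt = _mean_over(latt_list, distance)
    gamma = _ratio(m_real.cc, m_rand.cc, "CC_rand")
    lam = _ratio(m_real.cpl, m_rand.cpl, "CPL_rand")
    sigma = _ratio(gamma, lam, "lambda")
    omega = _ratio(m_rand.cpl, m_real.cpl, "CPL") - _ratio(
        m_real.cc, m_latt.cc, "CC_latt"
    )
    gamma_e = _ratio(m_real.eloc, m_rand.eloc, "Eloc_rand")
    lambda_e = _ratio(m_rand.eglob, m_real.eglob, "Eglob")
    sigma_e = _ratio(gamma_e, lambda_e, "lambda_e")
    omega_e = _ratio(m_real.eglob, m_rand.eglob, "Eglob_rand") - _ratio(
        m_real.eloc, m_latt.eloc, "Eloc_latt"
    )
    return SmallWorldMetrics(
        gamma=gamma,
        lam=lam,
        sigma=sigma,
        omega=omega,
        gamma_e=gamma_e,
        lambda_e=lambda_e,
        sigma_e=sigma_e,
        omega_e=omega_e,
        real=m_real,
        lattice=m_latt,
        random=m_rand,
    )
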