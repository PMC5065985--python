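"""Hyper-frequency networks: electrode x frequency nodes, ICI edges.

An HFN node is one (electrode, frequency-of-interest) combination; with 58
electrodes and the 10 FOIs 2-20 Hz this gives 580 nodes.  Nodes are ordered
frequency-major (10 blocks of 58 electrodes), so within-frequency coupling
occupies the diagonal blocks of the adjacency matrix and cross-frequency
coupling the off-diagonal blocks.  The directed edge weight i -> j is the
windowed ICI of the ordered pair, and the network is sparsified with a fixed
threshold (default 0.26) chosen to exceed the chance level established by
surrogate data while keeping the cost (realized fraction of possible edges)
around 20 %.

Two surrogate constructions are provided for that chance level: random
permutation of the samples of each channel, and phase shuffling, which
permutes the phase spectrum of each channel while keeping the amplitude
spectrum (hence the power spectrum) exactly.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, replace
from typing import Optional, Sequence, Union

import numpy as np

from .coupling import CouplingWindowTensor, sliding_window_coupling
from .synthetic import SegmentedRecording
from .wavelet import DEFAULT_FOIS, recording_phases

__all__ = [
    "HFNode",
    "HFNGraph",
    "SurrogateNull",
    "node_table",
    "node_pairs",
    "build_hfn",
    "hfn_sequence",
    "apply_threshold",
    "make_surrogates",
    "surrogate_critical_value",
]

DEFAULT_THRESHOLD = 0.26


@dataclass(frozen=True)
class HFNode:
    """One (electrode, frequency) node with its frequency-major index."""

    electrode: str
    foi: float
    index: int


def node_table(labels: Sequence[str], fois: Sequence[float]) -> list[HFNode]:
    """Frequency-major node ordering: index = foi_block * n_channels + rank."""
    nodes = []
    for b, f in enumerate(fois):
        for r, lab in enumerate(labels):
            nodes.append(HFNode(electrode=lab, foi=float(f), index=b * len(labels) + r))
    return nodes


def node_pairs(labels: Sequence[str], fois: Sequence[float]) -> list[tuple]:
    """All ordered pairs of distinct HFN nodes as coupling-pair tuples."""
    nodes = node_table(labels, fois)
    return [
        (a.electrode, a.foi, b.electrode, b.foi)
        for a in nodes
        for b in nodes
        if a.index != b.index
    ]


@dataclass
class HFNGraph:
    """Directed weighted adjacency over HFN nodes.

    ``adjacency[i, j]`` is the coupling weight (ICI) from node i to node j;
    the diagonal is zero (no self coupling).  ``threshold`` is None before
    sparsification; afterwards every retained entry exceeds it.  ``cost`` is
    the number of nonzero off-diagonal entries over N*(N-1).
    """

    adjacency: np.ndarray
    nodes: list[HFNode]
    window_index: Optional[int] = None
    threshold: Optional[float] = None

    def __post_init__(self) -> None:
        a = np.asarray(self.adjacency, dtype=float)
        if a.ndim != 2 or a.shape[0] != a.shape[1]:
            raise ValueError("adjacency must be square")
        if a.shape[0] != len(self.nodes):
            raise ValueError("adjacency size must match node count")
        np.fill_diagonal(a, 0.0)
        self.adjacency = a

    @property
    def n_nodes(self) -> int:
        return self.adjacency.shape[0]

    @property
    def cost(self) -> float:
        n = self.n_nodes
        if n < 2:
            return 0.0
        return float(np.count_nonzero(self.adjacency)) / (n * (n - 1))


def build_hfn(
    coupling: CouplingWindowTensor,
    window_index: int,
    labels: Optional[Sequence[str]] = None,
    fois: Optional[Sequence[float]] = None,
    weight: str = "ici",
) -> HFNGraph:
    """Assemble the HFN adjacency of one sliding window.

    ``coupling`` must cover every ordered pair of the node set; labels/fois
    default to the distinct channels and frequencies found in the pairs
    (insertion order for channels, ascending for frequencies).
    """
    if labels is None:
        labels = list(dict.fromkeys([p[0] for p in coupling.pairs] + [p[2] for p in coupling.pairs]))
    else:
        labels = list(labels)
    if fois is None:
        fois = sorted({p[1] for p in coupling.pairs} | {p[3] for p in coupling.pairs})
    fois = [float(f) for f in fois]
    nodes = node_table(labels, fois)
    pos = {(n.electrode, n.foi): n.index for n in nodes}
    n = len(nodes)
    adj = np.zeros((n, n))
    seen = np.zeros((n, n), dtype=bool)
    values = coupling.indices[weight][:, window_index]
    for k, (ch_i, f_m, ch_j, f_n) in enumerate(coupling.pairs):
        i = pos.get((ch_i, float(f_m)))
        j = pos.get((ch_j, float(f_n)))
        if i is None or j is None:
            raise ValueError(f"pair {coupling.pairs[k]} outside the node set")
        adj[i, j] = values[k]
        seen[i, j] = True
    np.fill_diagonal(seen, True)
    if not seen.all():
        missing = np.argwhere(~seen)[0]
        a, b = nodes[missing[0]], nodes[missing[1]]
        raise ValueError(
            f"coupling tensor lacks the ordered pair "
            f"({a.electrode}@{a.foi} -> {b.electrode}@{b.foi})"
        )
    return HFNGraph(adjacency=adj, nodes=nodes, window_index=window_index)


def hfn_sequence(
    coupling: CouplingWindowTensor,
    labels: Optional[Sequence[str]] = None,
    fois: Optional[Sequence[float]] = None,
    threshold: Optional[float] = DEFAULT_THRESHOLD,
) -> list[HFNGraph]:
    """One (optionally thresholded) HFN per sliding window."""
    graphs = []
    for w in range(coupling.n_windows):
        g = build_hfn(coupling, w, labels=labels, fois=fois)
        if threshold is not None:
            g = apply_threshold(g, threshold)
        graphs.append(g)
    return graphs


def apply_threshold(g: HFNGraph, threshold: float = DEFAULT_THRESHOLD) -> HFNGraph:
    """Zero all entries <= threshold; surviving weights are kept as-is."""
    if threshold < 0:
        raise ValueError("threshold must be nonnegative")
    adj = np.where(g.adjacency > threshold, g.adjacency, 0.0)
    return HFNGraph(
        adjacency=adj, nodes=g.nodes, window_index=g.window_index, threshold=threshold
    )


def make_surrogates(
    rec: SegmentedRecording,
    method: str = "phase-shuffle",
    seed: Optional[int] = None,
) -> SegmentedRecording:
    """Destroy temporal structure while keeping per-channel sample statistics.

    ``time-shuffle`` permutes the samples of each channel independently
    (preserving the sample multiset); ``phase-shuffle`` permutes the phases
    of the positive-frequency Fourier bins of each channel while keeping the
    amplitude spectrum exactly, then inverse-transforms.
    """
    rng = np.random.default_rng(seed)
    data = rec.data
    if method == "time-shuffle":
        out = np.empty_like(data)
        for c in range(data.shape[0]):
            out[c] = data[c, rng.permutation(data.shape[1])]
    elif method == "phase-shuffle":
        n = data.shape[1]
        spec = np.fft.rfft(data, axis=1)
        out_spec = spec.copy()
        # bins 1 .. last (excluding DC; excluding Nyquist when n is even)
        stop = spec.shape[1] - 1 if n % 2 == 0 else spec.shape[1]
        for c in range(data.shape[0]):
            ph = np.angle(spec[c, 1:stop])
            out_spec[c, 1:stop] = np.abs(spec[c, 1:stop]) * np.exp(
                1j * rng.permutation(ph)
            )
        out = np.fft.irfft(out_spec, n=n, axis=1)
    else:
        raise ValueError("method must be 'time-shuffle' or 'phase-shuffle'")
    return SegmentedRecording(
        data=out, fs=rec.fs, labels=list(rec.labels), schedule=rec.schedule
    )


@dataclass
class SurrogateNull:
    """Bootstrap null for the coupling threshold.

    ``critical_value`` is the (1 - alpha) point of the bootstrap distribution
    of the mean coupling value on surrogate data (percentile construction by
    default; ``normal`` uses mean + z * SE).
    """

    method: str
    n_boot: int
    alpha: float
    critical_value: float
    boot_means: np.ndarray
    values: np.ndarray
    degenerate: bool = False


def surrogate_critical_value(
    rec: SegmentedRecording,
    method: str = "phase-shuffle",
    n_boot: int = 1000,
    alpha: float = 1e-4,
    seed: Optional[int] = None,
    fois: Optional[Sequence[float]] = None,
    pairs: Optional[Sequence[tuple]] = None,
    n_surrogates: int = 1,
    ci: str = "percentile",
    index: str = "ici",
    **coupling_kwargs,
) -> SurrogateNull:
    """Significance level of windowed coupling from surrogate recordings.

    Windowed ICI values are computed on ``n_surrogates`` surrogate versions
    of ``rec`` (all ordered node pairs of the given FOIs unless explicit
    ``pairs`` are supplied), pooled, and bootstrapped (``n_boot`` resamples
    of the mean).  The critical value is the upper (1 - alpha) bootstrap
    confidence bound of the mean coupling under the null of no temporal
    structure.
    """
    if n_boot < 100:
        raise ValueError("n_boot must be at least 100")
    if not 0 < alpha < 1:
        raise ValueError("alpha must lie in (0, 1)")
    rng = np.random.default_rng(seed)
    if fois is None:
        fois = [f for f in DEFAULT_FOIS if f < rec.fs / 2]
    if pairs is None:
        pairs = node_pairs(rec.labels, fois)
    pooled = []
    for _ in range(n_surrogates):
        sur = make_surrogates(rec, method=method, seed=int(rng.integers(2**31)))
        phases = recording_phases(sur, freqs=fois)
        cwt = sliding_window_coupling(phases, pairs, **coupling_kwargs)
        pooled.append(cwt.indices[index].ravel())
    values = np.concatenate(pooled)
    degenerate = bool(np.ptp(values) == 0)
    if degenerate:
        warnings.warn("surrogate coupling values are constant; null is degenerate")
    boot = rng.choice(values, size=(n_boot, values.size), replace=True).mean(axis=1)
    if ci == "percentile":
        critical = float(np.quantile(boot, 1.0 - alpha))
    elif ci == "normal":
        from scipy.stats import norm

        critical = float(boot.mean() + norm.ppf(1.0 - alpha) * boot.std(ddof=1))
    else:
        raise ValueError("ci must be 'percentile' or 'normal'")
    return SurrogateNull(
        method=method,
        n_boot=n_boot,
        alpha=alpha,
        critical_value=critical,
        boot_means=boot,
        values=values,
        degenerate=degenerate,
    )
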