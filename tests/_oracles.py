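"""Independent brute-force reference implementations used only by the tests.

These deliberately take the slow, literal route (explicit loops, networkx
Dijkstra) so that they share no code path with the vectorized package
implementations they check.
"""

import networkx as nx
import numpy as np


def strengths_bf(w):
    n = w.shape[0]
    s_in = np.zeros(n)
    s_out = np.zeros(n)
    for i in range(n):
        for j in range(n):
            s_out[i] += w[i, j]
            s_in[i] += w[j, i]
    return s_in, s_out


def clustering_bf(w):
    """Weighted-directed clustering: literal expansion of the cube of
    (W^(1/3) + W^T^(1/3)) over both triangle orientations."""
    n = w.shape[0]
    wr = np.cbrt(w)
    a = (w > 0).astype(int)
    out = np.zeros(n)
    for i in range(n):
        t = 0.0
        for j in range(n):
            for h in range(n):
                t += (wr[i, j] + wr[j, i]) * (wr[j, h] + wr[h, j]) * (wr[h, i] + wr[i, h])
        t /= 2.0
        k_tot = int(a[i, :].sum() + a[:, i].sum())
        k_bi = int((a[i, :] * a[:, i]).sum())
        den = k_tot * (k_tot - 1) - 2 * k_bi
        out[i] = t / den if den > 0 else 0.0
    return out


def _length_graph(w, exponent=1.0):
    g = nx.DiGraph()
    g.add_nodes_from(range(w.shape[0]))
    for i, j in zip(*np.nonzero(w)):
        g.add_edge(int(i), int(j), length=(1.0 / w[i, j]) ** exponent)
    return g


def path_metrics_bf(w):
    """(cpl_i over reachable targets, eglob_i with unreachable -> 0)."""
    n = w.shape[0]
    g = _length_graph(w)
    cpl = np.full(n, np.nan)
    eglob = np.zeros(n)
    for i in range(n):
        dist = nx.single_source_dijkstra_path_length(g, i, weight="length")
        ds = [d for j, d in dist.items() if j != i]
        if ds:
            cpl[i] = float(np.mean(ds))
        eglob[i] = sum(1.0 / d for d in ds if d > 0) / (n - 1) if n > 1 else 0.0
    return cpl, eglob


def local_efficiency_bf(w):
    n = w.shape[0]
    out = np.zeros(n)
    for u in range(n):
        nbrs = [v for v in range(n) if v != u and (w[u, v] > 0 or w[v, u] > 0)]
        if len(nbrs) < 2:
            continue
        sub = nx.DiGraph()
        sub.add_nodes_from(nbrs)
        for i in nbrs:
            for j in nbrs:
                if i != j and w[i, j] > 0:
                    sub.add_edge(i, j, length=np.cbrt(1.0 / w[i, j]))
        numer = 0.0
        for j in nbrs:
            dist = nx.single_source_dijkstra_path_length(sub, j, weight="length")
            for h in nbrs:
                if h == j:
                    continue
                d = dist.get(h, np.inf)
                if np.isfinite(d) and d > 0:
                    numer += (
                        (np.cbrt(w[u, j]) + np.cbrt(w[j, u]))
                        * (np.cbrt(w[u, h]) + np.cbrt(w[h, u]))
                        / d
                    )
        sa = np.array([int(w[u, v] > 0) + int(w[v, u] > 0) for v in nbrs], float)
        den = sa.sum() ** 2 - (sa**2).sum()
        out[u] = numer / den if den > 0 else 0.0
    return out


def window_counts_bf(code, start, width):
    """Literal counter of +1 / -1 fractions in one window of a ternary code."""
    pos = neg = 0
    for k in range(start, start + width):
        if code[k] == 1:
            pos += 1
        elif code[k] == -1:
            neg += 1
    return pos / width, neg / width


def clean_bf(code, period, fs_phase):
    """Literal run-length cleaning: scan runs of nonzero codes one by one."""
    code = list(code)
    out = list(code)
    i = 0
    while i < len(code):
        if code[i] == 0:
            i += 1
            continue
        j = i
        while j < len(code) and code[j] != 0:
            j += 1
        if (j - i) / fs_phase < period:
            for k in range(i, j):
                out[k] = 0
        i = j
    return np.array(out, dtype=np.int8)


def modularity_bf(w, assignment):
    """Double-loop evaluation of the weighted modularity of a partition."""
    w = np.array(w, dtype=float)
    np.fill_diagonal(w, 0.0)
    n = w.shape[0]
    l = w.sum()
    if l == 0:
        return 0.0
    k = w.sum(axis=1)
    q = 0.0
    for i in range(n):
        for j in range(n):
            if assignment[i] == assignment[j] and assignment[i] >= 0:
                q += w[i, j] - k[i] * k[j] / l
    return q / l
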