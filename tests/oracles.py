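"""Independent brute-force oracles for topology metrics.

Everything here works directly on a dense adjacency matrix with plain
loops, BFS and dense eigendecompositions — no shared code with the
package implementation.
"""

from __future__ import annotations

import numpy as np


def bfs_distances(a: np.ndarray) -> np.ndarray:
    """All-pairs directed geodesic lengths; 0 where unreachable or i == j."""
    n = a.shape[0]
    d = np.zeros((n, n))
    for s in range(n):
        dist = {s: 0}
        frontier = [s]
        while frontier:
            nxt = []
            for u in frontier:
                for v in range(n):
                    if a[u, v] and v not in dist:
                        dist[v] = dist[u] + 1
                        nxt.append(v)
            frontier = nxt
        for v, dv in dist.items():
            if v != s:
                d[s, v] = dv
    return d


def avg_path_length(a: np.ndarray) -> float:
    n = a.shape[0]
    return bfs_distances(a).sum() / (n * (n - 1))


def degrees(a: np.ndarray):
    k_in = a.sum(axis=0)
    k_out = a.sum(axis=1)
    return k_in + k_out, k_in, k_out


def clustering(a: np.ndarray) -> np.ndarray:
    n = a.shape[0]
    out = np.zeros(n)
    for i in range(n):
        k = a[:, i].sum() + a[i, :].sum()
        if k <= 1:
            continue
        nbrs = [j for j in range(n) if j != i and (a[i, j] or a[j, i])]
        e = sum(1 for u in nbrs for w in nbrs if u != w and a[u, w])
        out[i] = e / (k * (k - 1))
    return out


def all_shortest_paths(a: np.ndarray, s: int, t: int) -> list[tuple[int, ...]]:
    """Every geodesic from s to t, by depth-limited DFS along BFS distances."""
    d = bfs_distances(a)
    if s == t or d[s, t] == 0:
        return []
    target_len = int(d[s, t])
    paths = []

    def extend(path):
        u = path[-1]
        if u == t:
            if len(path) - 1 == target_len:
                paths.append(tuple(path))
            return
        if len(path) - 1 >= target_len:
            return
        for v in range(a.shape[0]):
            if a[u, v] and v not in path:
                # only continue along geodesic structure
                if v == t or (d[v, t] > 0 and len(path) + d[v, t] - 1 < target_len + 1):
                    extend(path + [v])

    extend([s])
    return paths


def betweenness(a: np.ndarray) -> np.ndarray:
    n = a.shape[0]
    out = np.zeros(n)
    for s in range(n):
        for t in range(n):
            if s == t:
                continue
            paths = all_shortest_paths(a, s, t)
            if not paths:
                continue
            for i in range(n):
                if i in (s, t):
                    continue
                through = sum(1 for p in paths if i in p)
                out[i] += through / len(paths)
    return out / ((n - 1) * (n - 2))


def hits_eig(a: np.ndarray):
    """Hub/authority via dense eigendecomposition of A A^T and A^T A.

    Returns (hub vector, authority vector, top eigenvalue) with the
    vectors taken as |principal eigenvector|, unit Euclidean norm.
    """
    hh = a @ a.T
    vals, vecs = np.linalg.eigh(hh)
    lam = vals[-1]
    h = np.abs(vecs[:, -1])
    aa = a.T @ a
    vals2, vecs2 = np.linalg.eigh(aa)
    auth = np.abs(vecs2[:, -1])
    return h / np.linalg.norm(h), auth / np.linalg.norm(auth), lam


def sym_eigencentrality(a: np.ndarray):
    """Principal eigenpair of the OR-symmetrized adjacency (dense solve)."""
    s = ((a + a.T) > 0).astype(float)
    vals, vecs = np.linalg.eigh(s)
    v = np.abs(vecs[:, -1])
    return v / np.linalg.norm(v), vals[-1], vals


def efficiency(a: np.ndarray) -> float:
    n = a.shape[0]
    if n < 2:
        return 0.0
    d = bfs_distances(a)
    total = sum(
        1.0 / d[i, j] for i in range(n) for j in range(n) if i != j and d[i, j] > 0
    )
    return total / (n * (n - 1))


def local_efficiency(a: np.ndarray) -> np.ndarray:
    n = a.shape[0]
    out = np.zeros(n)
    for i in range(n):
        k = a[:, i].sum() + a[i, :].sum()
        nbrs = [j for j in range(n) if j != i and (a[i, j] or a[j, i])]
        if len(nbrs) < 2 or k <= 1:
            continue
        sub = a[np.ix_(nbrs, nbrs)]
        out[i] = efficiency(sub)
    return out


def random_digraph(rng: np.random.Generator, n_max: int = 7) -> np.ndarray:
    """Random binary adjacency, zero diagonal, at least one edge."""
    n = int(rng.integers(2, n_max + 1))
    while True:
        a = (rng.random((n, n)) < rng.uniform(0.15, 0.6)).astype(np.int8)
        np.fill_diagonal(a, 0)
        if a.sum() >= 1:
            return a
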