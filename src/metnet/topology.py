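"""Topological characterization of substrate-product networks.

Nine local metrics per metabolite node — degree, in-degree, out-degree,
directed local clustering, HITS hub and authority scores, local
efficiency, betweenness and eigencentrality — plus network-level
summaries: mean degree, average shortest path length (with the
convention that unreachable ordered pairs contribute distance zero),
global efficiency and discrete power-law exponents of the in-/out-degree
distributions.

Conventions that differ from common library defaults:

* Average path length L sums geodesic lengths over all ordered pairs and
  divides by N(N-1), counting unreachable pairs as 0.  This shrinks L on
  fragmented digraphs but is the stated convention of the method.
* Local clustering is directed-literal: with k_i the total degree
  (in + out, bidirectional arcs counted twice) and e_i the number of
  ordered neighbor pairs (u, w) joined by an arc u->w, C_i =
  e_i / (k_i (k_i - 1)).  An undirected-projection variant is available
  via ``undirected=True``.
* HITS is iterated from the all-ones start with Euclidean renormalization.
* Eigencentrality is computed on the symmetrized adjacency (an arc in
  either direction counts), since the directed spectral radius of a
  largely acyclic digraph can vanish; power iteration runs on the shifted
  matrix A + I, which shares the Perron vector and cannot oscillate on
  bipartite components.
"""

from __future__ import annotations

from dataclasses import dataclass
import warnings

import networkx as nx
import numpy as np
import pandas as pd
from scipy.optimize import minimize_scalar
from scipy.special import zeta

from .network import MetabolicNetwork

METRIC_NAMES = (
    "degree",
    "in_degree",
    "out_degree",
    "clustering",
    "hub",
    "authority",
    "efficiency",
    "betweenness",
    "eigencentrality",
)


class DegenerateNetworkError(ValueError):
    pass


# ---------------------------------------------------------------- degrees


def degrees(net: MetabolicNetwork):
    """Per-node (k, k_in, k_out) dicts and the mean degree E/N."""
    g = net.graph
    k_in = dict(g.in_degree())
    k_out = dict(g.out_degree())
    k = {v: k_in[v] + k_out[v] for v in g}
    mean_degree = g.number_of_edges() / g.number_of_nodes()
    return k, k_in, k_out, mean_degree


# ------------------------------------------------------------- distances


def shortest_distances(net: MetabolicNetwork):
    """All-pairs directed geodesic matrix D (0 when unreachable) and L.

    D follows the node order of ``net.nodes``.  L averages over all
    N(N-1) ordered pairs, unreachable pairs included as zeros.
    """
    nodes = net.nodes
    n = len(nodes)
    if n < 2:
        raise DegenerateNetworkError("need at least 2 nodes for distances")
    index = {v: i for i, v in enumerate(nodes)}
    d = np.zeros((n, n))
    for src, lengths in nx.all_pairs_shortest_path_length(net.graph):
        i = index[src]
        for dst, dist in lengths.items():
            d[i, index[dst]] = dist
    length = d.sum() / (n * (n - 1))
    return d, length


# ------------------------------------------------------------ clustering


def _neighborhood(g: nx.DiGraph, v) -> set:
    return (set(g.predecessors(v)) | set(g.successors(v))) - {v}


def local_clustering(net: MetabolicNetwork, undirected: bool = False) -> dict:
    """Directed local clustering C_i = e_i / (k_i (k_i - 1)).

    e_i counts ordered neighbor pairs joined by an arc; k_i is the total
    degree (so a bidirectional arc contributes 2).  C_i = 0 when k_i <= 1.
    With ``undirected=True`` the conventional undirected clustering of the
    symmetrized projection is returned instead.
    """
    g = net.graph
    if undirected:
        return nx.clustering(g.to_undirected())
    out = {}
    for v in g:
        k = g.in_degree(v) + g.out_degree(v)
        if k <= 1:
            out[v] = 0.0
            continue
        nbrs = _neighborhood(g, v)
        e = sum(1 for u in nbrs for w in nbrs if u != w and g.has_edge(u, w))
        out[v] = e / (k * (k - 1))
    return out


# ------------------------------------------------------------------ HITS


def hits_scores(net: MetabolicNetwork, tol: float = 1e-8, max_iter: int = 1000):
    """Kleinberg hub/authority scores by mutual-reinforcement iteration.

    Starts from all-ones, renormalizes both vectors to unit Euclidean norm
    each sweep, and stops when the max absolute change falls below ``tol``.
    Returns (hub, authority) dicts of non-negative unit-norm scores.
    """
    g = net.graph
    if g.number_of_edges() == 0:
        raise DegenerateNetworkError("HITS undefined on an edgeless graph")
    nodes = net.nodes
    a = nx.to_scipy_sparse_array(g, nodelist=nodes, dtype=float, format="csr")
    h = np.ones(len(nodes))
    auth = np.ones(len(nodes))
    h /= np.linalg.norm(h)
    auth /= np.linalg.norm(auth)
    for _ in range(max_iter):
        auth_new = a.T @ h
        auth_new /= np.linalg.norm(auth_new)
        h_new = a @ auth_new
        h_new /= np.linalg.norm(h_new)
        if max(np.abs(h_new - h).max(), np.abs(auth_new - auth).max()) < tol:
            h, auth = h_new, auth_new
            break
        h, auth = h_new, auth_new
    else:
        warnings.warn("HITS did not converge; returning last iterate")
    return dict(zip(nodes, h)), dict(zip(nodes, auth))


# ----------------------------------------------------------- betweenness


def betweenness(net: MetabolicNetwork) -> dict:
    """Directed shortest-path betweenness, normalized by (N-1)(N-2).

    Ordered endpoint pairs, endpoints excluded; values lie in [0, 1].
    """
    if net.n_nodes < 3:
        raise DegenerateNetworkError("betweenness needs at least 3 nodes")
    return nx.betweenness_centrality(net.graph, normalized=True)


# ------------------------------------------------------- eigencentrality


def eigencentrality(net: MetabolicNetwork, tol: float = 1e-10, max_iter: int = 10000):
    """Principal eigenpair of the symmetrized adjacency by power iteration.

    Returns (scores dict, leading eigenvalue).  The eigenvector is
    non-negative with unit Euclidean norm.
    """
    g = net.graph
    if g.number_of_edges() == 0:
        raise DegenerateNetworkError("eigencentrality undefined on an edgeless graph")
    nodes = net.nodes
    a = nx.to_scipy_sparse_array(
        g.to_undirected(), nodelist=nodes, dtype=float, format="csr"
    )
    x = np.ones(len(nodes))
    x /= np.linalg.norm(x)
    lam = 0.0
    for _ in range(max_iter):
        # shift by +I: same eigenvectors, strictly dominant top eigenvalue
        y = a @ x + x
        norm = np.linalg.norm(y)
        x_new = y / norm
        if np.abs(x_new - x).max() < tol:
            x = x_new
            lam = norm - 1.0
            break
        x = x_new
        lam = norm - 1.0
    else:
        warnings.warn("eigencentrality power iteration did not converge")
    x = np.abs(x)  # Perron vector is non-negative; clean sign noise
    x /= np.linalg.norm(x)
    return dict(zip(nodes, x)), lam


# ------------------------------------------------------------ efficiency


def _subgraph_efficiency(g: nx.DiGraph) -> float:
    """Mean reciprocal directed geodesic over ordered pairs (0 if unreachable)."""
    n = g.number_of_nodes()
    if n < 2:
        return 0.0
    total = 0.0
    for src, lengths in nx.all_pairs_shortest_path_length(g):
        for dst, dist in lengths.items():
            if dst != src and dist > 0:
                total += 1.0 / dist
    return total / (n * (n - 1))


def local_efficiency(net: MetabolicNetwork) -> dict:
    """Efficiency of each node's neighbor-induced directed subgraph.

    Proxy for fault tolerance: how well the neighborhood of v communicates
    once v is removed.  Zero for nodes with fewer than two neighbors.
    """
    g = net.graph
    out = {}
    for v in g:
        nbrs = _neighborhood(g, v)
        if len(nbrs) < 2 or (g.in_degree(v) + g.out_degree(v)) <= 1:
            out[v] = 0.0
            continue
        out[v] = _subgraph_efficiency(g.subgraph(nbrs))
    return out


def global_efficiency(net: MetabolicNetwork) -> float:
    """Mean reciprocal geodesic distance over all ordered node pairs."""
    return _subgraph_efficiency(net.graph)


# ------------------------------------------------------------- power law


def powerlaw_mle(sample: np.ndarray, x_min: int = 1) -> float | None:
    """Discrete power-law exponent by maximum likelihood with fixed x_min.

    Maximizes  -n log zeta(g, x_min) - g * sum(log k)  over g in (1, 20].
    Returns None when the sample is too small (< 10 values) or degenerate
    (all values equal, or the optimum sticks to the search boundary).
    """
    sample = np.asarray(sample)
    sample = sample[sample >= x_min]
    if sample.size < 10 or np.all(sample == sample[0]):
        return None
    log_sum = np.log(sample).sum()

    def nll(g):
        return sample.size * np.log(zeta(g, x_min)) + g * log_sum

    res = minimize_scalar(nll, bounds=(1.0001, 20.0), method="bounded")
    gamma = float(res.x)
    if gamma > 19.5:  # degenerate: distribution too steep to be a power law fit
        return None
    return gamma


def powerlaw_exponents(net: MetabolicNetwork) -> tuple[float | None, float | None]:
    """(gamma_in, gamma_out) fitted to the nonzero degree samples; None if not estimable."""
    k_in = np.array([d for _, d in net.graph.in_degree() if d > 0])
    k_out = np.array([d for _, d in net.graph.out_degree() if d > 0])
    return powerlaw_mle(k_in), powerlaw_mle(k_out)


# ------------------------------------------------------------- assembly


@dataclass
class GlobalMetrics:
    taxon_id: str
    mean_degree: float
    avg_path_length: float
    global_efficiency: float
    gamma_in: float | None
    gamma_out: float | None


def compute_node_metrics(
    net: MetabolicNetwork, undirected_clustering: bool = False
) -> pd.DataFrame:
    """All nine local metrics as a DataFrame indexed by metabolite.

    Columns follow :data:`METRIC_NAMES`; row order is the sorted node list.
    """
    k, k_in, k_out, _ = degrees(net)
    clustering = local_clustering(net, undirected=undirected_clustering)
    if net.n_edges >= 1:
        hub, auth = hits_scores(net)
        eig, _ = eigencentrality(net)
    else:
        hub = auth = eig = {v: 0.0 for v in net.graph}
    eff = local_efficiency(net)
    if net.n_nodes >= 3:
        btw = betweenness(net)
    else:
        btw = {v: 0.0 for v in net.graph}
    nodes = net.nodes
    return pd.DataFrame(
        {
            "degree": [float(k[v]) for v in nodes],
            "in_degree": [float(k_in[v]) for v in nodes],
            "out_degree": [float(k_out[v]) for v in nodes],
            "clustering": [clustering[v] for v in nodes],
            "hub": [hub[v] for v in nodes],
            "authority": [auth[v] for v in nodes],
            "efficiency": [eff[v] for v in nodes],
            "betweenness": [btw[v] for v in nodes],
            "eigencentrality": [eig[v] for v in nodes],
        },
        index=pd.Index(nodes, name="metabolite"),
    )


def compute_global_metrics(net: MetabolicNetwork) -> GlobalMetrics:
    _, _, _, mean_k = degrees(net)
    if net.n_nodes >= 2:
        _, avg_len = shortest_distances(net)
    else:
        avg_len = 0.0
    g_in, g_out = powerlaw_exponents(net)
    return GlobalMetrics(
        taxon_id=net.taxon_id,
        mean_degree=mean_k,
        avg_path_length=avg_len,
        global_efficiency=global_efficiency(net),
        gamma_in=g_in,
        gamma_out=g_out,
    )
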