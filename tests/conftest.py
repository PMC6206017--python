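import networkx as nx
import numpy as np
import pytest

from metnet.network import MetabolicNetwork, build_network
from metnet.reaction_io import ReactionDirection, ReactionRecord, ReactionSet


def net_from_adjacency(a: np.ndarray, taxon_id: str = "X") -> MetabolicNetwork:
    """MetabolicNetwork over nodes n00, n01, ... with the given adjacency.

    Node names are chosen so that lexicographic order equals index order,
    keeping oracle vectors and metric tables aligned.
    """
    n = a.shape[0]
    names = [f"n{i:02d}" for i in range(n)]
    g = nx.DiGraph()
    g.add_nodes_from(names)
    for i in range(n):
        for j in range(n):
            if a[i, j]:
                g.add_edge(names[i], names[j])
    return MetabolicNetwork(taxon_id, g)


def net_from_edges(edges, extra_nodes=(), taxon_id: str = "X") -> MetabolicNetwork:
    g = nx.DiGraph()
    g.add_edges_from(edges)
    g.add_nodes_from(extra_nodes)
    return MetabolicNetwork(taxon_id, g)


def make_reaction(rid, subs, prods, direction=ReactionDirection.LEFT_TO_RIGHT):
    return ReactionRecord(rid, tuple(subs), tuple(prods), direction)


@pytest.fixture(scope="session")
def synthetic_dataset():
    """Small clade-structured synthetic dataset shared across tests.

    4 clades x 3 leaves, losses off, gains clade-disjoint by tree
    structure: the regime in which the generating topology is exactly
    recoverable.
    """
    from metnet.synth import clade_signal_config, evolve_repertoires

    cfg = clade_signal_config(n_clades=4, leaves_per_clade=3, seed=2026)
    leaves, true_tree = evolve_repertoires(cfg)
    return cfg, leaves, true_tree


@pytest.fixture(scope="session")
def synthetic_pipeline_state(synthetic_dataset):
    """Networks, node-metric tables and character sets for the synthetic data."""
    from metnet.features import common_set, full_set
    from metnet.topology import compute_node_metrics

    _, leaves, true_tree = synthetic_dataset
    networks = {t: build_network(rs) for t, rs in leaves.items()}
    tables = {t: compute_node_metrics(n) for t, n in networks.items()}
    nets = list(networks.values())
    return {
        "networks": networks,
        "tables": tables,
        "common": common_set(nets),
        "full": full_set(nets),
        "true_tree": true_tree,
    }
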