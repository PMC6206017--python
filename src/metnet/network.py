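"""Directed substrate-product network construction.

Every substrate metabolite of a reaction is linked to every product
metabolite, respecting reaction direction; a reversible reaction
contributes both orientations as two separate arcs.  Nodes are the
distinct metabolites of the reaction set (metabolites appearing only on
both sides of the same reaction remain as isolated nodes), edges are
unweighted and de-duplicated, and self-loops are dropped by default.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import networkx as nx
import numpy as np
import pandas as pd

from .reaction_io import ReactionDirection, ReactionSet


class EmptyReactionSetError(ValueError):
    pass


@dataclass
class MetabolicNetwork:
    """Directed unweighted graph over metabolite nodes.

    ``nodes`` is lexicographically sorted so the adjacency layout is
    deterministic across runs and taxa; ``graph`` is the underlying
    networkx DiGraph.
    """

    taxon_id: str
    graph: nx.DiGraph = field(repr=False)

    @property
    def nodes(self) -> list[str]:
        return sorted(self.graph.nodes)

    @property
    def n_nodes(self) -> int:
        return self.graph.number_of_nodes()

    @property
    def n_edges(self) -> int:
        return self.graph.number_of_edges()

    def adjacency(self) -> np.ndarray:
        """Dense binary adjacency with rows/columns in ``nodes`` order."""
        return nx.to_numpy_array(self.graph, nodelist=self.nodes, dtype=np.int8)


def build_network(
    reactions: ReactionSet, keep_self_loops: bool = False
) -> MetabolicNetwork:
    """Build the substrate-product digraph of one taxon.

    Raises :class:`EmptyReactionSetError` on an empty reaction set.
    """
    if not reactions.records:
        raise EmptyReactionSetError(f"taxon {reactions.taxon_id!r} has no reactions")
    g = nx.DiGraph()
    for rec in reactions.records:
        g.add_nodes_from(rec.substrates)
        g.add_nodes_from(rec.products)
        forward = rec.direction in (
            ReactionDirection.LEFT_TO_RIGHT,
            ReactionDirection.REVERSIBLE,
        )
        backward = rec.direction in (
            ReactionDirection.RIGHT_TO_LEFT,
            ReactionDirection.REVERSIBLE,
        )
        for s in rec.substrates:
            for p in rec.products:
                if s == p and not keep_self_loops:
                    continue
                if forward:
                    g.add_edge(s, p)
                if backward:
                    g.add_edge(p, s)
    return MetabolicNetwork(reactions.taxon_id, g)


def network_summary(
    networks: list[MetabolicNetwork],
    reaction_sets: list[ReactionSet],
    clade_map: dict[str, str],
) -> pd.DataFrame:
    """Per-taxon metabolite (N) and reaction (R) counts with per-clade means.

    Returns a DataFrame indexed by taxon with columns ``clade``, ``N``,
    ``R``, ``clade_mean_N``, ``clade_mean_R``.
    """
    nets = {m.taxon_id: m for m in networks}
    rsets = {r.taxon_id: r for r in reaction_sets}
    if set(nets) != set(rsets):
        raise ValueError("networks and reaction sets cover different taxa")
    missing = set(nets) - set(clade_map)
    if missing:
        raise KeyError(f"taxa missing from clade map: {sorted(missing)}")
    rows = [
        {
            "taxon": t,
            "clade": clade_map[t],
            "N": nets[t].n_nodes,
            "R": rsets[t].reaction_count,
        }
        for t in sorted(nets)
    ]
    df = pd.DataFrame(rows).set_index("taxon")
    means = df.groupby("clade")[["N", "R"]].mean()
    df["clade_mean_N"] = df["clade"].map(means["N"])
    df["clade_mean_R"] = df["clade"].map(means["R"])
    return df


def write_edge_list(net: MetabolicNetwork, path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        for u, v in sorted(net.graph.edges):
            fh.write(f"{u}\t{v}\n")


def write_node_list(net: MetabolicNetwork, path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        for n in net.nodes:
            fh.write(f"{n}\n")
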