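"""Feature vectors over metabolite character sets, and PCA projection.

Each taxon P is represented by a vector phi_P = [mu_1 ... mu_m] of one
topological metric evaluated at an ordered list of metabolite
"characters".  Characters come from either the common set (intersection
of all node sets) or the full set (union); a character absent from a
taxon's network takes the value 0 in that taxon's row, which is the
value every connectivity-derived metric assigns to an unconnected node.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.decomposition import PCA

from .network import MetabolicNetwork
from .reaction_io import ReactionRecord, ReactionSet
from .topology import METRIC_NAMES


@dataclass(frozen=True)
class MetaboliteSet:
    kind: str  # "common" | "full" | "custom"
    characters: tuple[str, ...]

    def __post_init__(self):
        if list(self.characters) != sorted(set(self.characters)):
            raise ValueError("characters must be sorted and duplicate-free")

    @property
    def m(self) -> int:
        return len(self.characters)


def common_set(networks: list[MetabolicNetwork]) -> MetaboliteSet:
    """Sorted intersection of metabolite node sets across all networks."""
    if len(networks) < 2:
        raise ValueError("common set needs at least 2 networks")
    inter = set(networks[0].graph.nodes)
    for net in networks[1:]:
        inter &= set(net.graph.nodes)
    if not inter:
        warnings.warn("common metabolite set is empty")
    return MetaboliteSet("common", tuple(sorted(inter)))


def full_set(networks: list[MetabolicNetwork]) -> MetaboliteSet:
    """Sorted union of metabolite node sets across all networks."""
    if not networks:
        raise ValueError("full set needs at least 1 network")
    union: set[str] = set()
    for net in networks:
        union |= set(net.graph.nodes)
    return MetaboliteSet("full", tuple(sorted(union)))


def common_reactions(reaction_sets: list[ReactionSet]) -> list[ReactionRecord]:
    """Reactions identical in (substrates, products, direction) across all taxa."""
    if len(reaction_sets) < 2:
        raise ValueError("common reactions need at least 2 sets")
    keys = set(r.key for r in reaction_sets[0].records)
    for rs in reaction_sets[1:]:
        keys &= set(r.key for r in rs.records)
    return [r for r in reaction_sets[0].records if r.key in keys]


@dataclass
class FeatureMatrix:
    """Taxa x characters matrix of one metric; rows are feature vectors phi_P."""

    metric: str
    characters: MetaboliteSet
    values: pd.DataFrame  # index: taxa, columns: characters

    @property
    def taxa(self) -> list[str]:
        return list(self.values.index)

    def to_array(self) -> np.ndarray:
        return self.values.to_numpy(dtype=float)

    def restrict(self, characters: MetaboliteSet) -> "FeatureMatrix":
        """Sub-matrix over another (contained) character set."""
        return FeatureMatrix(
            self.metric, characters, self.values[list(characters.characters)].copy()
        )


def assemble_features(
    metric_tables: dict[str, pd.DataFrame],
    metric: str,
    characters: MetaboliteSet,
) -> FeatureMatrix:
    """Align per-taxon node-metric tables on a shared character set.

    ``metric_tables`` maps taxon id to the node-metric DataFrame of
    :func:`metnet.topology.compute_node_metrics`.  Characters missing from
    a taxon's table are filled with 0.
    """
    if metric not in METRIC_NAMES:
        raise KeyError(f"unknown metric {metric!r}; choose from {METRIC_NAMES}")
    cols = list(characters.characters)
    rows = {}
    for taxon in sorted(metric_tables):
        series = metric_tables[taxon][metric]
        rows[taxon] = series.reindex(cols).fillna(0.0).to_numpy()
    values = pd.DataFrame.from_dict(rows, orient="index", columns=cols)
    if not np.isfinite(values.to_numpy()).all():
        raise ValueError("non-finite feature values")
    return FeatureMatrix(metric, characters, values)


def pca_project(fm: FeatureMatrix, n_components: int | None = None):
    """Column-centered PCA projection of the feature matrix.

    Returns (scores DataFrame indexed by taxa, explained-variance ratios).
    ``n_components=None`` keeps full rank (taxa - 1), in which case the
    pairwise Euclidean distances of the scores equal those of the raw
    centered rows.  The sign of each component is fixed so the
    largest-magnitude loading is positive.
    """
    x = fm.to_array()
    n_taxa, m = x.shape
    if n_components is None:
        n_components = min(n_taxa - 1, m)
    if not 1 <= n_components <= min(n_taxa - 1, m):
        raise ValueError(f"n_components must be in [1, {min(n_taxa - 1, m)}]")
    if np.allclose(x, x[0]):
        raise ValueError("constant feature matrix: PCA undefined")
    pca = PCA(n_components=n_components, svd_solver="full")
    scores = pca.fit_transform(x)
    # deterministic sign: largest-|loading| entry of each axis is positive
    for j in range(n_components):
        load = pca.components_[j]
        if load[np.argmax(np.abs(load))] < 0:
            pca.components_[j] = -load
            scores[:, j] = -scores[:, j]
    cols = [f"PC{j + 1}" for j in range(n_components)]
    return (
        pd.DataFrame(scores, index=fm.values.index, columns=cols),
        pca.explained_variance_ratio_,
    )


def metabolite_coverage_percent(subset_size: int, mean_count: float) -> float:
    """Share (in %) of an average repertoire covered by a subset of characters.

    E.g. the number of metabolites common to all taxa divided by the mean
    per-taxon metabolite count, expressed as a percentage.
    """
    if mean_count <= 0:
        raise ValueError("mean count must be positive")
    return 100.0 * subset_size / mean_count
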