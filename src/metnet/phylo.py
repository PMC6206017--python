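"""Distance matrices, UPGMA dendrograms and cophenetic correlation.

UPGMA agglomerates the closest pair of clusters, with inter-cluster
distance the unweighted arithmetic mean of member-pair distances.  The
merge *height* of the new internal node is half the merge distance, so
the cophenetic distance between any two leaves (twice the height of
their lowest common ancestor) equals the distance at which their
clusters merged.  Ties are broken lexicographically by smallest member
label, making trees deterministic across platforms.

The cophenetic correlation coefficient (CPCC) between two distance
structures is the Pearson correlation of their strictly-upper-triangle
entries after aligning taxa by label.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import dendropy
import numpy as np
import pandas as pd
from scipy.spatial.distance import pdist, squareform
from scipy.stats import pearsonr

from .features import FeatureMatrix


class ValidationError(ValueError):
    pass


@dataclass
class DistanceMatrix:
    taxa: list[str]
    values: np.ndarray

    def __post_init__(self):
        v = np.asarray(self.values, dtype=float)
        n = len(self.taxa)
        if v.shape != (n, n):
            raise ValidationError(f"matrix shape {v.shape} != ({n}, {n})")
        if not np.isfinite(v).all():
            raise ValidationError("non-finite distances")
        if not np.allclose(v, v.T, atol=1e-12):
            raise ValidationError("distance matrix not symmetric")
        if not np.allclose(np.diag(v), 0.0):
            raise ValidationError("nonzero diagonal")
        self.values = v

    def reorder(self, taxa: list[str]) -> "DistanceMatrix":
        idx = [self.taxa.index(t) for t in taxa]
        return DistanceMatrix(list(taxa), self.values[np.ix_(idx, idx)])

    def condensed(self) -> np.ndarray:
        return squareform(self.values, checks=False)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.taxa, columns=self.taxa)


@dataclass
class TreeNode:
    """Node of a rooted ultrametric dendrogram; leaves have height 0."""

    height: float
    label: str | None = None
    children: list["TreeNode"] = field(default_factory=list)

    @property
    def is_leaf(self) -> bool:
        return not self.children

    def leaf_labels(self) -> frozenset[str]:
        if self.is_leaf:
            return frozenset([self.label])
        out: set[str] = set()
        for c in self.children:
            out |= c.leaf_labels()
        return frozenset(out)

    def iter_nodes(self):
        yield self
        for c in self.children:
            yield from c.iter_nodes()


@dataclass
class Dendrogram:
    root: TreeNode

    @property
    def taxa(self) -> list[str]:
        return sorted(self.root.leaf_labels())

    def clades(self, nontrivial: bool = True) -> set[frozenset[str]]:
        """Leaf-label sets of internal nodes (optionally excluding singletons)."""
        out = set()
        for node in self.root.iter_nodes():
            labels = node.leaf_labels()
            if nontrivial and len(labels) < 2:
                continue
            out.add(labels)
        return out

    def cophenetic_matrix(self) -> DistanceMatrix:
        """Pairwise merge distances (2 x LCA height) between leaves."""
        taxa = self.taxa
        index = {t: i for i, t in enumerate(taxa)}
        n = len(taxa)
        d = np.zeros((n, n))

        def visit(node: TreeNode):
            if node.is_leaf:
                return
            child_sets = []
            for c in node.children:
                visit(c)
                child_sets.append(c.leaf_labels())
            for a in range(len(child_sets)):
                for b in range(a + 1, len(child_sets)):
                    for u in child_sets[a]:
                        for v in child_sets[b]:
                            d[index[u], index[v]] = d[index[v], index[u]] = (
                                2.0 * node.height
                            )

        visit(self.root)
        return DistanceMatrix(taxa, d)

    def to_newick(self) -> str:
        def fmt(node: TreeNode, parent_height: float) -> str:
            blen = parent_height - node.height
            if node.is_leaf:
                return f"{node.label}:{blen:.10g}"
            inner = ",".join(fmt(c, node.height) for c in node.children)
            return f"({inner}):{blen:.10g}"

        inner = ",".join(fmt(c, self.root.height) for c in self.root.children)
        return f"({inner});"


def euclidean_distances(fm: FeatureMatrix | pd.DataFrame) -> DistanceMatrix:
    """Pairwise Euclidean distances between taxon rows."""
    df = fm.values if isinstance(fm, FeatureMatrix) else fm
    x = df.to_numpy(dtype=float)
    if x.shape[0] < 2:
        raise ValidationError("need at least 2 taxa")
    if not np.isfinite(x).all():
        raise ValidationError("non-finite feature values")
    return DistanceMatrix(list(df.index), squareform(pdist(x, metric="euclidean")))


def upgma(dm: DistanceMatrix) -> Dendrogram:
    """Unweighted pair-group agglomeration with arithmetic-mean linkage."""
    # active clusters keyed by their lexicographically smallest member
    clusters: dict[str, TreeNode] = {
        t: TreeNode(height=0.0, label=t) for t in dm.taxa
    }
    sizes: dict[str, int] = {t: 1 for t in dm.taxa}
    dist: dict[frozenset[str], float] = {}
    for i, a in enumerate(dm.taxa):
        for j in range(i + 1, len(dm.taxa)):
            b = dm.taxa[j]
            dist[frozenset((a, b))] = dm.values[i, j]

    while len(clusters) > 1:
        # closest pair; ties resolved by sorted key-label pair
        best = min(
            (
                (dist[frozenset((a, b))], tuple(sorted((a, b))))
                for i, a in enumerate(sorted(clusters))
                for b in sorted(clusters)[i + 1:]
            ),
        )
        d_merge, (a, b) = best
        node = TreeNode(height=d_merge / 2.0, children=[clusters[a], clusters[b]])
        na, nb = sizes[a], sizes[b]
        for other in clusters:
            if other in (a, b):
                continue
            dist[frozenset((a, other))] = (
                na * dist[frozenset((a, other))] + nb * dist[frozenset((b, other))]
            ) / (na + nb)
            dist.pop(frozenset((b, other)), None)
        dist.pop(frozenset((a, b)), None)
        del clusters[b], sizes[b]
        clusters[a] = node
        sizes[a] = na + nb

    (root,) = clusters.values()
    # ensure heights are monotone root-ward (guards fp noise on tie merges)
    def clamp(node: TreeNode):
        for c in node.children:
            if c.height > node.height:
                c.height = node.height
            clamp(c)

    clamp(root)
    return Dendrogram(root)


def cophenetic_matrix(tree: Dendrogram) -> DistanceMatrix:
    return tree.cophenetic_matrix()


def cpcc(d1: DistanceMatrix, d2: DistanceMatrix) -> float:
    """Cophenetic correlation: Pearson r over aligned upper triangles."""
    if set(d1.taxa) != set(d2.taxa):
        raise ValidationError("distance matrices cover different taxa")
    if len(d1.taxa) < 3:
        raise ValidationError("CPCC needs at least 3 taxa")
    d2a = d2.reorder(d1.taxa)
    x, y = d1.condensed(), d2a.condensed()
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValidationError("zero variance in distances: CPCC undefined")
    return float(pearsonr(x, y).statistic)


def clade_difference(tree_a: Dendrogram, tree_b: Dendrogram) -> int:
    """Symmetric difference of non-trivial rooted clade sets (rooted RF count)."""
    if set(tree_a.taxa) != set(tree_b.taxa):
        raise ValidationError("trees cover different taxa")
    return len(tree_a.clades() ^ tree_b.clades())


# -------------------------------------------------------------------- I/O


def read_phylip_matrix(path: str | Path) -> DistanceMatrix:
    """Read a PHYLIP-style square distance matrix (count line, label + row)."""
    lines = [ln for ln in Path(path).read_text(encoding="utf-8").splitlines() if ln.strip()]
    n = int(lines[0].split()[0])
    taxa, rows = [], []
    for ln in lines[1 : n + 1]:
        parts = ln.split()
        taxa.append(parts[0])
        rows.append([float(x) for x in parts[1 : n + 1]])
    return DistanceMatrix(taxa, np.array(rows))


def write_phylip_matrix(dm: DistanceMatrix, path: str | Path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        fh.write(f"{len(dm.taxa)}\n")
        for t, row in zip(dm.taxa, dm.values):
            fh.write(t + "  " + "  ".join(f"{x:.10g}" for x in row) + "\n")


def read_newick(path_or_string: str | Path) -> Dendrogram:
    """Parse a rooted Newick tree into a Dendrogram.

    Node heights are reconstructed from branch lengths as the maximum
    leaf-ward path length below each node (exact for ultrametric trees).
    """
    s = str(path_or_string)
    if "(" in s:
        dtree = dendropy.Tree.get(data=s, schema="newick")
    else:
        dtree = dendropy.Tree.get(path=s, schema="newick")
    return _from_dendropy(dtree)


def _from_dendropy(dtree: dendropy.Tree) -> Dendrogram:
    def build(dnode) -> TreeNode:
        if dnode.is_leaf():
            return TreeNode(height=0.0, label=dnode.taxon.label.replace(" ", "_"))
        children = [build(c) for c in dnode.child_nodes()]
        height = max(
            c.height + (cn.edge.length if cn.edge.length is not None else 1.0)
            for c, cn in zip(children, dnode.child_nodes())
        )
        return TreeNode(height=height, children=children)

    return Dendrogram(build(dtree.seed_node))


def read_label_map(path: str | Path) -> dict[str, str]:
    """Two-column TSV mapping external labels to internal taxon ids."""
    out = {}
    for ln in Path(path).read_text(encoding="utf-8").splitlines():
        if not ln.strip() or ln.startswith("#"):
            continue
        a, b = ln.split("\t")[:2]
        out[a.strip()] = b.strip()
    return out


def read_reference(path: str | Path, label_map: dict[str, str] | None = None):
    """Read a reference phylogeny: PHYLIP square matrix or Newick tree.

    Returns a DistanceMatrix or Dendrogram; labels are renamed through
    ``label_map`` when given (unknown labels raise KeyError).
    """
    text = Path(path).read_text(encoding="utf-8").lstrip()
    if text.startswith("("):
        tree = read_newick(path)
        if label_map:
            for node in tree.root.iter_nodes():
                if node.is_leaf:
                    node.label = label_map[node.label]
        return tree
    dm = read_phylip_matrix(path)
    if label_map:
        dm.taxa = [label_map[t] for t in dm.taxa]
    return dm
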