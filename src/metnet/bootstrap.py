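"""Character-resampling support analysis for topology-based dendrograms.

For a grid of ensemble sizes m, characters (metabolite columns of a
feature matrix) are subsampled, a UPGMA tree is rebuilt from Euclidean
distances for each replicate, and each clade of a reference tree is
scored by the percentage of replicate trees in which its exact leaf set
appears as a cluster.  Sampling is without replacement by default
("random combinations" of characters); ``with_replacement=True`` gives
the classical bootstrap.

Reproducibility: a master seed spawns one child RNG per (size-index,
replicate) cell through ``numpy.random.SeedSequence(master, spawn_key=
(size_index, replicate))``, so every cell's subset is independent of the
others yet bit-reproducible.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .features import FeatureMatrix, MetaboliteSet
from .phylo import Dendrogram, euclidean_distances, upgma


@dataclass
class SupportReport:
    """Per-(clade, m) support percentages over bootstrap replicates."""

    clades: list[frozenset[str]]
    sizes: list[int]
    replicates: int
    seed: int
    support: pd.DataFrame = field(repr=False)  # index: clade id, columns: m

    def clade_id(self, clade: frozenset[str]) -> str:
        return "|".join(sorted(clade))

    def to_table(self) -> pd.DataFrame:
        """Long-format table: clade id, leaf set, m, support."""
        rows = []
        for clade in self.clades:
            cid = self.clade_id(clade)
            for m in self.sizes:
                rows.append(
                    {
                        "clade": cid,
                        "n_leaves": len(clade),
                        "m": m,
                        "support": self.support.loc[cid, m],
                    }
                )
        return pd.DataFrame(rows)


def _cell_rng(seed: int, size_index: int, replicate: int) -> np.random.Generator:
    return np.random.default_rng(
        np.random.SeedSequence(seed, spawn_key=(size_index, replicate))
    )


def sample_characters(
    full: MetaboliteSet,
    m: int,
    rng: np.random.Generator | int,
    with_replacement: bool = False,
) -> MetaboliteSet:
    """Uniform sample of m characters, sorted; deterministic given the RNG state."""
    if not 1 <= m <= full.m:
        raise ValueError(f"m must be in [1, {full.m}]")
    if isinstance(rng, int):
        rng = np.random.default_rng(rng)
    idx = rng.choice(full.m, size=m, replace=with_replacement)
    chars = sorted({full.characters[i] for i in idx})
    return MetaboliteSet("custom", tuple(chars))


def replicate_tree(
    fm: FeatureMatrix, subset: MetaboliteSet
) -> Dendrogram:
    """UPGMA tree of Euclidean distances restricted to a character subset."""
    return upgma(euclidean_distances(fm.restrict(subset)))


def support_analysis(
    fm: FeatureMatrix,
    reference: Dendrogram,
    sizes: list[int],
    replicates: int = 100,
    seed: int = 0,
    with_replacement: bool = False,
) -> SupportReport:
    """Clade support of a reference tree under character subsampling.

    For every ensemble size m and replicate, a character subset is drawn,
    a UPGMA tree rebuilt, and each non-trivial reference clade checked for
    exact presence.  Support is the percentage of replicates containing
    the clade.  Singleton clades are omitted (trivially present); the root
    clade is reported and is always 100.
    """
    if not sizes:
        raise ValueError("size grid is empty")
    if replicates < 1:
        raise ValueError("need at least one replicate")
    ref_leaves = set(reference.taxa)
    if not ref_leaves <= set(fm.taxa):
        raise ValueError("reference leaves not covered by the feature matrix")
    if ref_leaves != set(fm.taxa):
        fm = FeatureMatrix(
            fm.metric, fm.characters, fm.values.loc[sorted(ref_leaves)].copy()
        )
    clades = sorted(reference.clades(nontrivial=True), key=lambda c: (len(c), sorted(c)))
    counts = {c: {m: 0 for m in sizes} for c in clades}
    for si, m in enumerate(sizes):
        for rep in range(replicates):
            rng = _cell_rng(seed, si, rep)
            subset = sample_characters(
                fm.characters, m, rng, with_replacement=with_replacement
            )
            tree = replicate_tree(fm, subset)
            found = tree.clades(nontrivial=True)
            for c in clades:
                if c in found:
                    counts[c][m] += 1
    ids = ["|".join(sorted(c)) for c in clades]
    table = pd.DataFrame(
        [[100.0 * counts[c][m] / replicates for m in sizes] for c in clades],
        index=pd.Index(ids, name="clade"),
        columns=sizes,
    )
    return SupportReport(
        clades=clades, sizes=list(sizes), replicates=replicates, seed=seed,
        support=table,
    )
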