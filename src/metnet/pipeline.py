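"""End-to-end orchestration: parse -> build -> metrics -> features ->
distances -> UPGMA -> CPCC -> bootstrap, with a machine-readable report.
"""

from __future__ import annotations

import hashlib
import json
import logging
import sys
from dataclasses import dataclass, field
from pathlib import Path

from . import __version__
from .bootstrap import support_analysis
from .features import (
    FeatureMatrix,
    assemble_features,
    common_reactions,
    common_set,
    full_set,
)
from .network import build_network
from .phylo import (
    Dendrogram,
    DistanceMatrix,
    cpcc,
    euclidean_distances,
    read_label_map,
    read_reference,
    upgma,
    write_phylip_matrix,
)
from .features import pca_project
from .reaction_io import parse_reaction_file, read_synonym_map
from .topology import METRIC_NAMES, compute_global_metrics, compute_node_metrics

logger = logging.getLogger("metnet")


@dataclass
class RunConfig:
    """Validated pipeline configuration.

    ``reactions`` maps taxon id to a reaction-file path.  ``pca_components``
    of None means full rank (distance-identical to the raw vectors).
    """

    reactions: dict[str, str]
    out_dir: str
    metrics: list[str] = field(default_factory=lambda: list(METRIC_NAMES))
    character_set: str = "common"  # "common" | "full"
    pca_components: int | None = None
    dialect: str = "tsv"
    synonyms: str | None = None
    reference: str | None = None
    reference_label_map: str | None = None
    bootstrap_sizes: list[int] = field(default_factory=list)
    bootstrap_replicates: int = 100
    seed: int = 0

    def validate(self) -> None:
        if not self.reactions:
            raise ValueError("no reaction files configured")
        for taxon, path in self.reactions.items():
            if not Path(path).exists():
                raise FileNotFoundError(f"reaction file for {taxon!r}: {path}")
        unknown = set(self.metrics) - set(METRIC_NAMES)
        if unknown:
            raise ValueError(f"unknown metrics: {sorted(unknown)}")
        if self.character_set not in ("common", "full"):
            raise ValueError("character_set must be 'common' or 'full'")
        for opt in ("reference", "reference_label_map", "synonyms"):
            p = getattr(self, opt)
            if p is not None and not Path(p).exists():
                raise FileNotFoundError(f"{opt}: {p}")

    @classmethod
    def from_json(cls, path: str | Path) -> "RunConfig":
        data = json.loads(Path(path).read_text(encoding="utf-8"))
        return cls(**data)

    def config_hash(self) -> str:
        # out_dir excluded: the hash identifies the scientific configuration,
        # so identical runs to different directories produce identical reports
        payload = {k: v for k, v in self.__dict__.items() if k != "out_dir"}
        blob = json.dumps(payload, sort_keys=True, default=str)
        return hashlib.sha256(blob.encode()).hexdigest()[:12]


def run_pipeline(cfg: RunConfig) -> dict:
    """Execute the full pipeline; returns (and writes) the run report."""
    cfg.validate()
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    _setup_logging(out / "run.log")
    logger.info(
        "metnet %s | seed=%d | config=%s", __version__, cfg.seed, cfg.config_hash()
    )
    report: dict = {
        "version": __version__,
        "seed": cfg.seed,
        "config_hash": cfg.config_hash(),
        "stages": [],
    }

    synonyms = read_synonym_map(cfg.synonyms) if cfg.synonyms else None
    reaction_sets, networks, tables = {}, {}, {}
    for taxon in sorted(cfg.reactions):
        rs = parse_reaction_file(
            cfg.reactions[taxon], cfg.dialect, taxon_id=taxon, synonym_map=synonyms
        )
        reaction_sets[taxon] = rs
        networks[taxon] = build_network(rs)
        tables[taxon] = compute_node_metrics(networks[taxon])
        logger.info(
            "%s: R=%d N=%d E=%d", taxon, rs.reaction_count,
            networks[taxon].n_nodes, networks[taxon].n_edges,
        )
    report["stages"].append("parse+build+metrics")

    nets = [networks[t] for t in sorted(networks)]
    cset = common_set(nets) if len(nets) > 1 else full_set(nets)
    fset = full_set(nets)
    characters = cset if cfg.character_set == "common" else fset
    report["set_sizes"] = {
        "common": cset.m,
        "full": fset.m,
        "common_reactions": len(common_reactions(list(reaction_sets.values())))
        if len(reaction_sets) > 1
        else len(next(iter(reaction_sets.values())).records),
    }
    report["taxa"] = {
        t: {
            "N": networks[t].n_nodes,
            "R": reaction_sets[t].reaction_count,
            "mean_degree": compute_global_metrics(networks[t]).mean_degree,
        }
        for t in sorted(networks)
    }

    reference = None
    ref_dm: DistanceMatrix | None = None
    if cfg.reference:
        label_map = (
            read_label_map(cfg.reference_label_map)
            if cfg.reference_label_map
            else None
        )
        reference = read_reference(cfg.reference, label_map)
        ref_dm = (
            reference.cophenetic_matrix()
            if isinstance(reference, Dendrogram)
            else reference
        )
    else:
        logger.info("no reference phylogeny configured: CPCC stage skipped")

    report["cpcc"] = {}
    trees: dict[str, Dendrogram] = {}
    feature_matrices: dict[str, FeatureMatrix] = {}
    for metric in cfg.metrics:
        fm = assemble_features(tables, metric, characters)
        feature_matrices[metric] = fm
        if cfg.pca_components is not None:
            scores, _ = pca_project(fm, cfg.pca_components)
            dm = euclidean_distances(scores)
        else:
            dm = euclidean_distances(fm)
        tree = upgma(dm)
        trees[metric] = tree
        (out / f"tree_{metric}.nwk").write_text(
            tree.to_newick() + "\n", encoding="utf-8"
        )
        write_phylip_matrix(dm, out / f"distances_{metric}.phy")
        if ref_dm is not None:
            coph = tree.cophenetic_matrix()
            report["cpcc"][metric] = {
                "dendrogram": round(cpcc(coph, ref_dm), 10),
                "raw": round(cpcc(dm, ref_dm), 10),
            }
        logger.info("metric %s: tree written", metric)
    report["stages"].append("features+trees")

    if cfg.bootstrap_sizes:
        metric = cfg.metrics[0]
        fm_full = assemble_features(tables, metric, fset)
        ref_tree = (
            reference if isinstance(reference, Dendrogram) else trees[metric]
        )
        sr = support_analysis(
            fm_full,
            ref_tree,
            sizes=cfg.bootstrap_sizes,
            replicates=cfg.bootstrap_replicates,
            seed=cfg.seed,
        )
        sr.to_table().to_csv(out / "support.tsv", sep="\t", index=False)
        report["support_metric"] = metric
        report["support_max_m"] = {
            cid: float(sr.support.loc[cid, sr.sizes[-1]]) for cid in sr.support.index
        }
        report["stages"].append("bootstrap")

    (out / "report.json").write_text(
        json.dumps(report, indent=2, sort_keys=True) + "\n", encoding="utf-8"
    )
    return report


def _setup_logging(log_path: Path) -> None:
    if logger.handlers:
        return
    logger.setLevel(logging.INFO)
    fmt = logging.Formatter("%(asctime)s %(levelname)s %(message)s")
    for handler in (logging.StreamHandler(sys.stderr), logging.FileHandler(log_path)):
        handler.setFormatter(fmt)
        logger.addHandler(handler)
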