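"""Published reference values of the 17-plant PlantCyc study.

The method was originally applied to the metabolic reaction exports of
17 plants (PlantCyc v9.5) spanning chlorophytes, bryophytes, lycophytes,
monocots and dicots.  The curated reaction exports themselves are
distributed as supplementary data of the original publication and are
not bundled here; this module records the published summary numbers so
that reports and worked examples can state what a full rerun on those
inputs is expected to reproduce.
"""

from __future__ import annotations

#: Taxon code -> species, grouped by clade.
TAXA: dict[str, str] = {
    "BD": "Brachypodium distachyon",
    "HV": "Hordeum vulgare",
    "OSJ": "Oryza sativa japonica",
    "PV": "Panicum virgatum",
    "SI": "Setaria italica",
    "SB": "Sorghum bicolor",
    "ZM": "Zea mays",
    "AT": "Arabidopsis thaliana col",
    "BRP": "Brassica rapa pekinensis",
    "CP": "Carica papaya",
    "GM": "Glycine max",
    "ME": "Manihot esculenta",
    "PT": "Populus trichocarpa",
    "VV": "Vitis vinifera",
    "SM": "Selaginella moellendorffii",
    "PP": "Physcomitrella patens",
    "CR": "Chlamydomonas reinhardtii",
}

CLADES: dict[str, str] = {
    **{t: "Monocotyledons" for t in ("BD", "HV", "OSJ", "PV", "SI", "SB", "ZM")},
    **{t: "Dicotyledons" for t in ("AT", "BRP", "CP", "GM", "ME", "PT", "VV")},
    "SM": "Lycophytes",
    "PP": "Bryophytes",
    "CR": "Chlorophytes",
}

#: Network-size extremes over the 17 taxa (metabolite counts).
SMALLEST_NETWORK = ("CR", 2433)
LARGEST_NETWORK = ("AT", 3546)
SMALLEST_REACTIONS = ("CR", 2208)
LARGEST_REACTIONS = ("AT", 3424)

#: Character-set sizes.
COMMON_METABOLITES = 1880
FULL_METABOLITES = 4583
COMMON_REACTIONS = 1149

#: Mean per-taxon counts.
MEAN_METABOLITES = 2923
MEAN_REACTIONS = 2696

#: Published CPCC of each metric's UPGMA dendrogram (common set) against
#: the plastid-gene distance matrix.
CPCC_BY_METRIC: dict[str, float] = {
    "hub": 0.88,
    "degree": 0.85,
    "in_degree": 0.85,
    "out_degree": 0.88,
    "clustering": -0.11,
    "authority": 0.71,
    "efficiency": -0.19,
    "betweenness": 0.72,
    "eigencentrality": 0.29,
}
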