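"""Packaged study fixtures: the annotated gene table and segregation table.

Two small data sets ship with the package:

* the 20-gene annotated dictionary of the target organism (*O. alaskensis*
  G20), sub-categorized under six pathways, with GO terms (aspects filled
  in from the standard Gene Ontology definitions of the listed IDs);
* the 116-gene pathway × partition table from the pangenome segregation
  of the enriched gene set (counts per row: sulfur 12/4/2, ribosome
  27/3/1, nucleotide 25/3/2, transporters 2/6/4, energy 8/6/1,
  two-component 7/3/0; grand totals 81/25/10).

Also packaged are two synthetic reconstructions of inputs that were never
machine-published: a mined-symbol list shaped like the literature funnel
(91 symbols → 42 mapped → 22 redundant → 20 retained) and a small
pathway-clustered interaction network in which the sulfate
adenylyltransferase gene dde_2265 (*sat*) bridges every other pathway
cluster.  Both are synthetic stand-ins built to match the published
arithmetic, not recovered source data.
"""

from __future__ import annotations

import networkx as nx
import pandas as pd

from .annotate import GeneDictionary, GeneRecord, build_dictionary

__all__ = [
    "gene_table_records",
    "gene_table_dictionary",
    "segregation_gene_table",
    "funnel_dictionary",
    "mined_symbols",
    "bridging_network",
    "load_fixtures",
]

_MF = "molecular_function"
_BP = "biological_process"
_CC = "cellular_component"

_SULFUR = "sulfur metabolism"
_RIBO = "ribosome synthesis"
_NUC = "nucleotide metabolism"
_TRANS = "transporters"
_ENERGY = "energy metabolism"
_TCS = "two-component system"

# locus tag, symbol, synonyms, product, pathway, GO terms (id, aspect)
_GENE_TABLE = [
    ("dde_0527", "dsvB", ("dsrB",),
     "Sulfite reductase, dissimilatory-type beta subunit", _SULFUR,
     (("GO:0006790", _BP), ("GO:0009055", _MF), ("GO:0018551", _MF),
      ("GO:0020037", _MF), ("GO:0046872", _MF), ("GO:0051539", _MF))),
    ("dde_0526", "dsrA", (),
     "Sulfite reductase, dissimilatory-type alpha subunit", _SULFUR,
     (("GO:0018551", _MF), ("GO:0020037", _MF), ("GO:0046872", _MF),
      ("GO:0051539", _MF))),
    ("dde_3080", "cysL", ("cysI",),
     "Cysteine synthase A", _SULFUR,
     (("GO:0004124", _MF), ("GO:0006535", _BP))),
    ("dde_1110", "aprA", (),
     "Cysteine synthase A", _SULFUR,
     (("GO:0016491", _MF),)),
    ("dde_1109", "aprB", (),
     "Cysteine synthase A", _SULFUR,
     (("GO:0046872", _MF), ("GO:0051536", _MF))),
    ("dde_0762", "dsrC", (),
     "Sulfite reductase, dissimilatory-type gamma subunit", _SULFUR,
     (("GO:0005737", _CC), ("GO:0018551", _MF))),
    ("dde_1789", "cysH", (),
     "Phosphoadenosine phosphosulfate reductase", _SULFUR,
     (("GO:0003824", _MF),)),
    ("dde_2265", "sat", (),
     "Sulfate adenylyltransferase", _SULFUR,
     (("GO:0000103", _BP), ("GO:0004781", _MF), ("GO:0005524", _MF))),
    ("dde_3519", "modB", (),
     "Molybdate ABC transporter, inner membrane subunit", _TRANS,
     (("GO:0005886", _CC), ("GO:0015098", _MF), ("GO:0016021", _CC))),
    ("dde_0155", "modA", (),
     "Molybdenum ABC transporter, periplasmic molybdate-binding protein",
     _TRANS, (("GO:0015689", _BP), ("GO:0046872", _MF))),
    ("dde_3518", "modC", (),
     "Molybdenum ABC transporter, periplasmic molybdate-binding protein",
     _TRANS,
     (("GO:0015689", _BP), ("GO:0030973", _MF), ("GO:0046872", _MF))),
    ("dde_0717", "cyc", (),
     "Formate dehydrogenase, alpha subunit", _ENERGY,
     (("GO:0008863", _MF), ("GO:0008940", _MF), ("GO:0009055", _MF),
      ("GO:0042597", _CC), ("GO:0043546", _MF), ("GO:0045333", _BP),
      ("GO:0046872", _MF), ("GO:0047111", _MF), ("GO:0051539", _MF))),
    ("dde_0680", "dsrM", (),
     "Cytochrome b/b6 domain-containing protein", _ENERGY,
     (("GO:0005886", _CC), ("GO:0009055", _MF), ("GO:0016021", _CC),
      ("GO:0022904", _BP))),
    ("dde_0652", "hmcB", (),
     "Formate dehydrogenase iron-sulfur subunit", _ENERGY,
     (("GO:0046872", _MF), ("GO:0051536", _MF))),
    ("dde_1209", "hdrA", ("qmoA",),
     "4Fe-4S ferredoxin iron-sulfur binding domain-containing", _ENERGY,
     (("GO:0016491", _MF), ("GO:0046872", _MF), ("GO:0051536", _MF))),
    ("dde_1208", "hdrB", ("qmoB",),
     "Heterodisulfide reductase, C subunit", _ENERGY,
     (("GO:0051912", _MF),)),
    ("dde_2066", "trx", (),
     "Thioredoxin reductase", _RIBO,
     (("GO:0004791", _MF), ("GO:0005737", _CC), ("GO:0019430", _BP))),
    ("dde_1448", "upp", (),
     "Uracil phosphoribosyltransferase", _NUC,
     (("GO:0000287", _MF), ("GO:0004845", _MF), ("GO:0005525", _MF),
      ("GO:0006223", _BP), ("GO:0009116", _BP), ("GO:0044206", _BP))),
    ("dde_2134", "hydA", (),
     "Hydrogenase (NiFe) small subunit HydA", _TCS,
     (("GO:0008901", _MF), ("GO:0009375", _CC), ("GO:0042597", _CC),
      ("GO:0046872", _MF), ("GO:0047806", _MF), ("GO:0051538", _MF),
      ("GO:0051539", _MF))),
    ("dde_2135", "hydB", (),
     "Periplasmic (NiFeSe) hydrogenase, large subunit, "
     "selenocysteine-containing", _TCS,
     (("GO:0008901", _MF), ("GO:0016151", _MF), ("GO:0047806", _MF))),
]


def gene_table_records() -> list[GeneRecord]:
    """The 20 annotated genes of the study's curated table."""
    return [
        GeneRecord(locus_tag=t, symbol=s, synonyms=syn, product=p,
                   pathway=w, go_terms=go)
        for t, s, syn, p, w, go in _GENE_TABLE
    ]


def gene_table_dictionary() -> GeneDictionary:
    """The 20-gene dictionary built from the curated table."""
    return build_dictionary(gene_table_records())


# pathway -> partition -> genes; transcribed from the published segregation
_SEGREGATION = {
    _SULFUR: {
        "persistent": [
            "dde_0762", "dde_1109", "dde_1110", "dde_0527", "dde_0526",
            "dde_2271", "dde_3081", "dde_1112", "dde_2115", "dde_2265",
            "dde_3080", "dde_0528",
        ],
        "shell": ["dde_1789", "sucD", "dde_3604", "dde_1258"],
        "cloud": ["dde_0123", "dde_0276"],
    },
    _RIBO: {
        "persistent": [
            "rpsM", "rpsE", "rpsD", "fbp", "rpsR", "rpsK", "bamD", "rpmJ",
            "rplO", "rplQ", "rpmD", "rplS", "rpsP", "rplF", "polA", "rplR",
            "rpsH", "secY", "tsaD", "rplI", "rpsF", "dde_0002", "dde_2067",
            "dde_2063", "dde_2225", "dde_1390", "dde_2066",
        ],
        "shell": ["bamA", "dde_0210", "dde_2560"],
        "cloud": ["dde_2064"],
    },
    _NUC: {
        "persistent": [
            "pyrG", "prs", "ispH", "pyrH", "pyrC", "aroA", "pyrF", "pyrE",
            "pyrB", "glyA", "ndk", "frr", "pcm", "pyrR", "tmk", "upp",
            "surE", "hisC", "cmk", "dde_1449", "dde_2453", "dde_2112",
            "dde_1537", "dde_2120", "dde_1569",
        ],
        "shell": ["carA", "dde_2631", "tsf"],
        "cloud": ["dde_0140", "dde_0789"],
    },
    _TRANS: {
        "persistent": ["moaA", "moaC"],
        "shell": [
            "dde_3228", "dde_0154", "dde_3518", "dde_0513", "dde_3519",
            "dde_3520",
        ],
        "cloud": ["dde_0871", "dde_3517", "dde_0155", "dde_1055"],
    },
    _ENERGY: {
        "persistent": [
            "dde_3513", "dde_0812", "dde_1208", "dde_3514", "dde_1207",
            "dde_0718", "dde_0652", "dde_1209",
        ],
        "shell": [
            "dde_0813", "dde_0717", "dde_0706", "dde_1211", "dde_1210",
            "dde_0680",
        ],
        "cloud": ["dde_3515"],
    },
    _TCS: {
        "persistent": [
            "dde_3756", "dde_3237", "dde_3755", "dde_2138", "dde_0364",
            "dde_2139", "dde_2137",
        ],
        "shell": ["dde_2135", "dde_2136", "dde_2134"],
        "cloud": [],
    },
}


def segregation_gene_table() -> pd.DataFrame:
    """The 116 enriched genes with pathway and pangenome partition."""
    rows = [
        {"gene": g, "pathway": pathway, "partition": partition}
        for pathway, parts in _SEGREGATION.items()
        for partition, genes in parts.items()
        for g in genes
    ]
    return pd.DataFrame(rows, columns=["gene", "pathway", "partition"])


# Synthetic near-duplicate records for the literature funnel: distinct
# (invented) locus tags carrying the same product as a curated gene within
# the same symbol family — the "different name with same functionality"
# redundancy class.
_DUPLICATE_RECORDS = [
    ("dde_2597", "dsrA2", "Sulfite reductase, dissimilatory-type alpha subunit", _SULFUR),
    ("dde_2598", "dsvB2", "Sulfite reductase, dissimilatory-type beta subunit", _SULFUR),
    ("dde_2599", "dsrC2", "Sulfite reductase, dissimilatory-type gamma subunit", _SULFUR),
    ("dde_2600", "sat2", "Sulfate adenylyltransferase", _SULFUR),
    ("dde_2601", "cysH2", "Phosphoadenosine phosphosulfate reductase", _SULFUR),
    ("dde_2602", "trx2", "Thioredoxin reductase", _RIBO),
    ("dde_2603", "upp2", "Uracil phosphoribosyltransferase", _NUC),
    ("dde_2604", "modB2", "Molybdate ABC transporter, inner membrane subunit", _TRANS),
    ("dde_2605", "cyc2", "Formate dehydrogenase, alpha subunit", _ENERGY),
    ("dde_2606", "hdrB2", "Heterodisulfide reductase, C subunit", _ENERGY),
]

# Mined symbols that resolve to an already-listed locus tag (synonyms and
# case variants) — the "appeared twice" redundancy class.
_LOCUS_DUPLICATE_SYMBOLS = [
    "dsrB", "DsrA", "cysI", "qmoA", "qmoB", "Sat", "CysH", "AprA", "AprB",
    "ModA", "HydA", "HydB",
]

# Mined symbols with no homolog in the target genome (synthetic stand-in
# for the genes "not evolutionary homologous" to the genus).
_UNMAPPED_SYMBOLS = [
    "hynA", "hynB", "hysA", "hysB", "cooS", "cooH", "cooL", "fdnG", "fdoH",
    "nrfA", "nrfH", "napA", "cheA", "cheB", "fliC", "flgE", "motA", "pilA",
    "ftsZ", "mreB", "rodA", "dnaA", "dnaN", "gyrA", "gyrB", "recJ", "ruvA",
    "ruvB", "lexA", "uvrA", "tatA", "tatB", "secA", "ftsK", "minD", "parA",
    "soxB", "katG", "ahpC", "sodB", "feoB", "zupT", "corA", "mgtE", "nikA",
    "cbiK", "cobN", "hemB", "bioB",
]


def funnel_dictionary() -> GeneDictionary:
    """Synthetic funnel dictionary: 20 curated + 10 near-duplicate records."""
    records = gene_table_records() + [
        GeneRecord(locus_tag=t, symbol=s, product=p, pathway=w)
        for t, s, p, w in _DUPLICATE_RECORDS
    ]
    return build_dictionary(records)


def mined_symbols() -> list[str]:
    """Synthetic 91-symbol mined list shaped like the literature funnel.

    Against :func:`funnel_dictionary`, 42 symbols map into the genome; 22
    of the mapped entries are redundant (12 repeat a locus tag, 10 repeat
    a product within a symbol family) leaving the 20 curated genes.
    """
    canonical = [rec.symbol for rec in gene_table_records()]
    dup_product = [s for _, s, _, _ in _DUPLICATE_RECORDS]
    return canonical + _LOCUS_DUPLICATE_SYMBOLS + dup_product + list(_UNMAPPED_SYMBOLS)


# within-pathway edges of the synthetic bridging-network fixture
_CLUSTER_EDGES = {
    _SULFUR: [
        ("dde_0526", "dde_0527"), ("dde_0526", "dde_0762"),
        ("dde_0527", "dde_0762"), ("dde_1109", "dde_1110"),
        ("dde_1110", "dde_2265"), ("dde_1109", "dde_2265"),
        ("dde_2265", "dde_3080"), ("dde_2265", "dde_1789"),
        ("dde_0526", "dde_2265"),
    ],
    _RIBO: [("dde_2066", "rpsM"), ("dde_2066", "rplF"), ("rpsM", "rplF")],
    _NUC: [("dde_1448", "pyrB"), ("dde_1448", "ndk"), ("pyrB", "ndk")],
    _TRANS: [("dde_0155", "dde_3518"), ("dde_3518", "dde_3519"),
             ("dde_0155", "dde_3519")],
    _ENERGY: [("dde_0717", "dde_0680"), ("dde_1208", "dde_1209"),
              ("dde_0717", "dde_1209")],
    _TCS: [("dde_2134", "dde_2135")],
}

# cross-pathway edges: sat (dde_2265) reaches every other cluster; a couple
# of single-pathway bridges keep it from being the only cross-wired node
_CROSS_EDGES = [
    ("dde_2265", "dde_2066"), ("dde_2265", "dde_1448"),
    ("dde_2265", "dde_0155"), ("dde_2265", "dde_1209"),
    ("dde_2265", "dde_2134"),
    ("dde_0526", "dde_2134"),  # dsrA interacts with the two-component genes
    ("dde_0717", "dde_1448"),
]


def bridging_network() -> tuple[nx.Graph, dict[str, str]]:
    """Synthetic pathway-clustered network with dde_2265 as the bridge.

    Returns the scored graph and the node → pathway map.  Shaped after the
    published enriched-network figure: one cluster per pathway, with the
    *sat* gene wired into all five foreign clusters.
    """
    graph = nx.Graph()
    pathway_map: dict[str, str] = {}
    for pathway, edges in _CLUSTER_EDGES.items():
        for a, b in edges:
            graph.add_edge(a, b, combined_score=0.9, textmining_score=0.7,
                           experimental_score=0.6)
            pathway_map.setdefault(a, pathway)
            pathway_map.setdefault(b, pathway)
    for a, b in _CROSS_EDGES:
        graph.add_edge(a, b, combined_score=0.8, textmining_score=0.5,
                       experimental_score=0.4)
    for n, p in pathway_map.items():
        graph.nodes[n]["pathway"] = p
    return graph, pathway_map


def enrichment_fixture_graph() -> nx.Graph:
    """Six-node background graph for exhaustive enrichment-test oracles.

    Small enough that the null over all same-size node subsets can be
    enumerated exactly.
    """
    graph = nx.Graph()
    graph.add_nodes_from("abcdef")
    for a, b in [("a", "b"), ("b", "c"), ("c", "d"), ("d", "e"), ("e", "f"),
                 ("f", "a"), ("a", "c"), ("d", "f")]:
        graph.add_edge(a, b, combined_score=0.9, textmining_score=0.5,
                       experimental_score=0.5)
    return graph


def load_fixtures() -> tuple[GeneDictionary, pd.DataFrame]:
    """The packaged (gene dictionary, per-gene partition table) pair."""
    return gene_table_dictionary(), segregation_gene_table()
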