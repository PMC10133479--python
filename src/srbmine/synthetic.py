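"""Synthetic generators for every input the pipeline consumes.

The study's raw inputs — a literature corpus with gene mentions, a scored
protein–protein interaction network, and a gene-family × genome
presence/absence matrix with its contiguity graph — are not
machine-published, so this module generates statistically structured
stand-ins: a document corpus with planted mentions and decoy tokens, a
pathway-clustered random graph with STRING-like channel scores, and a
presence/absence matrix drawn from a planted multivariate Bernoulli
mixture whose true labels are returned for parameter-recovery tests.

One global integer seed feeds an independent child stream per generator
(via ``numpy.random.default_rng([seed, stream])``), so sub-experiments are
reproducible in isolation: fixing the seed fixes every artifact
bit-for-bit.
"""

from __future__ import annotations

import string
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .annotate import (
    AnnotatedDocument,
    GeneDictionary,
    GeneRecord,
    Mention,
    build_dictionary,
)

__all__ = [
    "ComponentSpec",
    "SimulationConfig",
    "PlantedTruth",
    "generate_gene_dictionary",
    "generate_corpus",
    "generate_ppi_network",
    "generate_pangenome",
    "PATHWAYS",
]

# The six pathway categories of the essential-gene study.
PATHWAYS = (
    "sulfur metabolism",
    "ribosome synthesis",
    "nucleotide metabolism",
    "transporters",
    "energy metabolism",
    "two-component system",
)

_GO_ASPECTS = ("molecular_function", "biological_process", "cellular_component")

# Filler vocabulary for synthetic prose; none of these survive as gene-like
# tokens (generated symbols always contain an uppercase letter or digit).
_FILLER = (
    "the growth of anaerobic cultures was monitored under sulfate reduction "
    "conditions and the expression profile suggested a role in electron "
    "transfer across the membrane while lactate served as donor during "
    "biofilm formation on metal surfaces in media with added molybdate "
    "where mutants showed impaired colony development and the operon was "
    "transcribed together with neighboring loci under stress"
).split()
_FILLER_SET = frozenset(_FILLER)


@dataclass(frozen=True)
class ComponentSpec:
    """One mixture component of the planted pangenome.

    ``p`` is the per-genome presence probability.  If ``block`` is given as
    ``(p_in, p_out)`` the component uses a genome-block pattern: probability
    ``p_in`` inside a contiguous half of the genomes and ``p_out`` outside —
    the environment-dependent "shell" structure — and ``p`` is ignored.
    """

    label: str
    weight: float
    p: float = 0.5
    block: tuple[float, float] | None = None

    def probs(self, n_genomes: int) -> np.ndarray:
        if self.block is None:
            return np.full(n_genomes, self.p)
        p_in, p_out = self.block
        probs = np.full(n_genomes, p_out)
        probs[: n_genomes // 2] = p_in
        return probs


def _default_mixture() -> tuple[ComponentSpec, ...]:
    return (
        ComponentSpec("persistent", 0.5, p=0.98),
        ComponentSpec("shell", 0.3, block=(0.9, 0.05)),
        ComponentSpec("cloud", 0.2, p=0.03),
    )


@dataclass
class SimulationConfig:
    """Knobs for every generator, with the study-shaped defaults.

    Defaults: 50 documents at 4 mentions/document with a 0.1 decoy
    fraction; 300 families × 40 genomes from a 3-component mixture
    (persistent ≈0.98, block shell 0.9/0.05, cloud 0.03); pathway-clustered
    PPI graph at within/between densities 0.6/0.02.
    """

    seed: int = 0
    n_genes: int = 60
    pathway_quotas: tuple[int, ...] | None = None
    n_docs: int = 50
    mention_rate: float = 4.0
    decoy_rate: float = 0.1
    n_families: int = 300
    n_genomes: int = 40
    mixture_spec: tuple[ComponentSpec, ...] = field(default_factory=_default_mixture)
    contiguity_prob: float = 0.05
    cross_contiguity_factor: float = 0.1
    cluster_density: float = 0.6
    background_density: float = 0.02

    def __post_init__(self) -> None:
        for name in ("n_genes", "n_docs", "n_families", "n_genomes"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be positive, got {getattr(self, name)}")
        for name in (
            "decoy_rate",
            "contiguity_prob",
            "cluster_density",
            "background_density",
        ):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {v}")
        if self.mention_rate < 0:
            raise ValueError("mention_rate must be non-negative")
        if self.pathway_quotas is not None:
            if len(self.pathway_quotas) != len(PATHWAYS):
                raise ValueError(
                    f"pathway_quotas needs {len(PATHWAYS)} entries"
                )
            if sum(self.pathway_quotas) != self.n_genes:
                raise ValueError("pathway_quotas must sum to n_genes")
        if len(self.mixture_spec) < 1:
            raise ValueError("mixture_spec must have at least one component")
        w = sum(c.weight for c in self.mixture_spec)
        if abs(w - 1.0) > 1e-9:
            raise ValueError(f"mixture weights must sum to 1, got {w}")
        for c in self.mixture_spec:
            ps = [c.p] if c.block is None else list(c.block)
            if any(not 0.0 <= p <= 1.0 for p in ps):
                raise ValueError(f"component {c.label}: probabilities outside [0,1]")

    def rng(self, stream: int) -> np.random.Generator:
        """Independent child stream; streams 0–3 feed the four generators."""
        return np.random.default_rng([self.seed, stream])


@dataclass
class PlantedTruth:
    """Ground truth planted by the generators.

    ``family_labels`` maps family id → mixture component label;
    ``gold_mentions`` maps doc_id → gold mention list; ``gene_pathways``
    maps locus tag → pathway.
    """

    family_labels: dict[str, str] = field(default_factory=dict)
    gold_mentions: dict[str, list[Mention]] = field(default_factory=dict)
    gene_pathways: dict[str, str] = field(default_factory=dict)


def _make_symbol(rng: np.random.Generator) -> str:
    """A gene-symbol-shaped token: 3 lowercase letters + uppercase letter."""
    stem = "".join(rng.choice(list(string.ascii_lowercase), size=3))
    return stem + rng.choice(list(string.ascii_uppercase))


def generate_gene_dictionary(config: SimulationConfig) -> GeneDictionary:
    """Generate an organism gene dictionary with the study's table schema.

    Locus tags follow the ``dde_`` + 4-digit pattern; each record carries a
    primary symbol, 0–3 synonyms, a product name, one of the six pathways,
    and 1–4 GO terms with aspects.  ``pathway_quotas`` fixes the pathway
    census exactly; otherwise pathways are drawn uniformly.
    """
    rng = config.rng(0)
    n = config.n_genes
    tags = [f"dde_{i:04d}" for i in rng.choice(10000, size=n, replace=False)]
    if config.pathway_quotas is not None:
        pathways = [
            p for p, q in zip(PATHWAYS, config.pathway_quotas) for _ in range(q)
        ]
    else:
        pathways = [PATHWAYS[i] for i in rng.integers(0, len(PATHWAYS), size=n)]
    seen: set[str] = set()
    records = []
    for tag, pathway in zip(tags, pathways):
        while True:
            symbol = _make_symbol(rng)
            # avoid surfaces that casefold onto corpus filler words
            if symbol.casefold() not in seen and symbol.casefold() not in _FILLER_SET:
                break
        seen.add(symbol.casefold())
        synonyms = []
        for _ in range(int(rng.integers(0, 4))):
            syn = _make_symbol(rng) + str(rng.integers(1, 10))
            if syn.casefold() not in seen:
                seen.add(syn.casefold())
                synonyms.append(syn)
        go_terms = tuple(
            (f"GO:{int(rng.integers(1, 10**7)):07d}", rng.choice(_GO_ASPECTS))
            for _ in range(int(rng.integers(1, 5)))
        )
        records.append(
            GeneRecord(
                locus_tag=tag,
                symbol=symbol,
                synonyms=tuple(synonyms),
                product=f"{symbol} family protein",
                pathway=pathway,
                go_terms=go_terms,
            )
        )
    return build_dictionary(records)


def _decoy_token(rng: np.random.Generator, dictionary: GeneDictionary) -> str:
    """A gene-look-alike token guaranteed absent from the dictionary."""
    while True:
        tok = _make_symbol(rng)
        if tok.casefold() not in dictionary.lookup:
            return tok


def generate_corpus(
    dictionary: GeneDictionary, config: SimulationConfig
) -> tuple[list[AnnotatedDocument], PlantedTruth]:
    """Generate free-text documents with planted gene mentions.

    Gold mention counts per document are Poisson(``mention_rate``); decoy
    tokens (gene-shaped, not in the dictionary) are added at
    Poisson(``mention_rate · decoy_rate / (1 − decoy_rate)``) so decoys make
    up the configured fraction of gene-like tokens in expectation.  Gold
    spans are recorded at exact 0-based half-open offsets and never overlap.
    """
    if len(dictionary) == 0:
        raise ValueError("dictionary is empty")
    rng = config.rng(1)
    all_surfaces = [
        s for rec in dictionary.records.values() for s in (rec.symbol, *rec.synonyms)
    ]
    decoy_mean = (
        config.mention_rate * config.decoy_rate / (1.0 - config.decoy_rate)
        if config.decoy_rate < 1.0
        else config.mention_rate
    )
    docs: list[AnnotatedDocument] = []
    truth = PlantedTruth(
        gene_pathways={t: r.pathway for t, r in dictionary.records.items()}
    )
    for d in range(config.n_docs):
        doc_id = f"doc_{d:04d}"
        n_gold = int(rng.poisson(config.mention_rate))
        n_decoy = int(rng.poisson(decoy_mean))
        # token stream: filler words with gene/decoy tokens interspersed
        specials: list[tuple[str, bool]] = [
            (str(rng.choice(all_surfaces)), True) for _ in range(n_gold)
        ] + [(_decoy_token(rng, dictionary), False) for _ in range(n_decoy)]
        rng.shuffle(specials)
        parts: list[str] = []
        gold: list[Mention] = []
        pos = 0
        for surface, is_gold in specials:
            n_fill = int(rng.integers(2, 7))
            filler = " ".join(rng.choice(_FILLER) for _ in range(n_fill))
            prefix = filler + " "
            pos += len(prefix)
            if is_gold:
                tag = dictionary.resolve(surface)
                assert tag is not None
                gold.append(Mention(pos, pos + len(surface), surface, tag))
            parts.append(prefix + surface)
            pos += len(surface) + 1  # joining space
        tail = " ".join(rng.choice(_FILLER) for _ in range(int(rng.integers(2, 7))))
        text = " ".join(parts + [tail]) if parts else tail
        docs.append(AnnotatedDocument(doc_id=doc_id, text=text, mentions=list(gold)))
        truth.gold_mentions[doc_id] = gold
    return docs, truth


def generate_ppi_network(
    dictionary: GeneDictionary, config: SimulationConfig
):
    """Generate a pathway-clustered scored interaction network.

    Within-pathway pairs receive an edge with probability
    ``cluster_density``, cross-pathway pairs with ``background_density``.
    Each edge carries ``combined`` (uniform on [0.4, 1]), ``textmining`` and
    ``experimental`` (uniform on [0, 1]) scores.  Returns a
    ``networkx.Graph`` with node attribute ``pathway``.
    """
    import networkx as nx

    if len(dictionary) == 0:
        raise ValueError("dictionary is empty")
    rng = config.rng(2)
    graph = nx.Graph()
    tags = sorted(dictionary.records)
    for tag in tags:
        graph.add_node(tag, pathway=dictionary.records[tag].pathway)
    for i, a in enumerate(tags):
        for b in tags[i + 1 :]:
            same = dictionary.records[a].pathway == dictionary.records[b].pathway
            density = config.cluster_density if same else config.background_density
            if rng.random() < density:
                graph.add_edge(
                    a,
                    b,
                    combined_score=round(0.4 + 0.6 * rng.random(), 3),
                    textmining_score=round(rng.random(), 3),
                    experimental_score=round(rng.random(), 3),
                )
    return graph


def generate_pangenome(
    config: SimulationConfig,
) -> tuple[pd.DataFrame, "object", PlantedTruth]:
    """Generate a planted presence/absence matrix and contiguity graph.

    Each family's component is drawn from the mixture weights; its row is
    independent Bernoulli per genome with the component's per-genome
    probabilities.  Contiguity edges link same-component family pairs with
    probability ``contiguity_prob`` and cross-component pairs with
    ``contiguity_prob · cross_contiguity_factor``.

    Returns ``(matrix, graph, truth)`` where ``matrix`` is a binary
    families × genomes DataFrame and ``graph`` a ``networkx.Graph``.
    """
    import networkx as nx

    if len(config.mixture_spec) >= 2:
        means = [float(np.mean(c.probs(config.n_genomes))) for c in config.mixture_spec]
        if len(set(np.round(means, 12))) != len(means):
            raise ValueError("mixture components must have distinct mean presence probabilities")
    rng = config.rng(3)
    F, G = config.n_families, config.n_genomes
    weights = np.array([c.weight for c in config.mixture_spec])
    comp_idx = rng.choice(len(weights), size=F, p=weights)
    probs = np.stack([c.probs(G) for c in config.mixture_spec])  # K x G
    X = (rng.random((F, G)) < probs[comp_idx]).astype(np.int8)
    # a gene family only exists because it was observed somewhere: rows are
    # zero-truncated, except for degenerate all-zero-probability components
    resample = (X.sum(axis=1) == 0) & (probs[comp_idx].max(axis=1) > 0)
    while resample.any():
        idx = np.flatnonzero(resample)
        X[idx] = (rng.random((len(idx), G)) < probs[comp_idx[idx]]).astype(np.int8)
        resample[idx] = X[idx].sum(axis=1) == 0
    families = [f"fam_{i:04d}" for i in range(F)]
    genomes = [f"genome_{j:03d}" for j in range(G)]
    matrix = pd.DataFrame(X, index=families, columns=genomes)
    labels = {families[i]: config.mixture_spec[comp_idx[i]].label for i in range(F)}

    graph = nx.Graph()
    graph.add_nodes_from(families)
    cross_p = config.contiguity_prob * config.cross_contiguity_factor
    # vectorized pair sampling
    iu, ju = np.triu_indices(F, k=1)
    same = comp_idx[iu] == comp_idx[ju]
    p_edge = np.where(same, config.contiguity_prob, cross_p)
    hit = rng.random(len(iu)) < p_edge
    for i, j in zip(iu[hit], ju[hit]):
        graph.add_edge(families[i], families[j])

    truth = PlantedTruth(family_labels=labels)
    return matrix, graph, truth
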