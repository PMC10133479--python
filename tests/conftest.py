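import numpy as np
import pandas as pd
import pytest

from srbmine import fixtures
from srbmine.synthetic import SimulationConfig


@pytest.fixture(scope="session")
def gene_dictionary():
    """The packaged 20-gene curated dictionary."""
    return fixtures.gene_table_dictionary()


@pytest.fixture(scope="session")
def segregation_table():
    """The packaged 116-gene pathway x partition table."""
    return fixtures.segregation_gene_table()


@pytest.fixture()
def small_config():
    return SimulationConfig(seed=42, n_genes=20, n_docs=10)


@pytest.fixture(scope="session")
def planted_pangenome():
    """One planted 300x40 three-component pangenome with its truth."""
    from srbmine.synthetic import generate_pangenome

    cfg = SimulationConfig(seed=7)
    matrix, graph, truth = generate_pangenome(cfg)
    return cfg, matrix, graph, truth


def mixture_means(cfg: SimulationConfig) -> dict[str, float]:
    """Planted mean presence probability per component label."""
    return {
        c.label: float(np.mean(c.probs(cfg.n_genomes))) for c in cfg.mixture_spec
    }


@pytest.fixture(scope="session")
def enrichment_graph():
    return fixtures.enrichment_fixture_graph()
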