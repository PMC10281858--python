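import networkx as nx
import numpy as np
import pandas as pd
import pytest

from netgwas.graph_neighborhoods import map_snps_to_genes
from netgwas.io_formats import GenotypeDataset


@pytest.fixture
def tiny_dataset():
    """3 samples x 4 SNPs with known coordinates on one chromosome."""
    return GenotypeDataset(
        dosages=np.array([[0, 1, 2, 0], [1, 1, 0, 2], [2, 0, 1, 1]], dtype=np.int8),
        snp_ids=["rs1", "rs2", "rs3", "rs4"],
        chrom=["1", "1", "1", "1"],
        pos=[100, 200, 300, 400],
        sample_ids=["a", "b", "c"],
    )


@pytest.fixture
def path_graph():
    """g1 - g2 - g3."""
    g = nx.Graph()
    g.add_edges_from([("g1", "g2"), ("g2", "g3")])
    return g


@pytest.fixture
def five_gene_dataset():
    """10 samples x 10 SNPs; genes g1..g5 tile two slots each on chrom 1."""
    rng = np.random.default_rng(1234)
    return GenotypeDataset(
        dosages=rng.integers(0, 3, size=(10, 10)).astype(np.int8),
        snp_ids=[f"rs{j}" for j in range(10)],
        chrom=["1"] * 10,
        pos=[100 * (j + 1) for j in range(10)],
        sample_ids=[f"s{i}" for i in range(10)],
    )


@pytest.fixture
def five_gene_annotation():
    return pd.DataFrame(
        {
            "gene_id": [f"g{k}" for k in range(1, 6)],
            "chrom": ["1"] * 5,
            "start": [100, 300, 500, 700, 900],
            "end": [200, 400, 600, 800, 1000],
        }
    )


@pytest.fixture
def five_gene_slot_map(five_gene_dataset, five_gene_annotation):
    return map_snps_to_genes(five_gene_dataset, five_gene_annotation)
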