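"""End-to-end orchestration: observed statistics, permutation null, p-values.

These helpers tie the neighborhood aggregation, the set LMM and the pooled
permutation null together on in-memory objects; the command-line layer and the
simulation benchmark both run through them so file-based and synthetic runs
exercise identical code.
"""

from __future__ import annotations

import logging

import networkx as nx
import numpy as np
import pandas as pd

from netgwas.graph_neighborhoods import SnpSlotMap, aggregate_neighborhood
from netgwas.io_formats import GenotypeDataset
from netgwas.set_lmm import (
    LmmFit,
    SetStatistic,
    SetTestError,
    UntestableNeighborhood,
    build_design,
    reml_fit_null,
    set_statistic,
)

logger = logging.getLogger(__name__)


def score_neighborhoods(
    dataset: GenotypeDataset,
    network: nx.Graph,
    slot_map: SnpSlotMap,
    y: np.ndarray,
    Xf: np.ndarray,
    k: int = 1,
    kernel_kind: str = "linear",
    standardize: bool = True,
    assignment: dict | None = None,
    fit_null: LmmFit | None = None,
    genes=None,
):
    """Fit the set LMM for every gene's k-hop neighborhood.

    Returns (statistics, skipped): one :class:`SetStatistic` per testable
    neighborhood in sorted gene order, plus the genes skipped as untestable
    (no SNPs / degenerate kernel) or numerically failed (logged).
    """
    if fit_null is None:
        fit_null = reml_fit_null(y, Xf)
    stats: list[SetStatistic] = []
    skipped: list = []
    for gene in sorted(network.nodes):
        if genes is not None and gene not in genes:
            continue
        feats = aggregate_neighborhood(gene, network, slot_map, k)
        try:
            L = build_design(feats, dataset, assignment=assignment, standardize=standardize)
            stats.append(
                set_statistic(y, Xf, L, kernel_kind, gene_id=gene, fit_null=fit_null)
            )
        except UntestableNeighborhood:
            skipped.append(gene)
        except SetTestError as exc:
            logger.warning("numerical failure for neighborhood %r: %s", gene, exc)
            skipped.append(gene)
    return stats, skipped


def run_association(
    dataset: GenotypeDataset,
    network: nx.Graph,
    slot_map: SnpSlotMap,
    y: np.ndarray,
    Xf: np.ndarray | None = None,
    k: int = 1,
    kernel_kind: str = "linear",
    n_permutations: int = 100,
    fraction: float = 0.5,
    pseudocount: int = 1,
    alpha: float = 0.05,
    base_seed: int = 0,
    standardize: bool = True,
):
    """Full single-trait run: observed statistics, pooled permutation null,
    empirical p-values and BH significance.

    Returns (results DataFrame with the standard result columns, NullPool).
    With an intercept-only ``Xf`` (the default) population structure is left
    to the permutation scheme, which preserves it under the null; principal
    components may be passed as extra fixed-effect columns.
    """
    from netgwas.significance import build_null_pool, empirical_pvalues, hierarchical_fdr

    y = np.asarray(y, dtype=float).ravel()
    if Xf is None:
        Xf = np.ones((len(y), 1))
    observed, skipped = score_neighborhoods(
        dataset, network, slot_map, y, Xf, k=k, kernel_kind=kernel_kind, standardize=standardize
    )
    if not observed:
        raise RuntimeError("no neighborhood was testable in the observed pass")
    if skipped:
        logger.info("%d neighborhoods untestable in the observed pass", len(skipped))
    pool = build_null_pool(
        dataset,
        network,
        slot_map,
        y,
        Xf,
        n_permutations=n_permutations,
        k=k,
        kernel_kind=kernel_kind,
        base_seed=base_seed,
        fraction=fraction,
        standardize=standardize,
    )
    ts = np.array([s.t for s in observed])
    pvals = empirical_pvalues(ts, pool, pseudocount)
    significant = hierarchical_fdr(pvals[None, :], alpha)[0]
    results = pd.DataFrame(
        {
            "gene_id": [s.gene_id for s in observed],
            "n_snps_in_neighborhood": [s.ns for s in observed],
            "lrt_statistic": ts,
            "pvalue": pvals,
            "fdr_significant": significant,
        }
    )
    return results, pool
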