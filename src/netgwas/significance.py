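"""Pooled permutation null, empirical p-values and multiple-testing control.

For each permutation index m, one circular SNP rotation and one fresh
degree-preserving network permutation are applied jointly; all neighborhoods
are re-aggregated on the permuted network and re-tested, and the resulting
statistics from all neighborhoods under all permutations are pooled into a
single null distribution T0. Pooling across neighborhoods sharply reduces the
number of permutations needed for fine-grained p-values.

The empirical p-value for an observed statistic t is

    p = (pseudocount + #{t0 in T0 : t0 >= t}) / (pseudocount + |T0|)

with pseudocount 1 by default, so p is never zero. Across multiple traits, a
two-stage hierarchical procedure (Simes combination per trait, BH across
traits, then BH within selected traits at level alpha * R / T) controls the
FDR over the trait x neighborhood grid.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import networkx as nx
import numpy as np
import pandas as pd
from statsmodels.stats.multitest import multipletests

from netgwas.circular_permutation import participating_slots, rotate, sample_rotations
from netgwas.graph_neighborhoods import SnpSlotMap, permute_network
from netgwas.io_formats import GenotypeDataset
from netgwas.set_lmm import SetStatistic, reml_fit_null

logger = logging.getLogger(__name__)


@dataclass
class NullPool:
    """The pooled permuted statistics with per-permutation provenance.

    ``manifest`` has one row per permutation index: (permutation_index,
    rotation, network_seed, n_stats), so any single null statistic can be
    regenerated.
    """

    stats: np.ndarray  # flat, all >= 0
    manifest: pd.DataFrame

    @property
    def size(self) -> int:
        return len(self.stats)


def build_null_pool(
    dataset: GenotypeDataset,
    network: nx.Graph,
    slot_map: SnpSlotMap,
    y: np.ndarray,
    Xf: np.ndarray,
    n_permutations: int,
    k: int = 1,
    kernel_kind: str = "linear",
    base_seed: int = 0,
    fraction: float = 0.5,
    standardize: bool = True,
) -> NullPool:
    """Compute the pooled null T0 = {t0[l, m]} over all neighborhoods l and
    permutations m.

    Each permutation applies one circular rotation (offsets drawn without
    replacement) and one degree-preserving network permutation, both seeded
    from ``base_seed`` so every permutation is individually reproducible from
    the manifest.
    """
    from netgwas.pipeline import score_neighborhoods  # local import, no cycle at runtime

    if n_permutations < 1:
        raise ValueError("need at least one permutation")
    slots = participating_slots(slot_map)
    ss = np.random.SeedSequence(base_seed)
    rot_seed, net_root = ss.spawn(2)
    rotations = sample_rotations(n_permutations, len(slots), np.random.default_rng(rot_seed))
    net_seeds = [int(s.generate_state(1)[0] % (2**31)) for s in net_root.spawn(n_permutations)]

    fit_null = reml_fit_null(y, Xf)
    pooled: list[float] = []
    rows = []
    for m, (rotation, net_seed) in enumerate(zip(rotations, net_seeds)):
        g_perm = permute_network(network, fraction=fraction, rng=np.random.default_rng(net_seed))
        assignment = rotate(slots, rotation)
        stats, _ = score_neighborhoods(
            dataset,
            g_perm,
            slot_map,
            y,
            Xf,
            k=k,
            kernel_kind=kernel_kind,
            standardize=standardize,
            assignment=assignment,
            fit_null=fit_null,
        )
        if not stats:
            raise RuntimeError(f"permutation {m}: no neighborhood was testable")
        pooled.extend(s.t for s in stats)
        rows.append(
            {
                "permutation_index": m,
                "rotation": rotation.r,
                "network_seed": net_seed,
                "n_stats": len(stats),
            }
        )
    return NullPool(stats=np.asarray(pooled, dtype=float), manifest=pd.DataFrame(rows))


def empirical_pvalue(t: SetStatistic | float, pool: NullPool, pseudocount: int = 1) -> float:
    """p = (pseudocount + #{t0 >= t}) / (pseudocount + |T0|); ties count for
    the null (conservative)."""
    t_val = t.t if isinstance(t, SetStatistic) else float(t)
    return float(empirical_pvalues(np.array([t_val]), pool, pseudocount)[0])


def empirical_pvalues(ts, pool: NullPool, pseudocount: int = 1) -> np.ndarray:
    if pool.size < 1:
        raise ValueError("null pool is empty")
    ts = np.asarray(ts, dtype=float)
    sorted_null = np.sort(pool.stats)
    # number of null stats >= t, with ties counted
    n_ge = pool.size - np.searchsorted(sorted_null, ts, side="left")
    return (pseudocount + n_ge) / (pseudocount + pool.size)


def write_null_pool(pool: NullPool, stats_path, manifest_path) -> None:
    pd.DataFrame({"t0": pool.stats}).to_csv(stats_path, sep="\t", index=False, float_format="%.12g")
    pool.manifest.to_csv(manifest_path, sep="\t", index=False)


def read_null_pool(stats_path, manifest_path) -> NullPool:
    stats = pd.read_csv(stats_path, sep="\t")["t0"].to_numpy(dtype=float)
    manifest = pd.read_csv(manifest_path, sep="\t")
    return NullPool(stats=stats, manifest=manifest)


# ---------------------------------------------------------------------------
# multiple testing


def bh_procedure(pvalues, alpha: float = 0.05):
    """Benjamini-Hochberg step-up. Returns (rejected bool array, adjusted p)."""
    pvalues = np.asarray(pvalues, dtype=float)
    if len(pvalues) == 0:
        return np.zeros(0, dtype=bool), np.zeros(0)
    if np.any((pvalues <= 0) | (pvalues > 1)):
        raise ValueError("p-values must lie in (0, 1]")
    rejected, adjusted, *_ = multipletests(pvalues, alpha=alpha, method="fdr_bh")
    return rejected, adjusted


def simes_pvalue(pvalues) -> float:
    """Simes combination: min over i of m * p_(i) / i."""
    p = np.sort(np.asarray(pvalues, dtype=float))
    m = len(p)
    if m == 0:
        return np.nan
    return float(min(1.0, np.min(m * p / np.arange(1, m + 1))))


def hierarchical_fdr(pvalue_matrix, alpha: float = 0.05) -> np.ndarray:
    """Two-stage FDR control over a T traits x ng neighborhoods p-value grid.

    Stage 1 combines each trait's p-values with Simes and applies BH across
    the T trait-level p-values at level alpha; stage 2 applies BH within each
    selected trait at level alpha * R / T, where R is the number of selected
    traits. Missing entries (NaN) are ignored. Returns a boolean matrix of the
    input shape marking significant (trait, neighborhood) pairs.
    """
    P = np.atleast_2d(np.asarray(pvalue_matrix, dtype=float))
    T, ng = P.shape
    significant = np.zeros_like(P, dtype=bool)
    trait_p = np.array(
        [simes_pvalue(P[i][np.isfinite(P[i])]) if np.isfinite(P[i]).any() else np.nan for i in range(T)]
    )
    usable = np.isfinite(trait_p)
    if not usable.any():
        return significant
    rejected_traits = np.zeros(T, dtype=bool)
    rej, _ = bh_procedure(trait_p[usable], alpha)
    rejected_traits[np.flatnonzero(usable)] = rej
    R = int(rejected_traits.sum())
    if R == 0:
        return significant
    level = alpha * R / T
    for i in np.flatnonzero(rejected_traits):
        ok = np.isfinite(P[i])
        rej_i, _ = bh_procedure(P[i][ok], level)
        significant[i, np.flatnonzero(ok)] = rej_i
    return significant
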