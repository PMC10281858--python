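"""Gene-to-SNP mapping, k-hop neighborhood aggregation and degree-preserving
network permutation.

A gene network is an undirected simple :class:`networkx.Graph` whose nodes are
gene ids. Each gene owns the genotype columns ("slots") whose genomic position
falls inside its annotated interval; the SNP set tested for a gene is the
union of the slots of the gene itself and of its k-hop network neighbors.
The degree-preserving permutation rewires edges by double-edge swaps until a
target fraction of the original edges has been displaced, keeping every node's
degree exactly — the network half of the permutation null.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import networkx as nx
import numpy as np

from netgwas.io_formats import GenotypeDataset

logger = logging.getLogger(__name__)


def build_network(edges, extra_nodes=()) -> nx.Graph:
    """Build an undirected simple graph from a deduplicated edge list."""
    g = nx.Graph()
    g.add_edges_from(edges)
    g.add_nodes_from(extra_nodes)
    if any(a == b for a, b in g.edges):
        raise ValueError("network contains self-loops")
    return g


@dataclass
class SnpSlotMap:
    """Mutually inverse maps between genotype column ordinals and genes.

    A slot is a fixed genomic coordinate — a column of the genotype matrix.
    A slot may fall inside zero, one or several (overlapping) genes.
    """

    gene_to_slots: dict  # gene_id -> np.ndarray of column ordinals, ascending
    slot_to_genes: dict  # column ordinal -> tuple of gene ids

    def genes_without_slots(self) -> list:
        return [g for g, s in self.gene_to_slots.items() if len(s) == 0]


@dataclass
class NeighborhoodFeatures:
    """The SNP slots aggregated for one gene's k-hop neighborhood.

    ``snp_slots`` is the deduplicated ascending union of the member genes'
    slots; a SNP shared by two member genes enters once (duplicated columns
    would only rescale the kernel).
    """

    gene_id: str
    member_genes: frozenset
    snp_slots: np.ndarray  # ascending column ordinals

    @property
    def ns(self) -> int:
        return len(self.snp_slots)


def map_snps_to_genes(genotypes: GenotypeDataset, annotation) -> SnpSlotMap:
    """Map each genotype column to the genes whose interval contains it.

    ``annotation`` is a DataFrame with columns gene_id, chrom, start, end
    (1-based inclusive). Genes with zero slots are retained (they still
    contribute topology) and logged.
    """
    gene_to_slots: dict = {}
    slot_to_genes: dict = {}
    chrom = np.asarray(genotypes.chrom)
    pos = np.asarray(genotypes.pos)
    for row in annotation.itertuples(index=False):
        mask = (chrom == row.chrom) & (pos >= row.start) & (pos <= row.end)
        slots = np.flatnonzero(mask)
        gene_to_slots[row.gene_id] = slots
        for s in slots:
            slot_to_genes.setdefault(int(s), []).append(row.gene_id)
    slot_to_genes = {s: tuple(gs) for s, gs in slot_to_genes.items()}
    empty = [g for g, s in gene_to_slots.items() if len(s) == 0]
    if empty:
        logger.info("%d genes contain no SNPs (kept as topology-only nodes)", len(empty))
    if not slot_to_genes:
        logger.warning("no SNP maps to any gene")
    return SnpSlotMap(gene_to_slots=gene_to_slots, slot_to_genes=slot_to_genes)


def aggregate_neighborhood(gene, network: nx.Graph, slot_map: SnpSlotMap, k: int) -> NeighborhoodFeatures:
    """Aggregate the SNP slots of ``gene`` and its k-hop network neighbors.

    k=0 degenerates to the gene's own slots. Slot order is ascending column
    ordinal, so the result is independent of edge-list order.
    """
    if gene not in network:
        raise KeyError(f"gene {gene!r} is not a node of the network")
    if k < 0:
        raise ValueError("k must be >= 0")
    if k == 0:
        members = {gene}
    else:
        members = set(nx.single_source_shortest_path_length(network, gene, cutoff=k))
    slot_arrays = [slot_map.gene_to_slots.get(g, np.empty(0, dtype=int)) for g in sorted(members)]
    if slot_arrays:
        slots = np.unique(np.concatenate(slot_arrays)).astype(int)
    else:
        slots = np.empty(0, dtype=int)
    return NeighborhoodFeatures(gene_id=gene, member_genes=frozenset(members), snp_slots=slots)


def permute_network(
    network: nx.Graph,
    fraction: float = 0.5,
    rng: np.random.Generator | None = None,
    attempt_factor: int = 100,
) -> nx.Graph:
    """Degree-preserving randomization by repeated double-edge swaps.

    Picks two existing edges (va, vb) and (vc, vd); the swap is rejected if
    the four endpoints are not distinct or if any edge already connects
    {va, vb} with {vc, vd}; otherwise the pair is rewired to (va, vc) and
    (vb, vd). Swapping continues until at least ``fraction`` of the original
    edges are no longer present, or ``attempt_factor * |E|`` candidate draws
    have been made (best effort returned with a warning). The degree of every
    node and the edge count are invariant.
    """
    if not 0 < fraction <= 1:
        raise ValueError("fraction must be in (0, 1]")
    if network.number_of_edges() < 2:
        raise ValueError("need at least 2 edges to swap")
    rng = np.random.default_rng(rng)
    g = network.copy()
    original = {frozenset(e) for e in network.edges}
    n_edges = len(original)
    target = int(np.ceil(fraction * n_edges))
    edges = [tuple(e) for e in g.edges]
    max_attempts = attempt_factor * n_edges

    def n_rearranged():
        return n_edges - sum(1 for e in original if g.has_edge(*tuple(e)))

    rearranged = n_rearranged()
    attempts = 0
    while rearranged < target and attempts < max_attempts:
        attempts += 1
        i, j = rng.integers(0, len(edges), size=2)
        if i == j:
            continue
        va, vb = edges[i]
        vc, vd = edges[j]
        if len({va, vb, vc, vd}) < 4:
            continue
        # reject if any endpoint of one edge already touches the other pair
        if (
            g.has_edge(va, vc)
            or g.has_edge(va, vd)
            or g.has_edge(vb, vc)
            or g.has_edge(vb, vd)
        ):
            continue
        g.remove_edge(va, vb)
        g.remove_edge(vc, vd)
        g.add_edge(va, vc)
        g.add_edge(vb, vd)
        edges[i] = (va, vc)
        edges[j] = (vb, vd)
        delta = 0
        for e in ((va, vb), (vc, vd)):
            if frozenset(e) in original:
                delta += 1
        for e in ((va, vc), (vb, vd)):
            if frozenset(e) in original:
                delta -= 1
        rearranged += delta
    if rearranged < target:
        logger.warning(
            "edge swap attempt cap reached: rearranged %d/%d edges (target %d)",
            rearranged,
            n_edges,
            target,
        )
    return g
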