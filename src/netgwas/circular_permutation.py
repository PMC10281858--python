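"""Circular rotation of SNP columns over fixed genomic coordinates.

The gene-mapped SNPs are laid on a circle in genomic order (chromosomes
concatenated; after the last SNP of the last chromosome one restarts from the
first). A permutation rotates the genotype columns around that circle by a
random offset while every genomic coordinate — and hence every gene's slot
membership — stays fixed. Relative SNP order is conserved, so linkage
disequilibrium is preserved exactly, and sample rows are never touched, so
population structure and relatedness are preserved too.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from netgwas.graph_neighborhoods import SnpSlotMap


@dataclass(frozen=True)
class Rotation:
    """A single circular offset; r=0 (identity) is forbidden because it would
    reproduce the observed statistics."""

    r: int
    p_total: int

    def __post_init__(self):
        if not 1 <= self.r <= self.p_total - 1:
            raise ValueError(
                f"rotation offset must lie in [1, {self.p_total - 1}], got {self.r}"
            )


def participating_slots(slot_map: SnpSlotMap) -> np.ndarray:
    """The genotype column ordinals that participate in the rotation.

    Exactly the slots mapped to at least one gene, in genomic order (column
    ordinals are already genomically sorted). Unmapped SNPs never enter any
    neighborhood, so they are excluded from the circle.
    """
    slots = np.array(sorted(slot_map.slot_to_genes), dtype=int)
    if slots.size == 0:
        raise ValueError("no SNP is mapped to any gene; nothing to rotate")
    return slots


def rotate(slots: np.ndarray, rotation: Rotation) -> dict[int, int]:
    """Return the slot -> source-column assignment for one rotation.

    The slot at circle ordinal i receives the genotype column that originally
    sat at ordinal (i - r) mod p_total. Genotype values are untouched; only
    the assignment of columns to genomic positions changes.
    """
    p_total = len(slots)
    if rotation.p_total != p_total:
        raise ValueError(
            f"rotation built for {rotation.p_total} slots applied to {p_total}"
        )
    shifted = np.roll(slots, rotation.r)  # shifted[i] = slots[(i - r) % p]
    return {int(s): int(c) for s, c in zip(slots, shifted)}


def compose_assignments(first: dict[int, int], second: dict[int, int]) -> dict[int, int]:
    """Assignment resulting from applying ``first`` then ``second``."""
    return {s: first[c] for s, c in second.items()}


def sample_rotations(n_rotations: int, p_total: int, rng) -> list[Rotation]:
    """Draw distinct rotation offsets uniformly from [1, p_total - 1].

    Non-repeating by construction; the identity offset is excluded.
    """
    if p_total < 2:
        raise ValueError("need at least 2 participating slots to rotate")
    if n_rotations > p_total - 1:
        raise ValueError(
            f"cannot draw {n_rotations} distinct rotations from [1, {p_total - 1}]; "
            "reduce the number of permutations or supply more mapped SNPs"
        )
    rng = np.random.default_rng(rng)
    offsets = rng.choice(np.arange(1, p_total), size=n_rotations, replace=False)
    return [Rotation(int(r), p_total) for r in offsets]
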