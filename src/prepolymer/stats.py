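"""Pre-polymer statistics: proximity partition, summary counts, chains.

The headline quantity is the number of C3'-C5' hydrogen bonds (3'-hydroxyl
donor to 5'-phosphate acceptor between different nucleotides), reported for
the whole box and for the subset of nucleotides near the substrate.  "Near"
means any atom of the nucleotide lies within the cutoff (default 7 Å,
inclusive) of any substrate atom under the minimum-image convention.

The bonded percentage follows the convention bonds / nucleotides x 100 —
e.g. 50 bonds among 200 nucleotides reads as 25% — even though each bond
involves two nucleotides; this mirrors how such counts are usually quoted.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Optional, Sequence

import numpy as np
from scipy.spatial import cKDTree

from .hbonds import HBond
from .system import Configuration

__all__ = [
    "ProximityRule",
    "ProximityPartition",
    "PrepolymerSummary",
    "proximity_partition",
    "prepolymer_summary",
    "chain_components",
]


@dataclass(frozen=True)
class ProximityRule:
    """Substrate-proximity rule: cutoff (Å) and which atoms are measured."""

    cutoff: float = 7.0
    mode: str = "any_atom"  # or "reference_atom" (the C3' marker)

    def __post_init__(self) -> None:
        if self.cutoff <= 0:
            raise ValueError("cutoff must be positive")
        if self.mode not in {"any_atom", "reference_atom"}:
            raise ValueError(f"unknown proximity mode {self.mode!r}")


@dataclass(frozen=True)
class ProximityPartition:
    near: frozenset[int]
    far: frozenset[int]


@dataclass(frozen=True)
class PrepolymerSummary:
    n_c3c5_total: int
    n_c3c5_near: int
    n_nucleotides_near: int
    n_nucleotides: int
    bonded_percent: float


def proximity_partition(
    config: Configuration, rule: ProximityRule = ProximityRule()
) -> ProximityPartition:
    """Split nucleotide residues into near/far of the substrate.

    A nucleotide is near iff the minimum-image distance from any of its
    atoms (or just its C3' marker in ``reference_atom`` mode) to any
    substrate atom is <= cutoff.  With no substrate all nucleotides are far.
    The partition is disjoint, exhaustive, and independent of atom order.
    """
    residues = config.residues("nucleotide")
    all_ids = frozenset(residues)
    substrate = config.select("substrate")
    if not substrate or not residues:
        return ProximityPartition(near=frozenset(), far=all_ids)

    box = None if config.box is None else np.asarray(config.box, dtype=float)
    sub_pos = np.array([a.position for a in substrate])
    if box is not None:
        tree = cKDTree(np.mod(sub_pos, box), boxsize=box)
    else:
        tree = cKDTree(sub_pos)

    near = set()
    for rid, atoms in residues.items():
        if rule.mode == "reference_atom":
            atoms = [a for a in atoms if a.name == "C3'"] or atoms
        pts = np.array([a.position for a in atoms])
        if box is not None:
            pts = np.mod(pts, box)
        d, _ = tree.query(pts, k=1)
        if np.min(d) <= rule.cutoff:
            near.add(rid)
    return ProximityPartition(near=frozenset(near), far=all_ids - near)


def prepolymer_summary(
    bonds: Iterable[HBond],
    partition: ProximityPartition,
    n_nucleotides: int,
    config: Configuration,
) -> PrepolymerSummary:
    """Count pre-polymer bonds, their near-substrate subset, and the bonded
    fraction (bonds / nucleotides x 100).

    A bond counts as near only when both partner nucleotides are near.
    """
    if n_nucleotides <= 0:
        raise ValueError("n_nucleotides must be positive")
    residue_of = {a.index: a.residue_id for a in config.atoms}

    total = 0
    near = 0
    for b in bonds:
        if b.category != "nuc_nuc_c3c5":
            continue
        total += 1
        if (
            residue_of[b.donor_index] in partition.near
            and residue_of[b.acceptor_index] in partition.near
        ):
            near += 1
    return PrepolymerSummary(
        n_c3c5_total=total,
        n_c3c5_near=near,
        n_nucleotides_near=len(partition.near),
        n_nucleotides=n_nucleotides,
        bonded_percent=100.0 * total / n_nucleotides,
    )


def chain_components(
    bonds: Iterable[HBond], config: Configuration, min_size: int = 2
) -> list[int]:
    """Sizes of connected nucleotide chains linked by C3'-C5' bonds.

    An exploratory extension beyond per-bond counting: nucleotides are graph
    nodes, pre-polymer bonds are edges, and the returned list holds the
    sizes (>= ``min_size``) of the connected components, sorted descending.
    """
    import networkx as nx

    residue_of = {a.index: a.residue_id for a in config.atoms}
    g = nx.Graph()
    for b in bonds:
        if b.category != "nuc_nuc_c3c5":
            continue
        g.add_edge(residue_of[b.donor_index], residue_of[b.acceptor_index])
    sizes = sorted((len(c) for c in nx.connected_components(g)), reverse=True)
    return [s for s in sizes if s >= min_size]
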