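"""Geometric hydrogen-bond detection and moiety-resolved classification.

A hydrogen bond is a donor-H...acceptor triple whose heavy-atom
donor-acceptor minimum-image distance is within ``da_cutoff`` and whose
deviation from linearity — the angle between the D->A and D->H directions —
is within ``angle_cutoff``.  Defaults (3.0 Å, 20°) follow the conventions of
common trajectory-visualization tooling; both are configurable.

Categories follow the moiety of the nucleotide-side atom: the headline
"C3'-C5'" pre-polymer bond is a 3'-hydroxyl donor on one nucleotide bonded
to a phosphate oxygen (O5'/OP1/OP2) of a different nucleotide — the
geometry that prefigures a phosphodiester linkage.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Optional, Sequence

import numpy as np
from scipy.spatial import cKDTree

from .system import Configuration, TopologyAnnotation, min_image_displacement

__all__ = [
    "HBondCriteria",
    "HBond",
    "detect_hbonds",
    "classify",
    "count_by_category",
    "hbond_trace",
    "CATEGORIES",
]

CATEGORIES = (
    "nuc_nuc_c3c5",
    "nuc_nuc_other",
    "nuc_substrate_base",
    "nuc_substrate_sugar_hydroxyl",
    "nuc_substrate_phosphate",
    "other",
)


@dataclass(frozen=True)
class HBondCriteria:
    """Distance / angle cutoffs for geometric hydrogen-bond detection."""

    da_cutoff: float = 3.0
    angle_cutoff: float = 20.0

    def __post_init__(self) -> None:
        if self.da_cutoff <= 0:
            raise ValueError("da_cutoff must be positive")
        if not 0 < self.angle_cutoff <= 90:
            raise ValueError("angle_cutoff must lie in (0, 90] degrees")


@dataclass(frozen=True)
class HBond:
    donor_index: int
    hydrogen_index: int
    acceptor_index: int
    distance: float
    angle: float
    category: str = "other"


def _angle_deg(d_to_h: np.ndarray, d_to_a: np.ndarray) -> float:
    nh = np.linalg.norm(d_to_h)
    na = np.linalg.norm(d_to_a)
    if nh == 0 or na == 0:
        return 0.0
    c = float(np.clip(d_to_h @ d_to_a / (nh * na), -1.0, 1.0))
    return float(np.degrees(np.arccos(c)))


def detect_hbonds(
    config: Configuration,
    topo: TopologyAnnotation,
    criteria: HBondCriteria = HBondCriteria(),
) -> list[HBond]:
    """All donor-H...acceptor triples meeting the geometric criteria.

    Honors the periodic box via the minimum-image convention; intra-residue
    pairs are excluded; output is sorted by (donor, acceptor, hydrogen).
    Neighbor candidates come from a k-d tree (periodic when the box is
    present); the result is contractually identical to an all-pairs search.
    """
    donors = list(topo.iter_donors())
    acceptors = list(topo.iter_acceptors())
    if not donors or not acceptors:
        return []

    n = len(config)
    for heavy, h, _, _ in donors:
        if not (0 <= heavy < n and 0 <= h < n):
            raise ValueError("annotation refers to atom indices outside the configuration")

    pos = config.positions
    box = None if config.box is None else np.asarray(config.box, dtype=float)
    residue_of = np.array([a.residue_id for a in config.atoms])

    acc_idx = np.array([a for a, _, _ in acceptors])
    acc_pos = pos[acc_idx]
    if box is not None:
        tree = cKDTree(np.mod(acc_pos, box), boxsize=box)
    else:
        tree = cKDTree(acc_pos)

    bonds: list[HBond] = []
    for heavy, h, _, _ in donors:
        dpos = pos[heavy]
        query_point = np.mod(dpos, box) if box is not None else dpos
        for k in tree.query_ball_point(query_point, criteria.da_cutoff + 1e-9):
            a_idx = int(acc_idx[k])
            if a_idx == heavy or residue_of[a_idx] == residue_of[heavy]:
                continue
            d_to_a = min_image_displacement(dpos, pos[a_idx], box)
            dist = float(np.linalg.norm(d_to_a))
            if dist > criteria.da_cutoff:
                continue
            d_to_h = min_image_displacement(dpos, pos[h], box)
            ang = _angle_deg(d_to_h, d_to_a)
            if ang > criteria.angle_cutoff:
                continue
            bonds.append(
                HBond(
                    donor_index=heavy,
                    hydrogen_index=h,
                    acceptor_index=a_idx,
                    distance=dist,
                    angle=ang,
                )
            )

    bonds.sort(key=lambda b: (b.donor_index, b.acceptor_index, b.hydrogen_index))
    return [classify_bond(b, config, topo) for b in bonds]


def classify(bond: HBond, topo: TopologyAnnotation, config: Configuration) -> str:
    """Category of a bond from the moieties of its donor and acceptor."""
    donor_m = topo.moiety_of(bond.donor_index)
    acceptor_m = topo.moiety_of(bond.acceptor_index)
    if donor_m is None or acceptor_m is None:
        return "other"
    d_moiety, _ = donor_m
    a_moiety, _ = acceptor_m
    d_group = config.atoms[bond.donor_index].group
    a_group = config.atoms[bond.acceptor_index].group

    if d_group == "nucleotide" and a_group == "nucleotide":
        if d_moiety == "sugar_hydroxyl" and a_moiety == "phosphate":
            # only the 3'-hydroxyl (not the 2') counts toward the pre-polymer
            rid = config.atoms[bond.donor_index].residue_id
            c3 = topo.c3_hydroxyl.get(rid)
            if c3 is not None and (
                bond.donor_index == c3[0] or bond.hydrogen_index in c3[1]
            ):
                return "nuc_nuc_c3c5"
        return "nuc_nuc_other"

    if {d_group, a_group} == {"nucleotide", "substrate"}:
        nuc_moiety = d_moiety if d_group == "nucleotide" else a_moiety
        if nuc_moiety == "base":
            return "nuc_substrate_base"
        if nuc_moiety == "sugar_hydroxyl":
            return "nuc_substrate_sugar_hydroxyl"
        if nuc_moiety == "phosphate":
            return "nuc_substrate_phosphate"
    return "other"


def classify_bond(bond: HBond, config: Configuration, topo: TopologyAnnotation) -> HBond:
    from dataclasses import replace

    return replace(bond, category=classify(bond, topo, config))


def count_by_category(bonds: Iterable[HBond]) -> dict[str, int]:
    """Bond counts per category; absent categories are reported as 0."""
    counts = {c: 0 for c in CATEGORIES}
    for b in bonds:
        counts[b.category] = counts.get(b.category, 0) + 1
    return counts


def bonds_to_dataframe(bonds: Sequence[HBond]):
    import pandas as pd

    return pd.DataFrame(
        {
            "donor_index": [b.donor_index for b in bonds],
            "hydrogen_index": [b.hydrogen_index for b in bonds],
            "acceptor_index": [b.acceptor_index for b in bonds],
            "distance": [b.distance for b in bonds],
            "angle": [b.angle for b in bonds],
            "category": [b.category for b in bonds],
        }
    )


def hbond_trace(
    series: Sequence[tuple[float, Configuration]],
    criteria: HBondCriteria = HBondCriteria(),
    proximity_rule=None,
    annotator=None,
):
    """Per-hydration-step bond counts for a dehydration series.

    ``series`` is a list of (hydration_percent, Configuration), sorted by
    decreasing hydration.  Returns a DataFrame with one row per step:
    total pre-polymer (C3'-C5') bonds, the near-substrate subset under the
    proximity rule (default: any atom within 7 Å of the substrate), and the
    number of nucleotide-substrate bonds.
    """
    import pandas as pd

    from .stats import ProximityRule, prepolymer_summary, proximity_partition
    from .system import annotate as default_annotate

    annotator = annotator or default_annotate
    proximity_rule = proximity_rule or ProximityRule()

    hyd = [h for h, _ in series]
    if hyd != sorted(hyd, reverse=True):
        raise ValueError("series must be sorted by decreasing hydration")

    rows = []
    for hydration, config in series:
        topo = annotator(config)
        bonds = detect_hbonds(config, topo, criteria)
        partition = proximity_partition(config, proximity_rule)
        n_nuc = len(config.nucleotide_residue_ids())
        counts = count_by_category(bonds)
        n_sub = (
            counts["nuc_substrate_base"]
            + counts["nuc_substrate_sugar_hydroxyl"]
            + counts["nuc_substrate_phosphate"]
        )
        if n_nuc:
            summary = prepolymer_summary(bonds, partition, n_nuc, config)
            n_total, n_near = summary.n_c3c5_total, summary.n_c3c5_near
        else:
            n_total = n_near = 0
        rows.append(
            {
                "hydration_percent": hydration,
                "n_c3c5_total": n_total,
                "n_c3c5_near": n_near,
                "n_nuc_substrate": n_sub,
            }
        )
    return pd.DataFrame(rows)
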