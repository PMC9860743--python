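"""Synthetic configurations with known ground truth.

The generators emulate the study systems at desk scale: 2-D monolayer
lattices standing in for ordered nucleotide layers on a substrate, randomly
packed reduced nucleotides with planted donor-H...acceptor geometries at
exactly known counts, mineral slabs with nucleotides at prescribed surface
offsets, and the wet-dry dehydration schedule (~12,500 -> ~600 waters over
10 steps for 200 nucleotides).  Every generator is a pure function of its
spec and seed.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Literal, Optional, Sequence

import numpy as np

from .system import AtomRecord, Configuration

__all__ = [
    "LatticeSpec",
    "PlantedSystemSpec",
    "DehydrationSchedule",
    "make_lattice_monolayer",
    "make_planted_hbond_system",
    "make_slab_system",
    "make_dehydration_schedule",
]


@dataclass(frozen=True)
class LatticeSpec:
    """2-D lattice unit cell: lengths a, b (Å), angle alpha (deg), jitter."""

    a: float
    b: float
    alpha: float = 90.0
    jitter_sd: float = 0.0
    n_a: int = 10
    n_b: int = 10

    def __post_init__(self) -> None:
        if self.a <= 0 or self.b <= 0:
            raise ValueError("lattice constants must be positive")
        if not 0 < self.alpha < 180:
            raise ValueError("alpha must lie in (0, 180) degrees")
        if self.jitter_sd < 0:
            raise ValueError("jitter_sd must be non-negative")

    @property
    def vectors(self) -> tuple[np.ndarray, np.ndarray]:
        """In-plane lattice vectors **a** (along x) and **b**."""
        alpha = math.radians(self.alpha)
        return (
            np.array([self.a, 0.0]),
            np.array([self.b * math.cos(alpha), self.b * math.sin(alpha)]),
        )


#: common unit cells reported for dried nucleotide monolayers
HEXAGONAL_MONOLAYER = LatticeSpec(a=6.8, b=4.3, alpha=120.0)
RECTANGULAR_MONOLAYER = LatticeSpec(a=5.7, b=4.5, alpha=90.0)


def make_lattice_monolayer(
    spec: LatticeSpec,
    marker_name: str = "C3'",
    seed: int = 0,
    z_thickness: float = 30.0,
    y_margin: float = 12.0,
) -> Configuration:
    """One marker atom per lattice node, in a periodic box.

    Nodes sit at ``i*a + j*b`` with optional Gaussian jitter.  The box is
    exactly commensurate along the a-direction (x) and, for alpha = 90°,
    along b as well.  For oblique cells the row shear makes an orthorhombic
    box incommensurate along y, so a vacuum margin (``y_margin``) is added
    there to keep minimum-image wrapping from fabricating pair distances;
    choose it at least as large as the r_max of any later pair analysis.
    """
    if spec.n_a * spec.n_b < 2:
        raise ValueError("lattice must contain at least 2 nodes")
    va, vb = spec.vectors
    rng = np.random.default_rng(seed)

    ii, jj = np.meshgrid(np.arange(spec.n_a), np.arange(spec.n_b), indexing="ij")
    xy = ii.reshape(-1, 1) * va + jj.reshape(-1, 1) * vb
    if spec.jitter_sd > 0:
        xy = xy + rng.normal(scale=spec.jitter_sd, size=xy.shape)

    box_x = spec.n_a * spec.a
    span_y = spec.n_b * abs(vb[1])
    # commensurate along y only when the accumulated row shear is a multiple
    # of the x-period (always true at alpha = 90°)
    shear = spec.n_b * vb[0]
    commensurate_y = math.isclose(shear % box_x, 0.0, abs_tol=1e-9) or math.isclose(
        shear % box_x, box_x, abs_tol=1e-9
    )
    box_y = span_y if commensurate_y else span_y + y_margin
    box = (box_x, box_y, z_thickness)

    pos = np.column_stack([xy, np.full(len(xy), z_thickness / 2.0)])
    pos[:, 0] %= box_x
    pos[:, 1] %= box_y

    if spec.jitter_sd > 0:
        from scipy.spatial import cKDTree

        tree = cKDTree(pos, boxsize=box)
        pairs = tree.query_pairs(0.5)
        if pairs:
            raise ValueError("jitter collapsed lattice nodes closer than 0.5 Å")

    atoms = [
        AtomRecord(
            index=i,
            name=marker_name,
            element="C",
            residue_id=i + 1,
            residue_type="AMP",
            group="nucleotide",
            position=p,
        )
        for i, p in enumerate(pos)
    ]
    return Configuration(atoms=atoms, box=box)


# ---------------------------------------------------------------------------
# planted hydrogen-bond systems


@dataclass(frozen=True)
class PlantedSystemSpec:
    """Randomly packed reduced nucleotides with a known number of planted
    3'-hydroxyl -> phosphate hydrogen bonds.

    Planted pairs realize the donor-H...acceptor geometry at exactly
    (bond_distance, bond_angle); every other inter-nucleotide donor-acceptor
    distance is kept above ``detection_cutoff + guard`` so a geometric
    detector recovers the planted set with recall and precision 1 by
    construction.
    """

    n_nucleotides: int = 200
    n_planted_bonds: int = 50
    bond_distance: float = 2.8
    bond_angle: float = 10.0
    box: tuple[float, float, float] = (85.0, 85.0, 85.0)
    min_separation: float = 4.0
    detection_cutoff: float = 3.0
    guard: float = 1.0
    seed: int = 0
    max_attempts: int = 5000

    def __post_init__(self) -> None:
        if self.n_planted_bonds * 2 > self.n_nucleotides:
            raise ValueError("each nucleotide may take part in at most one planted bond")
        if not 0 < self.bond_distance <= self.detection_cutoff:
            raise ValueError("bond_distance must lie inside the detection cutoff")
        if self.bond_angle < 0:
            raise ValueError("bond_angle must be non-negative")
        if self.min_separation < self.detection_cutoff + self.guard:
            object.__setattr__(self, "min_separation", self.detection_cutoff + self.guard)


# Reduced nucleotide fragment (local planar coordinates, Å), anchored at
# O3'.  Only atoms the analyses touch: the 3'-hydroxyl donor, the phosphate
# acceptors and the C3'/C5' markers.  The chain is laid out so that, when a
# pair is planted via OP1, every other fragment atom sits behind the
# acceptor anchor along the bond axis (axial component toward O3' >= 1.4 Å),
# which keeps unplanned donor-acceptor contacts outside the guard band.
_FRAGMENT = {
    "O3'": np.array([0.0, 0.0, 0.0]),
    "H3T": np.array([0.96, 0.0, 0.0]),
    "C3'": np.array([-0.7, -1.2, 0.0]),
    "C5'": np.array([-1.5, -2.4, 0.0]),
    "O5'": np.array([-2.6, -3.3, 0.0]),
    "P": np.array([-4.0, -3.9, 0.0]),
    "OP1": np.array([-5.5, -4.4, 0.0]),
}
_ELEMENTS = {"C3'": "C", "O3'": "O", "H3T": "H", "C5'": "C", "O5'": "O", "P": "P", "OP1": "O"}
_DONOR_ATOMS = ("O3'", "H3T")
_ACCEPTOR_ATOMS = ("O5'", "OP1")
_RESTYPES = ("AMP", "UMP", "CMP", "GMP")


def _random_rotation(rng: np.random.Generator) -> np.ndarray:
    """Uniform random rotation matrix from a normalized random quaternion."""
    q = rng.normal(size=4)
    q /= np.linalg.norm(q)
    w, x, y, z = q
    return np.array(
        [
            [1 - 2 * (y * y + z * z), 2 * (x * y - w * z), 2 * (x * z + w * y)],
            [2 * (x * y + w * z), 1 - 2 * (x * x + z * z), 2 * (y * z - w * x)],
            [2 * (x * z - w * y), 2 * (y * z + w * x), 1 - 2 * (x * x + y * y)],
        ]
    )


def _fragment_atoms(origin_o3: np.ndarray, R: np.ndarray) -> dict[str, np.ndarray]:
    """Fragment positioned with its O3' at ``origin_o3``, rotated by R."""
    o3_local = _FRAGMENT["O3'"]
    return {name: origin_o3 + R @ (xyz - o3_local) for name, xyz in _FRAGMENT.items()}


def _perpendicular(v: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    while True:
        w = rng.normal(size=3)
        w -= v * (w @ v)
        n = np.linalg.norm(w)
        if n > 1e-8:
            return w / n


def _pair_geometry(
    center: np.ndarray, spec: PlantedSystemSpec, rng: np.random.Generator
) -> tuple[dict[str, np.ndarray], dict[str, np.ndarray]]:
    """A donor and an acceptor fragment realizing the planted geometry.

    The donor's O3'->H axis points along a random unit vector u; the
    acceptor's OP1 sits at distance ``bond_distance`` from O3' along a
    direction at exactly ``bond_angle`` from u.  Both fragment bodies are
    folded away from the bond axis so no unplanned donor-acceptor contact
    can fall inside the detection cutoff plus guard band.
    """
    u = rng.normal(size=3)
    u /= np.linalg.norm(u)
    w = _perpendicular(u, rng)
    theta = math.radians(spec.bond_angle)
    v = math.cos(theta) * u + math.sin(theta) * w  # D->A direction

    o3_d = center - 0.5 * spec.bond_distance * v
    # donor fragment: O3'-H along u, remaining body behind the donor
    R_d = _rotation_aligning(np.array([1.0, 0.0, 0.0]), u, rng)
    donor = _fragment_atoms(o3_d, R_d)
    donor["H3T"] = o3_d + 0.96 * u  # enforce the planted angle exactly

    op1_a = o3_d + spec.bond_distance * v
    # acceptor fragment: body continues along +v away from the donor
    R_a = _rotation_aligning(
        (_FRAGMENT["OP1"] - _FRAGMENT["O3'"]) / np.linalg.norm(_FRAGMENT["OP1"] - _FRAGMENT["O3'"]),
        -v,
        rng,
    )
    o3_a = op1_a + R_a @ (_FRAGMENT["O3'"] - _FRAGMENT["OP1"])
    acceptor = _fragment_atoms(o3_a, R_a)
    return donor, acceptor


def _rotation_aligning(src: np.ndarray, dst: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    """Rotation taking unit vector src to dst, with random roll about dst."""
    src = src / np.linalg.norm(src)
    dst = dst / np.linalg.norm(dst)
    c = float(src @ dst)
    if c > 1 - 1e-12:
        R = np.eye(3)
    elif c < -1 + 1e-12:
        axis = _perpendicular(src, rng)
        R = _axis_angle(axis, math.pi)
    else:
        axis = np.cross(src, dst)
        axis /= np.linalg.norm(axis)
        R = _axis_angle(axis, math.acos(c))
    roll = _axis_angle(dst, rng.uniform(0, 2 * math.pi))
    return roll @ R


def _axis_angle(axis: np.ndarray, angle: float) -> np.ndarray:
    x, y, z = axis
    c, s = math.cos(angle), math.sin(angle)
    C = 1 - c
    return np.array(
        [
            [c + x * x * C, x * y * C - z * s, x * z * C + y * s],
            [y * x * C + z * s, c + y * y * C, y * z * C - x * s],
            [z * x * C - y * s, z * y * C + x * s, c + z * z * C],
        ]
    )


def make_planted_hbond_system(
    spec: PlantedSystemSpec,
) -> tuple[Configuration, list[tuple[int, int]]]:
    """Pack reduced nucleotides in a periodic box with planted bonds.

    Returns the configuration and the ground truth as (donor O3' index,
    acceptor phosphate-oxygen index) pairs.  Placement is rejection
    sampling: a candidate object (a bonded pair or a single nucleotide) is
    accepted only if all of its donor/acceptor atoms stay farther than
    ``detection_cutoff + guard`` from every previously placed object's
    donor/acceptor atoms (minimum image).  Raises if the box cannot be
    packed within the attempt budget.
    """
    rng = np.random.default_rng(spec.seed)
    box = np.asarray(spec.box, dtype=float)
    margin = spec.detection_cutoff + spec.guard

    placed_da: list[np.ndarray] = []  # donor/acceptor atoms of accepted objects

    def clashes(candidate_da: np.ndarray) -> bool:
        if not placed_da:
            return False
        prev = np.concatenate(placed_da)
        d = candidate_da[:, None, :] - prev[None, :, :]
        d -= box * np.round(d / box)
        return bool((np.linalg.norm(d, axis=-1) <= margin).any())

    objects: list[tuple[list[dict[str, np.ndarray]], bool]] = []
    n_pairs = spec.n_planted_bonds
    n_single = spec.n_nucleotides - 2 * n_pairs

    for kind in ["pair"] * n_pairs + ["single"] * n_single:
        for attempt in range(spec.max_attempts):
            center = rng.uniform(0, 1, size=3) * box
            if kind == "pair":
                donor, acceptor = _pair_geometry(center, spec, rng)
                frags = [donor, acceptor]
            else:
                R = _random_rotation(rng)
                frags = [_fragment_atoms(center, R)]
            da = np.array(
                [f[n] for f in frags for n in _DONOR_ATOMS + _ACCEPTOR_ATOMS]
            )
            if not clashes(da):
                # for a planted pair, exempt the planted contact itself from
                # the margin: only the cross terms to *other* objects matter,
                # which is what `clashes` checks (intra-candidate excluded)
                placed_da.append(da)
                objects.append((frags, kind == "pair"))
                break
        else:
            raise RuntimeError(
                "could not pack the requested system; try a larger box or fewer nucleotides"
            )

    atoms: list[AtomRecord] = []
    ground_truth: list[tuple[int, int]] = []
    rid = 0
    for frags, is_pair in objects:
        frag_indices = []
        for frag in frags:
            rid += 1
            start = len(atoms)
            for name in _FRAGMENT:
                atoms.append(
                    AtomRecord(
                        index=len(atoms),
                        name=name,
                        element=_ELEMENTS[name],
                        residue_id=rid,
                        residue_type=_RESTYPES[(rid - 1) % 4],
                        group="nucleotide",
                        position=np.mod(frag[name], box),
                    )
                )
            frag_indices.append(start)
        if is_pair:
            names = list(_FRAGMENT)
            donor_o3 = frag_indices[0] + names.index("O3'")
            acceptor_op1 = frag_indices[1] + names.index("OP1")
            ground_truth.append((donor_o3, acceptor_op1))

    return Configuration(atoms=atoms, box=tuple(box)), ground_truth


# ---------------------------------------------------------------------------
# mineral slab with nucleotides at prescribed offsets


def make_slab_system(
    slab_dims: Sequence[float] = (40.0, 50.0, 30.0),
    lattice_const: float = 2.0,
    n_nucleotides: int = 0,
    z_offsets: Optional[Sequence[float]] = None,
    seed: int = 0,
    box_height: float = 85.0,
    substrate_element: str = "O",
) -> Configuration:
    """Simple-cubic substrate slab with nucleotides above the top layer.

    Each nucleotide is a flat reduced fragment parallel to the surface, its
    reference atom (C3') placed directly above a randomly chosen top-layer
    substrate atom at the prescribed normal offset, so the minimum
    nucleotide-substrate distance equals the offset exactly.
    """
    z_offsets = list(z_offsets or [])
    if len(z_offsets) != n_nucleotides:
        raise ValueError("z_offsets must provide one offset per nucleotide")
    if any(z < 0 for z in z_offsets):
        raise ValueError("offsets must be non-negative")

    rng = np.random.default_rng(seed)
    nx, ny, nz = (max(1, int(math.floor(d / lattice_const)) + 1) for d in slab_dims)
    gx, gy, gz = np.meshgrid(
        np.arange(nx) * lattice_const,
        np.arange(ny) * lattice_const,
        np.arange(nz) * lattice_const,
        indexing="ij",
    )
    sub_pos = np.column_stack([gx.ravel(), gy.ravel(), gz.ravel()])
    top_z = sub_pos[:, 2].max()
    top_sites = sub_pos[sub_pos[:, 2] == top_z]

    atoms = [
        AtomRecord(
            index=i,
            name=substrate_element + "S",
            element=substrate_element,
            residue_id=0,
            residue_type="MIN",
            group="substrate",
            position=p,
        )
        for i, p in enumerate(sub_pos)
    ]

    site_ids = rng.choice(len(top_sites), size=n_nucleotides, replace=False) if n_nucleotides else []
    for k, (offset, site) in enumerate(zip(z_offsets, site_ids)):
        ref = top_sites[site] + np.array([0.0, 0.0, offset])
        angle = rng.uniform(0, 2 * math.pi)
        R = _axis_angle(np.array([0.0, 0.0, 1.0]), angle)  # in-plane spin only
        frag = {name: ref + R @ xyz for name, xyz in _FRAGMENT.items()}
        rid = k + 1
        for name in _FRAGMENT:
            atoms.append(
                AtomRecord(
                    index=len(atoms),
                    name=name,
                    element=_ELEMENTS[name],
                    residue_id=rid,
                    residue_type=_RESTYPES[k % 4],
                    group="nucleotide",
                    position=frag[name],
                )
            )

    box = (slab_dims[0] + lattice_const, slab_dims[1] + lattice_const, box_height)
    return Configuration(atoms=atoms, box=box)


# ---------------------------------------------------------------------------
# dehydration schedule


@dataclass(frozen=True)
class DehydrationStep:
    water_count: int
    hydration_percent: float
    waters_per_nucleotide: float


@dataclass(frozen=True)
class DehydrationSchedule:
    """Ordered water counts of a wet-dry cycle with hydration bookkeeping."""

    steps: tuple[DehydrationStep, ...]
    n_nucleotides: int

    def water_counts(self) -> list[int]:
        return [s.water_count for s in self.steps]

    def to_dataframe(self):
        import pandas as pd

        return pd.DataFrame(
            {
                "water_count": [s.water_count for s in self.steps],
                "hydration_percent": [s.hydration_percent for s in self.steps],
                "waters_per_nucleotide": [s.waters_per_nucleotide for s in self.steps],
            }
        )


def make_dehydration_schedule(
    initial_waters: int = 12500,
    final_waters: int = 600,
    n_steps: int = 10,
    n_nucleotides: int = 200,
    interpolation: Literal["linear", "geometric"] = "linear",
) -> DehydrationSchedule:
    """Water counts for a staged dehydration run.

    Defaults emulate removing water in 10 steps from 12,500 to 600 molecules
    around 200 nucleotides (62.5 -> 3.0 waters per nucleotide).  Percentages
    are relative to the initial count.
    """
    if not initial_waters > final_waters > 0:
        raise ValueError("need initial_waters > final_waters > 0")
    if n_steps < 2:
        raise ValueError("a schedule needs at least 2 steps")
    if n_nucleotides <= 0:
        raise ValueError("n_nucleotides must be positive")

    t = np.linspace(0.0, 1.0, n_steps)
    if interpolation == "linear":
        counts = initial_waters + t * (final_waters - initial_waters)
    elif interpolation == "geometric":
        counts = initial_waters * (final_waters / initial_waters) ** t
    else:
        raise ValueError(f"unknown interpolation {interpolation!r}")

    rounded = np.round(counts).astype(int)
    rounded[0], rounded[-1] = initial_waters, final_waters
    # enforce strict monotone decrease after integer rounding
    for i in range(1, n_steps):
        if rounded[i] >= rounded[i - 1]:
            rounded[i] = rounded[i - 1] - 1
    if rounded[-1] != final_waters:
        raise ValueError("schedule cannot decrease strictly with these endpoints/steps")

    steps = tuple(
        DehydrationStep(
            water_count=int(c),
            hydration_percent=100.0 * c / initial_waters,
            waters_per_nucleotide=c / n_nucleotides,
        )
        for c in rounded
    )
    return DehydrationSchedule(steps=steps, n_nucleotides=n_nucleotides)
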