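"""Molecular configurations: data model, PDB/GRO/XYZ I/O, topology annotation.

Coordinates are stored internally in angstroms; GRO files (nm) are converted
on read and write.  Only orthorhombic periodic boxes are supported — the
systems this package targets live in cubic boxes — and triclinic input is
rejected with a clear error.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Literal, Optional, Sequence

import numpy as np

__all__ = [
    "AtomRecord",
    "Configuration",
    "TopologyAnnotation",
    "AnnotationError",
    "read_configuration",
    "write_configuration",
    "annotate",
    "min_image_distance",
    "min_image_displacement",
    "normalize_atom_name",
]

Group = Literal["nucleotide", "substrate", "water", "ion"]

NUCLEOTIDE_RESIDUES = {"AMP", "UMP", "CMP", "GMP"}
WATER_RESIDUES = {"HOH", "SOL", "WAT", "TIP3", "TIP", "SPC", "T3P"}
ION_RESIDUES = {"NA", "CL", "K", "MG", "CA", "NA+", "CL-", "K+", "MG2", "CA2", "SOD", "CLA", "POT"}

#: phosphate oxygens accepted as the 5'-linkage acceptor set (both PDB v3 and
#: CHARMM spellings)
PHOSPHATE_OXYGENS = {"O5'", "OP1", "OP2", "OP3", "O1P", "O2P", "O3P"}

# Base donor/acceptor rule table per nucleotide type.  Donors map heavy atom
# name -> candidate hydrogen names; acceptors are heavy-atom names.
BASE_DONORS = {
    "AMP": {"N6": ("H61", "H62")},
    "UMP": {"N3": ("H3",)},
    "CMP": {"N4": ("H41", "H42")},
    "GMP": {"N1": ("H1",), "N2": ("H21", "H22")},
}
BASE_ACCEPTORS = {
    "AMP": {"N1", "N3", "N7"},
    "UMP": {"O2", "O4"},
    "CMP": {"O2", "N3"},
    "GMP": {"O6", "N3", "N7"},
}

#: candidate hydrogen names for the sugar hydroxyls
C3_HYDROXYL_H = ("H3T", "HO3'", "H3'")
C2_HYDROXYL_H = ("HO2'", "H2T", "HO2")

#: covalent O-H bond inference fallback cutoff (Å)
BOND_H_CUTOFF = 1.2


def normalize_atom_name(name: str) -> str:
    """Map the prime/apostrophe/star dialects of sugar-atom names to one form.

    PDB dialects write the ribose primes as ``'`` (v3), ``*`` (v2) or the
    typographic prime ``′``.  The apostrophe is canonical here.
    """
    return name.replace("′", "'").replace("*", "'").strip()


def _infer_group(residue_type: str) -> Optional[Group]:
    r = residue_type.upper()
    if r in NUCLEOTIDE_RESIDUES:
        return "nucleotide"
    if r in WATER_RESIDUES:
        return "water"
    if r in ION_RESIDUES:
        return "ion"
    return None


@dataclass
class AtomRecord:
    """One atom: identity, residue membership, group tag and position (Å)."""

    index: int
    name: str
    element: str
    residue_id: int
    residue_type: str
    group: Group
    position: np.ndarray
    partial_charge: Optional[float] = None

    def __post_init__(self) -> None:
        self.name = normalize_atom_name(self.name)
        self.position = np.asarray(self.position, dtype=float)
        if self.position.shape != (3,):
            raise ValueError(f"atom {self.index}: position must be a 3-vector")
        if not np.all(np.isfinite(self.position)):
            raise ValueError(f"atom {self.index}: non-finite coordinates")
        if self.group == "nucleotide" and self.residue_type not in NUCLEOTIDE_RESIDUES:
            raise ValueError(
                f"atom {self.index}: nucleotide group requires residue_type in "
                f"{sorted(NUCLEOTIDE_RESIDUES)}, got {self.residue_type!r}"
            )
        if self.partial_charge is not None and not np.isfinite(self.partial_charge):
            raise ValueError(f"atom {self.index}: non-finite partial charge")


@dataclass
class Configuration:
    """A set of atoms plus an optional orthorhombic periodic box (Å edges)."""

    atoms: list[AtomRecord] = field(default_factory=list)
    box: Optional[tuple[float, float, float]] = None

    def __post_init__(self) -> None:
        if self.box is not None:
            self.box = tuple(float(e) for e in self.box)  # type: ignore[assignment]
            if len(self.box) != 3 or any(e <= 0 for e in self.box):
                raise ValueError("box edges must be three strictly positive lengths")
        indices = [a.index for a in self.atoms]
        if indices != list(range(len(self.atoms))):
            raise ValueError("atom indices must be unique and contiguous from 0")

    def __len__(self) -> int:
        return len(self.atoms)

    @property
    def positions(self) -> np.ndarray:
        """(n, 3) coordinate array in Å (a copy)."""
        if not self.atoms:
            return np.zeros((0, 3))
        return np.array([a.position for a in self.atoms], dtype=float)

    def select(self, group: Group) -> list[AtomRecord]:
        return [a for a in self.atoms if a.group == group]

    def residues(self, group: Optional[Group] = None) -> dict[int, list[AtomRecord]]:
        """Atoms keyed by residue id, optionally restricted to one group."""
        out: dict[int, list[AtomRecord]] = {}
        for a in self.atoms:
            if group is not None and a.group != group:
                continue
            out.setdefault(a.residue_id, []).append(a)
        return out

    def nucleotide_residue_ids(self) -> list[int]:
        return sorted(self.residues("nucleotide"))


class AnnotationError(ValueError):
    """A residue cannot be annotated under the expected naming scheme."""


@dataclass
class TopologyAnnotation:
    """Donor/acceptor bookkeeping for a Configuration.

    Per-nucleotide maps are keyed by residue id; hydrogens attached to donor
    heavy atoms are resolved by name convention first, with a < 1.2 Å
    distance fallback, so connectivity records are not required.
    """

    c3_hydroxyl: dict[int, tuple[int, tuple[int, ...]]] = field(default_factory=dict)
    c2_hydroxyl: dict[int, tuple[int, tuple[int, ...]]] = field(default_factory=dict)
    phosphate_acceptors: dict[int, frozenset[int]] = field(default_factory=dict)
    base_donors: dict[int, tuple[tuple[int, tuple[int, ...]], ...]] = field(default_factory=dict)
    base_acceptors: dict[int, frozenset[int]] = field(default_factory=dict)
    substrate_donors: tuple[tuple[int, tuple[int, ...]], ...] = ()
    substrate_acceptors: frozenset[int] = frozenset()

    # ---- flattened views used by the hydrogen-bond detector ----------------

    def iter_donors(self) -> Iterable[tuple[int, int, str, int]]:
        """Yield (heavy_index, hydrogen_index, moiety, residue_id)."""
        for rid, (o, hs) in self.c3_hydroxyl.items():
            for h in hs:
                yield o, h, "sugar_hydroxyl", rid
        for rid, (o, hs) in self.c2_hydroxyl.items():
            for h in hs:
                yield o, h, "sugar_hydroxyl", rid
        for rid, entries in self.base_donors.items():
            for heavy, hs in entries:
                for h in hs:
                    yield heavy, h, "base", rid
        for heavy, hs in self.substrate_donors:
            for h in hs:
                yield heavy, h, "substrate", -1

    def iter_acceptors(self) -> Iterable[tuple[int, str, int]]:
        """Yield (acceptor_index, moiety, residue_id)."""
        for rid, accs in self.phosphate_acceptors.items():
            for a in accs:
                yield a, "phosphate", rid
        for rid, accs in self.base_acceptors.items():
            for a in accs:
                yield a, "base", rid
        for a in self.substrate_acceptors:
            yield a, "substrate", -1

    def moiety_of(self, atom_index: int) -> Optional[tuple[str, int]]:
        """(moiety, residue_id) of an annotated atom, hydrogens included."""
        for rid, (o, hs) in self.c3_hydroxyl.items():
            if atom_index == o or atom_index in hs:
                return "sugar_hydroxyl", rid
        for rid, (o, hs) in self.c2_hydroxyl.items():
            if atom_index == o or atom_index in hs:
                return "sugar_hydroxyl", rid
        for rid, accs in self.phosphate_acceptors.items():
            if atom_index in accs:
                return "phosphate", rid
        for rid, entries in self.base_donors.items():
            for heavy, hs in entries:
                if atom_index == heavy or atom_index in hs:
                    return "base", rid
        for rid, accs in self.base_acceptors.items():
            if atom_index in accs:
                return "base", rid
        for heavy, hs in self.substrate_donors:
            if atom_index == heavy or atom_index in hs:
                return "substrate", -1
        if atom_index in self.substrate_acceptors:
            return "substrate", -1
        return None


# ---------------------------------------------------------------------------
# periodic geometry


def min_image_displacement(
    p: np.ndarray, q: np.ndarray, box: Optional[Sequence[float]] = None
) -> np.ndarray:
    """Minimum-image displacement vector(s) q - p for an orthorhombic box."""
    d = np.asarray(q, dtype=float) - np.asarray(p, dtype=float)
    if box is not None:
        b = np.asarray(box, dtype=float)
        d = d - b * np.round(d / b)
    return d


def min_image_distance(
    p: np.ndarray, q: np.ndarray, box: Optional[Sequence[float]] = None
) -> float:
    """Minimum-image Euclidean distance (plain distance without a box)."""
    return float(np.linalg.norm(min_image_displacement(p, q, box), axis=-1))


# ---------------------------------------------------------------------------
# file I/O (MDAnalysis-backed)


def _mda():
    import MDAnalysis as mda  # deferred: import is slow

    return mda


def _guess_format(path: Path) -> str:
    suffix = path.suffix.lower().lstrip(".")
    if suffix in {"pdb", "gro", "xyz"}:
        return suffix
    raise ValueError(f"cannot infer format from {path.name!r}; pass format explicitly")


def _box_from_dimensions(dims) -> Optional[tuple[float, float, float]]:
    if dims is None:
        return None
    dims = np.asarray(dims, dtype=float)
    if np.all(dims[:3] == 0):
        return None
    if not np.allclose(dims[3:], 90.0):
        raise ValueError(f"only orthorhombic boxes are supported (angles {dims[3:]})")
    return tuple(float(x) for x in dims[:3])


def read_configuration(
    path, format: str = "auto", strict: bool = False
) -> Configuration:
    """Read a PDB, GRO or XYZ file into a :class:`Configuration`.

    Group tags are assigned from the residue name via a rule table
    (AMP/UMP/CMP/GMP -> nucleotide, water and common ion names recognized);
    unknown residues become substrate with a warning, or raise when
    ``strict`` is true.  GRO coordinates and box are converted nm -> Å.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    fmt = _guess_format(path) if format == "auto" else format.lower()
    if fmt not in {"pdb", "gro", "xyz"}:
        raise ValueError(f"unsupported format {fmt!r}")

    mda = _mda()
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        u = mda.Universe(str(path), format=fmt)
        names = u.atoms.names if hasattr(u.atoms, "names") else u.atoms.elements
        try:
            elements = u.atoms.elements
        except Exception:
            elements = [_element_from_name(n) for n in names]
        try:
            resnames = u.atoms.resnames
        except Exception:
            resnames = ["UNK"] * len(u.atoms)
        try:
            resids = u.atoms.resids
        except Exception:
            resids = [1] * len(u.atoms)
        positions = u.atoms.positions
        box = _box_from_dimensions(u.dimensions) if fmt != "xyz" else None

    atoms: list[AtomRecord] = []
    warned: set[str] = set()
    for i, (name, element, resname, resid, pos) in enumerate(
        zip(names, elements, resnames, resids, positions)
    ):
        resname = str(resname).strip().upper()
        group = _infer_group(resname)
        if group is None:
            if strict:
                raise ValueError(f"unknown residue type {resname!r} (atom {i})")
            if resname not in warned:
                warnings.warn(
                    f"residue {resname!r} not in the rule table; tagging as substrate",
                    stacklevel=2,
                )
                warned.add(resname)
            group = "substrate"
        atoms.append(
            AtomRecord(
                index=i,
                name=str(name),
                element=str(element).strip() or _element_from_name(str(name)),
                residue_id=int(resid),
                residue_type=resname,
                group=group,
                position=np.asarray(pos, dtype=float),
            )
        )
    return Configuration(atoms=atoms, box=box)


def _element_from_name(name: str) -> str:
    name = normalize_atom_name(name)
    for ch in name:
        if ch.isalpha():
            return ch.upper()
    return "X"


_PDB_COORD_LIMITS = (-999.999, 9999.999)


def write_configuration(config: Configuration, path, format: str = "auto") -> None:
    """Write a Configuration as PDB, GRO or XYZ (round-trip safe).

    PDB holds three decimals in Å and XYZ full precision; GRO quantizes to
    0.001 nm = 0.01 Å by format.  Coordinates outside the PDB fixed-width
    field raise; atom names wider than the format field trigger a warning.
    """
    path = Path(path)
    fmt = _guess_format(path) if format == "auto" else format.lower()
    if fmt not in {"pdb", "gro", "xyz"}:
        raise ValueError(f"unsupported format {fmt!r}")

    if len(config) == 0:
        _write_empty(path, fmt, config.box)
        return

    pos = config.positions
    if fmt == "pdb" and (pos.min() < _PDB_COORD_LIMITS[0] or pos.max() > _PDB_COORD_LIMITS[1]):
        raise ValueError("coordinates exceed the fixed-width PDB coordinate field")
    width = 4 if fmt == "pdb" else 5
    for a in config.atoms:
        if len(a.name) > width:
            warnings.warn(
                f"atom name {a.name!r} exceeds the {fmt.upper()} field width and "
                "will be truncated",
                stacklevel=2,
            )

    mda = _mda()
    resid_order: list[int] = []
    for a in config.atoms:
        if a.residue_id not in resid_order:
            resid_order.append(a.residue_id)
    resindex = {rid: i for i, rid in enumerate(resid_order)}
    restypes = {a.residue_id: a.residue_type for a in config.atoms}

    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        u = mda.Universe.empty(
            len(config),
            n_residues=len(resid_order),
            atom_resindex=[resindex[a.residue_id] for a in config.atoms],
            trajectory=True,
        )
        u.add_TopologyAttr("names", [a.name for a in config.atoms])
        u.add_TopologyAttr("elements", [a.element for a in config.atoms])
        u.add_TopologyAttr("resnames", [restypes[rid] for rid in resid_order])
        u.add_TopologyAttr("resids", resid_order)
        u.atoms.positions = pos
        if config.box is not None:
            u.dimensions = list(config.box) + [90.0, 90.0, 90.0]
        u.atoms.write(str(path))


def _write_empty(path: Path, fmt: str, box) -> None:
    if fmt == "pdb":
        lines = []
        if box is not None:
            lines.append(
                f"CRYST1{box[0]:9.3f}{box[1]:9.3f}{box[2]:9.3f}"
                f"{90.0:7.2f}{90.0:7.2f}{90.0:7.2f} P 1           1"
            )
        lines.append("END")
        path.write_text("\n".join(lines) + "\n")
    elif fmt == "gro":
        b = tuple(e / 10.0 for e in box) if box is not None else (0.0, 0.0, 0.0)
        path.write_text(f"empty system\n    0\n{b[0]:10.5f}{b[1]:10.5f}{b[2]:10.5f}\n")
    else:
        path.write_text("0\nempty system\n")


def read_trajectory(path, format: str = "xyz") -> list[Configuration]:
    """Read a multi-frame XYZ file as a list of Configurations."""
    path = Path(path)
    mda = _mda()
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        u = mda.Universe(str(path), format=format)
        names = u.atoms.names
        frames = []
        for _ in u.trajectory:
            atoms = [
                AtomRecord(
                    index=i,
                    name=str(n),
                    element=_element_from_name(str(n)),
                    residue_id=1,
                    residue_type="UNK",
                    group="substrate",
                    position=np.asarray(p, dtype=float),
                )
                for i, (n, p) in enumerate(zip(names, u.atoms.positions))
            ]
            frames.append(Configuration(atoms=atoms, box=None))
    return frames


# ---------------------------------------------------------------------------
# annotation


def _bonded_hydrogens(
    heavy: AtomRecord,
    candidates: Sequence[AtomRecord],
    preferred_names: Sequence[str],
    box,
) -> tuple[int, ...]:
    by_name = [h.index for h in candidates if h.name in preferred_names]
    if by_name:
        return tuple(sorted(by_name))
    by_dist = [
        h.index
        for h in candidates
        if min_image_distance(heavy.position, h.position, box) < BOND_H_CUTOFF
    ]
    return tuple(sorted(by_dist))


def annotate(config: Configuration, naming_scheme: str = "charmm") -> TopologyAnnotation:
    """Classify donor and acceptor atoms of every nucleotide and the substrate.

    Each nucleotide must expose an O3' (with its hydroxyl hydrogen) and a
    phosphate; base donor/acceptor sets follow a fixed per-base rule table.
    Substrate oxygens are donors when they carry a bonded hydrogen and
    acceptors otherwise.  Deterministic and idempotent for a fixed input.
    """
    if naming_scheme not in {"charmm", "pdb_v3"}:
        raise ValueError(f"unsupported naming scheme {naming_scheme!r}")
    anno = TopologyAnnotation()

    for rid, atoms in sorted(config.residues("nucleotide").items()):
        byname = {a.name: a for a in atoms}
        restype = atoms[0].residue_type
        hydrogens = [a for a in atoms if a.element == "H"]

        o3 = byname.get("O3'")
        if o3 is None:
            raise AnnotationError(f"nucleotide residue {rid} ({restype}) lacks O3'")
        phosphate = frozenset(a.index for a in atoms if a.name in PHOSPHATE_OXYGENS)
        if "P" not in byname or not phosphate:
            raise AnnotationError(f"nucleotide residue {rid} ({restype}) lacks a phosphate")

        h3 = _bonded_hydrogens(o3, hydrogens, C3_HYDROXYL_H, config.box)
        anno.c3_hydroxyl[rid] = (o3.index, h3)
        anno.phosphate_acceptors[rid] = phosphate

        o2 = byname.get("O2'")
        if o2 is not None:
            h2 = _bonded_hydrogens(o2, hydrogens, C2_HYDROXYL_H, config.box)
            if h2:
                anno.c2_hydroxyl[rid] = (o2.index, h2)

        donors = []
        for heavy_name, h_names in BASE_DONORS.get(restype, {}).items():
            heavy = byname.get(heavy_name)
            if heavy is None:
                continue
            hs = _bonded_hydrogens(heavy, hydrogens, h_names, config.box)
            if hs:
                donors.append((heavy.index, hs))
        if donors:
            anno.base_donors[rid] = tuple(donors)
        accs = frozenset(
            byname[n].index for n in BASE_ACCEPTORS.get(restype, set()) if n in byname
        )
        if accs:
            anno.base_acceptors[rid] = accs

    substrate = config.select("substrate")
    if substrate:
        sub_h = [a for a in substrate if a.element == "H"]
        donors = []
        acceptors = []
        for a in substrate:
            if a.element != "O":
                continue
            hs = _bonded_hydrogens(a, sub_h, (), config.box)
            if hs:
                donors.append((a.index, hs))
            else:
                acceptors.append(a.index)
        anno.substrate_donors = tuple(donors)
        anno.substrate_acceptors = frozenset(acceptors)

    return anno
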