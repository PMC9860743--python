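"""Shared builders and independent brute-force oracles for the test suite.

The oracles deliberately avoid the library's vectorized minimum-image code
paths: distances are minimized explicitly over the 27 nearest periodic
images and bond searches enumerate all donor-acceptor pairs.
"""

from __future__ import annotations

import itertools
import math

import numpy as np

from prepolymer.system import AtomRecord, Configuration


def build_config(records, box=None) -> Configuration:
    """records: iterable of (name, element, resid, restype, group, position)."""
    atoms = [
        AtomRecord(
            index=i,
            name=name,
            element=element,
            residue_id=rid,
            residue_type=rtype,
            group=group,
            position=np.asarray(pos, dtype=float),
        )
        for i, (name, element, rid, rtype, group, pos) in enumerate(records)
    ]
    return Configuration(atoms=atoms, box=box)


_SHIFTS = np.array(list(itertools.product((-1.0, 0.0, 1.0), repeat=3)))


def brute_min_image(p, q, box):
    """Minimum-image distance by exhaustive search over 27 image shifts."""
    p = np.asarray(p, dtype=float)
    q = np.asarray(q, dtype=float)
    if box is None:
        return float(np.linalg.norm(q - p))
    b = np.asarray(box, dtype=float)
    pw, qw = np.mod(p, b), np.mod(q, b)
    return float(min(np.linalg.norm(qw + s * b - pw) for s in _SHIFTS))


def _brute_displacement(p, q, box):
    p = np.asarray(p, dtype=float)
    q = np.asarray(q, dtype=float)
    if box is None:
        return q - p
    b = np.asarray(box, dtype=float)
    pw, qw = np.mod(p, b), np.mod(q, b)
    best = min((np.linalg.norm(qw + s * b - pw), tuple(s)) for s in _SHIFTS)
    return qw + np.array(best[1]) * b - pw


def brute_force_hbonds(config, topo, criteria):
    """All-pairs geometric hydrogen-bond search; returns {(d, h, a)}."""
    pos = config.positions
    box = config.box
    residue = {a.index: a.residue_id for a in config.atoms}
    found = set()
    for d, h, _, _ in topo.iter_donors():
        for a, _, _ in topo.iter_acceptors():
            if a == d or residue[a] == residue[d]:
                continue
            dist = brute_min_image(pos[d], pos[a], box)
            if dist > criteria.da_cutoff:
                continue
            v_da = _brute_displacement(pos[d], pos[a], box)
            v_dh = _brute_displacement(pos[d], pos[h], box)
            cosang = v_dh @ v_da / (np.linalg.norm(v_dh) * np.linalg.norm(v_da))
            ang = math.degrees(math.acos(max(-1.0, min(1.0, cosang))))
            if ang <= criteria.angle_cutoff:
                found.add((d, h, a))
    return found


def brute_rdf_counts(positions, box, bin_width, r_max):
    """Plain-loop minimum-image ordered-pair histogram."""
    n_bins = int(round(r_max / bin_width))
    counts = np.zeros(n_bins)
    n = len(positions)
    for i in range(n):
        for j in range(i + 1, n):
            d = brute_min_image(positions[i], positions[j], box)
            k = int(d / bin_width)
            if k < n_bins:
                counts[k] += 2
    return counts


# ---------------------------------------------------------------------------
# small molecular fixtures


def make_amp_residue(rid=1, origin=(0.0, 0.0, 0.0)):
    """A reduced AMP residue with sugar hydroxyls, phosphate and base sites.

    Positions are spread out so no intramolecular pair falls inside typical
    detection cutoffs; hydrogens sit within naming-convention reach of their
    heavy atoms.
    """
    o = np.asarray(origin, dtype=float)
    layout = {
        "C3'": (0, 0, 0),
        "O3'": (1.4, 0, 0),
        "H3T": (2.36, 0, 0),
        "O2'": (0.5, 6.0, 0),
        "HO2'": (0.5, 6.96, 0),
        "C5'": (-1.2, -1.2, 0),
        "O5'": (-6.0, -3.0, 0),
        "P": (-7.5, -3.5, 0),
        "OP1": (-8.6, -4.4, 0),
        "OP2": (-7.5, -5.0, 1.0),
        "N6": (6.0, -6.0, 0),
        "H61": (6.96, -6.0, 0),
        "H62": (5.5, -6.8, 0),
        "N1": (9.0, -9.0, 0),
        "N3": (12.0, -6.0, 0),
        "N7": (10.0, -3.0, 0),
    }
    elements = {n: ("H" if n.startswith("H") else n[0]) for n in layout}
    return [
        (name, elements[name], rid, "AMP", "nucleotide", o + np.asarray(p, float))
        for name, p in layout.items()
    ]


def make_bonded_pair(distance=2.8, angle_deg=10.0, box=(85.0, 85.0, 85.0), origin=(40.0, 40.0, 40.0)):
    """Two minimal nucleotides with one exact O3'-H...OP1 bond along +x."""
    o = np.asarray(origin, dtype=float)
    v = np.array([1.0, 0.0, 0.0])
    theta = math.radians(angle_deg)
    u = np.array([math.cos(theta), math.sin(theta), 0.0])
    records = [
        # donor residue: hydroxyl at origin, its own phosphate far behind
        ("O3'", "O", 1, "AMP", "nucleotide", o),
        ("H3T", "H", 1, "AMP", "nucleotide", o + 0.96 * u),
        ("P", "P", 1, "AMP", "nucleotide", o - 7.0 * v),
        ("OP1", "O", 1, "AMP", "nucleotide", o - 8.5 * v),
        # acceptor residue: phosphate oxygen at the planted distance
        ("OP1", "O", 2, "UMP", "nucleotide", o + distance * v),
        ("P", "P", 2, "UMP", "nucleotide", o + (distance + 1.6) * v),
        ("O3'", "O", 2, "UMP", "nucleotide", o + (distance + 8.0) * v),
        ("H3T", "H", 2, "UMP", "nucleotide", o + (distance + 8.96) * v),
    ]
    return build_config(records, box=box)


def random_fragment_soup(n_nucleotides, box, seed):
    """Unconstrained random reduced nucleotides (clusters may overlap).

    Used to stress the detector against the brute-force oracle: no guard
    bands, arbitrary clustering, bonds across periodic boundaries.
    """
    from prepolymer.synthetic import _FRAGMENT, _ELEMENTS, _fragment_atoms, _random_rotation

    rng = np.random.default_rng(seed)
    b = np.asarray(box, dtype=float)
    records = []
    restypes = ("AMP", "UMP", "CMP", "GMP")
    for rid in range(1, n_nucleotides + 1):
        center = rng.uniform(0, 1, 3) * b
        frag = _fragment_atoms(center, _random_rotation(rng))
        for name in _FRAGMENT:
            records.append(
                (name, _ELEMENTS[name], rid, restypes[rid % 4], "nucleotide", np.mod(frag[name], b))
            )
    return build_config(records, box=tuple(b))
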