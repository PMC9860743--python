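"""Configuration model, file round-trips, annotation, periodic geometry."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from prepolymer import (
    Configuration,
    PlantedSystemSpec,
    annotate,
    make_planted_hbond_system,
    min_image_distance,
    read_configuration,
    write_configuration,
)
from prepolymer.system import AnnotationError, normalize_atom_name

from helpers import brute_min_image, build_config, make_amp_residue


class TestIO:
    def test_minimal_pdb_single_atom(self, tmp_path):
        pdb = tmp_path / "one.pdb"
        pdb.write_text(
            "ATOM      1  O3' AMP A   1      10.000  20.000  30.000  1.00  0.00           O\n"
            "END\n"
        )
        config = read_configuration(pdb)
        assert len(config) == 1
        a = config.atoms[0]
        assert a.group == "nucleotide" and a.residue_type == "AMP"
        assert np.allclose(a.position, [10, 20, 30])

    def test_gro_box_converted_nm_to_angstrom(self, tmp_path):
        gro = tmp_path / "w.gro"
        gro.write_text(
            "tiny\n"
            "    1\n"
            "    1HOH     OW    1   0.100   0.200   0.300\n"
            "   8.5   8.5   8.5\n"
        )
        config = read_configuration(gro)
        assert config.box == (85.0, 85.0, 85.0)
        assert np.allclose(config.atoms[0].position, [1.0, 2.0, 3.0])

    @pytest.mark.parametrize("fmt,tol", [("pdb", 1e-3), ("gro", 5.1e-3), ("xyz", 1e-3)])
    def test_round_trip(self, tmp_path, fmt, tol):
        """write -> read preserves counts, identities and positions.

        PDB and XYZ hold >= 3 decimals in Å; GRO's fixed format stores nm to
        3 decimals, i.e. 0.01 Å quantization, hence its looser tolerance.
        """
        spec = PlantedSystemSpec(n_nucleotides=8, n_planted_bonds=2, box=(40, 40, 40), seed=3)
        config, _ = make_planted_hbond_system(spec)
        path = tmp_path / f"rt.{fmt}"
        write_configuration(config, path)
        back = read_configuration(path)
        assert len(back) == len(config)
        assert np.abs(back.positions - config.positions).max() < tol
        if fmt != "xyz":  # xyz records elements and positions only
            assert [a.name for a in back.atoms] == [a.name for a in config.atoms]
            assert [a.residue_id for a in back.atoms] == [a.residue_id for a in config.atoms]

    def test_empty_configuration_writes_valid_file(self, tmp_path):
        for fmt in ("pdb", "gro", "xyz"):
            path = tmp_path / f"empty.{fmt}"
            write_configuration(Configuration(), path)
            assert path.exists() and path.stat().st_size > 0

    def test_pdb_coordinate_overflow_raises(self, tmp_path):
        config = build_config([("O3'", "O", 1, "AMP", "nucleotide", (1e5, 0, 0))])
        with pytest.raises(ValueError, match="fixed-width"):
            write_configuration(config, tmp_path / "far.pdb")

    def test_unknown_residue_strict_vs_lenient(self, tmp_path):
        pdb = tmp_path / "min.pdb"
        pdb.write_text(
            "ATOM      1  SI  QTZ A   1       0.000   0.000   0.000  1.00  0.00          SI\n"
            "END\n"
        )
        with pytest.warns(UserWarning, match="rule table"):
            config = read_configuration(pdb)
        assert config.atoms[0].group == "substrate"
        with pytest.raises(ValueError, match="unknown residue"):
            read_configuration(pdb, strict=True)

    def test_missing_file(self):
        with pytest.raises(FileNotFoundError):
            read_configuration("/nonexistent/file.pdb")


class TestModel:
    def test_indices_must_be_contiguous(self):
        from prepolymer.system import AtomRecord

        a = AtomRecord(5, "O3'", "O", 1, "AMP", "nucleotide", np.zeros(3))
        with pytest.raises(ValueError, match="contiguous"):
            Configuration(atoms=[a])

    def test_box_must_be_positive(self):
        with pytest.raises(ValueError, match="positive"):
            Configuration(atoms=[], box=(85, -1, 85))

    def test_nucleotide_group_requires_known_residue(self):
        from prepolymer.system import AtomRecord

        with pytest.raises(ValueError, match="nucleotide group"):
            AtomRecord(0, "O3'", "O", 1, "XXX", "nucleotide", np.zeros(3))

    @pytest.mark.parametrize("raw,expected", [("O3′", "O3'"), ("O3*", "O3'"), ("O3'", "O3'")])
    def test_prime_dialects_normalized(self, raw, expected):
        assert normalize_atom_name(raw) == expected


class TestMinImage:
    def test_identical_points(self):
        assert min_image_distance(np.zeros(3), np.zeros(3), (85, 85, 85)) == 0.0

    def test_wraps_across_boundary(self):
        d = min_image_distance(np.array([0.0, 0, 0]), np.array([84.0, 0, 0]), (85, 85, 85))
        assert d == pytest.approx(1.0)

    def test_plain_distance_without_box(self):
        d = min_image_distance(np.array([0.0, 0, 0]), np.array([3.0, 4.0, 0]), None)
        assert d == pytest.approx(5.0)

    @settings(derandomize=True, max_examples=100)
    @given(
        p=st.lists(st.floats(-200, 200), min_size=3, max_size=3),
        q=st.lists(st.floats(-200, 200), min_size=3, max_size=3),
        edges=st.lists(st.floats(5, 120), min_size=3, max_size=3),
    )
    def test_matches_27_image_brute_force(self, p, q, edges):
        p, q = np.array(p), np.array(q)
        assert min_image_distance(p, q, edges) == pytest.approx(
            brute_min_image(p, q, edges), abs=1e-9
        )


class TestAnnotate:
    def test_complete_amp_residue(self):
        config = build_config(make_amp_residue())
        topo = annotate(config)
        o3, hs = topo.c3_hydroxyl[1]
        assert config.atoms[o3].name == "O3'" and len(hs) == 1
        assert len(topo.phosphate_acceptors[1]) >= 3  # O5', OP1, OP2
        assert 1 in topo.c2_hydroxyl
        assert len(topo.base_donors[1]) == 1  # N6 with H61/H62
        base_acc_names = {config.atoms[i].name for i in topo.base_acceptors[1]}
        assert base_acc_names == {"N1", "N3", "N7"}

    def test_water_only_configuration_is_empty(self):
        config = build_config(
            [
                ("OW", "O", 1, "HOH", "water", (0, 0, 0)),
                ("HW1", "H", 1, "HOH", "water", (0.96, 0, 0)),
            ]
        )
        topo = annotate(config)
        assert not topo.c3_hydroxyl and not topo.phosphate_acceptors
        assert not list(topo.iter_donors()) and not list(topo.iter_acceptors())

    def test_missing_o3_raises_with_residue_named(self):
        records = [r for r in make_amp_residue() if r[0] != "O3'"]
        with pytest.raises(AnnotationError, match="residue 1"):
            annotate(build_config(records))

    def test_missing_phosphate_raises(self):
        records = [r for r in make_amp_residue() if r[0] not in ("P", "O5'", "OP1", "OP2")]
        with pytest.raises(AnnotationError, match="phosphate"):
            annotate(build_config(records))

    def test_substrate_oxygen_donor_vs_acceptor(self):
        config = build_config(
            [
                ("OS", "O", 0, "MIN", "substrate", (0, 0, 0)),
                ("HS", "H", 0, "MIN", "substrate", (0.96, 0, 0)),
                ("OS", "O", 0, "MIN", "substrate", (10, 0, 0)),  # bare oxygen
                ("SI", "X", 0, "MIN", "substrate", (12, 0, 0)),
            ]
        )
        topo = annotate(config)
        assert [d for d, _ in topo.substrate_donors] == [0]
        assert topo.substrate_acceptors == frozenset({2})

    def test_deterministic_and_idempotent(self):
        config = build_config(make_amp_residue())
        assert annotate(config) == annotate(config)

    def test_hydrogen_bonding_by_distance_fallback(self):
        # hydrogen with a nonstandard name is still attached via < 1.2 Å
        records = [
            (n if n != "H3T" else "HX", e, r, t, g, p) for n, e, r, t, g, p in make_amp_residue()
        ]
        topo = annotate(build_config(records))
        _, hs = topo.c3_hydroxyl[1]
        assert len(hs) == 1
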