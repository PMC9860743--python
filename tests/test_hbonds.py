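"""Hydrogen-bond detection, classification and the dehydration trace."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from prepolymer import (
    HBondCriteria,
    PlantedSystemSpec,
    annotate,
    count_by_category,
    detect_hbonds,
    hbond_trace,
    make_planted_hbond_system,
)
from prepolymer.hbonds import CATEGORIES

from helpers import (
    brute_force_hbonds,
    build_config,
    make_amp_residue,
    make_bonded_pair,
    random_fragment_soup,
)


class TestDetect:
    def test_planted_pair_within_defaults(self):
        config = make_bonded_pair(distance=2.8, angle_deg=10.0)
        bonds = detect_hbonds(config, annotate(config))
        assert len(bonds) == 1
        b = bonds[0]
        assert b.distance == pytest.approx(2.8)
        assert b.angle == pytest.approx(10.0)
        assert b.category == "nuc_nuc_c3c5"

    def test_beyond_distance_cutoff(self):
        config = make_bonded_pair(distance=3.2, angle_deg=10.0)
        assert detect_hbonds(config, annotate(config)) == []

    def test_beyond_angle_cutoff(self):
        config = make_bonded_pair(distance=2.8, angle_deg=25.0)
        assert detect_hbonds(config, annotate(config)) == []

    def test_bond_across_periodic_boundary(self):
        # donor sits 1.4 Å inside the far x face; acceptor wraps around
        config = make_bonded_pair(distance=2.8, angle_deg=5.0, origin=(83.6, 40.0, 40.0))
        assert config.positions[:, 0].max() > 85.0  # construction really straddles
        bonds = detect_hbonds(config, annotate(config))
        assert len(bonds) == 1 and bonds[0].distance == pytest.approx(2.8)

    def test_output_sorted_by_donor_acceptor(self, planted_200_50_bonds):
        keys = [(b.donor_index, b.acceptor_index) for b in planted_200_50_bonds]
        assert keys == sorted(keys)

    @settings(derandomize=True, max_examples=15, deadline=None)
    @given(
        n=st.integers(5, 60),
        box_edge=st.floats(18.0, 45.0),
        cutoff=st.floats(2.4, 3.6),
        angle=st.floats(10.0, 60.0),
        seed=st.integers(0, 10_000),
    )
    def test_matches_all_pairs_brute_force(self, n, box_edge, cutoff, angle, seed):
        """Detector agrees exactly with O(n^2) minimum-image enumeration."""
        config = random_fragment_soup(n, (box_edge,) * 3, seed)
        topo = annotate(config)
        criteria = HBondCriteria(da_cutoff=cutoff, angle_cutoff=angle)
        got = {(b.donor_index, b.hydrogen_index, b.acceptor_index)
               for b in detect_hbonds(config, topo, criteria)}
        assert got == brute_force_hbonds(config, topo, criteria)

    @settings(derandomize=True, max_examples=10, deadline=None)
    @given(seed=st.integers(0, 10_000))
    def test_relaxing_cutoffs_is_monotone(self, seed):
        config = random_fragment_soup(30, (30.0, 30.0, 30.0), seed)
        topo = annotate(config)
        tight = detect_hbonds(config, topo, HBondCriteria(2.8, 15.0))
        loose = detect_hbonds(config, topo, HBondCriteria(3.4, 40.0))
        tight_keys = {(b.donor_index, b.hydrogen_index, b.acceptor_index) for b in tight}
        loose_keys = {(b.donor_index, b.hydrogen_index, b.acceptor_index) for b in loose}
        assert tight_keys <= loose_keys

    def test_classification_invariant_under_atom_reordering(self):
        config = make_bonded_pair()
        rng = np.random.default_rng(0)
        perm = rng.permutation(len(config))
        records = []
        for new_i, old_i in enumerate(perm):
            a = config.atoms[old_i]
            records.append((a.name, a.element, a.residue_id, a.residue_type, a.group, a.position))
        shuffled = build_config(records, box=config.box)
        b1 = detect_hbonds(config, annotate(config))
        b2 = detect_hbonds(shuffled, annotate(shuffled))
        assert [b.category for b in b1] == [b.category for b in b2]
        assert len(b1) == len(b2) == 1

    def test_criteria_validation(self):
        with pytest.raises(ValueError):
            HBondCriteria(da_cutoff=-1)
        with pytest.raises(ValueError):
            HBondCriteria(angle_cutoff=120)


class TestClassify:
    def _substrate_oh(self, origin, rid=0):
        return [
            ("OS", "O", rid, "MIN", "substrate", origin),
            ("HS", "H", rid, "MIN", "substrate", (origin[0] + 0.96, origin[1], origin[2])),
        ]

    def test_c3_hydroxyl_to_phosphate_is_prepolymer(self):
        config = make_bonded_pair()
        (bond,) = detect_hbonds(config, annotate(config))
        assert bond.category == "nuc_nuc_c3c5"

    def test_substrate_donor_to_base_nitrogen(self):
        records = make_amp_residue(rid=1)
        n7 = dict((r[0], r[5]) for r in records)["N7"]
        records += self._substrate_oh((n7[0] + 2.8, n7[1], n7[2]))
        # point the O-H at N7: hydrogen between substrate O and the base
        records[-1] = ("HS", "H", 0, "MIN", "substrate", (n7[0] + 2.8 - 0.96, n7[1], n7[2]))
        config = build_config(records)
        bonds = detect_hbonds(config, annotate(config))
        cats = {b.category for b in bonds}
        assert "nuc_substrate_base" in cats

    def test_sugar_hydroxyl_to_substrate_acceptor(self):
        records = make_amp_residue(rid=3)
        ho2 = dict((r[0], r[5]) for r in records)["HO2'"]
        # bare substrate oxygen straight beyond the O2'-H vector
        records.append(("OS", "O", 0, "MIN", "substrate", (ho2[0], ho2[1] + 1.9, ho2[2])))
        config = build_config(records)
        bonds = detect_hbonds(config, annotate(config))
        assert {b.category for b in bonds} == {"nuc_substrate_sugar_hydroxyl"}

    def test_phosphate_to_substrate_donor(self):
        records = make_amp_residue(rid=2)
        op1 = dict((r[0], r[5]) for r in records)["OP1"]
        records += [
            ("OS", "O", 0, "MIN", "substrate", (op1[0] - 2.8, op1[1], op1[2])),
            ("HS", "H", 0, "MIN", "substrate", (op1[0] - 2.8 + 0.96, op1[1], op1[2])),
        ]
        config = build_config(records)
        bonds = detect_hbonds(config, annotate(config))
        assert "nuc_substrate_phosphate" in {b.category for b in bonds}

    def test_c2_hydroxyl_to_phosphate_is_not_prepolymer(self):
        """Only the 3'-hydroxyl donor counts toward the C3'-C5' statistic."""
        records = make_amp_residue(rid=1)
        ho2 = dict((r[0], r[5]) for r in records)["HO2'"]
        records += [
            ("OP1", "O", 2, "UMP", "nucleotide", (ho2[0], ho2[1] + 1.9, ho2[2])),
            ("P", "P", 2, "UMP", "nucleotide", (ho2[0], ho2[1] + 3.5, ho2[2])),
            ("O3'", "O", 2, "UMP", "nucleotide", (ho2[0], ho2[1] + 9.0, ho2[2])),
        ]
        config = build_config(records)
        bonds = detect_hbonds(config, annotate(config))
        by_donor_res = [b for b in bonds if config.atoms[b.donor_index].residue_id == 1]
        assert by_donor_res and all(b.category == "nuc_nuc_other" for b in by_donor_res)


class TestCounts:
    def test_empty_is_all_zero(self):
        counts = count_by_category([])
        assert set(counts) == set(CATEGORIES)
        assert all(v == 0 for v in counts.values())

    def test_planted_c3c5_counts(self, planted_200_50_bonds):
        counts = count_by_category(planted_200_50_bonds)
        assert counts["nuc_nuc_c3c5"] == 50
        assert sum(counts.values()) == len(planted_200_50_bonds)


class TestTrace:
    def _series(self, bond_counts, box=(60.0, 60.0, 60.0)):
        series = []
        hydr = np.linspace(100, 5, len(bond_counts))
        for h, nb in zip(hydr, bond_counts):
            spec = PlantedSystemSpec(
                n_nucleotides=20, n_planted_bonds=nb, box=box, seed=int(nb) + 7
            )
            config, _ = make_planted_hbond_system(spec)
            series.append((float(h), config))
        return series

    def test_bond_count_rises_on_drying(self):
        table = hbond_trace(self._series([2, 5, 9]))
        assert list(table["n_c3c5_total"]) == [2, 5, 9]
        assert table["hydration_percent"].is_monotonic_decreasing

    def test_substrate_free_series_has_no_substrate_bonds(self):
        table = hbond_trace(self._series([1, 3]))
        assert (table["n_nuc_substrate"] == 0).all()

    def test_single_step(self):
        table = hbond_trace(self._series([4]))
        assert len(table) == 1

    def test_unsorted_series_rejected(self):
        series = self._series([1, 3])[::-1]
        with pytest.raises(ValueError, match="decreasing hydration"):
            hbond_trace(series)
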