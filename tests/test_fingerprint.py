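"""Hydrogen-bond detection, classing, moieties, indexing and counting."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from polprofiler import fixtures as fx
from polprofiler.fingerprint import (IndexingError, MoietyError,
                                     build_fingerprint, classify_distance,
                                     classify_moiety, count_contacts,
                                     find_direct_hbonds,
                                     find_water_bridges, index_positions)
from polprofiler.structure_io import Atom, Residue


class TestDirectBonds:
    @pytest.mark.parametrize("d,expected", [
        (3.20, "strong"),   # inclusive upper bound of the strong class
        (3.21, "weak"),
        (4.00, "weak"),
        (2.20, "strong"),
    ])
    def test_boundary_distances(self, d, expected, roundtrip):
        s, _ = fx.make_hbond_fixture([d])
        bonds, clashes = find_direct_hbonds(roundtrip(s, f"d{d}"))
        assert [b.strength for b in bonds] == [expected]
        assert not clashes

    def test_out_of_range_is_no_bond(self, roundtrip):
        s, _ = fx.make_hbond_fixture([4.01])
        bonds, clashes = find_direct_hbonds(roundtrip(s, "far"))
        assert bonds == [] and clashes == []

    def test_sub_minimum_is_clash_not_bond(self, roundtrip):
        s, _ = fx.make_hbond_fixture([2.1])
        bonds, clashes = find_direct_hbonds(roundtrip(s, "close"))
        assert bonds == []
        assert len(clashes) == 1 and clashes[0].distance < 2.2

    def test_five_pair_fixture_counts(self, roundtrip):
        s, truth = fx.make_hbond_fixture([2.5, 3.0, 3.2, 3.5, 4.2])
        bonds, _ = find_direct_hbonds(roundtrip(s, "five"))
        strong = sum(b.strength == "strong" for b in bonds)
        weak = sum(b.strength == "weak" for b in bonds)
        assert (strong, weak) == (truth["n_strong"], truth["n_weak"]) \
            == (3, 1)

    def test_acceptor_acceptor_pairs_suppressed(self, roundtrip):
        s, truth = fx.make_hbond_fixture([2.8, 2.8],
                                         roles=["acceptor", "donor"])
        bonds, _ = find_direct_hbonds(roundtrip(s, "roles"))
        assert len(bonds) == 1
        assert bonds[0].protein_atom.name == "NZ"

    @given(st.floats(min_value=0.5, max_value=6.0,
                     allow_nan=False, allow_infinity=False))
    @settings(max_examples=60, deadline=None)
    def test_distance_classes_partition_the_axis(self, d):
        assert classify_distance(d) in {"clash", "strong", "weak", "none"}
        # monotone thresholds
        if d < 2.199:
            assert classify_distance(d) == "clash"
        if 2.201 < d < 3.199:
            assert classify_distance(d) == "strong"
        if 3.201 < d < 3.999:
            assert classify_distance(d) == "weak"
        if d > 4.001:
            assert classify_distance(d) == "none"


class TestWaterBridges:
    def test_both_legs_strong_gives_strong_bridge(self, roundtrip):
        s, _ = fx.make_water_bridge_fixture([(2.8, 2.9)])
        bridges = find_water_bridges(roundtrip(s, "wb"))
        assert len(bridges) == 1
        assert bridges[0].strength == "strong"
        assert bridges[0].bridge_water is not None

    def test_weakest_leg_rule(self, roundtrip):
        s, _ = fx.make_water_bridge_fixture([(2.8, 3.6)])
        (bridge,) = find_water_bridges(roundtrip(s, "wb2"))
        assert bridge.strength == "weak"
        assert bridge.leg_distances == pytest.approx((2.8, 3.6), abs=1e-2)

    def test_two_water_chain_is_not_a_bridge(self, roundtrip):
        s, _ = fx.make_water_bridge_fixture([(2.8, 2.9)],
                                            chain_two_waters=True)
        assert find_water_bridges(roundtrip(s, "chain")) == []

    def test_no_waters_no_bridges(self, roundtrip):
        s, _ = fx.make_hbond_fixture([3.0])
        assert find_water_bridges(roundtrip(s, "dry")) == []


class TestMoiety:
    @pytest.mark.parametrize("resn,entity,atom,expected", [
        ("DT", "dna", "OP1", "phosphate_backbone"),
        ("DT", "dna", "O3'", "phosphate_backbone"),
        ("DA", "dna", "O4'", "sugar_o4p"),
        ("DA", "dna", "N7", "base_major_groove"),
        ("DA", "dna", "N3", "base_minor_groove"),
        ("DA", "dna", "N1", "base_wc_edge"),
        ("DG", "dna", "N2", "base_minor_groove"),
        ("DG", "dna", "O6", "base_major_groove"),
        ("DT", "dna", "O2", "base_minor_groove"),
        ("DT", "dna", "O4", "base_major_groove"),
        ("DC", "dna", "N3", "base_wc_edge"),
        ("DTP", "dntp_ligand", "O1G", "gamma_phosphate"),
        ("DTP", "dntp_ligand", "O2A", "alpha_phosphate"),
        ("DTP", "dntp_ligand", "O3B", "beta_phosphate"),
        ("DTP", "dntp_ligand", "O3'", "sugar_3oh"),
        ("DTP", "dntp_ligand", "N7", "base_major_groove"),
    ])
    def test_atom_to_moiety_table(self, resn, entity, atom, expected):
        res = Residue("X", 1, resn, [Atom(1, atom, atom[0], (0, 0, 0))],
                      entity=entity)
        assert classify_moiety(res, res.atoms[0]) == expected

    def test_unknown_atom_raises_with_context(self):
        res = Residue("X", 1, "DA", [Atom(1, "QQ", "Q", (0, 0, 0))],
                      entity="dna")
        with pytest.raises(MoietyError, match="DA1"):
            classify_moiety(res, res.atoms[0])

    def test_every_duplex_heavy_atom_maps(self, duplex_with_contacts):
        s, _ = duplex_with_contacts
        for res in s.residues:
            if res.entity in ("dna", "dntp_ligand"):
                for atom in res.atoms:
                    if atom.element == "P":
                        continue
                    assert classify_moiety(res, atom)


class TestPositionIndex:
    def test_duplex_indexing_matches_construction(self, roundtrip):
        s, truth = fx.make_duplex_complex()
        index = index_positions(roundtrip(s, "idx"))
        assert index.primer_chain == truth["primer_chain"]
        assert index.template_chain == truth["template_chain"]
        assert index.templating_key[1] == truth["templating_seq_id"]
        got = sorted(i for (strand, i) in index.labels.values()
                     if strand == "template")
        assert got == truth["template_positions"]
        # all ten published-style positions t-1..t-10 present
        assert set(range(-10, 0)) <= set(got)
        got_p = sorted(i for (strand, i) in index.labels.values()
                       if strand == "primer")
        assert got_p == truth["primer_positions"]

    def test_structure_without_ligand_raises(self, roundtrip):
        s, _ = fx.make_duplex_complex(with_ligand=False)
        with pytest.raises(IndexingError):
            index_positions(roundtrip(s, "nolig"))


class TestFingerprint:
    def test_planned_contacts_fully_recovered(self, roundtrip,
                                              duplex_with_contacts):
        s, truth = duplex_with_contacts
        fp = build_fingerprint(roundtrip(s, "fp"))
        assert len(fp.records) == len(truth["contacts"]) == 4
        got = {(r.label.strand, r.label.position, r.bond.klass)
               for r in fp.records}
        assert got == {("template", -7, "direct-strong"),
                       ("template", -3, "direct-weak"),
                       ("primer", 0, "direct-strong"),
                       ("template", -2, "water-strong")}
        assert all(r.label.moiety == "phosphate_backbone"
                   for r in fp.records)

    def test_count_matrix_total_equals_record_count(self, roundtrip,
                                                    duplex_with_contacts):
        s, _ = duplex_with_contacts
        fp = build_fingerprint(roundtrip(s, "cm"))
        assert sum(fp.count_matrix().values()) == len(fp.records)

    def test_count_contacts_filters(self, roundtrip, duplex_with_contacts):
        s, _ = duplex_with_contacts
        fp = build_fingerprint(roundtrip(s, "cc"))
        assert count_contacts(fp) == 4
        assert count_contacts(fp, strand="template",
                              mediation="direct") == 2
        assert count_contacts(fp, strand="template", positions=(-7, -3),
                              moieties="phosphate_backbone") == 2
        assert count_contacts(fp, strength="strong") == 3
        assert count_contacts(fp, strand="template",
                              distinct="residue_moiety") == 3

    def test_empty_fingerprint_counts_zero(self, roundtrip):
        s, _ = fx.make_duplex_complex()
        fp = build_fingerprint(roundtrip(s, "empty"))
        assert count_contacts(fp) == 0

    def test_fingerprint_invariant_to_atom_order(self, tmp_path):
        s, _ = fx.make_duplex_complex(contact_plan=[
            {"strand": "template", "position": -5, "atom": "OP1",
             "distance": 3.0, "role": "both"}])
        rng = np.random.default_rng(5)
        shuffled = fx.Structure(id=s.id)
        order = rng.permutation(len(s.residues))
        shuffled.residues = [s.residues[i] for i in order]
        fp_a = build_fingerprint(s)
        fp_b = build_fingerprint(shuffled)
        key = lambda r: (r.bond.protein_res.key, r.bond.partner_res.key,
                         r.bond.klass, r.label.moiety)
        assert sorted(map(key, fp_a.records)) == \
            sorted(map(key, fp_b.records))


def test_stacking_contact_detected(roundtrip):
    """An aromatic ring centroid within 4.5 A of a deoxyribose centroid is
    reported as a stacking contact, not a hydrogen bond."""
    s, _ = fx.make_duplex_complex()
    lig = next(r for r in s.residues if r.entity == "dntp_ligand")
    sugar = np.mean([a.coords for a in lig.atoms
                     if a.name in ("C1'", "C2'", "C3'", "C4'", "O4'")],
                    axis=0)
    tyr = Residue("E", 409, "TYR")
    ring = {"CG": (0, 0), "CD1": (1.2, 0.7), "CD2": (1.2, -0.7),
            "CE1": (2.6, 0.7), "CE2": (2.6, -0.7), "CZ": (3.2, 0.0)}
    base = sugar + np.array([0.0, 0.0, 3.6])
    for i, (name, (dx, dy)) in enumerate(ring.items()):
        tyr.atoms.append(Atom(900 + i, name, "C",
                              base + np.array([dx - 1.5, dy, 0.0])))
    s.residues.append(tyr)
    fx.classify_entities(s)
    fp = build_fingerprint(s)
    assert any(c.protein_res.res_name == "TYR" for c in fp.stacking)
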