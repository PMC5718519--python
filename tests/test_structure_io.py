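"""Parsing, entity classification, selection and B-factor lookup."""

import numpy as np
import pytest

from polprofiler import fixtures as fx
from polprofiler.structure_io import (Atom, LookupError_, ParseError,
                                      Residue, SelectionSyntaxError,
                                      Structure, atom_bfactor,
                                      classify_entities, prune_altlocs,
                                      read_structure, select, write_pdb)


def test_pdb_roundtrip_preserves_atoms(tmp_path):
    """write(read(f)) keeps atom count, names, coordinates (3 decimals),
    occupancies and B-factors."""
    s, _ = fx.make_duplex_complex()
    p1 = tmp_path / "a.pdb"
    write_pdb(s, p1)
    s2 = read_structure(p1)
    p2 = tmp_path / "b.pdb"
    write_pdb(s2, p2)
    s3 = read_structure(p2)
    assert s2.n_atoms == s.n_atoms == s3.n_atoms
    for (r2, a2), (r3, a3) in zip(s2.atoms(), s3.atoms()):
        assert a2.name == a3.name
        assert np.allclose(a2.coords, a3.coords, atol=5e-4)
        assert a2.occupancy == a3.occupancy
        assert a2.b_factor == a3.b_factor


def test_tiny_fixture_roundtrips_bit_exact(tmp_path, roundtrip):
    s = Structure("tiny")
    r = Residue("A", 1, "GLY")
    r.atoms = [Atom(1, "N", "N", (1.234, -2.5, 0.001)),
               Atom(2, "CA", "C", (2.0, 0.0, 0.25)),
               Atom(3, "C", "C", (3.125, 1.5, -4.75))]
    s.residues.append(r)
    s2 = roundtrip(classify_entities(s), "tiny")
    assert s2.n_atoms == 3
    for (_, a), (_, b) in zip(s.atoms(), s2.atoms()):
        assert a.name == b.name
        assert np.array_equal(a.coords, b.coords)  # 3-decimal coords exact


def test_duplex_fixture_residue_classification(roundtrip):
    s, truth = fx.make_duplex_complex()
    s2 = roundtrip(s, "duplex")
    counts = s2.entity_counts()
    assert counts["dna"] == truth["n_dna_residues"] == 27
    assert counts["dntp_ligand"] == 1


@pytest.mark.parametrize("resn,atoms,expected", [
    ("HOH", [("O", "O")], "water"),
    ("MN", [("MN", "MN")], "metal"),
    ("DTP", [("PA", "P"), ("PB", "P"), ("PG", "P")], "dntp_ligand"),
    ("ALA", [("N", "N"), ("CA", "C"), ("C", "C")], "protein"),
    ("UNX", [("X1", "C")], "other"),
])
def test_classify_entities_by_name_and_content(resn, atoms, expected):
    s = Structure("t")
    r = Residue("A", 1, resn)
    r.atoms = [Atom(i + 1, n, e, (float(i), 0, 0))
               for i, (n, e) in enumerate(atoms)]
    s.residues.append(r)
    assert classify_entities(s).residues[0].entity == expected


def test_entity_partition_is_total():
    s, _ = fx.make_duplex_complex()
    counts = s.entity_counts()
    assert sum(counts.values()) == len(s.residues)


class TestSelection:
    def test_calpha_count_matches_protein_length(self):
        open_s, _, _ = fx.make_rotation_pair(0.0, n_residues=40)
        assert len(select(open_s, "calpha")) == 40

    def test_chain_and_resi(self, duplex_with_contacts):
        s, _ = duplex_with_contacts
        sel = select(s, "chain=T and resi=5")
        assert {r.seq_id for r, _ in sel.pairs} == {5}
        assert {r.chain_id for r, _ in sel.pairs} == {"T"}

    def test_and_is_subset_and_not_is_complement(self, duplex_with_contacts):
        s, _ = duplex_with_contacts
        a = select(s, "entity=dna")
        ab = select(s, "entity=dna and name=P")
        not_a = select(s, "not entity=dna")
        ids_a = {id(x) for x in a.atoms}
        assert {id(x) for x in ab.atoms} <= ids_a
        assert len(a) + len(not_a) == s.n_atoms
        assert ids_a.isdisjoint({id(x) for x in not_a.atoms})

    def test_resi_range_and_or(self, duplex_with_contacts):
        s, _ = duplex_with_contacts
        sel = select(s, "chain=T and resi=1-3 and name=C1'")
        assert len(sel) == 3
        both = select(s, "entity=metal or entity=dntp_ligand")
        assert all(r.entity in ("metal", "dntp_ligand")
                   for r, _ in both.pairs)

    @pytest.mark.parametrize("expr", ["", "foo=bar", "resi=9-1",
                                      "name=", "bogus"])
    def test_malformed_expressions_raise(self, expr, duplex_with_contacts):
        s, _ = duplex_with_contacts
        with pytest.raises(SelectionSyntaxError):
            select(s, expr)

    def test_selection_is_order_stable(self, duplex_with_contacts):
        s, _ = duplex_with_contacts
        a = select(s, "entity=dna").atoms
        b = select(s, "entity=dna").atoms
        assert [x.serial for x in a] == [x.serial for x in b]


class TestBFactor:
    def test_stored_value_roundtrips(self, roundtrip):
        s = Structure("b")
        r = Residue("A", 7, "ALA")
        r.atoms = [Atom(1, "CA", "C", (0, 0, 0), 1.0, 10.0)]
        s.residues.append(r)
        s2 = roundtrip(classify_entities(s), "bf")
        assert atom_bfactor(s2, "A", 7, "CA") == pytest.approx(10.0)

    def test_ambiguous_altloc_requires_explicit_choice(self):
        s = Structure("b")
        r = Residue("A", 1, "SER")
        r.atoms = [Atom(1, "OG", "O", (0, 0, 0), 0.6, 11.0, "A"),
                   Atom(2, "OG", "O", (1, 1, 1), 0.4, 22.0, "B")]
        s.residues.append(r)
        with pytest.raises(LookupError_):
            atom_bfactor(s, "A", 1, "OG")
        assert atom_bfactor(s, "A", 1, "OG", altloc="B") == 22.0

    def test_missing_atom_raises(self):
        s = Structure("b")
        s.residues.append(Residue("A", 1, "GLY",
                                  [Atom(1, "CA", "C", (0, 0, 0))]))
        with pytest.raises(LookupError_):
            atom_bfactor(s, "A", 1, "CB")


def test_prune_altlocs_keeps_highest_occupancy_tie_breaks_a():
    s = Structure("p")
    r = Residue("A", 1, "SER")
    r.atoms = [Atom(1, "OG", "O", (0, 0, 0), 0.5, 11.0, "B"),
               Atom(2, "OG", "O", (1, 1, 1), 0.5, 22.0, "A"),
               Atom(3, "CA", "C", (2, 2, 2), 1.0, 5.0)]
    s.residues.append(r)
    pruned = prune_altlocs(s)
    og = pruned.residues[0].atom("OG")
    assert og.altloc == "A"
    assert pruned.residues[0].atom("CA").b_factor == 5.0


def test_unreadable_file_raises_parse_error(tmp_path):
    with pytest.raises(ParseError):
        read_structure(tmp_path / "missing.pdb")
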