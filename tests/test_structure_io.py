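"""Parsing, naming dialects, residue classification and chemistry partitions."""
import numpy as np
import pytest

from waterbridges.structure_io import (
    AMINO_ACIDS,
    MAIN_CHAIN_ATOMS,
    Moiety,
    ResidueClass,
    StructureParseError,
    canonical_atom_name,
    chain_part_of,
    classify_residue,
    moiety_of,
    parse_structure,
    write_pdb,
)
from waterbridges.hbond_detect import Role, donor_acceptor_roles
from waterbridges.synthetic_fixtures import _template

from helpers import make_residue

MINI_PDB = """\
ATOM      1  N   ARG A   1      10.000  10.000  10.000  1.00 20.00           N
ATOM      2  CA  ARG A   1      11.400  10.000  10.000  1.00 20.00           C
ATOM      3  NH1 ARG A   1      13.000  11.000  10.000  1.00 20.00           N
ATOM      4  P     A B   1      30.000  10.000  10.000  1.00 30.00           P
ATOM      5  O2* A   B   1      32.000  11.000  10.000  1.00 30.00           O
ATOM      6  N7    A B   1      34.000  12.000  10.000  1.00 30.00           N
HETATM    7  O   HOH W   1      20.000  10.500  10.000  1.00 40.00           O
END
"""

TWO_MODEL_PDB = """\
MODEL        1
ATOM      1  O   HOH W   1       0.000   0.000   0.000  1.00 10.00           O
ENDMDL
MODEL        2
ATOM      2  O   HOH W   1       5.000   0.000   0.000  1.00 11.00           O
HETATM    3  O   HOH W   2       9.000   0.000   0.000  1.00 12.00           O
ENDMDL
END
"""

ALTLOC_PDB = """\
ATOM      1  N  AARG A   1       0.000   0.000   0.000  0.40 20.00           N
ATOM      2  N  BARG A   1       1.000   0.000   0.000  0.60 21.00           N
ATOM      3  O  AARG A   1       3.000   0.000   0.000  0.50 22.00           O
ATOM      4  O  BARG A   1       4.000   0.000   0.000  0.50 23.00           O
END
"""


class TestParsing:
    def test_three_residue_classes(self, tmp_path):
        p = tmp_path / "mini.pdb"
        p.write_text(MINI_PDB)
        st = parse_structure(p)
        classes = {r.res_name: r.res_class for r in st.residues}
        assert classes == {
            "ARG": ResidueClass.AMINO_ACID,
            "A": ResidueClass.RIBONUCLEOTIDE,
            "HOH": ResidueClass.WATER,
        }

    def test_star_prime_dialect_normalized(self, tmp_path):
        p = tmp_path / "mini.pdb"
        p.write_text(MINI_PDB)
        st = parse_structure(p)
        nt = next(r for r in st.residues if r.res_name == "A")
        assert nt.atom("O2'") is not None
        assert "O2*" not in nt.atom_names()

    def test_model_selection(self, tmp_path):
        p = tmp_path / "models.pdb"
        p.write_text(TWO_MODEL_PDB)
        st1 = parse_structure(p, model=1)
        st2 = parse_structure(p, model=2)
        assert len(st1.residues) == 1
        assert len(st2.residues) == 2
        assert st1.residues[0].atom("O").coord[0] == pytest.approx(0.0)
        with pytest.raises(StructureParseError):
            parse_structure(p, model=3)

    def test_altloc_keeps_highest_occupancy_then_first(self, tmp_path):
        p = tmp_path / "alt.pdb"
        p.write_text(ALTLOC_PDB)
        (res,) = parse_structure(p).residues
        n = res.atom("N")
        assert n.altloc == "B" and n.occupancy == pytest.approx(0.6)
        o = res.atom("O")  # occupancy tie -> lexicographically first altloc
        assert o.altloc == "A"

    def test_missing_file_raises(self, tmp_path):
        with pytest.raises(StructureParseError):
            parse_structure(tmp_path / "absent.pdb")

    def test_structure_without_waters_is_valid(self, tmp_path):
        p = tmp_path / "dry.pdb"
        p.write_text("\n".join(l for l in MINI_PDB.splitlines() if "HOH" not in l) + "\n")
        st = parse_structure(p)
        assert st.waters() == []

    def test_mmcif_round_trip(self, tmp_path, ensemble):
        import gemmi
        _, structure, _ = ensemble
        pdb_path = tmp_path / "e.pdb"
        write_pdb(structure, pdb_path)
        doc = gemmi.read_structure(str(pdb_path)).make_mmcif_document()
        cif_path = tmp_path / "e.cif"
        doc.write_file(str(cif_path))
        st_cif = parse_structure(cif_path, fmt="mmcif")
        st_pdb = parse_structure(pdb_path, fmt="pdb")
        assert [r.res_name for r in st_cif.residues] == [r.res_name for r in st_pdb.residues]
        assert [r.res_class for r in st_cif.residues] == [r.res_class for r in st_pdb.residues]

    def test_pdb_round_trip(self, tmp_path, ensemble):
        """Writing a parsed fixture back to PDB and re-parsing is lossless."""
        _, structure, _ = ensemble
        p1 = tmp_path / "a.pdb"
        write_pdb(structure, p1)
        st1 = parse_structure(p1)
        p2 = tmp_path / "b.pdb"
        write_pdb(st1, p2)
        st2 = parse_structure(p2)
        assert len(st1.residues) == len(st2.residues) == len(structure.residues)
        for r1, r2 in zip(st1.residues, st2.residues):
            assert (r1.chain_id, r1.seq_num, r1.res_name, r1.res_class) == \
                   (r2.chain_id, r2.seq_num, r2.res_name, r2.res_class)
            assert r1.atom_names() == r2.atom_names()
            for a1, a2 in zip(r1.atoms, r2.atoms):
                assert np.allclose(a1.coord, a2.coord, atol=1e-6)
                assert a1.b_factor == pytest.approx(a2.b_factor)


class TestClassification:
    @pytest.mark.parametrize("name,expected", [
        ("HOH", ResidueClass.WATER),
        ("WAT", ResidueClass.WATER),
        ("A", ResidueClass.RIBONUCLEOTIDE),
        ("U", ResidueClass.RIBONUCLEOTIDE),
        ("ALA", ResidueClass.AMINO_ACID),
        ("PSU", ResidueClass.OTHER),   # modified nucleotides are out of scope
        ("DA", ResidueClass.OTHER),    # DNA is out of scope
        ("MG", ResidueClass.OTHER),
    ])
    def test_classify_residue(self, name, expected):
        assert classify_residue(name) is expected

    @pytest.mark.parametrize("raw,canonical", [
        ("O2*", "O2'"), ("O2′", "O2'"), ("O2'", "O2'"),
        ("O1P", "OP1"), ("O2P", "OP2"), ("N7", "N7"),
    ])
    def test_canonical_atom_name(self, raw, canonical):
        assert canonical_atom_name(raw) == canonical


class TestMoietyPartition:
    @pytest.mark.parametrize("nt,atom,expected", [
        ("A", "OP1", Moiety.PH),
        ("G", "N7", Moiety.NB),
        ("C", "O2'", Moiety.RB),
        ("U", "O5'", Moiety.PH),
        ("A", "O3'", Moiety.RB),
    ])
    def test_examples(self, nt, atom, expected):
        tpl = _template(nt)
        res = tpl._make_residue("B", 1, tpl.coords)
        assert moiety_of(res, atom) is expected

    @pytest.mark.parametrize("nt", ["A", "G", "C", "U"])
    def test_every_polar_atom_has_exactly_one_moiety(self, nt):
        tpl = _template(nt)
        res = tpl._make_residue("B", 1, tpl.coords)
        for atom, role in donor_acceptor_roles(res).items():
            if role is not Role.NONE:
                assert moiety_of(res, atom) in (Moiety.NB, Moiety.PH, Moiety.RB)

    def test_unknown_atom_flagged(self, caplog):
        tpl = _template("A")
        res = tpl._make_residue("B", 1, tpl.coords)
        res.atoms[0].name = "XX9"
        with caplog.at_level("WARNING"):
            assert moiety_of(res, "XX9") is Moiety.OTHER
        assert "UNKNOWN_ATOM" in caplog.text


class TestChainPart:
    @pytest.mark.parametrize("aa,atom,expected", [
        ("SER", "OG", "s"),
        ("GLY", "O", "m"),
        ("ARG", "NH1", "s"),
        ("ALA", "N", "m"),
    ])
    def test_examples(self, aa, atom, expected):
        tpl = _template(aa)
        res = tpl._make_residue("A", 1, tpl.coords)
        assert chain_part_of(res, atom) == expected

    @pytest.mark.parametrize("aa", sorted(AMINO_ACIDS))
    def test_total_over_polar_atoms(self, aa):
        tpl = _template(aa)
        res = tpl._make_residue("A", 1, tpl.coords)
        for atom, role in donor_acceptor_roles(res).items():
            if role is not Role.NONE:
                assert chain_part_of(res, atom) in ("m", "s")

    @pytest.mark.parametrize("aa", ["GLY", "LEU"])
    def test_gly_and_leu_have_no_polar_side_chain(self, aa):
        """The survey convention: only Gly and Leu lack H-bonding side chains."""
        tpl = _template(aa)
        res = tpl._make_residue("A", 1, tpl.coords)
        side_polar = [a for a, role in donor_acceptor_roles(res).items()
                      if role is not Role.NONE and a not in MAIN_CHAIN_ATOMS]
        assert side_polar == []
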