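"""Geometric bond detection: criteria, roles, hydrogen inference, hb2 ingestion."""
import numpy as np
import pytest

from waterbridges.structure_io import Structure
from waterbridges.hbond_detect import (
    BondKind,
    HBondCriteria,
    Role,
    detect_hbonds,
    donor_acceptor_roles,
    parse_hb2,
    write_hb2,
)
from waterbridges.synthetic_fixtures import _template

from helpers import bond_pair_set, brute_force_hbonds, make_residue


def structure_of(*residues):
    return Structure(pdb_id="test", model_index=1, residues=list(residues))


def water_at(xyz, chain="W", seq=1):
    return make_residue("HOH", [("O", "O", xyz)], chain=chain, seq=seq)


class TestCriteria:
    def test_defaults(self):
        c = HBondCriteria()
        assert (c.max_da, c.max_ha, c.min_dha_angle) == (3.35, 2.7, 90.0)

    @pytest.mark.parametrize("kwargs", [
        {"max_da": -1.0}, {"max_ha": 0.0}, {"min_dha_angle": -5.0},
        {"max_da": 2.0, "max_ha": 2.5},
    ])
    def test_invalid(self, kwargs):
        with pytest.raises(ValueError):
            HBondCriteria(**{"max_da": 3.35, "max_ha": 2.7, "min_dha_angle": 90.0, **kwargs})


class TestRoles:
    @pytest.mark.parametrize("res,atom,expected", [
        ("HOH", "O", Role.BOTH),
        ("A", "N7", Role.ACCEPTOR),
        ("A", "N6", Role.DONOR),
        ("ARG", "NH2", Role.DONOR),
        ("G", "O6", Role.ACCEPTOR),
        ("U", "O2'", Role.BOTH),
        ("HIS", "ND1", Role.BOTH),
        ("ASP", "OD1", Role.ACCEPTOR),
        ("A", "C5", Role.NONE),
    ])
    def test_role_table(self, res, atom, expected):
        tpl = _template(res)
        residue = tpl._make_residue("X", 1, tpl.coords)
        assert donor_acceptor_roles(residue)[atom] is expected

    def test_proline_backbone_n_is_not_a_donor(self):
        tpl = _template("PRO")
        residue = tpl._make_residue("X", 1, tpl.coords)
        assert donor_acceptor_roles(residue)["N"] is Role.NONE


class TestDetection:
    def test_water_rna_contact_within_cutoff(self):
        nt = make_residue("G", [("O6", "O", (0, 0, 0)), ("C6", "C", (-1.2, 0, 0))],
                          chain="B")
        st = structure_of(nt, water_at((2.8, 0, 0)))
        (bond,) = detect_hbonds(st)
        assert bond.kind is BondKind.WATER_RNA
        assert bond.da_distance == pytest.approx(2.8)

    def test_contact_beyond_cutoff_rejected(self):
        aa = make_residue("SER", [("OG", "O", (0, 0, 0))])
        st = structure_of(aa, water_at((3.40, 0, 0)))
        assert detect_hbonds(st) == []

    def test_water_water_not_enumerated(self):
        st = structure_of(water_at((0, 0, 0), seq=1), water_at((2.8, 0, 0), seq=2))
        assert detect_hbonds(st) == []

    def test_incompatible_roles_rejected(self):
        # two pure acceptors cannot form a bond
        aa = make_residue("ASP", [("OD1", "O", (0, 0, 0))])
        nt = make_residue("U", [("O4", "O", (2.9, 0, 0))], chain="B")
        assert detect_hbonds(structure_of(aa, nt)) == []

    def test_asn_amide_hydrogen_pointing_away(self):
        """An acceptor perpendicular to the amide plane at 3.0 Å from ND2 is
        out of reach of both sp2 hydrogens: the H-A distance exceeds 2.7 Å
        (analytically sqrt(0.25 + 0.75 + 9) = 3.16 Å for 1.0-Å N-H bonds), so
        the bond survives heavy-atom mode but not full-criteria mode."""
        asn = make_residue("ASN", [
            ("CG", "C", (-1.33, 0, 0)),
            ("OD1", "O", (-2.0, 1.1, 0)),
            ("ND2", "N", (0, 0, 0)),
        ])
        st = structure_of(asn, water_at((0, 0, 3.0)))
        assert len(detect_hbonds(st, mode="heavy_atom")) == 1
        assert detect_hbonds(st, mode="with_hydrogens") == []

    def test_asn_amide_hydrogen_toward_acceptor(self):
        # in the amide plane, anti to CG: within reach of one inferred H
        asn = make_residue("ASN", [
            ("CG", "C", (-1.33, 0, 0)),
            ("OD1", "O", (-2.0, 1.1, 0)),
            ("ND2", "N", (0, 0, 0)),
        ])
        st = structure_of(asn, water_at((1.5, -2.598, 0)))
        assert len(detect_hbonds(st, mode="with_hydrogens")) == 1

    def test_rotatable_donor_distance_only_in_both_modes(self):
        ser = make_residue("SER", [("OG", "O", (0, 0, 0)), ("CB", "C", (-1.4, 0, 0))])
        st = structure_of(ser, water_at((3.0, 0, 0)))
        assert len(detect_hbonds(st, mode="heavy_atom")) == 1
        assert len(detect_hbonds(st, mode="with_hydrogens")) == 1


class TestOracleEquivalence:
    def _random_structure(self, rng):
        from scipy.spatial.transform import Rotation
        residues = []
        names = rng.choice(["ARG", "ASN", "SER", "GLU", "A", "G", "C", "U"],
                           size=rng.integers(2, 4), replace=False)
        for i, name in enumerate(names):
            tpl = _template(str(name))
            rot = Rotation.from_rotvec(rng.uniform(-np.pi, np.pi, 3))
            shift = rng.uniform(0, 12, 3)
            coords = rot.apply(tpl.coords) + shift
            chain = "A" if tpl.res_class.value == "amino_acid" else "B"
            residues.append(tpl._make_residue(chain, i + 1, coords))
        for j in range(3):
            residues.append(water_at(rng.uniform(0, 12, 3), seq=j + 1))
        return structure_of(*residues)

    @pytest.mark.parametrize("seed", range(20))
    def test_matches_brute_force_all_pairs(self, seed):
        """Native detection equals an exhaustive all-pairs scan on small
        random structures (heavy-atom criteria)."""
        rng = np.random.default_rng(seed)
        st = self._random_structure(rng)
        native = bond_pair_set(detect_hbonds(st))
        brute = brute_force_hbonds(st, max_da=3.35)
        assert native == brute

    @pytest.mark.parametrize("seed", range(10))
    def test_loosening_criteria_is_monotone(self, seed):
        rng = np.random.default_rng(100 + seed)
        st = self._random_structure(rng)
        tight = bond_pair_set(detect_hbonds(st, HBondCriteria(max_da=3.1)))
        loose = bond_pair_set(detect_hbonds(st, HBondCriteria(max_da=3.6)))
        assert tight <= loose

    def test_angle_loosening_is_monotone_with_hydrogens(self, ensemble):
        _, structure, _ = ensemble
        strict = bond_pair_set(detect_hbonds(
            structure, HBondCriteria(min_dha_angle=120.0), mode="with_hydrogens"))
        loose = bond_pair_set(detect_hbonds(
            structure, HBondCriteria(min_dha_angle=60.0), mode="with_hydrogens"))
        assert strict <= loose

    def test_order_invariance(self, ensemble):
        _, structure, _ = ensemble
        st_rev = Structure(pdb_id=structure.pdb_id, model_index=1,
                           residues=list(reversed(structure.residues)))
        assert bond_pair_set(detect_hbonds(structure)) == bond_pair_set(detect_hbonds(st_rev))


class TestHb2:
    def test_single_record(self, tmp_path):
        nt = make_residue("A", [("N7", "N", (0, 0, 0))], chain="B", seq=5)
        water = water_at((2.9, 0, 0), seq=12)
        st = structure_of(nt, water)
        hb2 = tmp_path / "one.hb2"
        hb2.write_text("W0012-HOH O   B0005-  A N7   2.90 HN  1  -1.0 120.0  2.00 -1.0 -1.0     1\n")
        (bond,) = parse_hb2(hb2, st)
        assert bond.kind is BondKind.WATER_RNA
        assert bond.da_distance == pytest.approx(2.90)
        assert bond.donor[0] is water and bond.acceptor[0] is nt

    def test_unresolvable_record_skipped_with_warning(self, tmp_path, caplog):
        st = structure_of(water_at((0, 0, 0)))
        hb2 = tmp_path / "bad.hb2"
        hb2.write_text("W0001-HOH O   B0099-  G O6   2.80 HN  1  -1.0 120.0  2.00 -1.0 -1.0     1\n")
        with caplog.at_level("WARNING"):
            assert parse_hb2(hb2, st) == []
        assert "not found" in caplog.text

    def test_header_lines_ignored(self, tmp_path):
        st = structure_of(water_at((0, 0, 0)))
        hb2 = tmp_path / "hdr.hb2"
        hb2.write_text("HBPLUS Hydrogen Bond Calculator v 3.2\n"
                       "<- DONOR -> <-ACCEPTOR->\nshort\n")
        assert parse_hb2(hb2, st) == []

    def test_round_trip_equals_native_detection(self, tmp_path, ensemble):
        """Writing native bonds as .hb2 and re-ingesting them reproduces the
        native bond set exactly (native detection is the oracle)."""
        _, structure, _ = ensemble
        native = detect_hbonds(structure)
        hb2 = tmp_path / "ensemble.hb2"
        write_hb2(native, hb2)
        parsed = parse_hb2(hb2, structure)
        assert bond_pair_set(parsed) == bond_pair_set(native)
        assert all(b.kind is nb.kind for b, nb in zip(parsed, native))
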