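"""Nucleobase edge assignment: pair tables, single-atom rules, distance rule."""
import math

import numpy as np
import pytest

from waterbridges.structure_io import Atom, Moiety
from waterbridges.edge_classify import (
    DEFAULT_TABLES,
    Edge,
    assign_edge,
    assign_nucleotide,
    euclidean,
    load_edge_tables,
)
from waterbridges.synthetic_fixtures import _template

from helpers import make_residue


def nt_residue(name):
    tpl = _template(name)
    return tpl._make_residue("B", 1, tpl.coords)


def water_oxygen(xyz):
    return Atom(name="O", element="O", coord=np.asarray(xyz, dtype=float))


def water_near(res, atom_names, offset=2.85):
    """A water oxygen placed off the centroid of the named atoms, away from the residue."""
    coords = np.array([res.atom(a).coord for a in atom_names])
    target = coords.mean(axis=0)
    centroid = np.mean([a.coord for a in res.atoms], axis=0)
    direction = target - centroid
    direction /= np.linalg.norm(direction)
    return water_oxygen(target + offset * direction)


class TestEuclidean:
    def test_3_4_5_triangle(self):
        assert euclidean(water_oxygen((0, 0, 0)), water_oxygen((3, 4, 0))) == pytest.approx(5.0)

    def test_zero(self):
        a = water_oxygen((1, 2, 3))
        assert euclidean(a, a) == 0.0

    def test_unit_cube_diagonal_and_symmetry(self):
        a, o = water_oxygen((1, 1, 1)), water_oxygen((2, 2, 2))
        assert euclidean(a, o) == pytest.approx(math.sqrt(3))
        assert euclidean(a, o) == euclidean(o, a)


class TestPairList:
    @pytest.mark.parametrize("nt,atoms,edge", [
        ("A", ("N1", "N6"), Edge.WC),
        ("G", ("N1", "N2"), Edge.WC),
        ("G", ("N1", "O6"), Edge.WC),
        ("C", ("N3", "N4"), Edge.WC),
        ("C", ("N3", "O2"), Edge.WC),
        ("U", ("N3", "O2"), Edge.WC),
        ("U", ("N3", "O4"), Edge.WC),
        ("A", ("N6", "N7"), Edge.HG),
        ("G", ("N7", "O6"), Edge.HG),
        ("A", ("N3", "N9"), Edge.SG),
        ("G", ("N3", "N9"), Edge.SG),
        ("A", ("N3", "O2'"), Edge.SG),
        ("G", ("N2", "N3"), Edge.SG),
        ("C", ("N1", "O2"), Edge.SG),
        ("U", ("N1", "O2"), Edge.SG),
        ("C", ("O2", "O2'"), Edge.SG),
        ("U", ("O2", "O2'"), Edge.SG),
    ])
    def test_every_pair_rule(self, nt, atoms, edge):
        res = nt_residue(nt)
        a = assign_edge(res, list(atoms), water_near(res, atoms))
        assert a.edge is edge and a.method == "pair_list"

    def test_residue_awareness(self):
        # [N3, N4] exists only for rC; the same atom names on rU are no pair
        res = nt_residue("U")
        a = assign_edge(res, ["N3", "O4"], water_near(res, ("N3", "O4")))
        assert a.edge is Edge.WC
        ra = nt_residue("A")
        out = assign_edge(ra, ["N1", "N7"], water_near(ra, ("N1", "N7")))
        assert out.method == "unclassified" and out.edge is Edge.NONE

    def test_more_than_two_base_atoms_keeps_two_closest(self, caplog):
        res = nt_residue("G")
        water = water_near(res, ("N1", "O6"))
        with caplog.at_level("WARNING"):
            a = assign_edge(res, ["N1", "O6", "N3"], water)
        assert a.edge is Edge.WC
        assert "max 2" in caplog.text


class TestSingles:
    @pytest.mark.parametrize("nt,atom,edge", [
        ("A", "N1", Edge.WC),
        ("G", "N1", Edge.WC),
        ("A", "N7", Edge.HG),
        ("G", "N7", Edge.HG),
        ("A", "N3", Edge.SG),
        ("C", "N3", Edge.WC),
        ("U", "N3", Edge.WC),
        ("C", "N4", Edge.WC),
        ("U", "O4", Edge.WC),
    ])
    def test_unambiguous(self, nt, atom, edge):
        res = nt_residue(nt)
        a = assign_edge(res, [atom], water_near(res, (atom,)))
        assert a.edge is edge and a.method == "unambiguous_single"
        assert a.moiety is Moiety.NB

    def test_lone_o2_prime_is_sg_with_ribose_moiety(self):
        res = nt_residue("U")
        a = assign_edge(res, ["O2'"], water_near(res, ("O2'",)))
        assert a.edge is Edge.SG and a.moiety is Moiety.RB

    def test_o2_prime_with_o3_prime_is_ribose_mediated(self):
        res = nt_residue("C")
        a = assign_edge(res, ["O2'", "O3'"], water_near(res, ("O2'", "O3'")))
        assert a.edge is Edge.NONE and a.moiety is Moiety.RB
        assert a.method == "ribose_rule"


class TestDistanceRule:
    def test_ra_n6_watson_crick_side(self):
        """Water nearer N1 than C5 -> WC (the canonical rA N6 case)."""
        res = nt_residue("A")
        n6, n1 = res.atom("N6").coord, res.atom("N1").coord
        water = water_oxygen(n6 + 0.97 * (n1 - n6) / np.linalg.norm(n1 - n6) * 2.9)
        a = assign_edge(res, ["N6"], water)
        assert a.edge is Edge.WC and a.method == "distance_rule"

    def test_ra_n6_hoogsteen_side(self):
        res = nt_residue("A")
        n6, c5 = res.atom("N6").coord, res.atom("C5").coord
        water = water_oxygen(n6 + (c5 - n6) / np.linalg.norm(c5 - n6) * 2.9)
        a = assign_edge(res, ["N6"], water)
        assert a.edge is Edge.HG

    @pytest.mark.parametrize("nt,atom,adj,edge", [
        ("G", "O6", "N1", Edge.WC), ("G", "O6", "C5", Edge.HG),
        ("G", "N2", "N1", Edge.WC), ("G", "N2", "N3", Edge.SG),
        ("C", "O2", "N3", Edge.WC), ("C", "O2", "N1", Edge.SG),
        ("U", "O2", "N3", Edge.WC), ("U", "O2", "N1", Edge.SG),
    ])
    def test_all_ambiguous_atoms_both_sectors(self, nt, atom, adj, edge):
        res = nt_residue(nt)
        x_t, x_adj = res.atom(atom).coord, res.atom(adj).coord
        water = water_oxygen(x_t + (x_adj - x_t) / np.linalg.norm(x_adj - x_t) * 2.9)
        a = assign_edge(res, [atom], water)
        assert a.edge is edge and a.method == "distance_rule"

    def test_exact_tie_falls_to_second_edge(self):
        """The rule uses a strict less-than, so an equidistant water takes the
        second-listed edge (SG for pyrimidine O2)."""
        res = make_residue("C", [
            ("N1", "N", (-1.0, 0.0, 0.0)),
            ("O2", "O", (0.0, -1.2, 0.0)),
            ("N3", "N", (1.0, 0.0, 0.0)),
        ], chain="B")
        water = water_oxygen((0.0, -4.0, 0.0))  # on the N1/N3 bisector plane
        a = assign_edge(res, ["O2"], water)
        assert a.edge is Edge.SG

    def test_bisector_crossing_flips_edge_exactly_once(self):
        """Sliding the water continuously across the adjacent-atom bisector
        plane flips the assignment exactly once."""
        res = nt_residue("A")
        n6 = res.atom("N6").coord
        n1, c5 = res.atom("N1").coord, res.atom("C5").coord
        axis = (n1 - c5) / np.linalg.norm(n1 - c5)
        centroid = np.mean([a.coord for a in res.atoms], axis=0)
        out = n6 - centroid
        out -= np.dot(out, axis) * axis
        out /= np.linalg.norm(out)
        edges = []
        for t in np.linspace(-1.5, 1.5, 41):
            water = water_oxygen(n6 + 2.9 * out + t * axis)
            edges.append(assign_edge(res, ["N6"], water).edge)
        flips = sum(1 for a, b in zip(edges, edges[1:]) if a is not b)
        assert flips == 1
        assert edges[0] is Edge.HG and edges[-1] is Edge.WC


class TestAssignNucleotide:
    def test_phosphate_contact(self):
        res = nt_residue("U")
        a = assign_nucleotide(res, ["OP1"], water_near(res, ("OP1",)))
        assert a.moiety is Moiety.PH and a.annotation == "Ph"

    def test_mixed_moieties_dominant_group(self):
        # base + phosphate in one contact: annotated by the nucleobase group
        res = nt_residue("A")
        a = assign_nucleotide(res, ["N7", "OP2"], water_near(res, ("N7",)))
        assert a.annotation == "HG"

    def test_plain_ribose_contact(self):
        res = nt_residue("G")
        a = assign_nucleotide(res, ["O4'"], water_near(res, ("O4'",)))
        assert a.moiety is Moiety.RB and a.annotation == "Rb"

    def test_determinism(self):
        res = nt_residue("G")
        w = water_near(res, ("N7",))
        results = {assign_nucleotide(res, ["N7"], w).edge for _ in range(5)}
        assert results == {Edge.HG}


class TestTables:
    def test_pair_lists_mutually_disjoint_per_residue(self):
        seen = {}
        for (res, pair), edge in DEFAULT_TABLES.pairs.items():
            assert seen.setdefault((res, pair), edge) is edge

    def test_single_tables_disjoint(self):
        assert not set(DEFAULT_TABLES.unambiguous_singles) & set(DEFAULT_TABLES.ambiguous_singles)

    def test_reload_matches_default(self):
        tables = load_edge_tables()
        assert tables.pairs == DEFAULT_TABLES.pairs
        assert tables.unambiguous_singles == DEFAULT_TABLES.unambiguous_singles
        assert tables.ambiguous_singles == DEFAULT_TABLES.ambiguous_singles

    def test_custom_table_overrides(self, tmp_path):
        p = tmp_path / "rules.tsv"
        p.write_text("single\tA\tN1\tHG\t-\t-\t-\t-\n")
        tables = load_edge_tables(p)
        res = nt_residue("A")
        a = assign_edge(res, ["N1"], water_near(res, ("N1",)), tables)
        assert a.edge is Edge.HG
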