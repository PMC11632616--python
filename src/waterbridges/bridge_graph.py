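"""Bridging-water identification and multiplet topology labeling.

A *water bridge* is a single crystallographic water hydrogen-bonded to at
least one amino acid and at least one ribonucleotide.  Viewed as a graph
(residues and the water as nodes, hydrogen bonds as edges), a bridge is a
multiplet whose order is the number of participating entities; the order is
one greater than the degree of the water node.  The topology label counts
unique residues on each side, ``A_a:w:N_n``, and is prefixed ``cyc-`` when a
direct amino-acid–ribonucleotide hydrogen bond exists among the members,
closing a ring through the water.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import networkx as nx

from .structure_io import AMINO_ACIDS, Residue, ResidueClass, Structure
from .hbond_detect import (
    BondKind,
    DEFAULT_CRITERIA,
    HBondCriteria,
    HydrogenBond,
    detect_hbonds,
)

__all__ = [
    "WaterBridge",
    "ClassCount",
    "find_bridging_waters",
    "build_bridge",
    "survey_structure",
    "enumerate_theoretical_classes",
]

#: amino acids without a side-chain portion capable of hydrogen bonding, by
#: the survey convention underlying the 456-class arithmetic
NO_SIDECHAIN_AA = frozenset({"GLY", "LEU"})

#: waters with more hydrogen bonds than this are geometrically suspect
#: (above the tetrahedral limit) and get flagged, never filtered
TETRAHEDRAL_LIMIT = 4


@dataclass(eq=False)
class WaterBridge:
    """One bridging water with its hydrogen-bonded amino acids and ribonucleotides."""

    water: Residue
    aa_members: tuple[Residue, ...]
    nt_members: tuple[Residue, ...]
    water_bonds: tuple[HydrogenBond, ...]
    direct_bonds: tuple[HydrogenBond, ...] = ()

    @property
    def degree(self) -> int:
        """Degree of the water node: number of distinct bonded member residues."""
        return len(self.aa_members) + len(self.nt_members)

    @property
    def order(self) -> int:
        return self.degree + 1

    @property
    def cyclic(self) -> bool:
        return len(self.direct_bonds) > 0

    @property
    def topology(self) -> str:
        return f"A{len(self.aa_members)}:w:N{len(self.nt_members)}"

    @property
    def label(self) -> str:
        return ("cyc-" if self.cyclic else "") + self.topology

    @property
    def over_tetrahedral(self) -> bool:
        return len(self.water_bonds) > TETRAHEDRAL_LIMIT

    @property
    def b_factor(self) -> float:
        """B-factor of the bridging water oxygen (Å²)."""
        o = self.water.atom("O")
        return o.b_factor if o is not None else float("nan")

    def member_atoms(self, residue: Residue) -> list[str]:
        """Atoms of a member residue hydrogen-bonded to this water, sorted."""
        return sorted({b.atom_of(residue) for b in self.water_bonds if b.involves(residue)})

    def to_graph(self) -> nx.Graph:
        """The bridge as a networkx graph (nodes: residues + water; edges: H-bonds)."""
        g = nx.Graph()
        g.add_node(self.water, kind="water")
        for r in self.aa_members:
            g.add_node(r, kind="amino_acid")
        for r in self.nt_members:
            g.add_node(r, kind="ribonucleotide")
        for b in self.water_bonds:
            g.add_edge(self.water, b.partner_of(self.water)[0], direct=False)
        for b in self.direct_bonds:
            g.add_edge(b.donor[0], b.acceptor[0], direct=True)
        return g


def find_bridging_waters(hbonds: Sequence[HydrogenBond]) -> list[Residue]:
    """Waters with at least one water–RNA and one water–protein bond, sorted."""
    rna_side: set[int] = set()
    protein_side: set[int] = set()
    waters: dict[int, Residue] = {}
    for bond in hbonds:
        if bond.kind not in (BondKind.WATER_RNA, BondKind.WATER_PROTEIN):
            continue
        for res, _atom in (bond.donor, bond.acceptor):
            if res.res_class is ResidueClass.WATER:
                waters[id(res)] = res
                (rna_side if bond.kind is BondKind.WATER_RNA else protein_side).add(id(res))
    bridging = [waters[i] for i in rna_side & protein_side]
    bridging.sort(key=lambda r: r.sort_key)
    return bridging


def build_bridge(water: Residue, hbonds: Sequence[HydrogenBond]) -> WaterBridge:
    """Assemble the bridge around one bridging water.

    Multiple hydrogen bonds from one residue to the water collapse to a
    single member, but every bond is retained in ``water_bonds``.  Direct
    protein–RNA bonds are included only when both residues are members of
    this bridge.
    """
    water_bonds = [b for b in hbonds if b.involves(water)
                   and b.kind in (BondKind.WATER_RNA, BondKind.WATER_PROTEIN)]
    aa: dict[int, Residue] = {}
    nt: dict[int, Residue] = {}
    for b in water_bonds:
        partner = b.partner_of(water)[0]
        if partner.res_class is ResidueClass.AMINO_ACID:
            aa[id(partner)] = partner
        elif partner.res_class is ResidueClass.RIBONUCLEOTIDE:
            nt[id(partner)] = partner
    if not aa or not nt:
        raise ValueError(
            f"{water.label} is not a bridging water "
            f"({len(aa)} amino-acid, {len(nt)} ribonucleotide partners)"
        )
    members = set(aa) | set(nt)
    direct = [
        b for b in hbonds
        if b.kind is BondKind.PROTEIN_RNA
        and id(b.donor[0]) in members and id(b.acceptor[0]) in members
    ]
    key = lambda r: r.sort_key
    return WaterBridge(
        water=water,
        aa_members=tuple(sorted(aa.values(), key=key)),
        nt_members=tuple(sorted(nt.values(), key=key)),
        water_bonds=tuple(water_bonds),
        direct_bonds=tuple(direct),
    )


def survey_structure(
    structure: Structure,
    criteria: HBondCriteria = DEFAULT_CRITERIA,
    mode: str = "heavy_atom",
    hbonds: Optional[Sequence[HydrogenBond]] = None,
) -> list[WaterBridge]:
    """All water bridges of one structure, one per bridging water, in
    deterministic (chain, residue number) order.

    ``hbonds`` can inject a pre-computed bond list (e.g. parsed HBPLUS
    output) in place of native detection.
    """
    if hbonds is None:
        hbonds = detect_hbonds(structure, criteria, mode)
    return [build_bridge(w, hbonds) for w in find_bridging_waters(hbonds)]


@dataclass(frozen=True)
class ClassCount:
    """Theoretical class counts for nucleobase-mediated triplet bridges."""

    single_portion: int
    dual_portion: int

    @property
    def total(self) -> int:
        return self.single_portion + self.dual_portion


def enumerate_theoretical_classes(topology: str = "A1wN1", cyclic: bool = False) -> ClassCount:
    """Count the theoretical composition classes of nucleobase-mediated triplets.

    4 nucleobases x 3 edges x (18 amino acids x 2 portions + 2 amino acids
    with main chain only) single-portion classes, plus 4 x 3 x 18 classes
    where one amino acid engages both main and side chain (ms).  The counts
    are identical for the acyclic and cyclic topology (the cyc- prefix adds
    no sub-typing).
    """
    if topology not in ("A1wN1", "A1:w:N1"):
        raise ValueError(f"class enumeration is defined for the triplet topology, got {topology!r}")
    n_bases = 4
    n_edges = 3
    dual_capable = len(AMINO_ACIDS - NO_SIDECHAIN_AA)   # 18
    main_only = len(NO_SIDECHAIN_AA)                    # 2
    single = n_bases * n_edges * (dual_capable * 2 + main_only)
    dual = n_bases * n_edges * dual_capable
    return ClassCount(single_portion=single, dual_portion=dual)
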