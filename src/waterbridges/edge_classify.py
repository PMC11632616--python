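"""Nucleobase-edge and moiety assignment for water–ribonucleotide contacts.

A nucleobase presents three hydrogen-bonding faces — Watson–Crick (WC),
Hoogsteen (HG) and Sugar (SG) — and a base-mediated water contact is
sub-classified by the face involved.  The assignment logic:

* two interacting base atoms: the pair determines the edge via residue-aware
  pair tables;
* one atom that belongs to a single edge (e.g. purine N1 -> WC, N7 -> HG):
  assigned directly;
* one atom shared by two edges (e.g. rA N6, between WC and HG): the
  Euclidean distance from the water oxygen to the two ring atoms adjacent to
  it decides — strictly closer to the WC-side neighbor means WC, otherwise
  the other edge (ties fall to the second-listed edge);
* O2' alone carries SG-edge semantics by convention, but O2' together with
  O3' is a ribose-sugar-mediated contact, not a base edge.

The tables ship as a human-readable TSV (``data/edge_rules.tsv``) so they can
be amended without code changes.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass
from enum import Enum
from importlib import resources
from pathlib import Path
from typing import Iterable, Optional, Sequence

import numpy as np

from .structure_io import Atom, Moiety, Residue, ResidueClass, canonical_atom_name, moiety_of

logger = logging.getLogger(__name__)

__all__ = [
    "Edge",
    "EdgeAssignment",
    "EdgePairTables",
    "DEFAULT_TABLES",
    "load_edge_tables",
    "euclidean",
    "assign_edge",
    "assign_nucleotide",
]


class Edge(Enum):
    WC = "WC"
    HG = "HG"
    SG = "SG"
    NONE = "NONE"


@dataclass(frozen=True)
class AmbiguousRule:
    """Distance disambiguation: strictly closer to ``adjacent1`` -> ``edge1``."""

    adjacent1: str
    edge1: Edge
    adjacent2: str
    edge2: Edge


@dataclass
class EdgePairTables:
    """Residue-aware lookup tables for edge assignment.

    ``pairs`` maps (res_name, frozenset of two atom names) -> Edge;
    ``unambiguous_singles`` maps (res_name, atom) -> Edge;
    ``ambiguous_singles`` maps (res_name, atom) -> AmbiguousRule.
    """

    pairs: dict[tuple[str, frozenset], Edge]
    unambiguous_singles: dict[tuple[str, str], Edge]
    ambiguous_singles: dict[tuple[str, str], AmbiguousRule]

    def __post_init__(self) -> None:
        overlap = set(self.unambiguous_singles) & set(self.ambiguous_singles)
        if overlap:
            raise ValueError(f"atoms listed as both ambiguous and unambiguous: {sorted(overlap)}")


def load_edge_tables(path: Optional[str | Path] = None) -> EdgePairTables:
    """Load edge rules from a TSV file (default: the packaged table)."""
    if path is None:
        text = resources.files("waterbridges.data").joinpath("edge_rules.tsv").read_text()
    else:
        text = Path(path).read_text()
    pairs: dict[tuple[str, frozenset], Edge] = {}
    singles: dict[tuple[str, str], Edge] = {}
    ambiguous: dict[tuple[str, str], AmbiguousRule] = {}
    for lineno, raw in enumerate(text.splitlines(), start=1):
        line = raw.strip()
        if not line or line.startswith("#"):
            continue
        fields = [f.strip() for f in line.split("\t")]
        if len(fields) != 8:
            raise ValueError(f"edge_rules line {lineno}: expected 8 tab-separated fields")
        kind, residues, atoms, edge, adj1, edge1, adj2, edge2 = fields
        res_names = [r.strip().upper() for r in residues.split(",")]
        atom_names = tuple(canonical_atom_name(a) for a in atoms.split(","))
        for res in res_names:
            if kind == "pair":
                if len(atom_names) != 2:
                    raise ValueError(f"edge_rules line {lineno}: pair rule needs two atoms")
                pairs[(res, frozenset(atom_names))] = Edge(edge)
            elif kind == "single":
                singles[(res, atom_names[0])] = Edge(edge)
            elif kind == "ambiguous":
                ambiguous[(res, atom_names[0])] = AmbiguousRule(
                    canonical_atom_name(adj1), Edge(edge1),
                    canonical_atom_name(adj2), Edge(edge2),
                )
            else:
                raise ValueError(f"edge_rules line {lineno}: unknown kind {kind!r}")
    return EdgePairTables(pairs=pairs, unambiguous_singles=singles, ambiguous_singles=ambiguous)


DEFAULT_TABLES = load_edge_tables()


@dataclass
class EdgeAssignment:
    """Moiety and (for base contacts) edge of one water–ribonucleotide contact."""

    nucleotide: Residue
    int_atoms: tuple[str, ...]
    moiety: Moiety
    edge: Edge
    method: str

    @property
    def annotation(self) -> str:
        """The nomenclature annotation: WC/HG/SG for base contacts, else Ph/Rb."""
        if self.edge is not Edge.NONE:
            return self.edge.value
        return self.moiety.value


def euclidean(a: Atom, o: Atom) -> float:
    """Plain Euclidean distance between two atoms (Å)."""
    return float(np.linalg.norm(a.coord - o.coord))


def _base_atoms(nt: Residue, names: Iterable[str]) -> list[str]:
    return [n for n in names if moiety_of(nt, n) is Moiety.NB]


def assign_edge(
    nt: Residue,
    int_atoms: Sequence[str],
    water_o: Atom,
    tables: EdgePairTables = DEFAULT_TABLES,
) -> EdgeAssignment:
    """Assign the nucleobase edge for the base-moiety atoms of one contact.

    ``int_atoms`` holds the nucleotide's base atoms bonded to the bridging
    water, plus O2'/O3' where the ribose rule applies.  A pair found in no
    table is left unclassified with a warning (the manual-review fallback);
    more than two base atoms violates the geometric two-atom bound, so the
    two closest to the water are kept.
    """
    if nt.res_class is not ResidueClass.RIBONUCLEOTIDE:
        raise ValueError(f"{nt.label}: edge assignment requires a ribonucleotide")
    if not int_atoms:
        raise ValueError(f"{nt.label}: int_atoms must be non-empty")
    atoms = sorted({canonical_atom_name(a) for a in int_atoms})

    if set(atoms) == {"O2'", "O3'"}:
        return EdgeAssignment(nt, tuple(atoms), Moiety.RB, Edge.NONE, "ribose_rule")

    base_pure = [a for a in atoms if a not in ("O2'", "O3'")]
    has_o2p = "O2'" in atoms
    if len(base_pure) > 2:
        base_pure.sort(key=lambda n: euclidean(nt.atom(n), water_o))
        kept = sorted(base_pure[:2])
        logger.warning("%s: %d base atoms bonded to one water (max 2); keeping %s",
                       nt.label, len(base_pure), kept)
        base_pure = kept
        atoms = kept
        has_o2p = False

    if len(base_pure) == 2:
        edge = tables.pairs.get((nt.res_name, frozenset(base_pure)))
        if edge is None:
            logger.warning("%s: atom pair %s in no edge table; left unclassified for review",
                           nt.label, base_pure)
            return EdgeAssignment(nt, tuple(atoms), Moiety.NB, Edge.NONE, "unclassified")
        return EdgeAssignment(nt, tuple(atoms), Moiety.NB, edge, "pair_list")

    if len(base_pure) == 1 and has_o2p:
        pair = frozenset({base_pure[0], "O2'"})
        edge = tables.pairs.get((nt.res_name, pair))
        if edge is None:
            logger.warning("%s: atom pair %s in no edge table; left unclassified for review",
                           nt.label, sorted(pair))
            return EdgeAssignment(nt, tuple(atoms), Moiety.NB, Edge.NONE, "unclassified")
        return EdgeAssignment(nt, tuple(atoms), Moiety.NB, edge, "pair_list")

    if not base_pure:
        if has_o2p:
            # lone 2'-OH contact: ribose atom carrying SG-edge semantics
            return EdgeAssignment(nt, tuple(atoms), Moiety.RB, Edge.SG, "unambiguous_single")
        logger.warning("%s: only O3' passed to assign_edge; plain ribose contact", nt.label)
        return EdgeAssignment(nt, tuple(atoms), Moiety.RB, Edge.NONE, "moiety")

    (atom,) = base_pure
    rule = tables.ambiguous_singles.get((nt.res_name, atom))
    if rule is not None:
        a1 = nt.atom(rule.adjacent1)
        a2 = nt.atom(rule.adjacent2)
        if a1 is None or a2 is None:
            logger.warning("%s: adjacent atoms %s/%s missing; contact unclassified",
                           nt.label, rule.adjacent1, rule.adjacent2)
            return EdgeAssignment(nt, tuple(atoms), Moiety.NB, Edge.NONE, "unclassified")
        edge = rule.edge1 if euclidean(a1, water_o) < euclidean(a2, water_o) else rule.edge2
        return EdgeAssignment(nt, tuple(atoms), Moiety.NB, edge, "distance_rule")
    edge = tables.unambiguous_singles.get((nt.res_name, atom))
    if edge is not None:
        return EdgeAssignment(nt, tuple(atoms), Moiety.NB, edge, "unambiguous_single")
    logger.warning("%s: no edge rule for single atom %s; contact unclassified", nt.label, atom)
    return EdgeAssignment(nt, tuple(atoms), Moiety.NB, Edge.NONE, "unclassified")


def assign_nucleotide(
    nt: Residue,
    int_atoms: Sequence[str],
    water_o: Atom,
    tables: EdgePairTables = DEFAULT_TABLES,
) -> EdgeAssignment:
    """Classify the full water contact of one ribonucleotide (any moiety mix).

    Routes base atoms (and O2'/O3') through :func:`assign_edge`; contacts
    touching several moieties are annotated by the dominant group
    (nucleobase > phosphate > ribose) and the multiplicity is logged.
    """
    atoms = sorted({canonical_atom_name(a) for a in int_atoms})
    if not atoms:
        raise ValueError(f"{nt.label}: no interacting atoms")
    by_moiety: dict[Moiety, list[str]] = {}
    for a in atoms:
        by_moiety.setdefault(moiety_of(nt, a), []).append(a)
    by_moiety.pop(Moiety.OTHER, None)  # unknown atoms excluded, already logged
    if len(by_moiety) > 1 and not (set(by_moiety) == {Moiety.NB, Moiety.RB}
                                   and by_moiety[Moiety.RB] in (["O2'"], ["O2'", "O3'"], ["O3'"])):
        logger.info("%s: water contact spans moieties %s; annotating by dominant group",
                    nt.label, sorted(m.value for m in by_moiety))

    nb = by_moiety.get(Moiety.NB, [])
    rb = by_moiety.get(Moiety.RB, [])
    edge_atoms = list(nb)
    if "O2'" in rb:
        edge_atoms.append("O2'")
        if "O3'" in rb:
            edge_atoms.append("O3'")
    if edge_atoms:
        sub = assign_edge(nt, edge_atoms, water_o, tables)
        return EdgeAssignment(nt, tuple(atoms), sub.moiety, sub.edge, sub.method)
    if Moiety.PH in by_moiety:
        return EdgeAssignment(nt, tuple(atoms), Moiety.PH, Edge.NONE, "moiety")
    return EdgeAssignment(nt, tuple(atoms), Moiety.RB, Edge.NONE, "moiety")
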