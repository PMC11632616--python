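"""Geometric hydrogen-bond detection between water, amino acids and ribonucleotides.

Bonds are accepted under three criteria — donor–acceptor distance, hydrogen–
acceptor distance and donor–hydrogen–acceptor angle, defaulting to
3.35 Å / 2.7 Å / 90° — the cutoffs commonly used for polar contacts at
nucleic-acid–protein interfaces.  Two evaluation modes exist:

``heavy_atom`` (default)
    only the D–A distance is enforced.  Crystal structures at typical
    resolution carry no hydrogens, and hydrogen placement for rotatable
    donors (water, hydroxyls, ammonium) is underdetermined, so a
    distance-only criterion treats all donors uniformly.

``with_hydrogens``
    donors with fixed sp2 geometry (amides, guanidinium, ring NH, nucleobase
    amino groups) get an idealized hydrogen and the full three-criterion
    test; rotatable donors still fall back to the D–A distance.

A parser for HBPLUS ``.hb2`` output is provided so a survey can ingest the
exact bond lists produced by that program instead of native detection.
"""
from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from enum import Enum
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
from scipy.spatial import cKDTree

from .structure_io import (
    Atom,
    Residue,
    ResidueClass,
    Structure,
    canonical_atom_name,
)

logger = logging.getLogger(__name__)

__all__ = [
    "HBondCriteria",
    "HydrogenBond",
    "BondKind",
    "Role",
    "donor_acceptor_roles",
    "detect_hbonds",
    "parse_hb2",
    "write_hb2",
]


class Role(Enum):
    DONOR = "donor"
    ACCEPTOR = "acceptor"
    BOTH = "both"
    NONE = "none"


class BondKind(Enum):
    WATER_RNA = "water_rna"
    WATER_PROTEIN = "water_protein"
    PROTEIN_RNA = "protein_rna"
    OTHER = "other"


@dataclass(frozen=True)
class HBondCriteria:
    """Geometric cutoffs: D–A and H–A distances (Å) and minimum D–H–A angle (deg)."""

    max_da: float = 3.35
    max_ha: float = 2.7
    min_dha_angle: float = 90.0

    def __post_init__(self) -> None:
        if not (self.max_da > 0 and self.max_ha > 0 and self.min_dha_angle > 0):
            raise ValueError("all criteria must be positive")
        if self.max_ha >= self.max_da:
            raise ValueError("max_ha must be smaller than max_da")


DEFAULT_CRITERIA = HBondCriteria()


@dataclass(eq=False)
class HydrogenBond:
    donor: tuple[Residue, str]
    acceptor: tuple[Residue, str]
    da_distance: float
    ha_distance: Optional[float] = None
    dha_angle: Optional[float] = None
    kind: BondKind = BondKind.OTHER

    @property
    def residues(self) -> tuple[Residue, Residue]:
        return (self.donor[0], self.acceptor[0])

    def involves(self, residue: Residue) -> bool:
        return residue is self.donor[0] or residue is self.acceptor[0]

    def partner_of(self, residue: Residue) -> tuple[Residue, str]:
        if residue is self.donor[0]:
            return self.acceptor
        if residue is self.acceptor[0]:
            return self.donor
        raise ValueError(f"{residue.label} is not part of this bond")

    def atom_of(self, residue: Residue) -> str:
        if residue is self.donor[0]:
            return self.donor[1]
        if residue is self.acceptor[0]:
            return self.acceptor[1]
        raise ValueError(f"{residue.label} is not part of this bond")

    def __repr__(self) -> str:  # pragma: no cover - debugging aid
        d, a = self.donor, self.acceptor
        return (f"HydrogenBond({d[0].label}:{d[1]} -> {a[0].label}:{a[1]}, "
                f"{self.da_distance:.2f} A, {self.kind.value})")


# ---------------------------------------------------------------------------
# donor/acceptor role tables
# ---------------------------------------------------------------------------

_D, _A, _B = Role.DONOR, Role.ACCEPTOR, Role.BOTH

# backbone roles shared by all amino acids (proline N carries no amide H)
_AA_BACKBONE = {"N": _D, "O": _A, "OXT": _A}
_AA_SIDE = {
    "ARG": {"NE": _D, "NH1": _D, "NH2": _D},
    "ASN": {"ND2": _D, "OD1": _A},
    "GLN": {"NE2": _D, "OE1": _A},
    "ASP": {"OD1": _A, "OD2": _A},
    "GLU": {"OE1": _A, "OE2": _A},
    "HIS": {"ND1": _B, "NE2": _B},  # protonation ambiguous -> both roles
    "LYS": {"NZ": _D},
    "SER": {"OG": _B},
    "THR": {"OG1": _B},
    "TYR": {"OH": _B},
    "TRP": {"NE1": _D},
    "CYS": {"SG": _B},
    "MET": {"SD": _A},
}

_NT_COMMON = {
    "OP1": _A, "OP2": _A, "OP3": _A,
    "O5'": _A, "O4'": _A, "O3'": _A,
    "O2'": _B,
}
_NT_BASE = {
    "A": {"N6": _D, "N1": _A, "N3": _A, "N7": _A},
    "G": {"N1": _D, "N2": _D, "O6": _A, "N3": _A, "N7": _A},
    "C": {"N4": _D, "N3": _A, "O2": _A},
    "U": {"N3": _D, "O2": _A, "O4": _A},
}

#: donors whose hydrogen can rotate freely; evaluated on D-A distance only
ROTATABLE_DONORS = frozenset({
    ("HOH", "O"), ("SER", "OG"), ("THR", "OG1"), ("TYR", "OH"),
    ("LYS", "NZ"), ("CYS", "SG"),
})


def _role_table(residue: Residue) -> dict[str, Role]:
    if residue.res_class is ResidueClass.WATER:
        return {"O": _B}
    if residue.res_class is ResidueClass.AMINO_ACID:
        table = dict(_AA_BACKBONE)
        if residue.res_name == "PRO":
            table["N"] = Role.NONE
        table.update(_AA_SIDE.get(residue.res_name, {}))
        return table
    if residue.res_class is ResidueClass.RIBONUCLEOTIDE:
        table = dict(_NT_COMMON)
        table.update(_NT_BASE[residue.res_name])
        return table
    return {}


def donor_acceptor_roles(residue: Residue) -> dict[str, Role]:
    """Role of every atom in the residue (NONE for apolar/unlisted atoms)."""
    if residue.res_class not in (ResidueClass.WATER, ResidueClass.AMINO_ACID,
                                 ResidueClass.RIBONUCLEOTIDE):
        raise ValueError(f"{residue.label}: roles defined only for water/amino acid/ribonucleotide")
    table = _role_table(residue)
    return {a.name: table.get(a.name, Role.NONE) for a in residue.atoms}


def _polar_atoms(residue: Residue) -> list[tuple[Atom, Role]]:
    table = _role_table(residue)
    out = []
    for a in residue.atoms:
        role = table.get(a.name, Role.NONE)
        if role is not Role.NONE:
            out.append((a, role))
    return out


_KIND_MAP = {
    frozenset({ResidueClass.WATER, ResidueClass.RIBONUCLEOTIDE}): BondKind.WATER_RNA,
    frozenset({ResidueClass.WATER, ResidueClass.AMINO_ACID}): BondKind.WATER_PROTEIN,
    frozenset({ResidueClass.AMINO_ACID, ResidueClass.RIBONUCLEOTIDE}): BondKind.PROTEIN_RNA,
}


def bond_kind(res1: Residue, res2: Residue) -> BondKind:
    return _KIND_MAP.get(frozenset({res1.res_class, res2.res_class}), BondKind.OTHER)


# ---------------------------------------------------------------------------
# idealized hydrogen placement for fixed-geometry donors
# ---------------------------------------------------------------------------

_NH_LENGTH = 1.00  # Å

# ("bisector", n1, n2): one H along the external bisector of two ring/chain
# neighbors.  ("sp2amino", c, plane): two H at +-120 deg from the D->C bond in
# the plane defined by C's other substituent.
_DONOR_FRAMES: dict[tuple[str, str], tuple] = {
    ("ARG", "NE"): ("bisector", "CD", "CZ"),
    ("ARG", "NH1"): ("sp2amino", "CZ", "NE"),
    ("ARG", "NH2"): ("sp2amino", "CZ", "NE"),
    ("ASN", "ND2"): ("sp2amino", "CG", "OD1"),
    ("GLN", "NE2"): ("sp2amino", "CD", "OE1"),
    ("TRP", "NE1"): ("bisector", "CD1", "CE2"),
    ("HIS", "ND1"): ("bisector", "CG", "CE1"),
    ("HIS", "NE2"): ("bisector", "CD2", "CE1"),
    ("A", "N6"): ("sp2amino", "C6", "N1"),
    ("G", "N1"): ("bisector", "C2", "C6"),
    ("G", "N2"): ("sp2amino", "C2", "N1"),
    ("C", "N4"): ("sp2amino", "C4", "N3"),
    ("U", "N3"): ("bisector", "C2", "C4"),
}


def _unit(v: np.ndarray) -> np.ndarray:
    return v / np.linalg.norm(v)


def _infer_hydrogens(residue: Residue, donor: Atom) -> Optional[list[np.ndarray]]:
    """Idealized H positions for a fixed-geometry donor, or None if rotatable.

    Backbone amide N needs the preceding residue's carbonyl carbon, which is
    outside the residue, so it is treated as frame-less (distance-only).
    """
    frame = _DONOR_FRAMES.get((residue.res_name, donor.name))
    if frame is None:
        return None
    kind = frame[0]
    a1 = residue.atom(frame[1])
    a2 = residue.atom(frame[2])
    if a1 is None or a2 is None:
        return None
    d = donor.coord
    if kind == "bisector":
        u = -_unit(_unit(a1.coord - d) + _unit(a2.coord - d))
        return [d + _NH_LENGTH * u]
    # sp2 amino: two H in the sp2 plane at +-120 deg from the D->C bond
    c, plane = a1.coord, a2.coord
    u_dc = _unit(c - d)
    normal = np.cross(c - d, plane - c)
    norm = np.linalg.norm(normal)
    if norm < 1e-8:
        return None
    normal /= norm
    perp = np.cross(normal, u_dc)
    hs = []
    for sign in (+1.0, -1.0):
        u_h = -u_dc * math.cos(math.radians(60)) + sign * perp * math.sin(math.radians(60))
        hs.append(d + _NH_LENGTH * _unit(u_h))
    return hs


def _evaluate_direction(
    donor_res: Residue,
    donor: Atom,
    acceptor: Atom,
    criteria: HBondCriteria,
) -> Optional[tuple[Optional[float], Optional[float]]]:
    """Check the H-A / D-H-A criteria for one donor->acceptor direction.

    Returns (ha, angle) on success (None values where not evaluated), or
    None when the direction fails the hydrogen criteria.
    """
    hs = _infer_hydrogens(donor_res, donor)
    if hs is None:
        return (None, None)  # rotatable/frame-less donor: D-A distance decides
    best: Optional[tuple[float, float]] = None
    for h in hs:
        ha = float(np.linalg.norm(acceptor.coord - h))
        v1 = donor.coord - h
        v2 = acceptor.coord - h
        cosang = float(np.dot(v1, v2) / (np.linalg.norm(v1) * np.linalg.norm(v2)))
        angle = math.degrees(math.acos(max(-1.0, min(1.0, cosang))))
        if ha <= criteria.max_ha and angle >= criteria.min_dha_angle:
            if best is None or ha < best[0]:
                best = (ha, angle)
    return best


def detect_hbonds(
    structure: Structure,
    criteria: HBondCriteria = DEFAULT_CRITERIA,
    mode: str = "heavy_atom",
) -> list[HydrogenBond]:
    """Enumerate hydrogen bonds of the three interface kinds.

    Water–water contacts and within-class pairs are not emitted: bridges are
    defined by water–RNA, water–protein and direct protein–RNA bonds only.
    Each unordered atom pair yields at most one bond.  Output order is
    deterministic (donor residue, donor atom, acceptor residue, acceptor atom).
    """
    if mode not in ("heavy_atom", "with_hydrogens"):
        raise ValueError(f"unknown mode {mode!r}")
    entries: list[tuple[Residue, Atom, Role]] = []
    for res in structure.residues:
        if res.res_class is ResidueClass.OTHER:
            continue
        for atom, role in _polar_atoms(res):
            entries.append((res, atom, role))
    if not entries:
        return []
    coords = np.array([a.coord for _, a, _ in entries])
    tree = cKDTree(coords)
    bonds: list[HydrogenBond] = []
    for i, j in sorted(tree.query_pairs(criteria.max_da)):
        res_i, atom_i, role_i = entries[i]
        res_j, atom_j, role_j = entries[j]
        if res_i is res_j:
            continue
        kind = bond_kind(res_i, res_j)
        if kind is BondKind.OTHER:
            continue
        da = float(np.linalg.norm(atom_i.coord - atom_j.coord))
        if da > criteria.max_da:
            continue
        directions = []
        if role_i in (_D, _B) and role_j in (_A, _B):
            directions.append(((res_i, atom_i), (res_j, atom_j)))
        if role_j in (_D, _B) and role_i in (_A, _B):
            directions.append(((res_j, atom_j), (res_i, atom_i)))
        if not directions:
            continue
        accepted = None
        for (dres, datom), (ares, aatom) in directions:
            if mode == "heavy_atom":
                accepted = ((dres, datom), (ares, aatom), None, None)
                break
            result = _evaluate_direction(dres, datom, aatom, criteria)
            if result is not None:
                accepted = ((dres, datom), (ares, aatom), result[0], result[1])
                break
        if accepted is None:
            continue
        (dres, datom), (ares, aatom), ha, angle = accepted
        bonds.append(
            HydrogenBond(
                donor=(dres, datom.name),
                acceptor=(ares, aatom.name),
                da_distance=da,
                ha_distance=ha,
                dha_angle=angle,
                kind=kind,
            )
        )
    bonds.sort(key=lambda b: (b.donor[0].sort_key, b.donor[1],
                              b.acceptor[0].sort_key, b.acceptor[1]))
    return bonds


# ---------------------------------------------------------------------------
# HBPLUS .hb2 ingestion
# ---------------------------------------------------------------------------

def _parse_hb2_endpoint(text: str) -> Optional[tuple[str, int, str, str, str]]:
    """Decode one 14-char hb2 endpoint: chain, seqnum, icode, resname, atom."""
    if len(text) < 14:
        return None
    chain = text[0]
    num = text[1:5]
    icode = text[5]
    res_name = text[6:9].strip().upper()
    atom = text[10:14].strip()
    if not num.strip().isdigit() or not res_name or not atom:
        return None
    return chain, int(num), "" if icode == "-" else icode.strip(), res_name, canonical_atom_name(atom)


def parse_hb2(path: str | Path, structure: Structure) -> list[HydrogenBond]:
    """Ingest an HBPLUS ``.hb2`` bond list, resolving records against ``structure``.

    Records naming residues absent from the structure (or malformed lines)
    are skipped with a warning.  Resulting bonds carry the same kind
    classification native detection would produce.
    """
    path = Path(path)
    bonds: list[HydrogenBond] = []
    for lineno, line in enumerate(path.read_text().splitlines(), start=1):
        if len(line) < 33:
            continue
        donor_spec = _parse_hb2_endpoint(line[0:14])
        acceptor_spec = _parse_hb2_endpoint(line[14:28])
        if donor_spec is None or acceptor_spec is None:
            continue  # header or comment line
        try:
            da = float(line[28:33])
        except ValueError:
            logger.warning("%s:%d: malformed distance field, record skipped", path.name, lineno)
            continue
        endpoints = []
        ok = True
        for chain, num, icode, res_name, atom in (donor_spec, acceptor_spec):
            res = structure.find_residue(chain, num, icode)
            if res is None or res.res_name != res_name:
                logger.warning("%s:%d: residue %s/%s%d%s not found in structure, record skipped",
                               path.name, lineno, chain, res_name, num, icode)
                ok = False
                break
            if res.atom(atom) is None:
                logger.warning("%s:%d: atom %s missing from %s, record skipped",
                               path.name, lineno, atom, res.label)
                ok = False
                break
            endpoints.append((res, atom))
        if not ok:
            continue
        rest = line[33:].split()
        ha = angle = None
        # hb2 tail: category, gap, CA-CA, DHA angle, H-A, H-A-AA, D-A-AA, count
        if len(rest) >= 5:
            try:
                angle_v, ha_v = float(rest[3]), float(rest[4])
                angle = angle_v if angle_v >= 0 else None
                ha = ha_v if ha_v >= 0 else None
            except ValueError:
                pass
        bonds.append(
            HydrogenBond(
                donor=endpoints[0],
                acceptor=endpoints[1],
                da_distance=da,
                ha_distance=ha,
                dha_angle=angle,
                kind=bond_kind(endpoints[0][0], endpoints[1][0]),
            )
        )
    return bonds


def write_hb2(bonds: Sequence[HydrogenBond], path: str | Path) -> None:
    """Write bonds in HBPLUS ``.hb2`` fixed-width layout (for fixtures/round-trips)."""
    lines = []
    for b in bonds:
        parts = []
        for res, atom in (b.donor, b.acceptor):
            parts.append(f"{res.chain_id:1s}{res.seq_num:04d}{res.icode or '-':1s}"
                         f"{res.res_name:>3s} {atom:<4s}")
        angle = b.dha_angle if b.dha_angle is not None else -1.0
        ha = b.ha_distance if b.ha_distance is not None else -1.0
        lines.append(f"{parts[0]}{parts[1]}{b.da_distance:5.2f} ??  1  -1.0"
                     f" {angle:5.1f} {ha:5.2f} -1.0 -1.0     1")
    Path(path).write_text("\n".join(lines) + ("\n" if lines else ""))
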