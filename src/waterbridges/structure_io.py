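"""Crystal-structure ingestion and residue-level chemistry.

Reads PDB/mmCIF coordinate files (via gemmi), normalizes atom naming across
the common dialects (``O2*`` / ``O2'`` / ``O2′``, ``O1P``/``OP1``), resolves
alternate conformers, and classifies residues into the four classes the
bridge analysis distinguishes: amino acid, ribonucleotide, water, other.

Only the four canonical ribonucleotides (rA, rG, rC, rU) and the twenty
canonical amino acids are in scope; modified residues, ligands, DNA and ions
all map to :attr:`ResidueClass.OTHER` and are ignored downstream.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass, field
from enum import Enum
from pathlib import Path
from typing import Iterable, Iterator, Optional, Sequence

import gemmi
import numpy as np

logger = logging.getLogger(__name__)

__all__ = [
    "Atom",
    "Residue",
    "Structure",
    "ResidueClass",
    "Moiety",
    "StructureParseError",
    "AMINO_ACIDS",
    "RIBONUCLEOTIDES",
    "DEFAULT_WATER_NAMES",
    "canonical_atom_name",
    "classify_residue",
    "parse_structure",
    "write_pdb",
    "moiety_of",
    "chain_part_of",
    "display_name",
]

AMINO_ACIDS = frozenset(
    "ALA ARG ASN ASP CYS GLN GLU GLY HIS ILE LEU LYS MET PHE PRO SER THR TRP TYR VAL".split()
)
RIBONUCLEOTIDES = frozenset({"A", "G", "C", "U"})
DEFAULT_WATER_NAMES = frozenset({"HOH", "WAT", "DOD", "H2O"})

#: main-chain atoms of an amino acid; everything else polar is side chain
MAIN_CHAIN_ATOMS = frozenset({"N", "CA", "C", "O", "OXT"})

_PHOSPHATE_ATOMS = frozenset({"P", "OP1", "OP2", "OP3", "O5'"})
_RIBOSE_ATOMS = frozenset({"O2'", "O3'", "O4'", "C1'", "C2'", "C3'", "C4'", "C5'"})
_NUCLEOBASE_ATOMS = {
    "A": frozenset({"N1", "C2", "N3", "C4", "C5", "C6", "N6", "N7", "C8", "N9"}),
    "G": frozenset({"N1", "C2", "N2", "N3", "C4", "C5", "C6", "O6", "N7", "C8", "N9"}),
    "C": frozenset({"N1", "C2", "O2", "N3", "C4", "N4", "C5", "C6"}),
    "U": frozenset({"N1", "C2", "O2", "N3", "C4", "O4", "C5", "C6"}),
}

_ATOM_ALIASES = {"O1P": "OP1", "O2P": "OP2", "O3P": "OP3"}


class StructureParseError(Exception):
    """Raised when a coordinate file cannot be read or interpreted."""


class ResidueClass(Enum):
    AMINO_ACID = "amino_acid"
    RIBONUCLEOTIDE = "ribonucleotide"
    WATER = "water"
    OTHER = "other"


class Moiety(Enum):
    """Part of a ribonucleotide contacting the water: nucleobase, phosphate, ribose."""

    NB = "Nb"
    PH = "Ph"
    RB = "Rb"
    OTHER = "?"


def canonical_atom_name(name: str) -> str:
    """Normalize prime-dialect and legacy phosphate-oxygen atom names.

    ``O2*``, ``O2'`` and ``O2′`` all map to ``O2'``; ``O1P`` maps to ``OP1``.
    """
    n = name.strip().replace("*", "'").replace("′", "'")
    return _ATOM_ALIASES.get(n, n)


def classify_residue(res_name: str, water_names: frozenset = DEFAULT_WATER_NAMES) -> ResidueClass:
    """Deterministic residue-name classification; unknown names are OTHER."""
    name = res_name.strip().upper()
    if name in water_names:
        return ResidueClass.WATER
    if name in AMINO_ACIDS:
        return ResidueClass.AMINO_ACID
    if name in RIBONUCLEOTIDES:
        return ResidueClass.RIBONUCLEOTIDE
    return ResidueClass.OTHER


@dataclass
class Atom:
    name: str
    element: str
    coord: np.ndarray
    b_factor: float = 0.0
    occupancy: float = 1.0
    altloc: str = ""

    def __post_init__(self) -> None:
        self.coord = np.asarray(self.coord, dtype=float)
        if self.coord.shape != (3,) or not np.all(np.isfinite(self.coord)):
            raise ValueError(f"atom {self.name}: coordinate must be 3 finite components")


@dataclass(eq=False)
class Residue:
    chain_id: str
    seq_num: int
    res_name: str
    res_class: ResidueClass
    atoms: list[Atom] = field(default_factory=list)
    icode: str = ""

    @property
    def seq_id(self) -> str:
        """Residue number plus insertion code, e.g. ``"42"`` or ``"42A"``."""
        return f"{self.seq_num}{self.icode}"

    @property
    def sort_key(self) -> tuple:
        return (self.chain_id, self.seq_num, self.icode, self.res_name)

    @property
    def label(self) -> str:
        return f"{self.chain_id}/{self.res_name}{self.seq_id}"

    def atom(self, name: str) -> Optional[Atom]:
        name = canonical_atom_name(name)
        for a in self.atoms:
            if a.name == name:
                return a
        return None

    def atom_names(self) -> list[str]:
        return [a.name for a in self.atoms]


@dataclass
class Structure:
    pdb_id: str
    model_index: int
    residues: list[Residue]
    resolution: Optional[float] = None

    def iter_atoms(self) -> Iterator[tuple[Residue, Atom]]:
        for res in self.residues:
            for atom in res.atoms:
                yield res, atom

    def waters(self) -> list[Residue]:
        return [r for r in self.residues if r.res_class is ResidueClass.WATER]

    def find_residue(self, chain_id: str, seq_num: int, icode: str = "") -> Optional[Residue]:
        for r in self.residues:
            if r.chain_id == chain_id and r.seq_num == seq_num and r.icode == icode:
                return r
        return None


def _resolve_altlocs(atoms: Sequence[Atom]) -> list[Atom]:
    # keep the highest-occupancy conformer per atom name; ties -> lexicographically
    # first altloc, so a single coherent geometry survives per residue
    by_name: dict[str, Atom] = {}
    for a in atoms:
        prev = by_name.get(a.name)
        if prev is None or (-a.occupancy, a.altloc) < (-prev.occupancy, prev.altloc):
            by_name[a.name] = a
    return list(by_name.values())


_FMT_MAP = {
    "pdb": gemmi.CoorFormat.Pdb,
    "mmcif": gemmi.CoorFormat.Mmcif,
    "auto": gemmi.CoorFormat.Detect,
}


def parse_structure(
    path: str | Path,
    fmt: str = "auto",
    model: int = 1,
    water_names: frozenset = DEFAULT_WATER_NAMES,
) -> Structure:
    """Read a PDB or mmCIF file into a :class:`Structure`.

    Exactly one model is retained (``model`` is 1-based; the default matches
    X-ray practice where a single model is deposited).  Hydrogens present in
    the file are dropped; alternate conformers are resolved to the
    highest-occupancy one.  A structure without waters parses fine and simply
    yields no bridges downstream.
    """
    path = Path(path)
    if not path.exists():
        raise StructureParseError(f"{path}: file does not exist")
    if fmt not in _FMT_MAP:
        raise ValueError(f"fmt must be one of {sorted(_FMT_MAP)}, got {fmt!r}")
    try:
        st = gemmi.read_structure(str(path), format=_FMT_MAP[fmt])
    except (RuntimeError, ValueError) as exc:
        raise StructureParseError(f"{path}: {exc}") from exc
    if len(st) == 0:
        raise StructureParseError(f"{path}: no coordinate models found")
    if not 1 <= model <= len(st):
        raise StructureParseError(
            f"{path}: model {model} requested but file has {len(st)} model(s)"
        )
    gmodel = st[model - 1]

    residues: list[Residue] = []
    for chain in gmodel:
        for gres in chain:
            atoms: list[Atom] = []
            for ga in gres:
                if ga.element.is_hydrogen:
                    continue
                atoms.append(
                    Atom(
                        name=canonical_atom_name(ga.name),
                        element=ga.element.name,
                        coord=np.array([ga.pos.x, ga.pos.y, ga.pos.z]),
                        b_factor=float(ga.b_iso),
                        occupancy=float(ga.occ),
                        altloc="" if ga.altloc in ("\0", " ", "") else ga.altloc,
                    )
                )
            if not atoms:
                continue
            atoms = _resolve_altlocs(atoms)
            res_name = gres.name.strip().upper()
            res_class = classify_residue(res_name, water_names)
            if res_class is ResidueClass.WATER and not any(a.element == "O" for a in atoms):
                res_class = ResidueClass.OTHER
            residues.append(
                Residue(
                    chain_id=chain.name,
                    seq_num=gres.seqid.num,
                    res_name=res_name,
                    res_class=res_class,
                    atoms=atoms,
                    icode=(gres.seqid.icode or "").strip(),
                )
            )
    resolution = float(st.resolution) if st.resolution else None
    pdb_id = (st.name or path.stem).strip() or path.stem
    return Structure(pdb_id=pdb_id, model_index=model, residues=residues, resolution=resolution)


def write_pdb(structure: Structure, path: str | Path) -> None:
    """Write a canonicalized PDB file (ATOM/HETATM/END records only).

    Deterministic: same Structure -> byte-identical file.  Used mainly to
    materialize synthetic fixtures.
    """
    lines: list[str] = []
    serial = 0
    for res in structure.residues:
        record = "ATOM" if res.res_class in (ResidueClass.AMINO_ACID, ResidueClass.RIBONUCLEOTIDE) else "HETATM"
        for atom in res.atoms:
            serial += 1
            name = atom.name
            # PDB alignment: names of <4 chars with 1-char elements start in column 14
            if len(name) < 4 and len(atom.element) < 2:
                field_name = f" {name:<3s}"
            else:
                field_name = f"{name:<4s}"
            x, y, z = atom.coord
            lines.append(
                f"{record:<6s}{serial:>5d} {field_name}{atom.altloc or ' ':1s}"
                f"{res.res_name:>3s} {res.chain_id:1s}{res.seq_num:>4d}{res.icode or ' ':1s}   "
                f"{x:8.3f}{y:8.3f}{z:8.3f}{atom.occupancy:6.2f}{atom.b_factor:6.2f}"
                f"          {atom.element:>2s}  "
            )
    lines.append("END")
    Path(path).write_text("\n".join(lines) + "\n")


def moiety_of(residue: Residue, atom_name: str) -> Moiety:
    """Map a ribonucleotide atom to its moiety: nucleobase, phosphate or ribose.

    The partition assigns O3' and O2' to the ribose (their combination is what
    the ribose rule calls sugar-mediated) and keeps O5' with the phosphate
    ester.  Atoms outside the residue's chemical graph are flagged and mapped
    to OTHER so downstream stages can exclude them.
    """
    if residue.res_class is not ResidueClass.RIBONUCLEOTIDE:
        raise ValueError(f"{residue.label}: moiety_of requires a ribonucleotide")
    name = canonical_atom_name(atom_name)
    if name in _PHOSPHATE_ATOMS:
        return Moiety.PH
    if name in _RIBOSE_ATOMS:
        return Moiety.RB
    if name in _NUCLEOBASE_ATOMS[residue.res_name]:
        return Moiety.NB
    logger.warning("UNKNOWN_ATOM: %s atom %s not in %s chemical graph",
                   residue.label, name, residue.res_name)
    return Moiety.OTHER


def chain_part_of(residue: Residue, atom_name: str) -> str:
    """Return ``"m"`` (main chain) or ``"s"`` (side chain) for an amino-acid atom."""
    if residue.res_class is not ResidueClass.AMINO_ACID:
        raise ValueError(f"{residue.label}: chain_part_of requires an amino acid")
    return "m" if canonical_atom_name(atom_name) in MAIN_CHAIN_ATOMS else "s"


def display_name(residue: Residue) -> str:
    """Field-standard residue name: ``rA`` for adenosine, 3-letter codes for amino acids."""
    if residue.res_class is ResidueClass.RIBONUCLEOTIDE:
        return "r" + residue.res_name
    return residue.res_name.capitalize() if residue.res_class is ResidueClass.AMINO_ACID else residue.res_name
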