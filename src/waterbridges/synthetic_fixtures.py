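"""Synthetic PDB fixtures containing geometrically valid water bridges.

Every pipeline stage is testable without downloading crystal structures: a
:class:`FixtureManifest` names the bridges to realize (topology, cyclicity,
amino-acid portions, nucleotide moieties/edges, B-factors) and
:func:`generate_fixture` writes a PDB whose expected inventory is fully
determined by the manifest.

Residues use ideal heavy-atom geometry (the chemical component dictionary
templates bundled with biotite) and are placed rigidly around each bridging
water by a small penalized least-squares fit.  Intended hydrogen bonds are
realized at ~2.85 Å — inside the 3.35 Å donor–acceptor cutoff with at least
0.2 Å margin — while every unintended polar contact is kept at least 3.55 Å
away, so detection is robust to placement rounding.  No attempt is made to
mimic crystallographic realism (symmetry mates, disorder).
"""
from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
from biotite.structure.info import residue as ccd_residue
from scipy.optimize import minimize
from scipy.spatial.transform import Rotation

from .structure_io import (
    Atom,
    Residue,
    ResidueClass,
    Structure,
    canonical_atom_name,
    classify_residue,
    write_pdb,
)
from .hbond_detect import Role, donor_acceptor_roles
from .edge_classify import DEFAULT_TABLES, Edge, EdgePairTables
from .nomenclature import BridgeName, render_terms

__all__ = [
    "AASpec",
    "NTSpec",
    "BridgeSpec",
    "FixtureManifest",
    "ExpectedBridge",
    "FixtureError",
    "generate_fixture",
    "generate_edge_probe",
    "default_ensemble",
]

CONTACT_DIST = 2.85       # target water-oxygen ... partner heavy atom distance, Å
CONTACT_RANGE = (2.60, 3.12)
DIRECT_DIST = 2.90        # direct amino-acid--ribonucleotide bond target, Å
DIRECT_RANGE = (2.55, 3.25)
CLEARANCE = 3.55          # minimum distance for every unintended polar pair, Å
STERIC = 2.75             # minimum distance for any other cross-residue pair, Å
CLOSER_MARGIN = 0.40      # margin for distance-rule (edge-sector) placement, Å
SITE_SPACING = 50.0       # grid spacing between bridge sites, Å

PURINES = {"A", "G"}

_DEFAULT_SIDE_ATOM = {
    "ARG": "NH1", "LYS": "NZ", "ASN": "ND2", "GLN": "NE2", "ASP": "OD1",
    "GLU": "OE2", "SER": "OG", "THR": "OG1", "TYR": "OH", "HIS": "NE2",
    "TRP": "NE1", "CYS": "SG", "MET": "SD",
}
_DEFAULT_EDGE_ATOM = {
    ("A", "WC"): ("N1",), ("G", "WC"): ("N1",),
    ("C", "WC"): ("N3",), ("U", "WC"): ("N3",),
    ("A", "HG"): ("N7",), ("G", "HG"): ("N7",),
    ("A", "SG"): ("N3",), ("G", "SG"): ("N3",),
    ("C", "SG"): ("O2",), ("U", "SG"): ("O2",),
}

_TETRAHEDRAL = np.array([(1, 1, 1), (1, -1, -1), (-1, 1, -1), (-1, -1, 1)]) / np.sqrt(3)
_BIPYRAMID = np.array([
    (1.0, 0.0, 0.0),
    (-0.5, np.sqrt(3) / 2, 0.0),
    (-0.5, -np.sqrt(3) / 2, 0.0),
    (0.0, 0.0, 1.0),
    (0.0, 0.0, -1.0),
])


class FixtureError(ValueError):
    """Raised before writing anything when a manifest request is infeasible."""


# ---------------------------------------------------------------------------
# manifest
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class AASpec:
    """One amino-acid member: residue, interacting portion, optional explicit atoms."""

    res_name: str
    portion: str = "s"                      # m / s / ms
    water_atoms: Optional[tuple[str, ...]] = None

    def resolved_atoms(self) -> tuple[str, ...]:
        if self.water_atoms is not None:
            return tuple(canonical_atom_name(a) for a in self.water_atoms)
        name = self.res_name.upper()
        if self.portion == "m":
            return ("O",)
        side = _DEFAULT_SIDE_ATOM.get(name)
        if side is None:
            raise FixtureError(f"{name} has no default H-bonding side-chain atom "
                               f"(portion {self.portion!r} infeasible)")
        return ("O", side) if self.portion == "ms" else (side,)


@dataclass(frozen=True)
class NTSpec:
    """One ribonucleotide member: residue and requested annotation (WC/HG/SG/Ph/Rb)."""

    res_name: str
    annotation: str = "WC"
    water_atoms: Optional[tuple[str, ...]] = None

    def resolved_atoms(self) -> tuple[str, ...]:
        if self.water_atoms is not None:
            return tuple(canonical_atom_name(a) for a in self.water_atoms)
        name = self.res_name.upper()
        if self.annotation == "Ph":
            return ("OP2",)
        if self.annotation == "Rb":
            return ("O2'", "O3'")
        atoms = _DEFAULT_EDGE_ATOM.get((name, self.annotation))
        if atoms is None:
            raise FixtureError(f"no realizable {self.annotation} contact for r{name}")
        return atoms


@dataclass(frozen=True)
class BridgeSpec:
    """One requested water bridge."""

    aa: tuple[AASpec, ...]
    nt: tuple[NTSpec, ...]
    cyclic: bool = False
    # ((aa index, atom), (nt index, atom)); defaults to aa[0] backbone N -> nt[0] OP1
    direct_bond: Optional[tuple[tuple[int, str], tuple[int, str]]] = None
    water_b: float = 30.0

    @property
    def topology(self) -> str:
        return f"A{len(self.aa)}:w:N{len(self.nt)}"

    @property
    def label(self) -> str:
        return ("cyc-" if self.cyclic else "") + self.topology


@dataclass
class FixtureManifest:
    entries: list[BridgeSpec]
    seed: int = 0
    decoy_waters: int = 0
    decoy_bonds: int = 0
    bulk_water_b: float = 50.0

    def to_json(self) -> str:
        def spec(e: BridgeSpec) -> dict:
            return {
                "aa": [{"res_name": a.res_name, "portion": a.portion,
                        "water_atoms": list(a.water_atoms) if a.water_atoms else None}
                       for a in e.aa],
                "nt": [{"res_name": n.res_name, "annotation": n.annotation,
                        "water_atoms": list(n.water_atoms) if n.water_atoms else None}
                       for n in e.nt],
                "cyclic": e.cyclic,
                "direct_bond": [list(map(list, e.direct_bond))] if e.direct_bond else None,
                "water_b": e.water_b,
            }
        return json.dumps({
            "seed": self.seed,
            "decoy_waters": self.decoy_waters,
            "decoy_bonds": self.decoy_bonds,
            "bulk_water_b": self.bulk_water_b,
            "entries": [spec(e) for e in self.entries],
        }, indent=2)


@dataclass
class ExpectedBridge:
    """Oracle record: what the pipeline must recover for one manifest entry."""

    water_label: str
    label: str
    cyclic: bool
    name: BridgeName
    aa_terms: list[tuple[str, str]]          # (display name, portion), unordered
    nt_terms: list[tuple[str, str]]          # (display name, annotation), unordered
    water_b: float
    n_water_bonds: int
    over_tetrahedral: bool


# ---------------------------------------------------------------------------
# templates
# ---------------------------------------------------------------------------

_DROP_ATOMS = {"OXT", "OP3"}


_BASE_ATOMS = {
    "A": {"N1", "C2", "N3", "C4", "C5", "C6", "N6", "N7", "C8", "N9"},
    "G": {"N1", "C2", "N2", "N3", "C4", "C5", "C6", "O6", "N7", "C8", "N9"},
    "C": {"N1", "C2", "O2", "N3", "C4", "N4", "C5", "C6"},
    "U": {"N1", "C2", "O2", "N3", "C4", "O4", "C5", "C6"},
}


class _Template:
    def __init__(self, res_name: str):
        res_name = res_name.upper()
        arr = ccd_residue(res_name)
        keep = (arr.element != "H") & (arr.element != "D")
        arr = arr[keep]
        names = [canonical_atom_name(str(n)) for n in arr.atom_name]
        mask = [n not in _DROP_ATOMS for n in names]
        self.res_name = res_name
        self.atom_names = [n for n, m in zip(names, mask) if m]
        self.elements = [str(e) for e, m in zip(arr.element, mask) if m]
        coords = np.asarray(arr.coord, dtype=float)[np.array(mask)]
        self.coords = coords - coords.mean(axis=0)
        self.res_class = classify_residue(res_name)
        # polar-atom roles via a throwaway Residue
        probe = self._make_residue("?", 0, self.coords)
        self.roles = donor_acceptor_roles(probe)
        # internal torsions the placement fit may adjust, mirroring genuine
        # conformational freedom: glycosidic chi for nucleotides, the
        # carbonyl-O spin and side-chain chi1 for amino acids
        self.torsions: list[tuple[int, int, np.ndarray]] = []   # (axis from, axis to, group)
        if self.res_class is ResidueClass.RIBONUCLEOTIDE:
            glyco_n = "N9" if res_name in PURINES else "N1"
            base = _BASE_ATOMS[res_name]
            self.torsions.append((
                self.index("C1'"), self.index(glyco_n),
                np.array([n in base for n in self.atom_names]),
            ))
        elif self.res_class is ResidueClass.AMINO_ACID:
            backbone = {"N", "CA", "C", "O"}
            side = np.array([n not in backbone and n != "CB" for n in self.atom_names])
            self.torsions.append((
                self.index("CA"), self.index("C"),
                np.array([n == "O" for n in self.atom_names]),
            ))
            if side.any() and "CB" in self.atom_names:
                self.torsions.append((self.index("CA"), self.index("CB"), side))

    def conformer(self, angles: Sequence[float]) -> np.ndarray:
        """Template coordinates with the internal torsions set to ``angles`` (radians)."""
        coords = self.coords.copy()
        for (i_from, i_to, group), angle in zip(self.torsions, angles):
            if abs(angle) < 1e-12:
                continue
            pivot = coords[i_to]
            axis = coords[i_to] - coords[i_from]
            axis = axis / np.linalg.norm(axis)
            rot = Rotation.from_rotvec(angle * axis)
            coords[group] = rot.apply(coords[group] - pivot) + pivot
        return coords

    def index(self, atom: str) -> int:
        try:
            return self.atom_names.index(canonical_atom_name(atom))
        except ValueError:
            raise FixtureError(f"{self.res_name} has no atom {atom!r}") from None

    def polar_mask(self) -> np.ndarray:
        return np.array([self.roles.get(n, Role.NONE) is not Role.NONE
                         for n in self.atom_names])

    def _make_residue(self, chain: str, seq: int, coords: np.ndarray,
                      b: float = 20.0) -> Residue:
        atoms = [Atom(name=n, element=e, coord=c, b_factor=b, occupancy=1.0)
                 for n, e, c in zip(self.atom_names, self.elements, coords)]
        return Residue(chain_id=chain, seq_num=seq, res_name=self.res_name,
                       res_class=self.res_class, atoms=atoms)


_template_cache: dict[str, _Template] = {}


def _template(res_name: str) -> _Template:
    key = res_name.upper()
    if key not in _template_cache:
        _template_cache[key] = _Template(key)
    return _template_cache[key]


# ---------------------------------------------------------------------------
# rigid placement
# ---------------------------------------------------------------------------

def _member_directions(n: int) -> np.ndarray:
    if n <= 4:
        return _TETRAHEDRAL[:n]
    if n == 5:
        return _BIPYRAMID
    raise FixtureError(f"water coordination of {n} members is not realizable")


def _relu(x: np.ndarray) -> np.ndarray:
    return np.maximum(0.0, x)


def _fit_member(
    tpl: _Template,
    water: np.ndarray,
    direction: np.ndarray,
    contact_idx: list[int],
    closer_pairs: list[tuple[int, int]],
    direct_targets: list[tuple[int, int]],
    placed: np.ndarray,
    placed_polar_mask: np.ndarray,
    rng: np.random.Generator,
    placed_cross_mask: Optional[np.ndarray] = None,
) -> np.ndarray:
    """Place one rigid residue around the water; returns its coordinates.

    Minimizes a penalty holding the contact atoms at ~2.85 Å from the water
    oxygen, honoring edge-sector (closer-than) and direct-bond restraints
    (``direct_targets``: template atom index -> row of ``placed``), and
    pushing every unintended polar contact beyond the clearance radius.
    Polar clearance is enforced against the water and against the opposite
    biopolymer class (``placed_cross_mask``) — only those pairs can create
    unintended bonds; same-class polar proximity is harmless and common in
    real packed structures.
    """
    polar = tpl.polar_mask()
    non_contact_polar = polar.copy()
    for i in contact_idx:
        non_contact_polar[i] = False
    contact_centroid = tpl.coords[contact_idx].mean(axis=0)
    body = tpl.coords.mean(axis=0) - contact_centroid
    if np.linalg.norm(body) < 1e-6:
        body = np.array([1.0, 0.0, 0.0])

    n_atoms = len(tpl.coords)
    m_placed = len(placed)
    if placed_cross_mask is None:
        placed_cross_mask = np.ones(m_placed, dtype=bool)
    # pairwise enforcement masks against already-placed atoms; the restrained
    # direct-bond pair is exempt from both clearance and sterics
    enforce = np.ones((n_atoms, m_placed), dtype=bool)
    for i, row in direct_targets:
        enforce[i, row] = False
    clearance_mask = enforce & polar[:, None] & (placed_polar_mask & placed_cross_mask)[None, :]

    n_torsions = len(tpl.torsions)

    def build(params: np.ndarray) -> np.ndarray:
        rot = Rotation.from_rotvec(params[:3])
        base = tpl.conformer(params[6:6 + n_torsions]) if n_torsions else tpl.coords
        return rot.apply(base) + params[3:6]

    def penalty(params: np.ndarray) -> float:
        coords = build(params)
        total = 0.0
        # soft sector prior: keep the residue body in its own direction cone
        # so crowded sites leave later members room (not a hard constraint)
        centroid_dir = coords.mean(axis=0) - water
        norm = np.linalg.norm(centroid_dir)
        if norm > 1e-8:
            total += 2.0 * float(np.sum((centroid_dir / norm - direction) ** 2))
        for i in contact_idx:
            d = np.linalg.norm(coords[i] - water)
            total += 10.0 * (d - CONTACT_DIST) ** 2
        for i_close, i_far in closer_pairs:
            d_close = np.linalg.norm(coords[i_close] - water)
            d_far = np.linalg.norm(coords[i_far] - water)
            total += 10.0 * _relu(d_close - d_far + CLOSER_MARGIN + 0.25) ** 2
        for i, row in direct_targets:
            d = np.linalg.norm(coords[i] - placed[row])
            total += 10.0 * (d - DIRECT_DIST) ** 2
        if non_contact_polar.any():
            d = np.linalg.norm(coords[non_contact_polar] - water, axis=1)
            total += 4.0 * np.sum(_relu(CLEARANCE + 0.15 - d) ** 2)
        if m_placed:
            d = np.linalg.norm(coords[:, None, :] - placed[None, :, :], axis=2)
            total += 4.0 * np.sum(_relu(CLEARANCE + 0.15 - d[clearance_mask]) ** 2)
            total += 2.0 * np.sum(_relu(STERIC + 0.1 - d[enforce]) ** 2)
        # keep non-contact atoms out of the water's steric shell too
        mask = np.ones(n_atoms, dtype=bool)
        for i in contact_idx:
            mask[i] = False
        d = np.linalg.norm(coords[mask] - water, axis=1)
        total += 2.0 * np.sum(_relu(STERIC + 0.1 - d) ** 2)
        return float(total)

    def verify(params: np.ndarray) -> bool:
        coords = build(params)
        for i in contact_idx:
            d = np.linalg.norm(coords[i] - water)
            if not (CONTACT_RANGE[0] <= d <= CONTACT_RANGE[1]):
                return False
        for i_close, i_far in closer_pairs:
            if (np.linalg.norm(coords[i_far] - water)
                    - np.linalg.norm(coords[i_close] - water)) < CLOSER_MARGIN:
                return False
        for i, row in direct_targets:
            d = np.linalg.norm(coords[i] - placed[row])
            if not (DIRECT_RANGE[0] <= d <= DIRECT_RANGE[1]):
                return False
        if non_contact_polar.any():
            if np.linalg.norm(coords[non_contact_polar] - water, axis=1).min() < CLEARANCE:
                return False
        if m_placed:
            d = np.linalg.norm(coords[:, None, :] - placed[None, :, :], axis=2)
            if clearance_mask.any() and d[clearance_mask].min() < CLEARANCE:
                return False
            if enforce.any() and d[enforce].min() < STERIC:
                return False
        mask = np.ones(n_atoms, dtype=bool)
        for i in contact_idx:
            mask[i] = False
        if mask.any() and np.linalg.norm(coords[mask] - water, axis=1).min() < STERIC:
            return False
        return True

    # initial guesses: contact centroid on the member direction, residue body
    # pointing outward; then spins about the direction axis and random jitters
    align = Rotation.align_vectors(direction[None, :], (body / np.linalg.norm(body))[None, :])[0]
    starts = []
    first_torsion = (0.0, np.pi, np.pi / 2, -np.pi / 2) if n_torsions else (0.0,)
    for t0 in first_torsion:
        for spin_deg in (0, 60, 120, 180, 240, 300):
            spin = Rotation.from_rotvec(np.radians(spin_deg) * direction)
            rot = spin * align
            trans = water + (CONTACT_DIST + 0.05) * direction - rot.apply(contact_centroid)
            x0 = np.concatenate([rot.as_rotvec(), trans, np.zeros(n_torsions)])
            if n_torsions:
                x0[6] = t0
            starts.append(x0)
    for _ in range(60):
        rot = Rotation.from_rotvec(rng.uniform(-np.pi, np.pi, 3))
        wobble = direction + rng.uniform(-0.3, 0.3, 3)
        wobble /= np.linalg.norm(wobble)
        trans = water + (CONTACT_DIST + 0.05) * wobble - rot.apply(contact_centroid)
        starts.append(np.concatenate([rot.as_rotvec(), trans,
                                      rng.uniform(-np.pi, np.pi, n_torsions)]))

    for x0 in starts:
        result = minimize(penalty, x0, method="Nelder-Mead",
                          options={"maxiter": 2000, "xatol": 1e-4, "fatol": 1e-8})
        if verify(result.x):
            return build(result.x)
        # polish near-misses from a slightly perturbed restart
        result = minimize(penalty, result.x + rng.normal(0, 0.02, len(result.x)),
                          method="Nelder-Mead",
                          options={"maxiter": 1000, "xatol": 1e-5, "fatol": 1e-10})
        if verify(result.x):
            return build(result.x)
    raise FixtureError(
        f"could not place {tpl.res_name} without violating geometry margins "
        f"(contacts {[tpl.atom_names[i] for i in contact_idx]})"
    )


# ---------------------------------------------------------------------------
# generation
# ---------------------------------------------------------------------------

def _closer_pairs_for(tpl: _Template, spec: NTSpec, tables: EdgePairTables) -> list[tuple[int, int]]:
    """Edge-sector restraints for distance-rule atoms in the contact set."""
    atoms = spec.resolved_atoms()
    if len(atoms) != 1 or spec.annotation in ("Ph", "Rb"):
        return []
    rule = tables.ambiguous_singles.get((tpl.res_name, atoms[0]))
    if rule is None:
        return []
    want = Edge(spec.annotation)
    if want is rule.edge1:
        close, far = rule.adjacent1, rule.adjacent2
    elif want is rule.edge2:
        close, far = rule.adjacent2, rule.adjacent1
    else:
        raise FixtureError(f"r{tpl.res_name} {atoms[0]} cannot realize edge {want.value}")
    return [(tpl.index(close), tpl.index(far))]


def _check_roles(tpl: _Template, atoms: Sequence[str]) -> None:
    for a in atoms:
        role = tpl.roles.get(canonical_atom_name(a), Role.NONE)
        if role is Role.NONE:
            raise FixtureError(f"{tpl.res_name} atom {a} is not a hydrogen-bond donor/acceptor")


def _check_direct_roles(aa_tpl: _Template, aa_atom: str, nt_tpl: _Template, nt_atom: str) -> None:
    r1 = aa_tpl.roles.get(canonical_atom_name(aa_atom), Role.NONE)
    r2 = nt_tpl.roles.get(canonical_atom_name(nt_atom), Role.NONE)
    donates = (r1 in (Role.DONOR, Role.BOTH) and r2 in (Role.ACCEPTOR, Role.BOTH)) or \
              (r2 in (Role.DONOR, Role.BOTH) and r1 in (Role.ACCEPTOR, Role.BOTH))
    if not donates:
        raise FixtureError(
            f"direct bond {aa_tpl.res_name}:{aa_atom} -- {nt_tpl.res_name}:{nt_atom} "
            f"has incompatible donor/acceptor roles"
        )


def _expected_for(spec: BridgeSpec, water_label: str) -> ExpectedBridge:
    aa_terms = [(a.res_name.capitalize(), a.portion) for a in spec.aa]
    nt_terms = [("r" + n.res_name.upper(), n.annotation) for n in spec.nt]
    name = render_terms(spec.cyclic, aa_terms, nt_terms)
    n_bonds = sum(len(a.resolved_atoms()) for a in spec.aa) + \
        sum(len(n.resolved_atoms()) for n in spec.nt)
    return ExpectedBridge(
        water_label=water_label,
        label=spec.label,
        cyclic=spec.cyclic,
        name=name,
        aa_terms=aa_terms,
        nt_terms=nt_terms,
        water_b=spec.water_b,
        n_water_bonds=n_bonds,
        over_tetrahedral=n_bonds > 4,
    )


def generate_fixture(
    manifest: FixtureManifest,
    out_path: Optional[str | Path] = None,
    tables: EdgePairTables = DEFAULT_TABLES,
) -> tuple[Structure, list[ExpectedBridge]]:
    """Realize a manifest as a synthetic structure plus its expected inventory.

    Raises :class:`FixtureError` before producing anything if a request is
    infeasible.  Same manifest (including seed) -> identical output, so the
    written PDB is byte-reproducible.
    """
    rng = np.random.default_rng(manifest.seed)
    residues: list[Residue] = []
    expected: list[ExpectedBridge] = []
    aa_seq = nt_seq = wat_seq = 0
    site = 0

    def site_center(i: int) -> np.ndarray:
        return np.array([(i % 5) * SITE_SPACING,
                         ((i // 5) % 5) * SITE_SPACING,
                         (i // 25) * SITE_SPACING], dtype=float)

    hoh = _template("HOH")

    def add_water(pos: np.ndarray, b: float) -> Residue:
        nonlocal wat_seq
        wat_seq += 1
        res = Residue(chain_id="W", seq_num=wat_seq, res_name="HOH",
                      res_class=ResidueClass.WATER,
                      atoms=[Atom(name="O", element="O", coord=pos, b_factor=b)])
        residues.append(res)
        return res

    for entry in manifest.entries:
        if not entry.aa or not entry.nt:
            raise FixtureError("a bridge needs at least one amino acid and one ribonucleotide")
        water = site_center(site)
        site += 1
        n_members = len(entry.aa) + len(entry.nt)
        dirs = _member_directions(n_members)
        direct = entry.direct_bond
        if entry.cyclic and direct is None:
            direct = ((0, "N"), (0, "OP1"))
        if not entry.cyclic and direct is not None:
            raise FixtureError("direct_bond given for an acyclic entry")

        # nucleotides first (they anchor any direct bond), then amino acids
        order = [("nt", i) for i in range(len(entry.nt))] + \
                [("aa", i) for i in range(len(entry.aa))]

        def place_entry(attempt: int) -> list[np.ndarray]:
            placed_coords: list[np.ndarray] = []
            placed = np.empty((0, 3))
            placed_polar_mask = np.empty((0,), dtype=bool)
            placed_is_nt = np.empty((0,), dtype=bool)
            nt_atom_row: dict[tuple[int, str], int] = {}
            for slot, (kind, idx) in enumerate(order):
                if kind == "nt":
                    spec = entry.nt[idx]
                    tpl = _template(spec.res_name)
                    atoms = spec.resolved_atoms()
                    _check_roles(tpl, atoms)
                    closer = _closer_pairs_for(tpl, spec, tables)
                    direct_targets: list[tuple[int, int]] = []
                else:
                    spec = entry.aa[idx]
                    tpl = _template(spec.res_name)
                    atoms = spec.resolved_atoms()
                    _check_roles(tpl, atoms)
                    closer = []
                    direct_targets = []
                    if direct is not None and direct[0][0] == idx:
                        (aa_i, aa_atom), (nt_i, nt_atom) = direct
                        row = nt_atom_row.get((nt_i, canonical_atom_name(nt_atom)))
                        if row is None:
                            raise FixtureError(
                                f"direct bond references unknown nt atom {nt_atom!r}")
                        _check_direct_roles(tpl, aa_atom,
                                            _template(entry.nt[nt_i].res_name), nt_atom)
                        direct_targets = [(tpl.index(aa_atom), row)]
                contact_idx = [tpl.index(a) for a in atoms]
                member_rng = np.random.default_rng([manifest.seed, site, slot, attempt])
                cross = placed_is_nt if kind == "aa" else ~placed_is_nt
                coords = _fit_member(tpl, water, dirs[slot], contact_idx, closer,
                                     direct_targets, placed, placed_polar_mask,
                                     member_rng, placed_cross_mask=cross)
                placed_coords.append(coords)
                if kind == "nt":
                    for local_i, name_i in enumerate(tpl.atom_names):
                        nt_atom_row[(idx, name_i)] = len(placed) + local_i
                placed = np.vstack([placed, coords])
                placed_polar_mask = np.concatenate([placed_polar_mask, tpl.polar_mask()])
                placed_is_nt = np.concatenate([
                    placed_is_nt, np.full(len(coords), kind == "nt")])
            return placed_coords

        # greedy member placement can paint itself into a corner; re-randomize
        # the whole entry a few times before declaring the request infeasible
        placed_coords = None
        for attempt in range(6):
            try:
                placed_coords = place_entry(attempt)
                break
            except FixtureError:
                if attempt == 5:
                    raise

        for (kind, idx), coords in zip(order, placed_coords):
            if kind == "nt":
                tpl = _template(entry.nt[idx].res_name)
                nt_seq += 1
                residues.append(tpl._make_residue("B", nt_seq, coords))
            else:
                tpl = _template(entry.aa[idx].res_name)
                aa_seq += 1
                residues.append(tpl._make_residue("A", aa_seq, coords))
        water_res = add_water(water, entry.water_b)
        expected.append(_expected_for(entry, water_res.label))

    # decoy bonds: within-class water motifs that must NOT become bridges
    for k in range(manifest.decoy_bonds):
        water = site_center(site)
        site += 1
        protein_case = (k % 2 == 0)
        tpl = _template("SER" if protein_case else "A")
        contact = [tpl.index("OG" if protein_case else "N1")]
        placed = np.empty((0, 3))
        placed_polar_mask = np.empty((0,), dtype=bool)
        for slot in range(2):
            member_rng = np.random.default_rng([manifest.seed, site, slot])
            coords = _fit_member(tpl, water, _TETRAHEDRAL[slot], contact, [], [],
                                 placed, placed_polar_mask, member_rng,
                                 placed_cross_mask=np.zeros(len(placed), dtype=bool))
            placed = np.vstack([placed, coords])
            placed_polar_mask = np.concatenate([placed_polar_mask, tpl.polar_mask()])
            if protein_case:
                aa_seq += 1
                residues.append(tpl._make_residue("A", aa_seq, coords))
            else:
                nt_seq += 1
                residues.append(tpl._make_residue("B", nt_seq, coords))
        add_water(water, manifest.bulk_water_b)

    # isolated bulk waters
    for _ in range(manifest.decoy_waters):
        add_water(site_center(site), manifest.bulk_water_b)
        site += 1

    structure = Structure(pdb_id=f"synthetic-{manifest.seed}", model_index=1,
                          residues=residues)
    if out_path is not None:
        out_path = Path(out_path)
        write_pdb(structure, out_path)
        out_path.with_suffix(".manifest.json").write_text(manifest.to_json() + "\n")
    return structure, expected


# ---------------------------------------------------------------------------
# edge probes
# ---------------------------------------------------------------------------

def generate_edge_probe(
    nt_name: str,
    target_atom: str,
    displacement: float,
    tables: EdgePairTables = DEFAULT_TABLES,
) -> tuple[Structure, Edge]:
    """A lone nucleotide plus one water probing the distance rule.

    The water sits at hydrogen-bond distance from ``target_atom`` and is slid
    by ``displacement`` (Å) along the axis joining the two adjacent atoms
    (positive values move it toward the first-listed adjacent atom).  The
    expected edge is computed analytically from the final coordinates by
    comparing the two adjacent-atom distances — the same strictly-closer
    comparison the classifier is required to make.
    """
    nt_name = nt_name.upper()
    target_atom = canonical_atom_name(target_atom)
    rule = tables.ambiguous_singles.get((nt_name, target_atom))
    if rule is None:
        raise FixtureError(f"r{nt_name} {target_atom} is not an ambiguous-edge atom")
    tpl = _template(nt_name)
    coords = tpl.coords
    x_t = coords[tpl.index(target_atom)]
    x_1 = coords[tpl.index(rule.adjacent1)]
    x_2 = coords[tpl.index(rule.adjacent2)]
    axis = x_1 - x_2
    axis /= np.linalg.norm(axis)
    centroid = coords.mean(axis=0)
    out = x_t - centroid
    out -= np.dot(out, axis) * axis
    out /= np.linalg.norm(out)

    polar = tpl.polar_mask()
    other_polar = polar.copy()
    other_polar[tpl.index(target_atom)] = False

    normal = np.cross(axis, out)
    normal /= np.linalg.norm(normal)
    water_pos = None
    for tilt_deg in (0, 15, -15, 30, -30, 45, -45):
        tilt = np.radians(tilt_deg)
        direction = np.cos(tilt) * out + np.sin(tilt) * normal
        for radius in np.arange(2.80, 3.16, 0.05):
            candidate = x_t + radius * direction + displacement * axis
            d_target = np.linalg.norm(candidate - x_t)
            if not (2.60 <= d_target <= 3.12):
                continue
            if np.linalg.norm(coords[other_polar] - candidate, axis=1).min() < CLEARANCE:
                continue
            water_pos = candidate
            break
        if water_pos is not None:
            break
    if water_pos is None:
        raise FixtureError(
            f"no clash-free probe position for r{nt_name} {target_atom} "
            f"at displacement {displacement:+.2f}"
        )
    d1 = float(np.linalg.norm(x_1 - water_pos))
    d2 = float(np.linalg.norm(x_2 - water_pos))
    expected = rule.edge1 if d1 < d2 else rule.edge2

    residues = [
        tpl._make_residue("B", 1, coords),
        Residue(chain_id="W", seq_num=1, res_name="HOH", res_class=ResidueClass.WATER,
                atoms=[Atom(name="O", element="O", coord=water_pos, b_factor=30.0)]),
    ]
    return Structure(pdb_id=f"probe-{nt_name}-{target_atom}", model_index=1,
                     residues=residues), expected


# ---------------------------------------------------------------------------
# the default test ensemble
# ---------------------------------------------------------------------------

def default_ensemble(seed: int = 2024, decoy_waters: int = 6, decoy_bonds: int = 2) -> FixtureManifest:
    """The standard synthetic survey: every observed topology (triplet to
    quintet, cyclic and acyclic), every realizable two-atom pair rule, all
    distance-rule atoms in both sectors, the lone-O2' and O2'+O3' ribose
    cases, ms portions, and an over-tetrahedral water."""
    A, N, B = AASpec, NTSpec, BridgeSpec
    entries: list[BridgeSpec] = [
        # two-atom pair-list cases (every pair whose atoms can both H-bond water)
        B((A("ARG"),), (N("A", "WC", ("N1", "N6")),)),
        B((A("LYS"),), (N("G", "WC", ("N1", "N2")),)),
        B((A("ASN"),), (N("G", "WC", ("N1", "O6")),)),
        B((A("GLN"),), (N("C", "WC", ("N3", "N4")),)),
        B((A("SER"),), (N("C", "WC", ("N3", "O2")),)),
        B((A("THR"),), (N("U", "WC", ("N3", "O2")),)),
        B((A("TYR"),), (N("U", "WC", ("N3", "O4")),)),
        B((A("HIS"),), (N("A", "HG", ("N6", "N7")),)),
        B((A("TRP"),), (N("G", "HG", ("N7", "O6")),)),
        B((A("CYS"),), (N("A", "SG", ("N3", "O2'")),)),
        B((A("MET"),), (N("G", "SG", ("N2", "N3")),)),
        B((A("ASP"),), (N("C", "SG", ("O2", "O2'")),)),
        B((A("GLU"),), (N("U", "SG", ("O2", "O2'")),)),
        # distance-rule singles, both sectors of every ambiguous atom
        B((A("ARG"),), (N("A", "WC", ("N6",)),)),
        B((A("LYS"),), (N("A", "HG", ("N6",)),)),
        B((A("ASN"),), (N("G", "WC", ("O6",)),)),
        B((A("GLN"),), (N("G", "HG", ("O6",)),)),
        B((A("SER"),), (N("G", "WC", ("N2",)),)),
        B((A("THR"),), (N("G", "SG", ("N2",)),)),
        B((A("TYR"),), (N("C", "WC", ("O2",)),)),
        B((A("HIS"),), (N("C", "SG", ("O2",)),)),
        B((A("TRP"),), (N("U", "WC", ("O2",)),)),
        B((A("GLU"),), (N("U", "SG", ("O2",)),)),
        # unambiguous singles
        B((A("ARG"),), (N("A", "SG", ("N3",)),)),      # Arg(s):w:rA(SG)
        B((A("ASP"),), (N("A", "WC", ("N1",)),)),
        B((A("LYS"),), (N("G", "HG", ("N7",)),)),
        B((A("ASN"),), (N("C", "WC", ("N3",)),)),
        B((A("GLN"),), (N("U", "WC", ("O4",)),)),
        B((A("SER"),), (N("G", "SG", ("O2'",)),)),     # lone 2'-OH -> SG semantics
        # phosphate / ribose moieties
        B((A("GLY", "m"),), (N("U", "Ph"),)),
        B((A("THR"),), (N("C", "Rb"),)),               # O2'+O3' ribose rule
        B((A("PRO", "m"),), (N("A", "Ph"),)),
        # ms portion and main-chain-only contacts
        B((A("SER", "ms"),), (N("A", "WC", ("N1",)),)),
        B((A("ALA", "m"),), (N("G", "WC", ("N1",)),)),
        B((A("LEU", "m"),), (N("U", "Ph"),)),
        # quartets
        B((A("ARG"), A("SER", "m")), (N("A", "WC", ("N1",)),)),
        B((A("LYS"),), (N("G", "HG", ("N7",)), N("U", "Ph"))),
        # quintets
        B((A("TYR"), A("SER", "m"), A("ALA", "m")), (N("A", "HG", ("N7",)),)),
        B((A("ASN"), A("GLN")), (N("C", "WC", ("N3",)), N("A", "Ph"))),
        B((A("GLU"),), (N("G", "WC", ("N1", "O6")), N("A", "Rb"), N("U", "Ph"))),
        # cyclic topologies (direct amino-acid--ribonucleotide bond closes a ring)
        B((A("GLU"),), (N("G", "WC", ("O6",)),), cyclic=True,
          direct_bond=((0, "OE1"), (0, "N1"))),        # cyc-Glu(s):w:rG(WC)
        B((A("ARG"),), (N("U", "Ph"),), cyclic=True,
          direct_bond=((0, "NE"), (0, "OP1"))),
        B((A("SER"), A("GLY", "m")), (N("A", "SG", ("N3",)),), cyclic=True,
          direct_bond=((0, "N"), (0, "N1"))),
        B((A("LYS"),), (N("C", "WC", ("N3",)), N("U", "Ph")), cyclic=True,
          direct_bond=((0, "N"), (1, "OP1"))),
        B((A("THR"), A("ALA", "m"), A("GLY", "m")), (N("G", "HG", ("N7",)),), cyclic=True,
          direct_bond=((0, "N"), (0, "O6"))),
        B((A("ASP"), A("ASN", "m")), (N("A", "WC", ("N1",)), N("U", "Ph")), cyclic=True,
          direct_bond=((1, "N"), (1, "OP1"))),
        # over-tetrahedral water: five hydrogen bonds through an ms contact
        B((A("SER", "ms"), A("ARG")), (N("A", "WC", ("N1",)), N("U", "Ph"))),
    ]
    for i, e in enumerate(entries):
        entries[i] = BridgeSpec(aa=e.aa, nt=e.nt, cyclic=e.cyclic,
                                direct_bond=e.direct_bond,
                                water_b=25.0 + (i % 7) * 2.5)
    return FixtureManifest(entries=entries, seed=seed,
                           decoy_waters=decoy_waters, decoy_bonds=decoy_bonds)
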