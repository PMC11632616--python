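"""Survey-level aggregation of per-structure bridge inventories.

The counting unit for the residue-level tables is the hydrogen bond: one
water–residue-atom bond contributes one count (``unit="residues"`` switches
to counting each bonded residue once per water).  Topology tables count
bridges; B-factor means weight each water oxygen once.  The pair matrix
counts amino-acid–ribonucleotide co-membership within a bridge, once per
pair per bridge.
"""
from __future__ import annotations

import json
import logging
from collections import Counter
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Optional, Sequence

import numpy as np
import pandas as pd

from .structure_io import (
    AMINO_ACIDS,
    Moiety,
    Residue,
    ResidueClass,
    Structure,
    chain_part_of,
    display_name,
    moiety_of,
    parse_structure,
)
from .hbond_detect import BondKind, DEFAULT_CRITERIA, HBondCriteria, HydrogenBond, parse_hb2
from .bridge_graph import WaterBridge, survey_structure
from .edge_classify import DEFAULT_TABLES, Edge, EdgeAssignment, EdgePairTables, assign_nucleotide
from .nomenclature import BridgeName, render_name

logger = logging.getLogger(__name__)

__all__ = [
    "ClassifiedBridge",
    "StructureInventory",
    "SurveySummary",
    "TripletClassTable",
    "classify_bridge",
    "build_inventory",
    "analyze_file",
    "aggregate",
    "triplet_class_table",
    "write_reports",
    "write_inventory_jsonl",
]

_NT_DISPLAY = ["rA", "rC", "rG", "rU"]
_AA_DISPLAY = sorted(n.capitalize() for n in AMINO_ACIDS)


@dataclass
class ClassifiedBridge:
    """A water bridge with per-member classifications and its systematic name."""

    bridge: WaterBridge
    portions: dict[int, str]                 # id(aa residue) -> m/s/ms
    assignments: list[EdgeAssignment]
    name: Optional[BridgeName]               # None when a contact is unclassifiable


@dataclass
class StructureInventory:
    """Everything aggregate() needs from one structure."""

    pdb_id: str
    n_waters: int
    water_bfactors: list[float]
    bridges: list[ClassifiedBridge]


def classify_bridge(bridge: WaterBridge, tables: EdgePairTables = DEFAULT_TABLES) -> ClassifiedBridge:
    """Attach portions, edge assignments and the systematic name to a bridge."""
    water_o = bridge.water.atom("O")
    portions = {}
    for res in bridge.aa_members:
        parts = {chain_part_of(res, a) for a in bridge.member_atoms(res)}
        portions[id(res)] = "ms" if parts == {"m", "s"} else parts.pop()
    assignments = [
        assign_nucleotide(res, bridge.member_atoms(res), water_o, tables)
        for res in bridge.nt_members
    ]
    try:
        name = render_name(bridge, assignments)
    except ValueError as exc:
        logger.warning("bridge at %s left unnamed: %s", bridge.water.label, exc)
        name = None
    return ClassifiedBridge(bridge=bridge, portions=portions, assignments=assignments, name=name)


def build_inventory(
    structure: Structure,
    criteria: HBondCriteria = DEFAULT_CRITERIA,
    mode: str = "heavy_atom",
    hbonds: Optional[Sequence[HydrogenBond]] = None,
    tables: EdgePairTables = DEFAULT_TABLES,
) -> StructureInventory:
    """Run the full per-structure pipeline: detect, bridge, classify, name."""
    bridges = survey_structure(structure, criteria, mode, hbonds=hbonds)
    waters = structure.waters()
    bfactors = [w.atom("O").b_factor for w in waters if w.atom("O") is not None]
    return StructureInventory(
        pdb_id=structure.pdb_id,
        n_waters=len(waters),
        water_bfactors=bfactors,
        bridges=[classify_bridge(b, tables) for b in bridges],
    )


def analyze_file(
    path: str | Path,
    fmt: str = "auto",
    criteria: HBondCriteria = DEFAULT_CRITERIA,
    mode: str = "heavy_atom",
    hb2: Optional[str | Path] = None,
    tables: EdgePairTables = DEFAULT_TABLES,
) -> StructureInventory:
    """Parse one coordinate file and build its bridge inventory.

    When ``hb2`` names an HBPLUS output file, its bond list replaces native
    detection.
    """
    structure = parse_structure(path, fmt=fmt)
    hbonds = parse_hb2(hb2, structure) if hb2 is not None else None
    return build_inventory(structure, criteria, mode, hbonds=hbonds, tables=tables)


def _percent(counts: dict[str, int]) -> dict[str, float]:
    total = sum(counts.values())
    if total == 0:
        return {k: 0.0 for k in counts}
    return {k: 100.0 * v / total for k, v in counts.items()}


@dataclass
class SurveySummary:
    n_structures: int
    n_waters_total: int
    n_bridging_waters: int
    n_bridges: int
    bonds_by_nucleotide: dict[str, int]
    bonds_by_moiety: dict[str, int]
    bonds_by_amino_acid: dict[str, int]
    bonds_by_chain_part: dict[str, int]
    pair_matrix: pd.DataFrame
    topology_freq: dict[str, int]
    bfactor_mean_bridging: float
    bfactor_mean_all_waters: float
    bfactor_mean_by_order: dict[int, float]

    @property
    def pct_by_nucleotide(self) -> dict[str, float]:
        return _percent(self.bonds_by_nucleotide)

    @property
    def pct_by_moiety(self) -> dict[str, float]:
        return _percent(self.bonds_by_moiety)

    @property
    def pct_by_amino_acid(self) -> dict[str, float]:
        return _percent(self.bonds_by_amino_acid)

    @property
    def pct_by_chain_part(self) -> dict[str, float]:
        return _percent(self.bonds_by_chain_part)

    @property
    def pct_purine(self) -> float:
        p = self.pct_by_nucleotide
        return p.get("rA", 0.0) + p.get("rG", 0.0)

    @property
    def pct_pyrimidine(self) -> float:
        p = self.pct_by_nucleotide
        return p.get("rC", 0.0) + p.get("rU", 0.0)


def aggregate(inventories: Sequence[StructureInventory], unit: str = "bonds") -> SurveySummary:
    """Fold per-structure inventories into the survey summary.

    ``unit="bonds"`` counts every water–residue hydrogen bond;
    ``unit="residues"`` counts each bonded (water, residue) pair once.
    """
    if unit not in ("bonds", "residues"):
        raise ValueError(f"unit must be 'bonds' or 'residues', got {unit!r}")
    by_nt: Counter = Counter()
    by_moiety: Counter = Counter()
    by_aa: Counter = Counter()
    by_part: Counter = Counter()
    pair_matrix = pd.DataFrame(0, index=_AA_DISPLAY, columns=_NT_DISPLAY, dtype=int)
    topology: Counter = Counter()
    bridging_b: list[float] = []
    all_water_b: list[float] = []
    b_by_order: dict[int, list[float]] = {}
    n_waters = 0
    n_bridges = 0

    for inv in inventories:
        n_waters += inv.n_waters
        all_water_b.extend(inv.water_bfactors)
        for cb in inv.bridges:
            bridge = cb.bridge
            n_bridges += 1
            topology[bridge.label] += 1
            bridging_b.append(bridge.b_factor)
            b_by_order.setdefault(bridge.order, []).append(bridge.b_factor)
            for aa in bridge.aa_members:
                for nt in bridge.nt_members:
                    pair_matrix.loc[display_name(aa), display_name(nt)] += 1
            bonds = bridge.water_bonds
            if unit == "residues":
                seen: set[tuple[int, BondKind]] = set()
                kept = []
                for b in bonds:
                    partner = b.partner_of(bridge.water)
                    key = (id(partner[0]), b.kind)
                    if key not in seen:
                        seen.add(key)
                        kept.append(b)
                bonds = kept
            for b in bonds:
                partner, atom = b.partner_of(bridge.water)
                if b.kind is BondKind.WATER_RNA:
                    by_nt[display_name(partner)] += 1
                    by_moiety[moiety_of(partner, atom).value] += 1
                else:
                    by_aa[display_name(partner)] += 1
                    by_part[chain_part_of(partner, atom)] += 1

    return SurveySummary(
        n_structures=len(inventories),
        n_waters_total=n_waters,
        n_bridging_waters=n_bridges,
        n_bridges=n_bridges,
        bonds_by_nucleotide={k: by_nt.get(k, 0) for k in _NT_DISPLAY},
        bonds_by_moiety={m.value: by_moiety.get(m.value, 0) for m in (Moiety.NB, Moiety.PH, Moiety.RB)},
        bonds_by_amino_acid={k: by_aa.get(k, 0) for k in _AA_DISPLAY},
        bonds_by_chain_part={"m": by_part.get("m", 0), "s": by_part.get("s", 0)},
        pair_matrix=pair_matrix,
        topology_freq=dict(sorted(topology.items())),
        bfactor_mean_bridging=float(np.mean(bridging_b)) if bridging_b else float("nan"),
        bfactor_mean_all_waters=float(np.mean(all_water_b)) if all_water_b else float("nan"),
        bfactor_mean_by_order={k: float(np.mean(v)) for k, v in sorted(b_by_order.items())},
    )


@dataclass
class TripletClassTable:
    """Counts of nucleobase-mediated triplet classes, split by cyclicity."""

    acyclic: Counter = field(default_factory=Counter)   # (aa, portion, nt, edge) -> count
    cyclic: Counter = field(default_factory=Counter)

    def to_dataframe(self) -> pd.DataFrame:
        rows = []
        for cyc, table in ((False, self.acyclic), (True, self.cyclic)):
            for (aa, portion, nt, edge), count in sorted(table.items()):
                rows.append({"cyclic": cyc, "amino_acid": aa, "portion": portion,
                             "nucleotide": nt, "edge": edge, "count": count})
        return pd.DataFrame(rows, columns=["cyclic", "amino_acid", "portion",
                                           "nucleotide", "edge", "count"])


def triplet_class_table(inventories: Sequence[StructureInventory]) -> TripletClassTable:
    """Tabulate A1:w:N1 bridges whose nucleotide contact is nucleobase-mediated."""
    table = TripletClassTable()
    for inv in inventories:
        for cb in inv.bridges:
            bridge = cb.bridge
            if bridge.topology != "A1:w:N1":
                continue
            assignment = cb.assignments[0]
            if assignment.edge is Edge.NONE:
                continue  # phosphate/ribose-mediated or unclassified
            aa = bridge.aa_members[0]
            key = (display_name(aa), cb.portions[id(aa)],
                   display_name(bridge.nt_members[0]), assignment.edge.value)
            (table.cyclic if bridge.cyclic else table.acyclic)[key] += 1
    return table


# ---------------------------------------------------------------------------
# report writing
# ---------------------------------------------------------------------------

def _write_table(path: Path, header: list[str], rows: Iterable[Sequence]) -> None:
    lines = ["\t".join(header)]
    for row in rows:
        lines.append("\t".join(str(x) for x in row))
    path.write_text("\n".join(lines) + "\n")


def _fmt_pct(x: float) -> str:
    return f"{x:.1f}"


def write_reports(summary: SurveySummary, class_table: TripletClassTable, out_dir: str | Path) -> list[Path]:
    """Write deterministic TSV tables plus one JSON with the full summary.

    Re-running on identical input produces byte-identical files.  Percentages
    are printed to one decimal.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    written = []

    def table(name: str, header, rows):
        p = out / name
        _write_table(p, header, rows)
        written.append(p)

    pct_nt = summary.pct_by_nucleotide
    table("by_nucleotide.tsv", ["nucleotide", "bonds", "percent"],
          [(k, summary.bonds_by_nucleotide[k], _fmt_pct(pct_nt[k])) for k in _NT_DISPLAY])
    pct_m = summary.pct_by_moiety
    table("by_moiety.tsv", ["moiety", "bonds", "percent"],
          [(k, summary.bonds_by_moiety[k], _fmt_pct(pct_m[k])) for k in ("Nb", "Ph", "Rb")])
    pct_aa = summary.pct_by_amino_acid
    table("by_amino_acid.tsv", ["amino_acid", "bonds", "percent"],
          [(k, summary.bonds_by_amino_acid[k], _fmt_pct(pct_aa[k])) for k in _AA_DISPLAY])
    pct_part = summary.pct_by_chain_part
    table("by_chain_part.tsv", ["chain_part", "bonds", "percent"],
          [(k, summary.bonds_by_chain_part[k], _fmt_pct(pct_part[k])) for k in ("m", "s")])
    table("topology_freq.tsv", ["topology", "bridges"],
          sorted(summary.topology_freq.items()))
    table("pair_matrix.tsv", ["amino_acid"] + _NT_DISPLAY,
          [[aa] + [int(summary.pair_matrix.loc[aa, nt]) for nt in _NT_DISPLAY]
           for aa in _AA_DISPLAY])
    df = class_table.to_dataframe()
    table("triplet_classes.tsv", list(df.columns), df.itertuples(index=False))

    payload = {
        "n_structures": summary.n_structures,
        "n_waters_total": summary.n_waters_total,
        "n_bridging_waters": summary.n_bridging_waters,
        "n_bridges": summary.n_bridges,
        "bonds_by_nucleotide": summary.bonds_by_nucleotide,
        "bonds_by_moiety": summary.bonds_by_moiety,
        "bonds_by_amino_acid": summary.bonds_by_amino_acid,
        "bonds_by_chain_part": summary.bonds_by_chain_part,
        "pct_by_nucleotide": {k: round(v, 4) for k, v in summary.pct_by_nucleotide.items()},
        "pct_by_moiety": {k: round(v, 4) for k, v in summary.pct_by_moiety.items()},
        "pct_by_amino_acid": {k: round(v, 4) for k, v in summary.pct_by_amino_acid.items()},
        "pct_by_chain_part": {k: round(v, 4) for k, v in summary.pct_by_chain_part.items()},
        "topology_freq": summary.topology_freq,
        "bfactor_mean_bridging": round(summary.bfactor_mean_bridging, 4)
            if np.isfinite(summary.bfactor_mean_bridging) else None,
        "bfactor_mean_all_waters": round(summary.bfactor_mean_all_waters, 4)
            if np.isfinite(summary.bfactor_mean_all_waters) else None,
        "bfactor_mean_by_order": {str(k): round(v, 4)
                                  for k, v in summary.bfactor_mean_by_order.items()},
    }
    jpath = out / "summary.json"
    jpath.write_text(json.dumps(payload, indent=2, sort_keys=True) + "\n")
    written.append(jpath)
    return written


def write_inventory_jsonl(inventories: Sequence[StructureInventory], path: str | Path) -> None:
    """One JSON line per bridge: water id, members, bonds, label, name, B-factor."""
    lines = []
    for inv in inventories:
        for cb in inv.bridges:
            b = cb.bridge
            record = {
                "pdb_id": inv.pdb_id,
                "water": b.water.label,
                "label": b.label,
                "cyclic": b.cyclic,
                "order": b.order,
                "over_tetrahedral": b.over_tetrahedral,
                "b_factor": round(b.b_factor, 3),
                "name": cb.name.text if cb.name is not None else None,
                "aa_members": [
                    {"residue": r.label, "portion": cb.portions[id(r)],
                     "atoms": b.member_atoms(r)} for r in b.aa_members
                ],
                "nt_members": [
                    {"residue": a.nucleotide.label, "annotation": a.annotation,
                     "atoms": list(a.int_atoms), "method": a.method}
                    for a in cb.assignments
                ],
                "n_water_bonds": len(b.water_bonds),
                "n_direct_bonds": len(b.direct_bonds),
            }
            lines.append(json.dumps(record, sort_keys=True))
    Path(path).write_text("\n".join(lines) + ("\n" if lines else ""))
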