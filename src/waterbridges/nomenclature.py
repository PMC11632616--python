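"""Systematic water-bridge names, e.g. ``cyc-Thr(s)|Gly(m):w:rU(Ph)|rC(Rb)|rG(Rb)``.

Grammar (BNF)::

    name      ::= ["cyc-"] aa_terms ":w:" nt_terms
    aa_terms  ::= aa_term ("|" aa_term)*
    nt_terms  ::= nt_term ("|" nt_term)*
    aa_term   ::= AA3 "(" portion ")"        portion ::= "m" | "s" | "ms"
    nt_term   ::= ("rA"|"rC"|"rG"|"rU") "(" annot ")"
    annot     ::= "WC" | "HG" | "SG" | "Ph" | "Rb"

Canonical ordering: on the amino-acid side, main-chain (m) terms sit
immediately left of ``:w:``, preceded by ms terms, preceded by side-chain (s)
terms; within a group, names run in descending alphabetical order.  On the
nucleotide side, base-mediated terms come first (WC, then HG, then SG
closest-to-farthest from ``:w:``), then phosphate, then ribose, alphabetical
within each group.
"""
from __future__ import annotations

import re
from dataclasses import dataclass
from typing import Optional, Sequence

from .structure_io import AMINO_ACIDS, chain_part_of, display_name
from .bridge_graph import WaterBridge
from .edge_classify import EdgeAssignment

__all__ = [
    "BridgeName",
    "NameParseError",
    "render_name",
    "render_terms",
    "parse_name",
]

#: left-to-right order of amino-acid portion groups (m ends up nearest :w:)
_PORTION_LTR = ("s", "ms", "m")
#: left-to-right order of nucleotide annotation groups (WC nearest :w:)
_ANNOT_LTR = ("WC", "HG", "SG", "Ph", "Rb")

_AA_NAMES = frozenset(n.capitalize() for n in AMINO_ACIDS)
_NT_NAMES = frozenset({"rA", "rC", "rG", "rU"})


class NameParseError(ValueError):
    """Malformed bridge name; carries the character position of the fault."""

    def __init__(self, message: str, position: int):
        super().__init__(f"{message} (position {position})")
        self.position = position


@dataclass(frozen=True)
class BridgeName:
    cyclic: bool
    aa_terms: tuple[tuple[str, str], ...]  # (3-letter name, portion)
    nt_terms: tuple[tuple[str, str], ...]  # (rX name, annotation)

    @property
    def text(self) -> str:
        aa = "|".join(f"{name}({portion})" for name, portion in self.aa_terms)
        nt = "|".join(f"{name}({annot})" for name, annot in self.nt_terms)
        return ("cyc-" if self.cyclic else "") + aa + ":w:" + nt


def render_terms(
    cyclic: bool,
    aa_terms: Sequence[tuple[str, str]],
    nt_terms: Sequence[tuple[str, str]],
    aa_tiebreak: Optional[Sequence[tuple]] = None,
    nt_tiebreak: Optional[Sequence[tuple]] = None,
) -> BridgeName:
    """Canonically ordered :class:`BridgeName` from unordered term lists.

    ``*_tiebreak`` supply per-term sort keys (e.g. (chain, residue number))
    used only to order identical terms deterministically.
    """
    aa_tb = list(aa_tiebreak) if aa_tiebreak is not None else [()] * len(aa_terms)
    nt_tb = list(nt_tiebreak) if nt_tiebreak is not None else [()] * len(nt_terms)
    if len(aa_tb) != len(aa_terms) or len(nt_tb) != len(nt_terms):
        raise ValueError("tie-break lists must match term lists in length")

    def aa_key(item):
        (name, portion), tb = item
        if portion not in _PORTION_LTR:
            raise ValueError(f"invalid amino-acid portion {portion!r}")
        # descending alphabetical within a portion group
        return (_PORTION_LTR.index(portion), tuple(-ord(c) for c in name), tb)

    def nt_key(item):
        (name, annot), tb = item
        if annot not in _ANNOT_LTR:
            raise ValueError(f"invalid nucleotide annotation {annot!r}")
        return (_ANNOT_LTR.index(annot), name, tb)

    aa_sorted = tuple(t for t, _ in sorted(zip(aa_terms, aa_tb), key=aa_key))
    nt_sorted = tuple(t for t, _ in sorted(zip(nt_terms, nt_tb), key=nt_key))
    return BridgeName(cyclic=cyclic, aa_terms=aa_sorted, nt_terms=nt_sorted)


def render_name(bridge: WaterBridge, assignments: Sequence[EdgeAssignment]) -> BridgeName:
    """Systematic name of a classified bridge.

    Amino-acid portions are derived from the bridge's own water bonds (an
    amino acid contacting through both main and side chain gets ``ms``);
    every ribonucleotide member must have an :class:`EdgeAssignment`.
    """
    by_nt = {id(a.nucleotide): a for a in assignments}
    aa_terms, aa_tb = [], []
    for res in bridge.aa_members:
        parts = {chain_part_of(res, atom) for atom in bridge.member_atoms(res)}
        portion = "ms" if parts == {"m", "s"} else parts.pop()
        aa_terms.append((display_name(res), portion))
        aa_tb.append(res.sort_key)
    nt_terms, nt_tb = [], []
    for res in bridge.nt_members:
        assignment = by_nt.get(id(res))
        if assignment is None:
            raise ValueError(f"no edge assignment for bridge member {res.label}")
        annot = assignment.annotation
        if annot not in _ANNOT_LTR:
            raise ValueError(f"{res.label}: unclassified contact cannot be named")
        nt_terms.append((display_name(res), annot))
        nt_tb.append(res.sort_key)
    return render_terms(bridge.cyclic, aa_terms, nt_terms, aa_tb, nt_tb)


_TERM_RE = re.compile(r"([A-Za-z]{1,3})\(([A-Za-z]{1,2})\)")


def _parse_side(text: str, offset: int, nucleotide_side: bool) -> tuple[tuple[str, str], ...]:
    terms = []
    pos = offset
    if not text:
        raise NameParseError("empty term list", pos)
    for piece in text.split("|"):
        m = _TERM_RE.fullmatch(piece)
        if m is None:
            raise NameParseError(f"malformed term {piece!r}", pos)
        name, annot = m.group(1), m.group(2)
        if nucleotide_side:
            if name not in _NT_NAMES:
                raise NameParseError(f"unknown ribonucleotide {name!r}", pos)
            if annot not in _ANNOT_LTR:
                raise NameParseError(f"unknown annotation {annot!r}", pos + len(name))
        else:
            if name not in _AA_NAMES:
                raise NameParseError(f"unknown amino acid {name!r}", pos)
            if annot not in _PORTION_LTR:
                raise NameParseError(f"unknown portion {annot!r}", pos + len(name))
        terms.append((name, annot))
        pos += len(piece) + 1
    return tuple(terms)


def parse_name(text: str) -> BridgeName:
    """Parse a systematic bridge name back into its term lists (inverse of
    rendering on canonical names)."""
    cyclic = text.startswith("cyc-")
    body = text[4:] if cyclic else text
    offset = 4 if cyclic else 0
    if ":w:" not in body:
        raise NameParseError("missing central ':w:' token", offset)
    left, right = body.split(":w:", 1)
    aa_terms = _parse_side(left, offset, nucleotide_side=False)
    nt_terms = _parse_side(right, offset + len(left) + 3, nucleotide_side=True)
    return BridgeName(cyclic=cyclic, aa_terms=aa_terms, nt_terms=nt_terms)
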