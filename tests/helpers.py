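"""Shared test utilities: hand-built residues and an independent bond oracle."""
import itertools

import numpy as np

from waterbridges.structure_io import Atom, Residue, ResidueClass, classify_residue
from waterbridges.hbond_detect import Role, donor_acceptor_roles


def make_residue(res_name, atoms, chain="A", seq=1):
    """Residue from (atom name, element, xyz) triples."""
    return Residue(
        chain_id=chain,
        seq_num=seq,
        res_name=res_name,
        res_class=classify_residue(res_name),
        atoms=[Atom(name=n, element=e, coord=np.asarray(c, dtype=float))
               for n, e, c in atoms],
    )


def brute_force_hbonds(structure, max_da):
    """All-pairs reference detector: unordered polar atom pairs of the three
    interface kinds within the donor-acceptor cutoff, with compatible roles."""
    kinds = {
        frozenset({ResidueClass.WATER, ResidueClass.RIBONUCLEOTIDE}),
        frozenset({ResidueClass.WATER, ResidueClass.AMINO_ACID}),
        frozenset({ResidueClass.AMINO_ACID, ResidueClass.RIBONUCLEOTIDE}),
    }
    entries = []
    for res in structure.residues:
        if res.res_class is ResidueClass.OTHER:
            continue
        roles = donor_acceptor_roles(res)
        for atom in res.atoms:
            role = roles.get(atom.name, Role.NONE)
            if role is not Role.NONE:
                entries.append((res, atom, role))
    found = set()
    for (r1, a1, role1), (r2, a2, role2) in itertools.combinations(entries, 2):
        if r1 is r2:
            continue
        if frozenset({r1.res_class, r2.res_class}) not in kinds:
            continue
        if float(np.linalg.norm(a1.coord - a2.coord)) > max_da:
            continue
        fwd = role1 in (Role.DONOR, Role.BOTH) and role2 in (Role.ACCEPTOR, Role.BOTH)
        rev = role2 in (Role.DONOR, Role.BOTH) and role1 in (Role.ACCEPTOR, Role.BOTH)
        if fwd or rev:
            found.add(frozenset({(r1.sort_key, a1.name), (r2.sort_key, a2.name)}))
    return found


def bond_pair_set(bonds):
    """Unordered (residue, atom) endpoint pairs of a HydrogenBond list."""
    return {
        frozenset({(b.donor[0].sort_key, b.donor[1]),
                   (b.acceptor[0].sort_key, b.acceptor[1])})
        for b in bonds
    }
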