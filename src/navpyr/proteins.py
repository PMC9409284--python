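"""Residue templates: atom typing, connectivity and side-chain torsions.

United-atom (heavy atoms only) templates for the residue set used by the
package.  Polar hydrogens are implicit: donor capability is a flag on the
heavy atom and H positions are inferred geometrically where an angle test
needs them.
"""

from __future__ import annotations

import numpy as np

from .channel_io import ChannelStructure
from .energetics import ParameterizationError, Topology, TorsionDOF

__all__ = ["RESIDUE_TEMPLATES", "protein_topology", "side_chain_torsions"]

# atom name -> (type, donor, acceptor); backbone shared by all residues.
# Backbone amides are internally hydrogen-bonded within helices, so they
# carry no donor/acceptor flag for the explicit H-bond energy term; only
# side-chain polar groups form the wells the docking protocol senses.
_BACKBONE = {
    "N": ("N", False, False),
    "CA": ("CA", False, False),
    "C": ("C", False, False),
    "O": ("O", False, False),
}
_BB_BONDS = [("N", "CA"), ("CA", "C"), ("C", "O")]

#: side-chain atoms, bonds and chi dihedrals per residue name
RESIDUE_TEMPLATES: dict[str, dict] = {
    "GLY": {"atoms": {}, "bonds": [], "chi": []},
    "ALA": {"atoms": {"CB": ("CH3", False, False)}, "bonds": [("CA", "CB")], "chi": []},
    "SER": {
        "atoms": {"CB": ("CH2", False, False), "OG": ("OH", True, True)},
        "bonds": [("CA", "CB"), ("CB", "OG")],
        "chi": [("N", "CA", "CB", "OG")],
    },
    "CYS": {
        "atoms": {"CB": ("CH2", False, False), "SG": ("S", False, True)},
        "bonds": [("CA", "CB"), ("CB", "SG")],
        "chi": [("N", "CA", "CB", "SG")],
    },
    "THR": {
        "atoms": {
            "CB": ("CH2", False, False),
            "OG1": ("OH", True, True),
            "CG2": ("CH3", False, False),
        },
        "bonds": [("CA", "CB"), ("CB", "OG1"), ("CB", "CG2")],
        "chi": [("N", "CA", "CB", "OG1")],
    },
    "MET": {
        "atoms": {
            "CB": ("CH2", False, False),
            "CG": ("CH2", False, False),
            "SD": ("S", False, True),
            "CE": ("CH3", False, False),
        },
        "bonds": [("CA", "CB"), ("CB", "CG"), ("CG", "SD"), ("SD", "CE")],
        "chi": [
            ("N", "CA", "CB", "CG"),
            ("CA", "CB", "CG", "SD"),
            ("CB", "CG", "SD", "CE"),
        ],
    },
    "ASP": {
        "atoms": {
            "CB": ("CH2", False, False),
            "CG": ("CD", False, False),
            "OD1": ("OD", False, True),
            "OD2": ("OD", False, True),
        },
        "bonds": [("CA", "CB"), ("CB", "CG"), ("CG", "OD1"), ("CG", "OD2")],
        "chi": [("N", "CA", "CB", "CG"), ("CA", "CB", "CG", "OD1")],
    },
    "ASN": {
        "atoms": {
            "CB": ("CH2", False, False),
            "CG": ("C", False, False),
            "OD1": ("O", False, True),
            "ND2": ("N", True, False),
        },
        "bonds": [("CA", "CB"), ("CB", "CG"), ("CG", "OD1"), ("CG", "ND2")],
        "chi": [("N", "CA", "CB", "CG"), ("CA", "CB", "CG", "OD1")],
    },
    "ARG": {
        "atoms": {
            "CB": ("CH2", False, False),
            "CG": ("CH2", False, False),
            "CD": ("CH2", False, False),
            "NE": ("NR", True, False),
            "CZ": ("CZ", False, False),
            "NH1": ("NR", True, False),
            "NH2": ("NR", True, False),
        },
        "bonds": [
            ("CA", "CB"), ("CB", "CG"), ("CG", "CD"), ("CD", "NE"),
            ("NE", "CZ"), ("CZ", "NH1"), ("CZ", "NH2"),
        ],
        "chi": [
            ("N", "CA", "CB", "CG"),
            ("CA", "CB", "CG", "CD"),
            ("CB", "CG", "CD", "NE"),
        ],
    },
    "LEU": {
        "atoms": {
            "CB": ("CH2", False, False),
            "CG": ("CH2", False, False),
            "CD1": ("CH3", False, False),
            "CD2": ("CH3", False, False),
        },
        "bonds": [("CA", "CB"), ("CB", "CG"), ("CG", "CD1"), ("CG", "CD2")],
        "chi": [("N", "CA", "CB", "CG"), ("CA", "CB", "CG", "CD1")],
    },
    "PHE": {
        "atoms": {
            "CB": ("CH2", False, False),
            "CG": ("CAR", False, False),
            "CD1": ("CAR", False, False),
            "CD2": ("CAR", False, False),
            "CE1": ("CAR", False, False),
            "CE2": ("CAR", False, False),
            "CZ": ("CAR", False, False),
        },
        "bonds": [
            ("CA", "CB"), ("CB", "CG"), ("CG", "CD1"), ("CG", "CD2"),
            ("CD1", "CE1"), ("CD2", "CE2"), ("CE1", "CZ"), ("CE2", "CZ"),
        ],
        "chi": [("N", "CA", "CB", "CG"), ("CA", "CB", "CG", "CD1")],
    },
}


def protein_topology(structure: ChannelStructure) -> Topology:
    """Type every protein atom and collect bonds/donors/acceptors.

    Consecutive residues (native numbers differing by 1) are joined by a
    peptide bond.  Hetero residues are rejected: ligands carry their own
    topologies.
    """
    types: list[str] = [""] * structure.n_atoms
    names = [
        f"{structure.residues[structure.atom_res[i]].name}"
        f"{structure.residues[structure.atom_res[i]].resnum}:{structure.atom_names[i]}"
        for i in range(structure.n_atoms)
    ]
    bonds: list[tuple[int, int]] = []
    donors: list[int] = []
    acceptors: list[int] = []
    prev_c: dict[int, int] = {}  # resnum -> index of C, for peptide bonds
    for ri, res in enumerate(structure.residues):
        if res.hetero:
            raise ParameterizationError(
                f"hetero residue {res.name}{res.resnum} has no protein template"
            )
        tmpl = RESIDUE_TEMPLATES.get(res.name)
        if tmpl is None:
            raise ParameterizationError(f"no template for residue {res.name}")
        spec = dict(_BACKBONE)
        spec.update(tmpl["atoms"])
        local: dict[str, int] = {}
        for i in structure.atoms_of_residue(ri):
            aname = structure.atom_names[i]
            if aname not in spec:
                raise ParameterizationError(
                    f"atom {aname} not in template of {res.name}{res.resnum}"
                )
            t, don, acc = spec[aname]
            types[i] = t
            local[aname] = int(i)
            if don:
                donors.append(int(i))
            if acc:
                acceptors.append(int(i))
        for a, b in _BB_BONDS + tmpl["bonds"]:
            if a in local and b in local:
                bonds.append((local[a], local[b]))
        if (res.resnum - 1) in prev_c and "N" in local:
            bonds.append((prev_c[res.resnum - 1], local["N"]))
        if "C" in local:
            prev_c[res.resnum] = local["C"]
    if any(t == "" for t in types):
        missing = [names[i] for i, t in enumerate(types) if t == ""][:3]
        raise ParameterizationError(f"untyped atoms: {missing}")

    # Intra-residue pairs and near-range backbone pairs within one
    # sequence run are excluded from the nonbonded terms: residues and
    # helical backbones are internally rigid in this reduced model, so
    # those interactions are constant and the idealized geometry must not
    # generate artificial forces from them.
    extra: list[tuple[int, int]] = []
    atoms_by_res = [structure.atoms_of_residue(ri) for ri in range(len(structure.residues))]
    backbone = {"N", "CA", "C", "O"}
    for ri, idx in enumerate(atoms_by_res):
        for a in range(len(idx)):
            for b in range(a + 1, len(idx)):
                extra.append((int(idx[a]), int(idx[b])))
        for rj in range(ri + 1, min(ri + 5, len(structure.residues))):
            delta = structure.residues[rj].resnum - structure.residues[ri].resnum
            if not 1 <= delta <= 4:
                continue
            for i in idx:
                for j in atoms_by_res[rj]:
                    if delta <= 2 or (
                        structure.atom_names[i] in backbone
                        and structure.atom_names[j] in backbone
                    ):
                        extra.append((int(i), int(j)))
    return Topology(
        types=types,
        elements=list(structure.elements),
        bonds=bonds,
        names=names,
        donors=donors,
        acceptors=acceptors,
        extra_exclusions=extra,
    )


def side_chain_torsions(
    structure: ChannelStructure, res_indices: list[int]
) -> list[TorsionDOF]:
    """Chi-angle DOFs for the given residues (root-to-leaf order).

    The moving set of each chi is every side-chain atom beyond the rotated
    bond, found by template connectivity.
    """
    dofs: list[TorsionDOF] = []
    for ri in res_indices:
        res = structure.residues[ri]
        tmpl = RESIDUE_TEMPLATES.get(res.name)
        if tmpl is None or not tmpl["chi"]:
            continue
        local = {
            structure.atom_names[i]: int(i) for i in structure.atoms_of_residue(ri)
        }
        adj: dict[str, set[str]] = {}
        for a, b in _BB_BONDS + tmpl["bonds"]:
            adj.setdefault(a, set()).add(b)
            adj.setdefault(b, set()).add(a)
        for chi in tmpl["chi"]:
            a, b, c, d = chi
            if not all(x in local for x in chi):
                continue
            # atoms on the d-side of bond b-c
            seen = {b, c}
            stack = [c]
            moving: set[str] = set()
            while stack:
                cur = stack.pop()
                for nb in adj.get(cur, ()):
                    if nb not in seen:
                        seen.add(nb)
                        moving.add(nb)
                        stack.append(nb)
            idx = np.array(sorted(local[m] for m in moving if m in local), dtype=int)
            if len(idx):
                dofs.append(
                    TorsionDOF(
                        atoms=(local[a], local[b], local[c], local[d]), moving=idx
                    )
                )
    return dofs
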