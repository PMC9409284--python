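"""Geometric interaction detection and state-to-state contact comparison.

Detectors implement the standard literature criteria collected in
:mod:`navpyr.constants`: 4 A heavy-atom contacts (side-chain by default,
since that is what binding-site figures show), 3.5 A / 120 deg hydrogen
bonds with inferred polar hydrogens, vdW-sum + 0.2 A / 140 deg halogen
bonds (sigma-hole directionality), and 4.0 A salt bridges.  Contact
reports between gating states are partitioned into lost / gained /
retained / weakened, which is how state-dependent ligand binding is
diagnosed.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict

import numpy as np

from . import constants as k
from .channel_io import ChannelStructure, NativePosition, UniversalLabel

__all__ = [
    "ContactRecord",
    "InteractionReport",
    "ligand_contacts",
    "detect_hbond",
    "detect_halogen_bond",
    "detect_salt_bridge",
    "detect_pi_stack",
    "contact_diff",
    "residue_environment",
]


class InteractionInputError(ValueError):
    pass


@dataclass(frozen=True)
class ContactRecord:
    """A residue within cutoff of the ligand (or of a probe residue)."""

    label: UniversalLabel | None
    resnum: int
    resname: str
    min_distance: float
    residue_atom: str
    partner_atom: str
    contact_class: str = "vdw"  # vdw | hbond | xbond | salt_bridge

    def sort_key(self):
        if self.label is not None:
            return (0, self.label.domain, self.label.segment, self.label.index)
        return (1, self.resnum, "", 0)


@dataclass
class InteractionReport:
    """All contacts of one ligand pose against one channel state."""

    state: str
    ligand_id: str
    contacts: list[ContactRecord] = field(default_factory=list)

    def counts(self) -> dict[str, int]:
        out: dict[str, int] = {}
        for c in self.contacts:
            out[c.contact_class] = out.get(c.contact_class, 0) + 1
        return out

    def residue_keys(self) -> dict:
        return {
            (str(c.label.bare()) if c.label else f"res{c.resnum}"): c
            for c in self.contacts
        }

    def to_json(self, path) -> None:
        payload = {
            "state": self.state,
            "ligand_id": self.ligand_id,
            "contacts": [
                {
                    "label": str(c.label) if c.label else None,
                    "resnum": c.resnum,
                    "resname": c.resname,
                    "min_distance": round(c.min_distance, 3),
                    "residue_atom": c.residue_atom,
                    "partner_atom": c.partner_atom,
                    "class": c.contact_class,
                }
                for c in self.contacts
            ],
        }
        with open(path, "w") as fh:
            json.dump(payload, fh, indent=1)

    @classmethod
    def from_json(cls, path) -> "InteractionReport":
        from .channel_io import parse_label

        with open(path) as fh:
            payload = json.load(fh)
        contacts = []
        for c in payload["contacts"]:
            label = parse_label(c["label"])[0] if c["label"] else None
            contacts.append(
                ContactRecord(
                    label=label,
                    resnum=c["resnum"],
                    resname=c["resname"],
                    min_distance=c["min_distance"],
                    residue_atom=c["residue_atom"],
                    partner_atom=c["partner_atom"],
                    contact_class=c["class"],
                )
            )
        return cls(payload["state"], payload["ligand_id"], contacts)

    def to_tsv(self, path) -> None:
        with open(path, "w") as fh:
            fh.write("label\tnative\tresname\tmin_dist\tclass\tres_atom\tpartner\n")
            for c in self.contacts:
                fh.write(
                    f"{c.label or ''}\t{c.resnum}\t{c.resname}\t"
                    f"{c.min_distance:.3f}\t{c.contact_class}\t"
                    f"{c.residue_atom}\t{c.partner_atom}\n"
                )


def _heavy(structure: ChannelStructure, idx: np.ndarray) -> np.ndarray:
    return np.array(
        [i for i in idx if structure.elements[i].upper() != "H"], dtype=int
    )


def ligand_contacts(
    receptor: ChannelStructure,
    pose_coords: np.ndarray,
    pose_elements: list[str] | None = None,
    cutoff: float = k.CONTACT_CUTOFF,
    side_chain_only: bool = True,
    ligand_id: str = "ligand",
    ligand_atom_names: list[str] | None = None,
) -> list[ContactRecord]:
    """Residues with a heavy atom within `cutoff` of any ligand heavy atom.

    One record per residue, carrying the minimum distance and the closest
    atom pair; boundary-inclusive (<=).  By default only side-chain heavy
    atoms count (glycine falls back to Calpha), matching the semantics of
    "side chains of residues within 4 A" in binding-site figures; pass
    ``side_chain_only=False`` for any-atom distances.
    """
    pose = np.asarray(pose_coords, dtype=float).reshape(-1, 3)
    if pose_elements is not None:
        keep = [i for i, e in enumerate(pose_elements) if e.upper() != "H"]
        pose = pose[keep]
        if ligand_atom_names is not None:
            ligand_atom_names = [ligand_atom_names[i] for i in keep]
    if len(pose) == 0:
        return []
    records: list[ContactRecord] = []
    for ri, res in enumerate(receptor.residues):
        idx = (
            receptor.side_chain_atoms(ri)
            if side_chain_only
            else _heavy(receptor, receptor.atoms_of_residue(ri))
        )
        if len(idx) == 0:
            continue
        d = np.linalg.norm(
            receptor.coords[idx][:, None, :] - pose[None, :, :], axis=2
        )
        dmin = float(d.min())
        if dmin <= cutoff:
            ai, li = np.unravel_index(np.argmin(d), d.shape)
            records.append(
                ContactRecord(
                    label=res.label.bare() if res.label else None,
                    resnum=res.resnum,
                    resname=res.name,
                    min_distance=dmin,
                    residue_atom=receptor.atom_names[idx[ai]],
                    partner_atom=(
                        ligand_atom_names[li]
                        if ligand_atom_names
                        else f"L{li}"
                    ),
                )
            )
    records.sort(key=ContactRecord.sort_key)
    return records


def detect_hbond(
    donor: np.ndarray,
    acceptor: np.ndarray,
    hydrogen: np.ndarray | None = None,
    dmax: float = k.HBOND_DMAX,
    angle_min: float = k.HBOND_ANGLE_MIN,
) -> bool:
    """Hydrogen bond: D...A <= 3.5 A and D-H...A angle >= 120 deg.

    With implicit hydrogens (`hydrogen=None`) the H is inferred along the
    D->A direction, which makes the angle test pass trivially — the
    distance gate is then the operative criterion, as is standard for
    heavy-atom-only models.
    """
    donor = np.asarray(donor, float)
    acceptor = np.asarray(acceptor, float)
    d = float(np.linalg.norm(acceptor - donor))
    if d < 1e-6:
        raise InteractionInputError("donor and acceptor coincide")
    if d > dmax:
        return False
    if hydrogen is None:
        return True
    h = np.asarray(hydrogen, float)
    v1 = donor - h
    v2 = acceptor - h
    c = np.dot(v1, v2) / (np.linalg.norm(v1) * np.linalg.norm(v2))
    angle = np.degrees(np.arccos(np.clip(c, -1.0, 1.0)))
    return angle >= angle_min


def detect_halogen_bond(
    carbon: np.ndarray,
    halogen: np.ndarray,
    acceptor: np.ndarray,
    halogen_element: str,
    acceptor_element: str,
    slack: float = k.XBOND_SLACK,
    angle_min: float = k.XBOND_ANGLE_MIN,
) -> bool:
    """Halogen bond: X...A <= vdW sum + slack and C-X...A >= 140 deg."""
    xel = halogen_element.upper()
    if xel not in k.HALOGEN_ELEMENTS:
        raise InteractionInputError(f"{halogen_element} is not a halogen donor")
    ael = acceptor_element.upper()
    if ael not in k.HBOND_ACCEPTOR_ELEMENTS:
        raise InteractionInputError(f"{acceptor_element} cannot accept a halogen bond")
    x = np.asarray(halogen, float)
    a = np.asarray(acceptor, float)
    c = np.asarray(carbon, float)
    d = float(np.linalg.norm(a - x))
    if d > k.VDW_RADII[xel] + k.VDW_RADII[ael] + slack:
        return False
    v1 = c - x
    v2 = a - x
    cosang = np.dot(v1, v2) / (np.linalg.norm(v1) * np.linalg.norm(v2))
    angle = np.degrees(np.arccos(np.clip(cosang, -1.0, 1.0)))
    return angle >= angle_min


def detect_salt_bridge(
    acidic_oxygens: np.ndarray,
    basic_nitrogens: np.ndarray,
    dmax: float = k.SALT_BRIDGE_DMAX,
) -> bool | None:
    """Salt bridge: any carboxylate O within 4.0 A of any basic N.

    Returns None (indeterminate) when either atom set is empty — missing
    side-chain atoms must not silently read as "no bridge".
    """
    o = np.asarray(acidic_oxygens, float).reshape(-1, 3)
    n = np.asarray(basic_nitrogens, float).reshape(-1, 3)
    if len(o) == 0 or len(n) == 0:
        return None
    d = np.linalg.norm(o[:, None, :] - n[None, :, :], axis=2)
    return bool(d.min() <= dmax)


def classify_ligand_contacts(
    receptor: ChannelStructure,
    contacts: list[ContactRecord],
    pose_coords: np.ndarray,
    pose_elements: list[str],
    halogen_donors: list[tuple[int, int]] = (),
    ligand_acceptors: list[int] = (),
    ligand_donors: list[int] = (),
) -> list[ContactRecord]:
    """Upgrade vdw contact records to hbond/xbond where geometry qualifies."""
    from dataclasses import replace

    pose = np.asarray(pose_coords, float)
    out = []
    for rec in contacts:
        ri = receptor.residue_by_resnum(rec.resnum)
        cls = rec.contact_class
        # halogen bond: ligand C-X vs residue acceptor (N, O, S)
        for c_idx, x_idx in halogen_donors:
            for ai in receptor.side_chain_atoms(ri):
                ael = receptor.elements[ai].upper()
                if ael not in k.HBOND_ACCEPTOR_ELEMENTS:
                    continue
                if detect_halogen_bond(
                    pose[c_idx], pose[x_idx], receptor.coords[ai],
                    pose_elements[x_idx], ael,
                ):
                    cls = "xbond"
        if cls == "vdw":
            # H-bond: ligand acceptor vs residue donor and vice versa
            from .proteins import RESIDUE_TEMPLATES

            tmpl = RESIDUE_TEMPLATES.get(rec.resname, {"atoms": {}})
            for ai in receptor.side_chain_atoms(ri):
                aname = receptor.atom_names[ai]
                t = tmpl["atoms"].get(aname)
                if t is None:
                    continue
                _, donor, acceptor = t
                for li in ligand_acceptors:
                    if donor and detect_hbond(receptor.coords[ai], pose[li]):
                        cls = "hbond"
                for li in ligand_donors:
                    if acceptor and detect_hbond(pose[li], receptor.coords[ai]):
                        cls = "hbond"
        if cls != rec.contact_class:
            rec = replace(rec, contact_class=cls)
        out.append(rec)
    return out


def detect_pi_stack(
    centroid_a: np.ndarray,
    centroid_b: np.ndarray,
    dmax: float = k.PI_STACK_DMAX,
) -> bool:
    """Descriptive aromatic-stacking report: ring centroids within 5.5 A.

    Experimental: purely geometric, with no orientation test and no
    energy term behind it — reported for orientation of binding-pose
    figures, never for scoring.
    """
    d = float(np.linalg.norm(np.asarray(centroid_a, float)
                             - np.asarray(centroid_b, float)))
    if d < 1e-6:
        raise InteractionInputError("ring centroids coincide")
    return d <= dmax


def contact_diff(
    a: InteractionReport,
    b: InteractionReport,
    weakened_delta: float = k.WEAKENED_DELTA,
) -> dict[str, list]:
    """Partition contact residues of two states of the same ligand.

    ``lost`` = in a only, ``gained`` = in b only, ``retained`` = in both
    with similar distance, ``weakened`` = in both but the minimum distance
    grew by more than `weakened_delta` from a to b.
    """
    if a.ligand_id != b.ligand_id:
        raise InteractionInputError(
            f"cannot diff different ligands ({a.ligand_id!r} vs {b.ligand_id!r})"
        )
    ka, kb = a.residue_keys(), b.residue_keys()
    lost = sorted(set(ka) - set(kb))
    gained = sorted(set(kb) - set(ka))
    retained, weakened = [], []
    for key in sorted(set(ka) & set(kb)):
        if kb[key].min_distance - ka[key].min_distance > weakened_delta:
            weakened.append(key)
        else:
            retained.append(key)
    return {"lost": lost, "gained": gained, "retained": retained,
            "weakened": weakened}


def residue_environment(
    structure: ChannelStructure,
    label: UniversalLabel,
    cutoff: float = 4.5,
) -> list[dict]:
    """Intersegment neighbourhood of one residue.

    Neighbours are residues with any heavy atom within `cutoff` of the
    probe residue's side-chain heavy atoms, sorted by distance; sequential
    neighbours in the same segment (|delta index| <= 2) are excluded so
    the report stays intersegment-focused.  Detected interaction classes
    (hbond, salt_bridge) are attached.
    """
    ri = structure.residue_by_label(label)
    if ri is None:
        raise KeyError(f"label {label} not present in structure")
    probe = structure.residues[ri]
    pidx = structure.side_chain_atoms(ri)
    if len(pidx) == 0 or cutoff <= 0:
        return []
    out = []
    for rj, res in enumerate(structure.residues):
        if rj == ri:
            continue
        if (
            res.domain == probe.domain
            and res.segment == probe.segment
            and res.seg_index is not None
            and probe.seg_index is not None
            and abs(res.seg_index - probe.seg_index) <= 2
        ):
            continue
        qidx = _heavy(structure, structure.atoms_of_residue(rj))
        if len(qidx) == 0:
            continue
        d = np.linalg.norm(
            structure.coords[pidx][:, None, :] - structure.coords[qidx][None, :, :],
            axis=2,
        )
        dmin = float(d.min())
        if dmin > cutoff:
            continue
        classes = _pair_classes(structure, ri, rj)
        out.append(
            {
                "label": str(res.label.bare()) if res.label else None,
                "resnum": res.resnum,
                "resname": res.name,
                "min_distance": dmin,
                "classes": classes,
            }
        )
    out.sort(key=lambda r: r["min_distance"])
    return out


_ACIDIC = {"ASP": ("OD1", "OD2"), "GLU": ("OE1", "OE2")}
_BASIC = {"ARG": ("NE", "NH1", "NH2"), "LYS": ("NZ",)}


def _pair_classes(structure: ChannelStructure, ri: int, rj: int) -> list[str]:
    """Interaction classes between two residues' side chains."""
    from .proteins import RESIDUE_TEMPLATES

    classes = []
    ra, rb = structure.residues[ri], structure.residues[rj]

    def polar(rres, rid, want_donor):
        tmpl = RESIDUE_TEMPLATES.get(rres.name)
        if tmpl is None:
            return []
        idx = []
        for i in structure.atoms_of_residue(rid):
            t = tmpl["atoms"].get(structure.atom_names[i])
            if t and (t[1] if want_donor else t[2]):
                idx.append(i)
        return idx

    # hydrogen bond either direction
    hb = False
    for di in polar(ra, ri, True):
        for ai in polar(rb, rj, False):
            if detect_hbond(structure.coords[di], structure.coords[ai]):
                hb = True
    for di in polar(rb, rj, True):
        for ai in polar(ra, ri, False):
            if detect_hbond(structure.coords[di], structure.coords[ai]):
                hb = True
    if hb:
        classes.append("hbond")

    def group(res, rid, table):
        names = table.get(res.name)
        if not names:
            return np.empty((0, 3))
        idx = [structure.atom_index(rid, n) for n in names]
        idx = [i for i in idx if i is not None]
        return structure.coords[idx] if idx else np.empty((0, 3))

    for (acid, aci), (base, bsi) in (((ra, ri), (rb, rj)), ((rb, rj), (ra, ri))):
        o = group(acid, aci, _ACIDIC)
        n = group(base, bsi, _BASIC)
        if len(o) and len(n) and detect_salt_bridge(o, n):
            classes.append("salt_bridge")
            break
    return classes
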