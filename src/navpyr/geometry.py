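"""Rigid-body superposition and RMSD machinery.

Channel models in different gating states (and different channels) are
3D-aligned on the Calpha atoms of their P1 helices, the most structurally
conserved part of P-loop channels; everything here is built around that
use case: named atom selections, SVD-based Kabsch fitting with reflection
correction, and plain subset RMSDs for morph-convergence reporting.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .channel_io import ChannelStructure, SEGMENT_CODES

__all__ = [
    "GeometryError",
    "SelectionError",
    "RigidTransform",
    "AtomSelection",
    "kabsch",
    "superpose",
    "rmsd_subset",
]

#: Universal indices treated as the P1 half of the re-entrant P-loop.
#: The hairpin is modeled as P1 helix + turn; indices above this bound are
#: turn/P2 residues and excluded from "p1" selections.
P1_MAX_INDEX = 5


class GeometryError(ValueError):
    """Degenerate or mismatched geometry input."""


class SelectionError(ValueError):
    """An atom selection matched nothing (or could not be parsed)."""


@dataclass(frozen=True)
class RigidTransform:
    """Proper rotation + translation, acting as ``x -> R x + t``."""

    rotation: np.ndarray
    translation: np.ndarray

    def __post_init__(self) -> None:
        R = np.asarray(self.rotation, dtype=float)
        t = np.asarray(self.translation, dtype=float)
        object.__setattr__(self, "rotation", R)
        object.__setattr__(self, "translation", t)
        if R.shape != (3, 3) or t.shape != (3,):
            raise GeometryError("rotation must be 3x3 and translation length 3")
        if not np.allclose(R.T @ R, np.eye(3), atol=1e-10):
            raise GeometryError("rotation is not orthonormal")
        if not np.isclose(np.linalg.det(R), 1.0, atol=1e-10):
            raise GeometryError("rotation determinant is not +1")

    @classmethod
    def identity(cls) -> "RigidTransform":
        return cls(np.eye(3), np.zeros(3))

    def apply(self, coords: np.ndarray) -> np.ndarray:
        return np.asarray(coords) @ self.rotation.T + self.translation


@dataclass(frozen=True)
class AtomSelection:
    """A deterministic atom selection over annotated structures.

    ``segments`` picks universal segment codes (plus ``s4`` for the
    voltage-sensing helix when annotated); ``p1_only`` restricts ``p`` to
    the P1 helix; ``domains``, ``atom_names`` and ``index_range`` narrow
    further.  Resolution returns a fixed ordered list of
    ``(key, atom_index)`` pairs where key = (domain, segment, seg_index,
    atom_name); pairing across two structures matches identical keys.
    """

    segments: tuple[str, ...] = SEGMENT_CODES
    atom_names: tuple[str, ...] = ("CA",)
    domains: tuple[int, ...] = (1, 2, 3, 4)
    p1_only: bool = False
    index_range: tuple[int, int] | None = None


    @classmethod
    def parse(cls, text: str) -> "AtomSelection":
        """Parse the CLI mini-language, e.g. ``p1-ca``, ``pm-ca``, ``i-ca``.

        Grammar: ``<segs>-<atom>`` where segs is ``p1``, ``pm`` (= k,o,p,i),
        ``all``, or a run of segment codes (``koi``); atom is an atom name.
        """
        try:
            segs, atom = text.lower().rsplit("-", 1)
        except ValueError:
            raise SelectionError(f"cannot parse selection {text!r}")
        atom = atom.upper()
        if segs == "p1":
            return cls(segments=("p",), atom_names=(atom,), p1_only=True)
        if segs in ("pm", "all"):
            return cls(segments=SEGMENT_CODES, atom_names=(atom,))
        if segs == "s4":
            return cls(segments=("s4",), atom_names=(atom,))
        codes = tuple(segs)
        if not all(c in SEGMENT_CODES for c in codes):
            raise SelectionError(f"unknown segment codes in {text!r}")
        return cls(segments=codes, atom_names=(atom,))

    def resolve(self, structure: ChannelStructure) -> list[tuple[tuple, int]]:
        out: list[tuple[tuple, int]] = []
        for ri, res in enumerate(structure.residues):
            if res.segment is None or res.segment not in self.segments:
                continue
            if res.domain not in self.domains:
                continue
            if self.p1_only and res.segment == "p" and res.seg_index > P1_MAX_INDEX:
                continue
            if self.index_range is not None and not (
                self.index_range[0] <= res.seg_index <= self.index_range[1]
            ):
                continue
            for i in structure.atoms_of_residue(ri):
                if structure.atom_names[i] in self.atom_names:
                    key = (res.domain, res.segment, res.seg_index,
                           structure.atom_names[i])
                    out.append((key, int(i)))
        out.sort(key=lambda kv: kv[0])
        return out


def paired_indices(
    a: ChannelStructure, b: ChannelStructure, selection: AtomSelection
) -> tuple[np.ndarray, np.ndarray, int]:
    """Indices of atoms matched by identical (label, atom-name) keys.

    Returns (indices_in_a, indices_in_b, n_unpaired); unpaired atoms are
    dropped, since superposition across different channels cannot expect
    full coverage.
    """
    sel_a = selection.resolve(a)
    sel_b = dict(selection.resolve(b))
    ia, ib = [], []
    unpaired = 0
    for key, i in sel_a:
        j = sel_b.get(key)
        if j is None:
            unpaired += 1
        else:
            ia.append(i)
            ib.append(j)
    unpaired += len(sel_b) - len(ib)
    return np.asarray(ia, dtype=int), np.asarray(ib, dtype=int), unpaired


def kabsch(P: np.ndarray, Q: np.ndarray) -> tuple[RigidTransform, float]:
    """Least-squares rigid fit of P onto Q (SVD Kabsch, reflection-corrected).

    Returns the transform minimizing the RMSD of ``R P + t`` against Q, and
    that minimal RMSD in A.
    """
    P = np.asarray(P, dtype=float)
    Q = np.asarray(Q, dtype=float)
    if P.shape != Q.shape or P.ndim != 2 or P.shape[1] != 3:
        raise GeometryError(f"point sets must be equal (n,3) arrays, got "
                            f"{P.shape} vs {Q.shape}")
    n = len(P)
    if n < 3:
        raise GeometryError("need at least 3 points")
    cp, cq = P.mean(axis=0), Q.mean(axis=0)
    Pc, Qc = P - cp, Q - cq
    # collinearity check: second singular value of the centered cloud
    if np.linalg.svd(Pc, compute_uv=False)[1] < 1e-8:
        raise GeometryError("degenerate (collinear) point set")
    H = Pc.T @ Qc
    U, S, Vt = np.linalg.svd(H)
    d = np.sign(np.linalg.det(Vt.T @ U.T))
    D = np.diag([1.0, 1.0, d])
    R = Vt.T @ D @ U.T
    t = cq - R @ cp
    rmsd = float(np.sqrt(np.mean(np.sum((Pc @ R.T - Qc) ** 2, axis=1))))
    return RigidTransform(R, t), rmsd


def superpose(
    mobile: ChannelStructure,
    reference: ChannelStructure,
    selection: AtomSelection,
) -> tuple[ChannelStructure, float]:
    """Fit `mobile` onto `reference` on the paired selection.

    All atoms of the returned copy are transformed; `reference` is
    untouched.  The fit RMSD over the selection is returned alongside.
    """
    ia, ib, _ = paired_indices(mobile, reference, selection)
    if len(ia) == 0:
        raise SelectionError("selection matched no paired atoms")
    tf, rmsd = kabsch(mobile.coords[ia], reference.coords[ib])
    fitted = mobile.copy()
    fitted.coords = tf.apply(fitted.coords)
    return fitted, rmsd


def rmsd_subset(
    a: ChannelStructure, b: ChannelStructure, selection: AtomSelection
) -> float:
    """Plain coordinate RMSD over the paired selection, without refitting."""
    ia, ib, _ = paired_indices(a, b, selection)
    if len(ia) == 0:
        raise SelectionError("selection matched no paired atoms")
    d = a.coords[ia] - b.coords[ib]
    return float(np.sqrt(np.mean(np.sum(d * d, axis=1))))


def coords_rmsd(P: np.ndarray, Q: np.ndarray) -> float:
    """RMSD of two equal-length coordinate arrays (no fitting)."""
    P, Q = np.asarray(P, float), np.asarray(Q, float)
    if P.shape != Q.shape:
        raise GeometryError("shape mismatch")
    return float(np.sqrt(np.mean(np.sum((P - Q) ** 2, axis=1))))
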