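"""Structures, sequences and the universal P-loop-channel residue nomenclature.

Voltage-gated sodium channels fold from a single chain of four homologous
domains (I-IV), each contributing an S4-S5 linker-helix (``k``), an outer
helix S5 (``o``), a membrane re-entrant P-loop (``p``) and a pore-lining
inner helix S6 (``i``) to the pore module.  Because native residue numbers
differ wildly between species, positions are addressed with a *universal
label*: domain number, segment code and the relative index of the residue
within the segment, e.g. ``2k11`` for position 11 of the domain-II linker
helix.  The same residue is often quoted in the literature with its house-fly
channel number, giving dual notations such as ``M918/2k11``.

This module houses the label grammar, the annotation tables that tie
universal indices to native residue numbers, structure reading/writing
(PDB and mmCIF, via gemmi), and numbering translation between reference
sequences through pairwise alignments.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Mapping

import gemmi
import numpy as np

__all__ = [
    "SEGMENT_CODES",
    "UniversalLabel",
    "NativePosition",
    "Span",
    "SegmentAnnotation",
    "Residue",
    "ChannelStructure",
    "LabelError",
    "AnnotationError",
    "StructureParseError",
    "NoEquivalentError",
    "parse_label",
    "format_label",
    "assign_labels",
    "translate_numbering",
    "read_structure",
    "write_structure",
]

#: Universal segment codes: k = S4-S5 linker-helix, o = outer helix S5,
#: p = P-loop, i = inner helix S6.
SEGMENT_CODES = ("k", "o", "p", "i")

#: Channel gating-state tags.  ``i`` prefix = inactivated pore module,
#: ``o`` = open pore module, ``o-i`` = opened then re-inactivated,
#: ``o-d`` = open pore module with deactivated voltage sensors.
STATE_TAGS = (
    "inactivated_pm",
    "open_pm",
    "open_to_inactivated",
    "open_pm_deactivated_vsm",
    "unknown",
)


class LabelError(ValueError):
    """A residue label string does not follow the universal grammar."""


class AnnotationError(ValueError):
    """A segment annotation is inconsistent (overlap, bad span, missing)."""


class StructureParseError(ValueError):
    """A structure file could not be parsed under the named standard."""


class NoEquivalentError(KeyError):
    """A position has no aligned equivalent in the other sequence."""


@dataclass(frozen=True, order=True)
class UniversalLabel:
    """A residue address portable across P-loop channels.

    Ordering is (domain, segment, index) so reports list residues in the
    canonical domain/segment walk.
    """

    domain: int
    segment: str
    index: int
    aa: str | None = field(default=None, compare=False)

    def __post_init__(self) -> None:
        if self.domain not in (1, 2, 3, 4):
            raise LabelError(f"domain must be 1-4, got {self.domain!r}")
        if self.segment not in SEGMENT_CODES:
            raise LabelError(
                f"segment must be one of {SEGMENT_CODES}, got {self.segment!r}"
            )
        if not isinstance(self.index, int) or self.index < 1:
            raise LabelError(f"index must be a positive integer, got {self.index!r}")
        if self.aa is not None and not re.fullmatch(r"[A-Z]", self.aa):
            raise LabelError(f"amino-acid code must be a single letter, got {self.aa!r}")

    def __str__(self) -> str:
        return format_label(self)

    def bare(self) -> "UniversalLabel":
        """The same address without the amino-acid letter."""
        return replace(self, aa=None)


@dataclass(frozen=True, order=True)
class NativePosition:
    """A residue number in a named reference sequence (e.g. housefly/X96668)."""

    reference: str
    resnum: int

    def __post_init__(self) -> None:
        if not self.reference:
            raise LabelError("reference name must be non-empty")
        if self.resnum < 1:
            raise LabelError(f"resnum must be >= 1, got {self.resnum}")


_LABEL_RE = re.compile(r"^(?P<aa>[A-Z])?(?P<dom>[1-4])(?P<seg>[a-z])(?P<idx>\d+)$")
_DUAL_RE = re.compile(
    r"^(?P<aa>[A-Z])(?P<native>\d+)/(?P<dom>[1-4])(?P<seg>[a-z])(?P<idx>\d+)$"
)


def parse_label(
    text: str, reference: str = "housefly/X96668"
) -> tuple[UniversalLabel, NativePosition | None]:
    """Parse ``"M918/2k11"``, ``"M2k11"`` or ``"2k11"``.

    Dual notation additionally yields the native position, numbered in
    `reference` (the housefly channel by default, as in the mutation
    literature).  Raises :class:`LabelError` on anything else.
    """
    text = text.strip()
    m = _DUAL_RE.match(text)
    if m:
        label = UniversalLabel(
            domain=int(m["dom"]), segment=m["seg"], index=int(m["idx"]), aa=m["aa"]
        )
        return label, NativePosition(reference, int(m["native"]))
    m = _LABEL_RE.match(text)
    if m:
        label = UniversalLabel(
            domain=int(m["dom"]), segment=m["seg"], index=int(m["idx"]), aa=m["aa"]
        )
        return label, None
    raise LabelError(f"unparseable residue label: {text!r}")


def format_label(label: UniversalLabel, native: NativePosition | None = None) -> str:
    """Inverse of :func:`parse_label`; round-trips exactly."""
    core = f"{label.domain}{label.segment}{label.index}"
    if native is not None:
        if label.aa is None:
            raise LabelError("dual notation needs the amino-acid letter")
        return f"{label.aa}{native.resnum}/{core}"
    return f"{label.aa or ''}{core}"


@dataclass(frozen=True)
class Span:
    """One contiguous native-numbering run of a (domain, segment).

    ``anchor`` is the native residue number that carries universal index 1.
    It may lie outside [first, last] when the scheme's origin precedes the
    modeled span.  A (domain, segment) may own several spans with different
    anchors: the universal scheme is alignment-based, so its indices can
    skip relative to any one native sequence (the packaged housefly table
    needs this for the domain-II P-loop and the domain-I S6).
    """

    domain: int
    segment: str
    first: int
    last: int
    anchor: int

    def __post_init__(self) -> None:
        if self.first > self.last:
            raise AnnotationError(f"span first > last: {self}")
        if self.domain not in (1, 2, 3, 4):
            raise AnnotationError(f"bad domain in span: {self}")

    def index_of(self, resnum: int) -> int:
        return resnum - self.anchor + 1


class SegmentAnnotation:
    """Segment spans for one channel's native numbering."""

    def __init__(self, spans: Iterable[Span], reference: str = "unknown"):
        self.spans: list[Span] = list(spans)
        self.reference = reference
        self._check_overlaps()

    def _check_overlaps(self) -> None:
        by_domain: dict[int, list[Span]] = {}
        for s in self.spans:
            by_domain.setdefault(s.domain, []).append(s)
        for dom, spans in by_domain.items():
            spans = sorted(spans, key=lambda s: s.first)
            for a, b in zip(spans, spans[1:]):
                if b.first <= a.last:
                    raise AnnotationError(
                        f"overlapping spans in domain {dom}: {a} / {b}"
                    )

    def locate(self, resnum: int) -> Span | None:
        for s in self.spans:
            if s.first <= resnum <= s.last:
                return s
        return None

    def spans_for(self, domain: int, segment: str) -> list[Span]:
        return [s for s in self.spans if s.domain == domain and s.segment == segment]

    @classmethod
    def from_tsv(cls, path: str | Path, reference: str = "unknown") -> "SegmentAnnotation":
        spans = []
        with open(path) as fh:
            header = fh.readline().rstrip("\n").split("\t")
            want = ["domain", "segment", "first", "last", "anchor"]
            if header[: len(want)] != want:
                raise AnnotationError(
                    f"{path}: expected columns {want}, got {header}"
                )
            for ln, line in enumerate(fh, start=2):
                if not line.strip() or line.startswith("#"):
                    continue
                parts = line.rstrip("\n").split("\t")
                try:
                    spans.append(
                        Span(
                            domain=int(parts[0]),
                            segment=parts[1],
                            first=int(parts[2]),
                            last=int(parts[3]),
                            anchor=int(parts[4]),
                        )
                    )
                except (IndexError, ValueError) as exc:
                    raise AnnotationError(f"{path}:{ln}: malformed row") from exc
        return cls(spans, reference=reference)

    def to_tsv(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            fh.write("domain\tsegment\tfirst\tlast\tanchor\n")
            for s in sorted(self.spans, key=lambda s: (s.domain, s.first)):
                fh.write(f"{s.domain}\t{s.segment}\t{s.first}\t{s.last}\t{s.anchor}\n")


_AA3TO1 = {
    "ALA": "A", "ARG": "R", "ASN": "N", "ASP": "D", "CYS": "C", "GLN": "Q",
    "GLU": "E", "GLY": "G", "HIS": "H", "ILE": "I", "LEU": "L", "LYS": "K",
    "MET": "M", "PHE": "F", "PRO": "P", "SER": "S", "THR": "T", "TRP": "W",
    "TYR": "Y", "VAL": "V",
}


@dataclass
class Residue:
    """One residue: name, native number, and (optional) segment assignment."""

    name: str
    resnum: int
    domain: int | None = None
    segment: str | None = None
    seg_index: int | None = None
    hetero: bool = False

    @property
    def one_letter(self) -> str | None:
        return _AA3TO1.get(self.name)

    @property
    def label(self) -> UniversalLabel | None:
        if self.domain is None or self.segment not in SEGMENT_CODES:
            return None
        return UniversalLabel(
            domain=self.domain,
            segment=self.segment,
            index=self.seg_index,
            aa=self.one_letter,
        )


class ChannelStructure:
    """An annotated 3D channel structure.

    Coordinates are a ``(n_atoms, 3)`` array in A.  Each atom links to
    exactly one residue through ``atom_res``.  The gating-state tag and the
    segment annotation travel with the object and survive file round-trips.
    """

    def __init__(
        self,
        coords: np.ndarray,
        atom_names: list[str],
        elements: list[str],
        atom_res: np.ndarray,
        residues: list[Residue],
        state: str = "unknown",
        annotation: SegmentAnnotation | None = None,
    ):
        self.coords = np.asarray(coords, dtype=float).reshape(-1, 3)
        self.atom_names = list(atom_names)
        self.elements = list(elements)
        self.atom_res = np.asarray(atom_res, dtype=int)
        self.residues = residues
        if state not in STATE_TAGS:
            raise ValueError(f"unknown state tag {state!r}")
        self.state = state
        self.annotation = annotation
        if not (
            len(self.atom_names) == len(self.elements) == len(self.coords)
            == len(self.atom_res)
        ):
            raise ValueError("atom array lengths disagree")
        if not np.all(np.isfinite(self.coords)):
            raise ValueError("non-finite coordinates")
        if annotation is not None:
            self.annotate(annotation)

    # -- basic queries -------------------------------------------------

    @property
    def n_atoms(self) -> int:
        return len(self.coords)

    def copy(self) -> "ChannelStructure":
        out = ChannelStructure.__new__(ChannelStructure)
        out.coords = self.coords.copy()
        out.atom_names = list(self.atom_names)
        out.elements = list(self.elements)
        out.atom_res = self.atom_res.copy()
        out.residues = [Residue(**vars(r)) for r in self.residues]
        out.state = self.state
        out.annotation = self.annotation
        return out

    def atoms_of_residue(self, res_index: int) -> np.ndarray:
        return np.nonzero(self.atom_res == res_index)[0]

    def atom_index(self, res_index: int, atom_name: str) -> int | None:
        for i in self.atoms_of_residue(res_index):
            if self.atom_names[i] == atom_name:
                return int(i)
        return None

    def residue_by_resnum(self, resnum: int) -> int | None:
        for i, r in enumerate(self.residues):
            if r.resnum == resnum:
                return i
        return None

    def residue_by_label(self, label: UniversalLabel) -> int | None:
        key = (label.domain, label.segment, label.index)
        for i, r in enumerate(self.residues):
            if (r.domain, r.segment, r.seg_index) == key:
                return i
        return None

    # -- annotation ----------------------------------------------------

    def annotate(self, annotation: SegmentAnnotation) -> None:
        """Tag residues with (domain, segment, in-segment index)."""
        self.annotation = annotation
        for r in self.residues:
            span = annotation.locate(r.resnum)
            if span is None:
                r.domain = r.segment = r.seg_index = None
            else:
                r.domain = span.domain
                r.segment = span.segment
                r.seg_index = span.index_of(r.resnum)

    def side_chain_atoms(self, res_index: int) -> np.ndarray:
        """Heavy side-chain atoms; Calpha stands in for glycine."""
        backbone = {"N", "CA", "C", "O", "OXT"}
        idx = [
            i
            for i in self.atoms_of_residue(res_index)
            if self.atom_names[i] not in backbone and self.elements[i] != "H"
        ]
        if not idx:
            ca = self.atom_index(res_index, "CA")
            idx = [] if ca is None else [ca]
        return np.asarray(idx, dtype=int)


def assign_labels(
    structure: ChannelStructure, annotation: SegmentAnnotation
) -> dict[NativePosition, UniversalLabel]:
    """Map every annotated residue's native position to its universal label.

    A residue at native number ``r`` inside a span gets index
    ``r - anchor + 1``; residues outside all spans are absent.  The map is
    injective per (domain, segment) because spans do not overlap.
    """
    structure.annotate(annotation)
    out: dict[NativePosition, UniversalLabel] = {}
    for r in structure.residues:
        lab = r.label
        if lab is not None:
            out[NativePosition(annotation.reference, r.resnum)] = lab
    return out


def translate_numbering(
    pos: NativePosition,
    alignment: tuple[tuple[str, str], tuple[str, str]],
    start_a: int = 1,
    start_b: int = 1,
) -> NativePosition:
    """Carry a residue number across a pairwise alignment.

    `alignment` is ``((name_a, gapped_a), (name_b, gapped_b))`` with equal
    gapped lengths; ``start_a``/``start_b`` number the first residue of each
    gapped sequence.  A position opposite a gap raises
    :class:`NoEquivalentError` rather than guessing a neighbour.
    """
    (name_a, seq_a), (name_b, seq_b) = alignment
    if len(seq_a) != len(seq_b):
        raise ValueError("gapped sequences differ in length")
    if pos.reference == name_a:
        src, dst, dst_name, src_start, dst_start = seq_a, seq_b, name_b, start_a, start_b
    elif pos.reference == name_b:
        src, dst, dst_name, src_start, dst_start = seq_b, seq_a, name_a, start_b, start_a
    else:
        raise ValueError(
            f"{pos.reference!r} is not one of the aligned sequences "
            f"({name_a!r}, {name_b!r})"
        )
    n_src = src_start - 1
    n_dst = dst_start - 1
    for col, (ca, cb) in enumerate(zip(src, dst)):
        if ca != "-":
            n_src += 1
        if cb != "-":
            n_dst += 1
        if ca != "-" and n_src == pos.resnum:
            if cb == "-":
                raise NoEquivalentError(
                    f"{pos.reference}:{pos.resnum} aligns to a gap in {dst_name}"
                )
            return NativePosition(dst_name, n_dst)
    raise NoEquivalentError(f"{pos.reference}:{pos.resnum} outside the alignment")


# -- structure file I/O ------------------------------------------------

_STATE_TOKEN = "CHANNEL_STATE"


def _structure_from_gemmi(st: gemmi.Structure, state: str) -> ChannelStructure:
    coords, names, elements, atom_res = [], [], [], []
    residues: list[Residue] = []
    if len(st) == 0:
        raise StructureParseError("no models in file")
    model = st[0]
    for chain in model:
        for res in chain:
            het = res.het_flag == "H"
            residues.append(
                Residue(name=res.name, resnum=res.seqid.num, hetero=het)
            )
            ri = len(residues) - 1
            for atom in res:
                coords.append([atom.pos.x, atom.pos.y, atom.pos.z])
                names.append(atom.name)
                elements.append(atom.element.name)
                atom_res.append(ri)
    if not coords:
        raise StructureParseError("file contains no atoms")
    return ChannelStructure(
        np.array(coords), names, elements, np.array(atom_res), residues, state=state
    )


def read_structure(path: str | Path, format: str | None = None) -> ChannelStructure:
    """Read a PDB or mmCIF file into a :class:`ChannelStructure`.

    The format is taken from the extension when not given.  Atom count,
    residue numbering and coordinates are preserved; residues carry no
    domain tags until :meth:`ChannelStructure.annotate` is applied.
    """
    path = Path(path)
    if format is None:
        format = "mmcif" if path.suffix.lower() in (".cif", ".mmcif") else "pdb"
    if format not in ("pdb", "mmcif"):
        raise ValueError(f"unknown structure format {format!r}")
    try:
        if format == "pdb":
            st = gemmi.read_pdb(str(path), split_chain_on_ter=False)
        else:
            st = gemmi.read_structure(str(path), format=gemmi.CoorFormat.Mmcif)
    except (RuntimeError, ValueError) as exc:
        raise StructureParseError(f"{path}: {exc}") from exc
    state = "unknown"
    if format == "pdb":
        for line in st.raw_remarks:
            if _STATE_TOKEN in line:
                state = line.split(_STATE_TOKEN, 1)[1].strip()
    else:
        title = st.info["_struct.title"] if "_struct.title" in st.info else ""
        if _STATE_TOKEN in title:
            state = title.split(_STATE_TOKEN, 1)[1].strip()
    if state not in STATE_TAGS:
        state = "unknown"
    return _structure_from_gemmi(st, state)


def _gemmi_from_structure(structure: ChannelStructure) -> gemmi.Structure:
    st = gemmi.Structure()
    st.name = "navpyr"
    model = gemmi.Model("1")
    chain = gemmi.Chain("A")
    for ri, res in enumerate(structure.residues):
        g = gemmi.Residue()
        g.name = res.name
        g.seqid = gemmi.SeqId(res.resnum, " ")
        g.het_flag = "H" if res.hetero else "A"
        for i in structure.atoms_of_residue(ri):
            a = gemmi.Atom()
            a.name = structure.atom_names[i]
            a.element = gemmi.Element(structure.elements[i])
            x, y, z = structure.coords[i]
            a.pos = gemmi.Position(x, y, z)
            a.occ = 1.0
            a.b_iso = 0.0
            g.add_atom(a)
        chain.add_residue(g)
    model.add_chain(chain)
    st.add_model(model)
    st.setup_entities()
    return st


def write_structure(
    structure: ChannelStructure, path: str | Path, format: str | None = None
) -> None:
    """Write PDB or mmCIF; the gating-state tag rides along in the header."""
    path = Path(path)
    if format is None:
        format = "mmcif" if path.suffix.lower() in (".cif", ".mmcif") else "pdb"
    st = _gemmi_from_structure(structure)
    if format == "pdb":
        st.raw_remarks = [f"REMARK 999 {_STATE_TOKEN} {structure.state}"]
        st.write_pdb(str(path))
    elif format == "mmcif":
        st.info["_struct.title"] = f"{_STATE_TOKEN} {structure.state}"
        st.make_mmcif_document().write_file(str(path))
    else:
        raise ValueError(f"unknown structure format {format!r}")
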