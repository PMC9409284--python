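"""The kdr resistance-mutation atlas.

A machine-readable transcription of the published catalogue of knockdown
resistance (kdr) mutations and engineered substitutions in insect sodium
channels, with each residue addressed both by its house-fly channel
number (GenBank X96668, the community reference numbering) and by its
universal P-loop-channel label.  Combination mutations (e.g. the classic
super-kdr pair M918T + L1014F) are stored as linked records so that
co-occurrence is expressible.

Site membership — whether a residue lines the PyR1 site (domain II/III
interface) or the PyR2 site (domain I/II interface) — is a per-label
lookup compiled from the catalogue's own location assignments, not a
per-segment rule: the IIS6 helix contributes its shallow residues
(2i12-2i16) to PyR2 and its deeper residues (2i18-2i26) to PyR1, so any
segment-level rule would misclassify.

Transcription conventions: species strings are verbatim (including
abbreviations); a component whose printed location is a cytoplasmic
linker or terminus is classed ``linker/other``; any other residue not in
the compiled PyR1/PyR2 membership is ``beyond``.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from importlib.resources import files
from pathlib import Path

import pandas as pd

from .channel_io import (
    ChannelStructure,
    NativePosition,
    SegmentAnnotation,
    UniversalLabel,
    parse_label,
)

__all__ = [
    "KdrMutation",
    "SiteMembership",
    "AtlasError",
    "load_atlas",
    "site_membership",
    "classify_site",
    "housefly_annotation",
    "mutation_report",
]

HOUSEFLY_REFERENCE = "housefly/X96668"

SITES = ("PyR1", "PyR2", "beyond", "linker/other")


class AtlasError(ValueError):
    """Malformed or inconsistent atlas data."""


@dataclass
class KdrMutation:
    """One mutation component, possibly linked to combination partners."""

    raw: str
    native: NativePosition
    label: UniversalLabel | None
    region: str | None
    wild_type: str
    substitutions: tuple[str, ...]
    species: str
    location: str
    site: str
    source: str  # table1..table4
    figures: str
    reference: str
    row: tuple[int, int] = (0, 0)  # (table, printed row)
    partners: list["KdrMutation"] = field(default_factory=list, repr=False)

    @property
    def is_kdr(self) -> bool:
        return self.source in ("table1", "table3")


def _atlas_path(name: str) -> Path:
    return Path(str(files("navpyr.data") / name))


def load_atlas(paths: list | None = None) -> list[KdrMutation]:
    """Load and cross-validate the packaged mutation tables.

    Every dual label is checked against :func:`parse_label` and against
    the packaged housefly segment annotation; combination rows become
    linked records.  Any malformed or inconsistent row aborts the load
    with its location.
    """
    if paths is None:
        paths = [_atlas_path(f"atlas_table{i}.tsv") for i in (1, 2, 3, 4)]
    annotation = housefly_annotation()
    records: list[KdrMutation] = []
    by_row: dict[tuple[int, int], list[KdrMutation]] = {}
    for path in paths:
        df = pd.read_csv(path, sep="\t", dtype=str).fillna("")
        if df.empty:
            raise AtlasError(f"{path}: atlas table is empty")
        for n, rec in enumerate(df.to_dict("records"), start=2):
            try:
                m = _parse_row(rec, annotation)
            except Exception as exc:
                raise AtlasError(f"{path}:{n}: {exc}") from exc
            records.append(m)
            by_row.setdefault(m.row, []).append(m)
    for group in by_row.values():
        for m in group:
            m.partners = [p for p in group if p is not m]
    return records


def _parse_row(rec: dict, annotation: SegmentAnnotation) -> KdrMutation:
    table = int(rec["table"])
    row = int(rec["row"])
    native = NativePosition(HOUSEFLY_REFERENCE, int(rec["native"]))
    label = None
    if rec["universal"]:
        label, _ = parse_label(rec["universal"])
        if rec["wt"]:
            label = UniversalLabel(
                domain=label.domain, segment=label.segment, index=label.index,
                aa=rec["wt"],
            )
        # dual-label consistency against parse_label on the raw token
        if "/" in rec["raw"]:
            core = rec["raw"].rstrip("/").rstrip()
            stem = core[: len(core) - len(rec["sub"])] if rec["sub"] else core
            parsed, parsed_native = parse_label(stem)
            if parsed.bare() != label.bare() or parsed_native.resnum != native.resnum:
                raise AtlasError(f"dual label {rec['raw']!r} inconsistent")
        # annotation consistency: the housefly anchors must reproduce it
        span = annotation.locate(native.resnum)
        if span is None:
            raise AtlasError(
                f"native {native.resnum} outside the packaged annotation"
            )
        got = (span.domain, span.segment, span.index_of(native.resnum))
        want = (label.domain, label.segment, label.index)
        if got != want:
            raise AtlasError(
                f"annotation maps {native.resnum} to {got}, table says {want}"
            )
    if rec["site"] not in SITES:
        raise AtlasError(f"unknown site class {rec['site']!r}")
    if not rec["wt"] or not rec["sub"]:
        raise AtlasError("missing wild-type or substitution")
    return KdrMutation(
        raw=rec["raw"],
        native=native,
        label=label,
        region=rec["region"] or None,
        wild_type=rec["wt"],
        substitutions=tuple(rec["sub"].split("/")),
        species=rec["species"],
        location=rec["location"],
        site=rec["site"],
        source=f"table{table}",
        figures=rec["figures"],
        reference=rec["ref"],
        row=(table, row),
    )


class SiteMembership:
    """Per-label PyR1/PyR2 membership compiled from the atlas."""

    def __init__(self, mapping: dict[UniversalLabel, str]):
        self.mapping = mapping

    def __contains__(self, label: UniversalLabel) -> bool:
        return label.bare() in self.mapping

    def __getitem__(self, label: UniversalLabel) -> str:
        return self.mapping[label.bare()]


def site_membership(atlas: list[KdrMutation] | None = None) -> SiteMembership:
    """Compile label -> site from the PyR1/PyR2 rows of tables 1 and 2.

    A label assigned to both sites anywhere in the catalogue is a
    load-time error — conflicts are surfaced, never resolved silently.
    """
    atlas = atlas if atlas is not None else load_atlas()
    mapping: dict[UniversalLabel, str] = {}
    for m in atlas:
        if m.source not in ("table1", "table2"):
            continue
        if m.label is None or m.site not in ("PyR1", "PyR2"):
            continue
        key = m.label.bare()
        if key in mapping and mapping[key] != m.site:
            raise AtlasError(
                f"label {key} assigned to both {mapping[key]} and {m.site}"
            )
        mapping[key] = m.site
    return SiteMembership(mapping)


def classify_site(
    label: UniversalLabel, membership: SiteMembership | None = None
) -> str:
    """PyR1 / PyR2 / beyond, by exact per-label lookup (total function)."""
    membership = membership or site_membership()
    if label in membership:
        return membership[label]
    return "beyond"


def housefly_annotation() -> SegmentAnnotation:
    """The packaged housefly (X96668) segment annotation.

    Anchors reproduce every dual label of the packaged tables; two
    segments carry split spans because the universal scheme's
    alignment-based indices skip relative to the housefly sequence
    (domain-I S6 around position 435, domain-II P-loop around 983).
    """
    return SegmentAnnotation.from_tsv(
        _atlas_path("housefly_annotation.tsv"), reference=HOUSEFLY_REFERENCE
    )


def mutation_report(
    structure: ChannelStructure,
    atlas: list[KdrMutation] | None = None,
    poses: list | None = None,
    cutoff: float = 4.0,
    environment_cutoff: float = 4.5,
) -> dict:
    """Structure-aware report over every atlas mutation.

    For each mutation resolvable in the (labeled) structure: its site
    class, whether any supplied ligand pose touches it (with the minimum
    distance), and — for mutations beyond the receptor sites — its
    intersegment environment.  Mutations whose residues are absent from
    the structure are listed separately rather than dropped.

    `poses` is a list of ``(pose_id, coords, elements)`` tuples.
    """
    from .interactions import ligand_contacts, residue_environment

    if all(r.label is None for r in structure.residues):
        raise AtlasError("structure carries no universal labels; annotate first")
    atlas = atlas if atlas is not None else load_atlas()
    membership = site_membership(atlas)

    contact_maps = []
    for pose_id, coords, elements in poses or []:
        recs = ligand_contacts(
            structure, coords, pose_elements=elements, cutoff=cutoff
        )
        contact_maps.append(
            (pose_id, {r.label.bare(): r for r in recs if r.label})
        )

    resolved, unresolved = [], []
    for m in atlas:
        if m.label is None or structure.residue_by_label(m.label.bare()) is None:
            unresolved.append(
                {"raw": m.raw, "species": m.species, "site": m.site,
                 "source": m.source}
            )
            continue
        entry = {
            "raw": m.raw,
            "label": str(m.label),
            "site": classify_site(m.label, membership),
            "species": m.species,
            "source": m.source,
        }
        if poses is not None:
            touches = {}
            for pose_id, cmap in contact_maps:
                rec = cmap.get(m.label.bare())
                touches[pose_id] = (
                    {"contact": True, "min_distance": round(rec.min_distance, 3)}
                    if rec
                    else {"contact": False}
                )
            entry["ligand_contacts"] = touches
        if entry["site"] == "beyond":
            entry["environment"] = residue_environment(
                structure, m.label.bare(), cutoff=environment_cutoff
            )
        resolved.append(entry)
    return {"mutations": resolved, "unresolved": unresolved}
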