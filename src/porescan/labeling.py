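"""Universal residue labels for P-loop channel pore domains.

A label is ``<repeat><segment><index>`` — repeat/subunit 1–4 (I–IV,
arranged clockwise viewed from the extracellular side), a segment letter
(``o`` outer helix, ``i`` inner helix, ``p`` P-loop), and the relative
position of the residue within the segment, e.g. ``2i19`` or ``3p48``.
The same label then denotes structurally homologous residues across
channels of very different sequence and author numbering.

Labels are assigned from a per-channel *segment map*: an explicit,
human-curated table saying which chain/residue range of the deposited
structure corresponds to which labelled segment.  The map author owns the
chain→repeat assignment and the index anchoring (e.g. anchoring the
selectivity-filter fingerprint); nothing is inferred from sequence.

Segment-map JSON schema (version 1)::

    {
      "schema_version": 1,
      "channel": "kcsa-1bl8",
      "entries": [
        {"repeat": 1, "segment": "p", "chain": "A",
         "first_resseq": 62, "first_index": 36, "length": 18},
        ...
      ]
    }

An entry covers ``length`` consecutive *polymer* residues of the chain
starting at author residue number ``first_resseq``; counting polymer
residues (rather than author numbers) makes ranges survive numbering gaps.
An entry may set ``"optional": true`` to tolerate disordered residues.
"""

from __future__ import annotations

import json
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable

from .structure_io import Atom, Residue, Structure

__all__ = [
    "ResidueLabel",
    "SegmentEntry",
    "SegmentMap",
    "LabeledStructure",
    "SegmentMapError",
    "LabelError",
    "parse_label",
    "load_segment_map",
    "assign_labels",
    "resolve",
]

SCHEMA_VERSION = 1
SEGMENTS = ("o", "i", "p")

_LABEL_RE = re.compile(r"^([1-4])([oip])(\d+)$")


class SegmentMapError(ValueError):
    """Segment-map config violates the schema or its invariants."""


class LabelError(KeyError):
    """A residue label cannot be parsed or resolved."""


@dataclass(frozen=True, order=True)
class ResidueLabel:
    repeat: int
    segment: str
    index: int

    def __post_init__(self) -> None:
        if self.repeat not in (1, 2, 3, 4):
            raise LabelError(f"repeat must be 1-4, got {self.repeat}")
        if self.segment not in SEGMENTS:
            raise LabelError(f"segment must be one of {SEGMENTS}, got {self.segment!r}")
        if self.index < 1:
            raise LabelError(f"index must be positive, got {self.index}")

    def __str__(self) -> str:
        return f"{self.repeat}{self.segment}{self.index}"


def parse_label(text: str) -> ResidueLabel:
    """Parse canonical label text like ``"2i19"``; inverse of ``str()``."""
    m = _LABEL_RE.match(text.strip())
    if not m:
        raise LabelError(f"cannot parse residue label {text!r}")
    return ResidueLabel(int(m.group(1)), m.group(2), int(m.group(3)))


@dataclass(frozen=True)
class SegmentEntry:
    repeat: int
    segment: str
    chain: str
    first_resseq: int
    first_index: int
    length: int
    optional: bool = False

    def labels(self) -> list[ResidueLabel]:
        return [
            ResidueLabel(self.repeat, self.segment, self.first_index + k)
            for k in range(self.length)
        ]


@dataclass
class SegmentMap:
    channel: str
    entries: list[SegmentEntry]

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        seen_labels: set[ResidueLabel] = set()
        for idx, e in enumerate(self.entries):
            if e.repeat not in (1, 2, 3, 4):
                raise SegmentMapError(f"entry {idx}: repeat {e.repeat} outside 1-4")
            if e.segment not in SEGMENTS:
                raise SegmentMapError(f"entry {idx}: unknown segment {e.segment!r}")
            if e.length < 1 or e.first_index < 1:
                raise SegmentMapError(f"entry {idx}: non-positive length or index")
            for lab in e.labels():
                if lab in seen_labels:
                    raise SegmentMapError(f"entry {idx}: duplicate label {lab}")
                seen_labels.add(lab)
        # no two entries may overlap in (chain, residue-number range); ranges
        # count polymer residues, so this is a necessary (author-number) check
        spans = [
            (e.chain, e.first_resseq, e.first_resseq + e.length - 1, i)
            for i, e in enumerate(self.entries)
        ]
        for i, (c1, a1, b1, e1) in enumerate(spans):
            for c2, a2, b2, e2 in spans[i + 1 :]:
                if c1 == c2 and a1 <= b2 and a2 <= b1:
                    raise SegmentMapError(
                        f"entries {e1} and {e2} overlap on chain {c1} "
                        f"({a1}-{b1} vs {a2}-{b2})"
                    )

    @property
    def repeat_of_chain(self) -> dict[str, set[int]]:
        out: dict[str, set[int]] = {}
        for e in self.entries:
            out.setdefault(e.chain, set()).add(e.repeat)
        return out

    def to_json(self) -> dict:
        return {
            "schema_version": SCHEMA_VERSION,
            "channel": self.channel,
            "entries": [
                {
                    "repeat": e.repeat,
                    "segment": e.segment,
                    "chain": e.chain,
                    "first_resseq": e.first_resseq,
                    "first_index": e.first_index,
                    "length": e.length,
                    **({"optional": True} if e.optional else {}),
                }
                for e in self.entries
            ],
        }

    def save(self, path: str | Path) -> Path:
        path = Path(path)
        path.write_text(json.dumps(self.to_json(), indent=1) + "\n")
        return path


def load_segment_map(path: str | Path) -> SegmentMap:
    """Load and validate a segment-map JSON file."""
    path = Path(path)
    try:
        doc = json.loads(path.read_text())
    except json.JSONDecodeError as exc:
        raise SegmentMapError(f"{path}: invalid JSON: {exc}") from exc
    return segment_map_from_dict(doc, source=str(path))


def segment_map_from_dict(doc: dict, source: str = "<dict>") -> SegmentMap:
    if doc.get("schema_version") != SCHEMA_VERSION:
        raise SegmentMapError(
            f"{source}: schema_version must be {SCHEMA_VERSION}, "
            f"got {doc.get('schema_version')!r}"
        )
    try:
        entries = [
            SegmentEntry(
                repeat=int(e["repeat"]),
                segment=str(e["segment"]),
                chain=str(e["chain"]),
                first_resseq=int(e["first_resseq"]),
                first_index=int(e["first_index"]),
                length=int(e["length"]),
                optional=bool(e.get("optional", False)),
            )
            for e in doc["entries"]
        ]
    except (KeyError, TypeError, ValueError) as exc:
        raise SegmentMapError(f"{source}: malformed entry: {exc}") from exc
    return SegmentMap(channel=str(doc.get("channel", "")), entries=entries)


@dataclass
class LabeledStructure:
    """A structure plus the (partial) bijection residues <-> labels.

    ``oriented`` marks that the coordinates are expressed in the template
    frame (pore axis = z, +z extracellular); it is set by the superposition
    stage and required by axis-dependent measurements.
    """

    structure: Structure
    label_of: dict[tuple[str, int, str], ResidueLabel] = field(default_factory=dict)
    residue_of: dict[ResidueLabel, Residue] = field(default_factory=dict)
    oriented: bool = False
    report: dict = field(default_factory=dict)

    def labels(self, repeat: int | None = None, segment: str | None = None) -> list[ResidueLabel]:
        out = [
            lab
            for lab in self.residue_of
            if (repeat is None or lab.repeat == repeat)
            and (segment is None or lab.segment == segment)
        ]
        return sorted(out)

    def has_label(self, label: ResidueLabel | str) -> bool:
        if isinstance(label, str):
            label = parse_label(label)
        return label in self.residue_of

    def copy(self) -> "LabeledStructure":
        s = self.structure.copy()
        label_of = dict(self.label_of)
        residue_of = {lab: s.get_residue(*res.key) for lab, res in self.residue_of.items()}
        return LabeledStructure(s, label_of, residue_of, self.oriented, dict(self.report))


def assign_labels(s: Structure, m: SegmentMap) -> LabeledStructure:
    """Attach universal labels to structure residues according to a map.

    Each mapped residue carries exactly one label.  A mapped residue absent
    from the structure raises unless the entry is marked optional; the
    report records mapped/unmapped counts.
    """
    ls = LabeledStructure(structure=s)
    missing: list[str] = []
    for e in m.entries:
        chain_res = s.chain_residues(e.chain, polymer_only=True)
        start_idx = None
        for i, r in enumerate(chain_res):
            if r.seqid == e.first_resseq and r.icode == "":
                start_idx = i
                break
        if start_idx is None:
            if e.optional:
                missing.extend(str(lab) for lab in e.labels())
                continue
            raise LabelError(
                f"segment {e.repeat}{e.segment}{e.first_index}.. : first residue "
                f"{e.chain}/{e.first_resseq} absent from structure"
            )
        for k in range(e.length):
            lab = ResidueLabel(e.repeat, e.segment, e.first_index + k)
            if start_idx + k >= len(chain_res):
                if e.optional:
                    missing.append(str(lab))
                    continue
                raise LabelError(f"mapped residue for label {lab} absent from structure")
            res = chain_res[start_idx + k]
            if res.key in ls.label_of:
                raise SegmentMapError(
                    f"residue {res.key} mapped twice ({ls.label_of[res.key]} and {lab})"
                )
            ls.label_of[res.key] = lab
            ls.residue_of[lab] = res
    n_polymer = sum(1 for r in s.residues if r.is_polymer)
    ls.report = {
        "mapped": len(ls.residue_of),
        "unmapped_polymer": n_polymer - len(ls.residue_of),
        "missing_optional": missing,
    }
    return ls


def resolve(
    ls: LabeledStructure, label: ResidueLabel | str, atom: str | None = None
) -> Residue | Atom:
    """Resolve a label to its residue, or a named atom within it."""
    if isinstance(label, str):
        label = parse_label(label)
    try:
        res = ls.residue_of[label]
    except KeyError:
        raise LabelError(f"label {label} is not assigned in this structure") from None
    if atom is None:
        return res
    return res.atom(atom)


def labels_in_range(
    segment: str, start: int, stop: int, repeats: Iterable[int] = (1, 2, 3, 4)
) -> list[ResidueLabel]:
    """All labels ``<r><segment><k>`` for k in [start, stop] and r in repeats."""
    return [
        ResidueLabel(r, segment, k) for r in repeats for k in range(start, stop + 1)
    ]
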