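"""Reading, segmenting, and chronologically grouping clinical notes.

Notes live in a JSON-lines corpus (one note per line, UTF-8) with the
fields of :class:`ClinicalNote`.  Sentence-level gold annotations live in
a standoff TSV addressed by 0-based half-open character offsets into the
note text.  All offsets in this package follow that one convention.
"""

from __future__ import annotations

import json
import re
from dataclasses import dataclass, field
from datetime import datetime
from pathlib import Path
from typing import Iterable, Sequence

__all__ = [
    "ClinicalNote",
    "Sentence",
    "NoteGroup",
    "AnnotationSet",
    "SegmentationRules",
    "CorpusError",
    "read_notes",
    "write_notes",
    "segment_note",
    "group_longitudinal",
    "read_annotations",
    "write_annotations",
]

SETTINGS = ("inpatient", "outpatient")
SENTENCE_KINDS = ("body", "header", "footer", "signature")
ANNOTATION_LABELS = ("new", "redundant")


class CorpusError(ValueError):
    """Raised for malformed corpus or annotation records."""


@dataclass(frozen=True)
class ClinicalNote:
    """One timestamped clinical note with authorship metadata.

    ``encounter_id`` may be empty for outpatient notes; an inpatient note
    without an encounter id is rejected at grouping time because its
    admission would be ambiguous.
    """

    note_id: str
    patient_id: str
    encounter_id: str
    timestamp: datetime
    setting: str
    specialty: str
    text: str

    def __post_init__(self) -> None:
        if self.setting not in SETTINGS:
            raise CorpusError(
                f"note {self.note_id!r}: setting {self.setting!r} "
                f"not in {SETTINGS}"
            )


@dataclass(frozen=True)
class Sentence:
    """A sentence (or header/footer/signature line) within a note.

    ``span`` is a 0-based half-open character range into the note text;
    ``text`` always equals the note substring at that span.
    """

    note_id: str
    index: int
    span: tuple[int, int]
    text: str
    kind: str = "body"

    def __post_init__(self) -> None:
        if self.kind not in SENTENCE_KINDS:
            raise CorpusError(f"invalid sentence kind {self.kind!r}")
        if self.span[0] >= self.span[1]:
            raise CorpusError(f"empty or inverted span {self.span}")


@dataclass
class NoteGroup:
    """A chronologically ordered run of notes scored as one sequence.

    Inpatient notes are grouped per (patient, encounter); outpatient notes
    are pooled per patient across encounters.
    """

    group_id: str
    notes: list[ClinicalNote]
    grouping: str  # "inpatient_encounter" | "outpatient_patient"


@dataclass
class AnnotationSet:
    """One rater's sentence-level new/redundant labels (standoff spans)."""

    rater_id: str
    labels: dict[tuple[str, tuple[int, int]], str] = field(default_factory=dict)

    def add(self, note_id: str, span: tuple[int, int], label: str) -> None:
        if label not in ANNOTATION_LABELS:
            raise CorpusError(
                f"rater {self.rater_id!r}: label {label!r} not in "
                f"{ANNOTATION_LABELS}"
            )
        if span[0] >= span[1]:
            raise CorpusError(
                f"rater {self.rater_id!r}: invalid span {span} in note "
                f"{note_id!r}"
            )
        key = (note_id, span)
        if key in self.labels and self.labels[key] != label:
            raise CorpusError(
                f"rater {self.rater_id!r}: conflicting labels for note "
                f"{note_id!r} span {span}"
            )
        self.labels[key] = label


_REQUIRED_FIELDS = (
    "note_id",
    "patient_id",
    "encounter_id",
    "timestamp",
    "setting",
    "specialty",
    "text",
)


def read_notes(path: str | Path) -> list[ClinicalNote]:
    """Read a JSON-lines corpus, preserving file order.

    Raises :class:`CorpusError` naming the offending note and field for
    records that are incomplete or carry an unparseable timestamp, and
    for duplicated note ids.
    """
    notes: list[ClinicalNote] = []
    seen: set[str] = set()
    with open(path, encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line:
                continue
            try:
                record = json.loads(line)
            except json.JSONDecodeError as exc:
                raise CorpusError(f"line {lineno}: invalid JSON: {exc}") from exc
            note_id = record.get("note_id", f"<line {lineno}>")
            for fld in _REQUIRED_FIELDS:
                if fld not in record:
                    raise CorpusError(
                        f"note {note_id!r}: missing field {fld!r}"
                    )
            try:
                ts = datetime.fromisoformat(record["timestamp"])
            except (TypeError, ValueError) as exc:
                raise CorpusError(
                    f"note {note_id!r}: unparseable timestamp "
                    f"{record['timestamp']!r}"
                ) from exc
            if record["note_id"] in seen:
                raise CorpusError(f"duplicate note_id {record['note_id']!r}")
            seen.add(record["note_id"])
            notes.append(
                ClinicalNote(
                    note_id=record["note_id"],
                    patient_id=record["patient_id"],
                    encounter_id=record["encounter_id"],
                    timestamp=ts,
                    setting=record["setting"],
                    specialty=record["specialty"],
                    text=record["text"],
                )
            )
    return notes


def write_notes(notes: Iterable[ClinicalNote], path: str | Path) -> None:
    """Write notes as JSON lines; inverse of :func:`read_notes`."""
    with open(path, "w", encoding="utf-8") as fh:
        for note in notes:
            fh.write(
                json.dumps(
                    {
                        "note_id": note.note_id,
                        "patient_id": note.patient_id,
                        "encounter_id": note.encounter_id,
                        "timestamp": note.timestamp.isoformat(),
                        "setting": note.setting,
                        "specialty": note.specialty,
                        "text": note.text,
                    },
                    ensure_ascii=False,
                )
                + "\n"
            )


# ---------------------------------------------------------------------------
# Sentence segmentation
# ---------------------------------------------------------------------------

DEFAULT_ABBREVIATIONS = ("Dr.", "pt.", "mg.", "q.d.")


@dataclass
class SegmentationRules:
    """Configurable segmentation rules.

    Lines are the primary unit.  Within a line, a sentence break occurs
    after ". ", "! " or "? " unless the period closes a known
    abbreviation.  A line of the form ``ALL CAPS:`` is a header; trailing
    lines matching a signature pattern (an e-signature phrase, or a name
    followed by a credential such as MD/DO/NP/PA) are signatures; lines
    matching ``footer_pattern`` are footers.
    """

    abbreviations: tuple[str, ...] = DEFAULT_ABBREVIATIONS
    header_pattern: str = r"^[A-Z][A-Z /]+:$"
    signature_patterns: tuple[str, ...] = (
        r"^Electronically signed by\b.*$",
        r"^[A-Z][A-Za-z .'-]*,?\s+(MD|DO|NP|PA)\.?$",
    )
    footer_pattern: str = r"^(?:-{3,}|=+|END OF NOTE|Page \d+ of \d+)$"


_BREAK_RE = re.compile(r"[.!?] ")


def _split_line(line: str, abbreviations: Sequence[str]) -> list[tuple[int, int]]:
    """Offsets of sentences within one line (relative to line start)."""
    spans: list[tuple[int, int]] = []
    start = 0
    for m in _BREAK_RE.finditer(line):
        end = m.start() + 1  # include the terminal punctuation
        head = line[start:end]
        if any(head.endswith(abbr) for abbr in abbreviations):
            continue
        spans.append((start, end))
        start = m.end()
    if start < len(line):
        spans.append((start, len(line)))
    return spans


def _strip_span(text: str, start: int, end: int) -> tuple[int, int] | None:
    while start < end and text[start].isspace():
        start += 1
    while end > start and text[end - 1].isspace():
        end -= 1
    if start >= end:
        return None
    return (start, end)


def segment_note(
    note: ClinicalNote, rules: SegmentationRules | None = None
) -> list[Sentence]:
    """Split a note into ordered, non-overlapping sentences.

    Sentences jointly cover all non-whitespace characters of the note;
    the segmentation is deterministic for a fixed rule set.  Empty text
    yields an empty list.
    """
    rules = rules or SegmentationRules()
    header_re = re.compile(rules.header_pattern)
    signature_res = [re.compile(p) for p in rules.signature_patterns]
    footer_re = re.compile(rules.footer_pattern)

    text = note.text
    sentences: list[Sentence] = []
    pos = 0
    for raw_line in text.split("\n"):
        line_start = pos
        pos += len(raw_line) + 1  # +1 for the newline (or EOF, harmless)
        stripped = raw_line.strip()
        if not stripped:
            continue
        if header_re.match(stripped):
            kind = "header"
        elif any(p.match(stripped) for p in signature_res):
            kind = "signature"
        elif footer_re.match(stripped):
            kind = "footer"
        else:
            kind = "body"
        if kind != "body":
            span = _strip_span(text, line_start, line_start + len(raw_line))
            if span is not None:
                sentences.append(
                    Sentence(
                        note_id=note.note_id,
                        index=len(sentences),
                        span=span,
                        text=text[span[0] : span[1]],
                        kind=kind,
                    )
                )
            continue
        for rel_start, rel_end in _split_line(raw_line, rules.abbreviations):
            span = _strip_span(text, line_start + rel_start, line_start + rel_end)
            if span is None:
                continue
            sentences.append(
                Sentence(
                    note_id=note.note_id,
                    index=len(sentences),
                    span=span,
                    text=text[span[0] : span[1]],
                    kind="body",
                )
            )
    return sentences


# ---------------------------------------------------------------------------
# Longitudinal grouping
# ---------------------------------------------------------------------------


def group_longitudinal(notes: Iterable[ClinicalNote]) -> list[NoteGroup]:
    """Partition notes into scoring groups, sorted by timestamp.

    Inpatient notes group per (patient_id, encounter_id); outpatient
    notes group per patient across encounters.  Ties on timestamp are
    broken by note_id for determinism.  An inpatient note with an empty
    encounter_id is an error.
    """
    buckets: dict[tuple[str, str, str], list[ClinicalNote]] = {}
    for note in notes:
        if note.setting == "inpatient":
            if not note.encounter_id:
                raise CorpusError(
                    f"inpatient note {note.note_id!r} has no encounter_id"
                )
            key = ("inpatient_encounter", note.patient_id, note.encounter_id)
        else:
            key = ("outpatient_patient", note.patient_id, "")
        buckets.setdefault(key, []).append(note)

    groups: list[NoteGroup] = []
    for (grouping, pid, eid), members in sorted(buckets.items()):
        members.sort(key=lambda n: (n.timestamp, n.note_id))
        group_id = f"{pid}:{eid}" if eid else pid
        groups.append(NoteGroup(group_id=group_id, notes=members, grouping=grouping))
    return groups


# ---------------------------------------------------------------------------
# Standoff annotations
# ---------------------------------------------------------------------------

_ANNOTATION_COLUMNS = ["rater_id", "note_id", "start", "end", "label"]


def read_annotations(path: str | Path) -> list[AnnotationSet]:
    """Read a standoff TSV (rater_id, note_id, start, end, label).

    Returns one :class:`AnnotationSet` per rater, in order of first
    appearance.  Bad labels, inverted spans, and conflicting duplicate
    rows raise :class:`CorpusError` naming the row.
    """
    raters: dict[str, AnnotationSet] = {}
    with open(path, encoding="utf-8") as fh:
        header = fh.readline().rstrip("\n").split("\t")
        if header != _ANNOTATION_COLUMNS:
            raise CorpusError(
                f"annotation header {header!r} != {_ANNOTATION_COLUMNS!r}"
            )
        for lineno, line in enumerate(fh, start=2):
            line = line.rstrip("\n")
            if not line:
                continue
            parts = line.split("\t")
            if len(parts) != 5:
                raise CorpusError(f"row {lineno}: expected 5 columns")
            rater_id, note_id, start_s, end_s, label = parts
            try:
                start, end = int(start_s), int(end_s)
            except ValueError as exc:
                raise CorpusError(f"row {lineno}: non-integer span") from exc
            if start >= end:
                raise CorpusError(f"row {lineno}: start {start} >= end {end}")
            if label not in ANNOTATION_LABELS:
                raise CorpusError(f"row {lineno}: bad label {label!r}")
            aset = raters.setdefault(rater_id, AnnotationSet(rater_id=rater_id))
            try:
                aset.add(note_id, (start, end), label)
            except CorpusError as exc:
                raise CorpusError(f"row {lineno}: {exc}") from exc
    return list(raters.values())


def write_annotations(sets: Iterable[AnnotationSet], path: str | Path) -> None:
    """Write annotation sets to the standoff TSV format."""
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("\t".join(_ANNOTATION_COLUMNS) + "\n")
        for aset in sets:
            for (note_id, (start, end)), label in sorted(aset.labels.items()):
                fh.write(
                    f"{aset.rater_id}\t{note_id}\t{start}\t{end}\t{label}\n"
                )
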