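"""Per-note redundancy and aggregation by specialty group and setting.

The redundancy of a note is the fraction of its scored sentences that
carry no new information.  Notes are attributed to a subject-matter
domain (SMD) group — the specialty axis of the HL7/LOINC document
ontology — through a case-insensitive specialty-string map, and
summarized as mean and sample standard deviation per (group, setting)
cell with marginals, mirroring the usual specialty-by-setting table.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd

from .corpus import ClinicalNote
from .novelty import SentenceVerdict

__all__ = [
    "RedundancyRecord",
    "SMDMap",
    "note_redundancy",
    "classify_smd",
    "aggregate_redundancy",
    "records_from_verdicts",
]

UNMAPPED = "Unmapped"

#: Specialty-string -> SMD group defaults covering the common specialty
#: names; lookups are case-insensitive on trimmed input and fully
#: overridable by a user-supplied TSV.
DEFAULT_SMD_ENTRIES: dict[str, str] = {
    "general medicine": "General Internal Medicine",
    "internal medicine": "General Internal Medicine",
    "hospital medicine": "General Internal Medicine",
    "family medicine": "General Internal Medicine",
    "gastroenterology": "Specialty Internal Medicine",
    "nephrology": "Specialty Internal Medicine",
    "cardiology": "Specialty Internal Medicine",
    "endocrinology": "Specialty Internal Medicine",
    "hematology": "Specialty Internal Medicine",
    "oncology": "Specialty Internal Medicine",
    "infectious disease": "Specialty Internal Medicine",
    "pulmonology": "Specialty Internal Medicine",
    "rheumatology": "Specialty Internal Medicine",
    "surgery": "Surgery",
    "general surgery": "Surgery",
    "transplant surgery": "Surgery",
    "orthopedic surgery": "Surgery",
    "neurosurgery": "Surgery",
    "urology": "Surgery",
    "pediatrics": "Pediatrics",
    "pediatric medicine": "Pediatrics",
    "psychiatry": "Psychiatry",
    "psychology": "Psychiatry",
    "radiology": "Radiology",
    "pathology": "Radiology",
    "blood banking and transfusion": "Radiology",
    "emergency medicine": "Emergency Medicine",
    "critical care medicine": "Critical Care Medicine",
    "pharmacy": "Non-physician",
    "occupational therapy": "Non-physician",
    "physical therapy": "Non-physician",
    "social work": "Non-physician",
    "nutrition": "Non-physician",
}

#: Groups pooled into the "Internal Medicine Overall" marginal row.
INTERNAL_MEDICINE_GROUPS = (
    "General Internal Medicine",
    "Specialty Internal Medicine",
)


@dataclass(frozen=True)
class RedundancyRecord:
    note_id: str
    redundancy: float
    n_sentences: int
    smd_group: str
    setting: str

    def __post_init__(self) -> None:
        if not 0.0 <= self.redundancy <= 1.0:
            raise ValueError("redundancy must lie in [0, 1]")
        if self.n_sentences <= 0:
            raise ValueError("n_sentences must be positive")


class SMDMap:
    """Case-insensitive specialty string -> SMD group label."""

    def __init__(self, entries: Mapping[str, str] | None = None):
        source = DEFAULT_SMD_ENTRIES if entries is None else entries
        self.entries = {k.strip().lower(): v for k, v in source.items()}

    def __getitem__(self, specialty: str) -> str:
        return self.entries.get(specialty.strip().lower(), UNMAPPED)

    @classmethod
    def from_tsv(cls, path: str | Path) -> "SMDMap":
        entries: dict[str, str] = {}
        with open(path, encoding="utf-8") as fh:
            for line in fh:
                line = line.rstrip("\n")
                if not line or line.startswith("#"):
                    continue
                specialty, group = line.split("\t")
                entries[specialty] = group
        return cls(entries)


def classify_smd(specialty: str, smd_map: SMDMap | None = None) -> str:
    """Map a raw specialty string to its SMD group (``Unmapped`` if absent)."""
    return (smd_map or SMDMap())[specialty]


def note_redundancy(
    verdicts: Sequence[SentenceVerdict], body_only: bool = False
) -> float:
    """Fraction of scored sentences without new information.

    Counts every scored sentence regardless of relevance; with
    ``body_only`` headers, footers and signature lines are excluded
    from both numerator and denominator.
    """
    if body_only:
        verdicts = [v for v in verdicts if v.sentence.kind == "body"]
    if not verdicts:
        raise ValueError(
            "no scored sentences: first note of a group, or empty note"
        )
    return sum(1 for v in verdicts if not v.new) / len(verdicts)


def records_from_verdicts(
    notes: Iterable[ClinicalNote],
    verdicts: Mapping[str, Sequence[SentenceVerdict]],
    smd_map: SMDMap | None = None,
    body_only: bool = False,
) -> list[RedundancyRecord]:
    """Roll per-sentence verdicts up to per-note redundancy records.

    Notes without verdicts (each group's first note) are skipped.
    """
    smd_map = smd_map or SMDMap()
    records = []
    for note in notes:
        note_verdicts = verdicts.get(note.note_id, [])
        if body_only:
            note_verdicts = [v for v in note_verdicts if v.sentence.kind == "body"]
        if not note_verdicts:
            continue
        records.append(
            RedundancyRecord(
                note_id=note.note_id,
                redundancy=note_redundancy(note_verdicts),
                n_sentences=len(note_verdicts),
                smd_group=smd_map[note.specialty],
                setting=note.setting,
            )
        )
    return records


def _cell_stats(values: pd.Series) -> tuple[int, float, float]:
    n = len(values)
    mean = float(values.mean())
    sd = float(values.std(ddof=1)) if n > 1 else 0.0
    return n, mean, sd


def aggregate_redundancy(
    records: Sequence[RedundancyRecord],
    include_im_overall: bool = True,
) -> pd.DataFrame:
    """Mean/SD redundancy per (SMD group, setting) with marginals.

    Returns a tidy frame with columns group, setting, n,
    mean_redundancy, sd_redundancy.  Settings are ``inpatient``,
    ``outpatient`` and the ``overall`` marginal; per-group rows appear
    only for cells with records (absent cells are simply absent).  An
    ``Overall`` group row pools every record, and with
    ``include_im_overall`` an ``Internal Medicine Overall`` row pools
    the general and specialty internal-medicine groups.
    """
    frame = pd.DataFrame(
        {
            "group": [r.smd_group for r in records],
            "setting": [r.setting for r in records],
            "redundancy": [r.redundancy for r in records],
        }
    )
    rows: list[dict] = []

    def emit(group_label: str, sub: pd.DataFrame) -> None:
        if sub.empty:
            return
        for setting in ("inpatient", "outpatient"):
            cell = sub[sub["setting"] == setting]["redundancy"]
            if len(cell) == 0:
                continue
            n, mean, sd = _cell_stats(cell)
            rows.append(
                {
                    "group": group_label,
                    "setting": setting,
                    "n": n,
                    "mean_redundancy": mean,
                    "sd_redundancy": sd,
                }
            )
        n, mean, sd = _cell_stats(sub["redundancy"])
        rows.append(
            {
                "group": group_label,
                "setting": "overall",
                "n": n,
                "mean_redundancy": mean,
                "sd_redundancy": sd,
            }
        )

    emit("Overall", frame)
    if include_im_overall:
        emit(
            "Internal Medicine Overall",
            frame[frame["group"].isin(INTERNAL_MEDICINE_GROUPS)],
        )
    for group in sorted(frame["group"].unique()):
        emit(group, frame[frame["group"] == group])
    return pd.DataFrame(
        rows, columns=["group", "setting", "n", "mean_redundancy", "sd_redundancy"]
    )
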