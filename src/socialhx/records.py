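"""Core record types and their plain-text serializations (JSONL / CSV)."""

from __future__ import annotations

import dataclasses
import datetime
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd

from socialhx.labels import CONDITIONS, LivingLabel, MaritalLabel


@dataclass
class NoteRecord:
    """One social-history snippet with its structured field and optional gold labels."""

    note_id: str
    patient_id: str
    admission_id: str
    text: str
    structured_status: str = ""
    gold_status: MaritalLabel | None = None
    gold_living: LivingLabel | None = None

    def to_json(self) -> str:
        d = dataclasses.asdict(self)
        d["gold_status"] = self.gold_status.value if self.gold_status else None
        d["gold_living"] = self.gold_living.value if self.gold_living else None
        return json.dumps(d, sort_keys=True)

    @classmethod
    def from_json(cls, line: str) -> "NoteRecord":
        d = json.loads(line)
        return cls(
            note_id=d["note_id"],
            patient_id=d["patient_id"],
            admission_id=d["admission_id"],
            text=d["text"],
            structured_status=d.get("structured_status", ""),
            gold_status=MaritalLabel(d["gold_status"]) if d.get("gold_status") else None,
            gold_living=LivingLabel(d["gold_living"]) if d.get("gold_living") else None,
        )


def write_corpus(records: Iterable[NoteRecord], path: str | Path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        for rec in records:
            fh.write(rec.to_json() + "\n")


def read_corpus(path: str | Path) -> list[NoteRecord]:
    with open(path, encoding="utf-8") as fh:
        return [NoteRecord.from_json(line) for line in fh if line.strip()]


@dataclass
class Admission:
    """One admission: calendar date, marital status at admission, condition flags."""

    date: datetime.date
    status: MaritalLabel
    flags: dict[str, bool] = field(default_factory=dict)


@dataclass
class PatientTimeline:
    """Ordered admissions for one patient.

    Invariant: admission dates strictly increase. ``evw_score`` is the
    Elixhauser–van Walraven comorbidity burden, a nonnegative integer.
    """

    patient_id: str
    age_at_first: float
    admissions: list[Admission]
    evw_score: int = 0

    def __post_init__(self) -> None:
        dates = [a.date for a in self.admissions]
        if any(b <= a for a, b in zip(dates, dates[1:])):
            raise ValueError(f"admissions of {self.patient_id} not strictly increasing")

    @property
    def statuses(self) -> list[MaritalLabel]:
        return [a.status for a in self.admissions]

    def span_days(self) -> int:
        return (self.admissions[-1].date - self.admissions[0].date).days


def write_cohort(timelines: Sequence[PatientTimeline], path: str | Path) -> None:
    """Write a cohort as a flat CSV, one row per admission."""
    rows = []
    for tl in timelines:
        for i, adm in enumerate(tl.admissions):
            row = {
                "patient_id": tl.patient_id,
                "admission_index": i,
                "date": adm.date.isoformat(),
                "status": adm.status.value,
                "age_at_first": tl.age_at_first,
                "evw_score": tl.evw_score,
            }
            for cond in CONDITIONS:
                row[cond] = int(adm.flags.get(cond, False))
            rows.append(row)
    cols = ["patient_id", "admission_index", "date", "status", *CONDITIONS,
            "age_at_first", "evw_score"]
    pd.DataFrame(rows, columns=cols).to_csv(path, index=False)


def read_cohort(path: str | Path) -> list[PatientTimeline]:
    df = pd.read_csv(path, dtype={"patient_id": str})
    timelines = []
    for pid, grp in df.groupby("patient_id", sort=True):
        grp = grp.sort_values("admission_index")
        admissions = [
            Admission(
                date=datetime.date.fromisoformat(r["date"]),
                status=MaritalLabel(r["status"]),
                flags={c: bool(r[c]) for c in CONDITIONS},
            )
            for _, r in grp.iterrows()
        ]
        timelines.append(
            PatientTimeline(
                patient_id=str(pid),
                age_at_first=float(grp["age_at_first"].iloc[0]),
                admissions=admissions,
                evw_score=int(grp["evw_score"].iloc[0]),
            )
        )
    return timelines
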