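"""Delimited-file readers/writers for the entity files.

Formats (CSV, ISO-8601 dates, header row required):

* events:     patient_id,date,code,code_type,lab_value
* exams:      exam_id,patient_id,exam_date,center
* enrollment: patient_id,start_date,end_date
* abstraction: wide one-row-per-exam format written by the generator
  (``source_present.<source>`` and ``<source>.<finding>`` 0/1 columns).
"""

from __future__ import annotations

import datetime
from pathlib import Path

import pandas as pd

from .types import CodedEvent, CodeType, ColonoscopyExam, EnrollmentSpan


def _read(path: str | Path, required: list[str]) -> pd.DataFrame:
    df = pd.read_csv(path, keep_default_na=False, dtype=str)
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing required columns {missing}")
    return df


def read_events(path: str | Path) -> list[CodedEvent]:
    df = _read(path, ["patient_id", "date", "code", "code_type"])
    events = []
    for r in df.itertuples():
        lab = getattr(r, "lab_value", "")
        events.append(
            CodedEvent(
                patient_id=r.patient_id,
                date=datetime.date.fromisoformat(r.date),
                code=r.code,
                code_type=CodeType(r.code_type),
                lab_value=lab if lab != "" else None,
            )
        )
    return events


def read_exams(path: str | Path) -> list[ColonoscopyExam]:
    df = _read(path, ["exam_id", "patient_id", "exam_date", "center"])
    return [
        ColonoscopyExam(
            exam_id=r.exam_id,
            patient_id=r.patient_id,
            exam_date=datetime.date.fromisoformat(r.exam_date),
            center=r.center,
        )
        for r in df.itertuples()
    ]


def read_enrollment(path: str | Path) -> list[EnrollmentSpan]:
    df = _read(path, ["patient_id", "start_date", "end_date"])
    return [
        EnrollmentSpan(
            patient_id=r.patient_id,
            start_date=datetime.date.fromisoformat(r.start_date),
            end_date=datetime.date.fromisoformat(r.end_date),
        )
        for r in df.itertuples()
    ]


def read_abstraction(path: str | Path):
    from .synth import abstraction_records_from_frame

    df = pd.read_csv(path, keep_default_na=False)
    return abstraction_records_from_frame(df)
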