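"""Shared domain types for colonoscopy-indication classification.

A colonoscopy is performed for one of three clinical reasons (its
*indication*): **screening** (asymptomatic, average-risk check),
**surveillance** (follow-up of prior polyps, colorectal cancer, IBD or a
CRC-related genetic syndrome), or **diagnostic** (work-up of
gastrointestinal signs, symptoms, or abnormal tests such as a positive
FIT/FOBT or laboratory iron-deficiency anemia).  Everything in this
package — the code-based classifiers, the chart-review gold standard and
the evaluation harness — passes these types around.

Batch data travel as :class:`pandas.DataFrame` objects whose column
schemas are documented in :mod:`colindic.io`; the dataclasses here are
the single-record API and the validated building blocks.
"""

from __future__ import annotations

import datetime
import enum
from dataclasses import dataclass, field


class Indication(str, enum.Enum):
    """Categorical colonoscopy indication."""

    DIAGNOSTIC = "diagnostic"
    SURVEILLANCE = "surveillance"
    SCREENING = "screening"
    #: Only the gold standard may produce this: no usable documentation
    #: source and no qualifying electronic lab signal.
    MISSING = "missing"


class CodeType(str, enum.Enum):
    """Coding vocabulary of a utilization event (study era: ICD-9)."""

    ICD9_DX = "ICD9_DX"
    ICD9_PX = "ICD9_PX"
    CPT = "CPT"
    HCPCS = "HCPCS"
    ICDO = "ICDO"
    LAB = "LAB"


class SourceMode(str, enum.Enum):
    """Which documentation sources the gold standard may consult."""

    COMPREHENSIVE = "comprehensive"
    REFERRAL_ONLY = "referral_only"
    PROCEDURE_ONLY = "procedure_only"


#: Chart-review documentation sources, in canonical order.
SOURCES: tuple[str, ...] = (
    "referral",
    "clinic_note",
    "procedure_report",
    "preprocedure_note",
)

#: Documentation sources visible in each mode.  Electronic lab data are
#: consulted in comprehensive mode only.
MODE_SOURCES: dict[SourceMode, tuple[str, ...]] = {
    SourceMode.COMPREHENSIVE: SOURCES,
    SourceMode.REFERRAL_ONLY: ("referral", "clinic_note"),
    SourceMode.PROCEDURE_ONLY: ("procedure_report", "preprocedure_note"),
}

#: The 17 abstracted signs and symptoms (active findings → diagnostic).
FINDINGS: tuple[str, ...] = (
    "positive_fit_fobt",
    "abnormal_imaging",
    "rectal_bleeding",
    "other_gi_bleeding",
    "iron_deficiency_anemia",
    "other_anemia",
    "diarrhea",
    "constipation",
    "change_in_bowel_habits",
    "ibs",
    "abdominal_mass",
    "abdominal_pain",
    "rectal_pain",
    "weight_loss",
    "suspected_crc",
    "ibd_active",
    "other_colitis",
)

#: Abstracted medical-history flags (→ surveillance when no diagnostic
#: finding is present).
HISTORIES: tuple[str, ...] = (
    "hx_polyps",
    "hx_ibd",
    "hx_crc",
    "hx_genetic_syndrome",
)


def normalize_code(code: str) -> str:
    """Normalize a medical code for exact-string matching."""
    return code.strip().upper()


@dataclass(frozen=True)
class CodedEvent:
    """One dated, typed medical code (or lab result) for a patient.

    ``lab_value`` must be present exactly when ``code_type`` is LAB; it is
    kept as a string (``"positive"``, ``"negative"``, ``"low"``,
    ``"normal"`` or a numeric literal such as ``"9.4"``) and parsed where
    a rule needs a number.
    """

    patient_id: str
    date: datetime.date
    code: str
    code_type: CodeType
    lab_value: str | None = None

    def __post_init__(self) -> None:
        if not self.code or not str(self.code).strip():
            raise ValueError("CodedEvent.code must be non-empty")
        if not isinstance(self.date, datetime.date):
            raise TypeError("CodedEvent.date must be a datetime.date")
        if (self.code_type is CodeType.LAB) != (self.lab_value is not None):
            raise ValueError("lab_value must be present iff code_type is LAB")

    @property
    def norm_code(self) -> str:
        return normalize_code(self.code)


@dataclass(frozen=True)
class ColonoscopyExam:
    """An index colonoscopy procedure."""

    exam_id: str
    patient_id: str
    exam_date: datetime.date
    center: str


@dataclass(frozen=True)
class EnrollmentSpan:
    """A continuous health-plan enrollment interval (inclusive ends)."""

    patient_id: str
    start_date: datetime.date
    end_date: datetime.date

    def __post_init__(self) -> None:
        if self.start_date > self.end_date:
            raise ValueError("EnrollmentSpan start_date must be <= end_date")


@dataclass
class TriggerTrace:
    """Audit trail of a hierarchical classification.

    ``fired`` maps each triggered code-set category to its witness
    events — every (code, code_type, date) inside the category window
    that matched.  ``indication`` is None when the exam was ineligible
    (insufficient prior enrollment), never a label.
    """

    exam_id: str
    eligible: bool
    fired: dict[str, list[CodedEvent]] = field(default_factory=dict)
    indication: Indication | None = None


@dataclass
class AbstractionRecord:
    """Per-exam chart-review findings, kept separate per source document.

    ``findings[source]`` and ``histories[source]`` are subsets of
    :data:`FINDINGS` / :data:`HISTORIES`; flags may only be set for
    sources marked present.  ``prior_incomplete`` carries the indication
    of a prior incomplete exam, which the gold standard carries forward.
    """

    exam_id: str
    source_present: dict[str, bool]
    findings: dict[str, set[str]] = field(default_factory=dict)
    histories: dict[str, set[str]] = field(default_factory=dict)
    prior_incomplete: bool = False
    prior_indication: Indication | None = None

    def __post_init__(self) -> None:
        for src in SOURCES:
            self.source_present.setdefault(src, False)
            self.findings.setdefault(src, set())
            self.histories.setdefault(src, set())
        for src in SOURCES:
            if (self.findings[src] or self.histories[src]) and not self.source_present[src]:
                raise ValueError(
                    f"{self.exam_id}: findings recorded for absent source {src!r}"
                )
            unknown = self.findings[src] - set(FINDINGS)
            if unknown:
                raise ValueError(f"unknown finding flags {sorted(unknown)}")
            unknown = self.histories[src] - set(HISTORIES)
            if unknown:
                raise ValueError(f"unknown history flags {sorted(unknown)}")
        if self.prior_incomplete and self.prior_indication is None:
            raise ValueError("prior_incomplete set without a prior indication")
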