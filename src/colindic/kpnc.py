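"""Hierarchical code-based indication classifier.

The classifier scans a patient's coded utilization history against the
code-set registry and assigns one of three labels with a strict
precedence: **diagnostic** triggers (GI signs/symptoms, a positive
FIT/FOBT within 365 days, laboratory iron-deficiency anemia within 180
days) dominate **surveillance** triggers (history of polyps, CRC, IBD or
a CRC-related genetic syndrome), which dominate the **screening**
default.  An exam with less than the required year of prior enrollment
is *ineligible* and receives no label at all.

Every classification carries a :class:`~colindic.types.TriggerTrace`
listing, per fired category, the witness events that matched — the
classifier is auditable, never just a label.
"""

from __future__ import annotations

import logging

import pandas as pd

from .config import CodeCategory, CodeSetRegistry, WindowConfig, eligible_exam, window_bounds
from .types import CodedEvent, ColonoscopyExam, EnrollmentSpan, Indication, TriggerTrace

logger = logging.getLogger(__name__)


def _num(value: str | None) -> float | None:
    try:
        return float(value)  # type: ignore[arg-type]
    except (TypeError, ValueError):
        return None


def _flag_positive(value: str | None) -> bool:
    return str(value).strip().lower() in {"positive", "pos", "+", "1", "true", "abnormal"}


def category_witnesses(
    category: CodeCategory,
    events: list[CodedEvent],
    exam: ColonoscopyExam,
    cfg: WindowConfig,
) -> list[CodedEvent]:
    """Events that make ``category`` fire for ``exam``.

    Coded (non-LAB) entries qualify by presence inside the category
    window.  LAB entries follow their rule: a qualitative positive
    FIT/FOBT/IDA flag qualifies directly; hemoglobin below the configured
    threshold qualifies as iron-deficiency evidence *unless* every
    ferritin measured in the same window is normal (iron stores
    demonstrably replete → not iron-deficiency anemia).
    """
    window = cfg.effective_window(category)
    start, end = window_bounds(exam.exam_date, window, cfg)
    in_window = [ev for ev in events if start <= ev.date < end]

    witnesses: list[CodedEvent] = []
    hgb_low: list[CodedEvent] = []
    ferritin_vals: list[CodedEvent] = []
    for ev in in_window:
        for entry in category.entries:
            if not entry.matches(ev.code, ev.code_type):
                continue
            if entry.lab_rule is None:
                witnesses.append(ev)
            elif entry.lab_rule == "flag_positive":
                if _flag_positive(ev.lab_value):
                    witnesses.append(ev)
            elif entry.lab_rule == "hgb_low":
                v = _num(ev.lab_value)
                if v is not None and v < cfg.hgb_threshold_g_dl:
                    hgb_low.append(ev)
            elif entry.lab_rule == "ferritin":
                ferritin_vals.append(ev)
            break  # one entry match per event is enough

    if hgb_low:
        ferritin_replete = bool(ferritin_vals) and all(
            not _flag_positive_low(ev, cfg) for ev in ferritin_vals
        )
        if not ferritin_replete:
            witnesses.extend(hgb_low)
    return witnesses


def _flag_positive_low(ev: CodedEvent, cfg: WindowConfig) -> bool:
    """A ferritin result indicating depleted iron stores."""
    v = _num(ev.lab_value)
    if v is not None:
        return v < cfg.ferritin_threshold_ng_ml
    return str(ev.lab_value).strip().lower() in {"low", "deficient"}


def assign_kpnc(
    exam: ColonoscopyExam,
    events: list[CodedEvent],
    registry: CodeSetRegistry,
    cfg: WindowConfig,
    spans: list[EnrollmentSpan] | None = None,
) -> TriggerTrace:
    """Classify one exam; diagnostic > surveillance > screening.

    If ``spans`` is given, eligibility (a full year of prior enrollment)
    is checked first; an ineligible exam gets ``eligible=False`` and no
    indication rather than a label.
    """
    if spans is not None and not eligible_exam(exam, spans, cfg):
        return TriggerTrace(exam_id=exam.exam_id, eligible=False)

    own = [ev for ev in events if ev.patient_id == exam.patient_id]
    fired: dict[str, list[CodedEvent]] = {}
    for name, cat in sorted(registry.categories.items()):
        if cat.indication_class is None:
            continue
        wit = category_witnesses(cat, own, exam, cfg)
        if wit:
            fired[name] = sorted(wit, key=lambda ev: (ev.date, ev.norm_code))

    classes = {registry.categories[name].indication_class for name in fired}
    if "diagnostic" in classes:
        label = Indication.DIAGNOSTIC
    elif "surveillance" in classes:
        label = Indication.SURVEILLANCE
    else:
        label = Indication.SCREENING
    return TriggerTrace(exam_id=exam.exam_id, eligible=True, fired=fired, indication=label)


def batch_assign(
    exams: list[ColonoscopyExam],
    events: list[CodedEvent],
    registry: CodeSetRegistry,
    cfg: WindowConfig,
    spans: list[EnrollmentSpan] | None = None,
) -> list[TriggerTrace]:
    """One trace per exam, order-stable, identical to one-at-a-time calls.

    Events whose patient matches no exam are logged and ignored.
    """
    patients = {x.patient_id for x in exams}
    orphans = sum(1 for ev in events if ev.patient_id not in patients)
    if orphans:
        logger.warning("%d events belong to no exam patient; excluded", orphans)

    by_patient: dict[str, list[CodedEvent]] = {}
    for ev in events:
        if ev.patient_id in patients:
            by_patient.setdefault(ev.patient_id, []).append(ev)
    span_by_patient: dict[str, list[EnrollmentSpan]] | None = None
    if spans is not None:
        span_by_patient = {}
        for s in spans:
            span_by_patient.setdefault(s.patient_id, []).append(s)

    traces = []
    for exam in exams:
        traces.append(
            assign_kpnc(
                exam,
                by_patient.get(exam.patient_id, []),
                registry,
                cfg,
                spans=None if span_by_patient is None else span_by_patient.get(exam.patient_id, []),
            )
        )
    return traces


def traces_to_frame(traces: list[TriggerTrace]) -> pd.DataFrame:
    """Tabular view: exam_id, eligible, label, fired_categories."""
    return pd.DataFrame(
        {
            "exam_id": [t.exam_id for t in traces],
            "eligible": [t.eligible for t in traces],
            "label": [t.indication.value if t.indication else "" for t in traces],
            "fired_categories": [";".join(sorted(t.fired)) for t in traces],
        }
    )
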