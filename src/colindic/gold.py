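"""Gold-standard indication assignment from chart abstraction plus labs.

The reference indication is assigned by a fixed decision tree over
chart-review findings and electronically captured lab results:

1. If the exam's documented reason is a *prior incomplete exam*, the
   prior exam's indication is carried forward (all modes, before any
   other branch).
2. Any gastrointestinal sign/symptom flagged in a visible, present
   documentation source — or, in comprehensive mode, laboratory
   iron-deficiency anemia within 180 days or a positive FIT/FOBT within
   365 days — makes the exam **diagnostic**.
3. Otherwise a history of IBD, CRC, colorectal polyps or a CRC-related
   genetic syndrome in a visible source makes it **surveillance**.
4. Otherwise, if at least one usable source document exists, the exam is
   **screening**; with no usable source and no qualifying lab signal the
   indication is **missing**.

The documentation-source mode restricts which documents are visible:
``comprehensive`` (all four plus electronic labs), ``referral_only``
(referral + clinic notes), ``procedure_only`` (procedure report +
pre-procedure notes).  Electronic labs participate in comprehensive mode
only.
"""

from __future__ import annotations

import pandas as pd

from .config import CodeSetRegistry, WindowConfig
from .kpnc import category_witnesses
from .types import (
    MODE_SOURCES,
    AbstractionRecord,
    CodedEvent,
    ColonoscopyExam,
    Indication,
    SourceMode,
)


def assign_gold(
    rec: AbstractionRecord,
    lab_events: list[CodedEvent],
    exam: ColonoscopyExam,
    registry: CodeSetRegistry,
    cfg: WindowConfig,
    mode: SourceMode = SourceMode.COMPREHENSIVE,
) -> Indication:
    """Run the decision tree for one exam."""
    if rec.exam_id != exam.exam_id:
        raise ValueError(f"record {rec.exam_id!r} does not match exam {exam.exam_id!r}")

    if rec.prior_incomplete:
        assert rec.prior_indication is not None
        return rec.prior_indication

    visible = [s for s in MODE_SOURCES[mode] if rec.source_present.get(s, False)]
    findings = set().union(*(rec.findings[s] for s in visible)) if visible else set()
    histories = set().union(*(rec.histories[s] for s in visible)) if visible else set()

    lab_hit = False
    if mode is SourceMode.COMPREHENSIVE:
        own = [ev for ev in lab_events if ev.patient_id == exam.patient_id]
        for cat_name in ("positive_fit_fobt", "iron_deficiency_anemia"):
            cat = registry.categories[cat_name]
            if category_witnesses(cat, own, exam, cfg):
                lab_hit = True
                break

    if findings or lab_hit:
        return Indication.DIAGNOSTIC
    if histories:
        return Indication.SURVEILLANCE
    if visible:
        return Indication.SCREENING
    return Indication.MISSING


def batch_assign_gold(
    records: list[AbstractionRecord],
    lab_events: list[CodedEvent],
    exams: list[ColonoscopyExam],
    registry: CodeSetRegistry,
    cfg: WindowConfig,
    mode: SourceMode = SourceMode.COMPREHENSIVE,
) -> pd.DataFrame:
    """One gold label per exam: exam_id, center, gold."""
    rec_by_id = {r.exam_id: r for r in records}
    by_patient: dict[str, list[CodedEvent]] = {}
    for ev in lab_events:
        by_patient.setdefault(ev.patient_id, []).append(ev)
    rows = []
    for exam in exams:
        rec = rec_by_id.get(exam.exam_id)
        if rec is None:
            raise KeyError(f"no abstraction record for exam {exam.exam_id!r}")
        label = assign_gold(
            rec, by_patient.get(exam.patient_id, []), exam, registry, cfg, mode
        )
        rows.append({"exam_id": exam.exam_id, "center": exam.center, "gold": label.value})
    return pd.DataFrame(rows)


def tabulate_indications(gold: pd.DataFrame) -> pd.DataFrame:
    """Per-center counts and percentages by indication.

    Expects columns ``center`` and ``gold``; percentages are of the
    center's total exam count (missing included in the denominator).
    Empty input yields an empty table rather than a division by zero.
    """
    order = [i.value for i in Indication]
    if gold.empty:
        return pd.DataFrame(columns=["center", "indication", "n", "pct"])
    rows = []
    for center, grp in gold.groupby("center", sort=True):
        total = len(grp)
        counts = grp["gold"].value_counts()
        for ind in order:
            n = int(counts.get(ind, 0))
            rows.append(
                {"center": center, "indication": ind, "n": n, "pct": 100.0 * n / total}
            )
    return pd.DataFrame(rows)
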