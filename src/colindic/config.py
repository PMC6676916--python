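"""Code-set registry, look-back windows and screening-model configuration.

Code inventories and scoring coefficients are deliberately *pluggable*
configuration: the classifier logic is fixed, while the code lists that
feed it are loaded from YAML.  The bundled defaults
(:func:`default_registry`, ``data/search_model.yaml``) are illustrative,
synthetic-compatible inventories — plausible ICD-9-era codes chosen so
the synthetic generator and the classifiers speak the same language —
not any published production list.

Window convention: a category with ``window_days = W`` scans the
half-open interval ``[exam_date - W, exam_date)``; codes on the exam day
itself are excluded by default (exam-day coding usually reflects the
procedure, not its indication) unless ``WindowConfig.include_exam_day``
is set.  ``window_days = None`` means unlimited look-back (history
categories: a prior polyp is a prior polyp however old the code).
"""

from __future__ import annotations

import dataclasses
import datetime
from dataclasses import dataclass, field
from pathlib import Path

import yaml

from .types import CodeType, ColonoscopyExam, EnrollmentSpan, normalize_code


class ConfigError(ValueError):
    """A configuration file is missing something or self-contradictory."""


# Categories every registry must define (the classifier hierarchy and the
# synthetic generator rely on them).
REQUIRED_CATEGORIES = (
    "diagnostic_symptom",
    "positive_fit_fobt",
    "iron_deficiency_anemia",
    "polyp_history",
    "ibd_history",
    "crc_history",
    "genetic_syndrome",
    "incomplete_exam_marker",
)

#: Lab-entry qualification rules understood by the classifiers.
LAB_RULES = ("flag_positive", "hgb_low", "ferritin")


@dataclass(frozen=True)
class CodeEntry:
    """One (code, code_type) member of a category.

    ``prefix`` turns on ICD-9-style family matching ("789.0" matches
    "789.00"… ).  ``shared`` permits the same code to appear in more than
    one category.  ``finding`` links the entry to the abstraction-level
    sign/symptom it encodes (used by the synthetic generator).
    ``lab_rule`` selects how a LAB event qualifies: "flag_positive"
    (qualitative positive result), "hgb_low" (hemoglobin below the
    configured threshold), "ferritin" (iron-store context, see
    :mod:`colindic.kpnc`).
    """

    code: str
    code_type: CodeType
    prefix: bool = False
    shared: bool = False
    finding: str | None = None
    lab_rule: str | None = None

    def __post_init__(self) -> None:
        if not self.code.strip():
            raise ConfigError("empty code in code-set entry")
        if self.lab_rule is not None:
            if self.code_type is not CodeType.LAB:
                raise ConfigError(f"lab_rule on non-LAB entry {self.code!r}")
            if self.lab_rule not in LAB_RULES:
                raise ConfigError(f"unknown lab_rule {self.lab_rule!r}")

    @property
    def norm_code(self) -> str:
        return normalize_code(self.code)

    def matches(self, code: str, code_type: CodeType) -> bool:
        if code_type is not self.code_type:
            return False
        c = normalize_code(code)
        return c.startswith(self.norm_code) if self.prefix else c == self.norm_code


@dataclass
class CodeCategory:
    """A named code set with a look-back window and a hierarchy role.

    ``indication_class`` is "diagnostic", "surveillance" or None (a
    category, like the incomplete-exam marker, that is not itself a
    classification trigger).
    """

    name: str
    indication_class: str | None
    window_days: int | None
    entries: list[CodeEntry] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.indication_class not in (None, "diagnostic", "surveillance"):
            raise ConfigError(
                f"category {self.name!r}: bad indication_class {self.indication_class!r}"
            )
        if self.window_days is not None and self.window_days <= 0:
            raise ConfigError(f"category {self.name!r}: window_days must be > 0")


@dataclass
class CodeSetRegistry:
    """All code-set categories, validated for cross-category collisions."""

    categories: dict[str, CodeCategory]

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        missing = [c for c in REQUIRED_CATEGORIES if c not in self.categories]
        if missing:
            raise ConfigError(f"missing required categories: {', '.join(missing)}")
        seen: dict[tuple[str, CodeType], tuple[str, CodeEntry]] = {}
        for cat in self.categories.values():
            for entry in cat.entries:
                key = (entry.norm_code, entry.code_type)
                if key in seen:
                    other_cat, other = seen[key]
                    if other_cat != cat.name and not (entry.shared and other.shared):
                        raise ConfigError(
                            f"code {entry.code!r} ({entry.code_type.value}) appears in "
                            f"both {other_cat!r} and {cat.name!r} without shared flag"
                        )
                else:
                    seen[key] = (cat.name, entry)

    def categories_for(self, code: str, code_type: CodeType) -> list[str]:
        """All categories containing (code, code_type); order-independent."""
        hits = [
            name
            for name, cat in sorted(self.categories.items())
            if any(e.matches(code, code_type) for e in cat.entries)
        ]
        return hits

    def finding_entries(self, finding: str) -> list[tuple[str, CodeEntry]]:
        """(category, entry) pairs encoding a given abstraction finding."""
        return [
            (name, e)
            for name, cat in sorted(self.categories.items())
            for e in cat.entries
            if e.finding == finding
        ]

    # -- serialization -------------------------------------------------

    def to_dict(self) -> dict:
        return {
            "categories": {
                name: {
                    "indication_class": cat.indication_class,
                    "window_days": cat.window_days,
                    "entries": [
                        {
                            k: (v.value if isinstance(v, CodeType) else v)
                            for k, v in dataclasses.asdict(e).items()
                            if not (k in ("prefix", "shared") and v is False)
                            and not (k in ("finding", "lab_rule") and v is None)
                        }
                        for e in cat.entries
                    ],
                }
                for name, cat in self.categories.items()
            }
        }

    @classmethod
    def from_dict(cls, d: dict) -> "CodeSetRegistry":
        try:
            raw = d["categories"]
        except (KeyError, TypeError):
            raise ConfigError("code-set file must have a top-level 'categories' map")
        cats = {}
        for name, spec in raw.items():
            entries = []
            for i, e in enumerate(spec.get("entries", [])):
                try:
                    entries.append(
                        CodeEntry(
                            code=str(e["code"]),
                            code_type=CodeType(e["code_type"]),
                            prefix=bool(e.get("prefix", False)),
                            shared=bool(e.get("shared", False)),
                            finding=e.get("finding"),
                            lab_rule=e.get("lab_rule"),
                        )
                    )
                except (KeyError, ValueError) as exc:
                    raise ConfigError(
                        f"category {name!r}, entry {i}: malformed code entry ({exc})"
                    ) from exc
            cats[name] = CodeCategory(
                name=name,
                indication_class=spec.get("indication_class"),
                window_days=spec.get("window_days"),
                entries=entries,
            )
        return cls(categories=cats)

    def save(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(self.to_dict(), sort_keys=True))


def load_codesets(path: str | Path) -> CodeSetRegistry:
    """Load and validate a code-set registry from a YAML file."""
    try:
        d = yaml.safe_load(Path(path).read_text())
    except yaml.YAMLError as exc:
        raise ConfigError(f"cannot parse code-set file {path}: {exc}") from exc
    return CodeSetRegistry.from_dict(d)


# ---------------------------------------------------------------------------
# Screening-probability model configuration


@dataclass(frozen=True)
class SearchTerm:
    """One linear-predictor term: a coefficient on a code-derived feature."""

    name: str
    coefficient: float
    category: str
    window_days: int | None = None  # None → the category's own window
    aggregation: str = "binary"  # "binary" presence or event "count"

    def __post_init__(self) -> None:
        if self.aggregation not in ("binary", "count"):
            raise ConfigError(f"term {self.name!r}: bad aggregation {self.aggregation!r}")


@dataclass
class SearchModel:
    """A logistic screening-probability model: p = expit(β0 + Σ βj·xj)."""

    intercept: float
    terms: list[SearchTerm] = field(default_factory=list)
    cutpoint: float | None = None

    def __post_init__(self) -> None:
        names = [t.name for t in self.terms]
        if len(names) != len(set(names)):
            raise ConfigError("duplicate feature names in screening model")
        if self.cutpoint is not None and not (0.0 < self.cutpoint < 1.0):
            raise ConfigError("cutpoint must lie strictly inside (0, 1)")

    def validate_against(self, registry: CodeSetRegistry) -> None:
        for t in self.terms:
            if t.category not in registry.categories:
                raise ConfigError(
                    f"term {t.name!r} references unknown category {t.category!r}"
                )

    def to_dict(self) -> dict:
        return {
            "intercept": float(self.intercept),
            "cutpoint": self.cutpoint,
            "terms": [
                {
                    "name": t.name,
                    "coefficient": float(t.coefficient),
                    "category": t.category,
                    "window_days": t.window_days,
                    "aggregation": t.aggregation,
                }
                for t in self.terms
            ],
        }

    @classmethod
    def from_dict(cls, d: dict) -> "SearchModel":
        try:
            terms = [
                SearchTerm(
                    name=t["name"],
                    coefficient=float(t["coefficient"]),
                    category=t["category"],
                    window_days=t.get("window_days"),
                    aggregation=t.get("aggregation", "binary"),
                )
                for t in d.get("terms", [])
            ]
            return cls(
                intercept=float(d["intercept"]), terms=terms, cutpoint=d.get("cutpoint")
            )
        except (KeyError, TypeError) as exc:
            raise ConfigError(f"malformed screening-model file: {exc}") from exc

    def save(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(self.to_dict(), sort_keys=True))


def load_search_model(
    path: str | Path, registry: CodeSetRegistry | None = None
) -> SearchModel:
    """Load a screening-model coefficient file, optionally resolving it
    against a registry."""
    try:
        d = yaml.safe_load(Path(path).read_text())
    except yaml.YAMLError as exc:
        raise ConfigError(f"cannot parse model file {path}: {exc}") from exc
    model = SearchModel.from_dict(d)
    if registry is not None:
        model.validate_against(registry)
    return model


# ---------------------------------------------------------------------------
# Windows and enrollment eligibility


@dataclass(frozen=True)
class WindowConfig:
    """Look-back windows (days) and lab thresholds.

    The iron-deficiency-anemia window is 180 days before the exam and the
    FIT/FOBT window 365 days; a full year of prior enrollment is required
    for an exam to be algorithm-eligible.
    """

    ida_window_days: int = 180
    fit_fobt_window_days: int = 365
    enrollment_lookback_days: int = 365
    include_exam_day: bool = False
    gap_tolerance_days: int = 0
    hgb_threshold_g_dl: float = 12.0
    ferritin_threshold_ng_ml: float = 15.0

    def __post_init__(self) -> None:
        for name in ("ida_window_days", "fit_fobt_window_days", "enrollment_lookback_days"):
            if getattr(self, name) <= 0:
                raise ConfigError(f"{name} must be positive")
        if self.gap_tolerance_days < 0:
            raise ConfigError("gap_tolerance_days must be >= 0")

    def effective_window(self, category: CodeCategory) -> int | None:
        """Category look-back, with the two lab windows owned by this config."""
        if category.name == "iron_deficiency_anemia":
            return self.ida_window_days
        if category.name == "positive_fit_fobt":
            return self.fit_fobt_window_days
        return category.window_days


def window_bounds(
    exam_date: datetime.date, window_days: int | None, cfg: WindowConfig
) -> tuple[datetime.date, datetime.date]:
    """Half-open [start, end) date interval scanned for a category."""
    end = exam_date + datetime.timedelta(days=1 if cfg.include_exam_day else 0)
    if window_days is None:
        start = datetime.date.min
    else:
        start = exam_date - datetime.timedelta(days=window_days)
    return start, end


def eligible_exam(
    exam: ColonoscopyExam, spans: list[EnrollmentSpan], cfg: WindowConfig
) -> bool:
    """True iff the patient is continuously enrolled for the look-back
    period ending at the exam date.

    Coverage of ``[exam_date - L, exam_date]`` (inclusive) is required;
    every uncovered run of days inside that interval must be no longer
    than ``cfg.gap_tolerance_days``.
    """
    relevant = [s for s in spans if s.patient_id == exam.patient_id]
    lo = exam.exam_date - datetime.timedelta(days=cfg.enrollment_lookback_days)
    hi = exam.exam_date
    clipped = sorted(
        (max(s.start_date, lo), min(s.end_date, hi))
        for s in relevant
        if s.end_date >= lo and s.start_date <= hi
    )
    if not clipped:
        return cfg.enrollment_lookback_days + 1 <= cfg.gap_tolerance_days
    cursor = lo
    for start, end in clipped:
        if start > cursor:
            gap = (start - cursor).days
            if gap > cfg.gap_tolerance_days:
                return False
        cursor = max(cursor, end + datetime.timedelta(days=1))
    if cursor <= hi:
        if (hi - cursor).days + 1 > cfg.gap_tolerance_days:
            return False
    return True


# ---------------------------------------------------------------------------
# Bundled illustrative registry


def default_registry() -> CodeSetRegistry:
    """Illustrative synthetic-compatible registry (not a published list).

    One or two plausible ICD-9-era codes per abstracted sign/symptom,
    lab pseudo-codes for FIT/FOBT, hemoglobin, ferritin and an
    iron-deficiency flag, and history code sets with unlimited look-back.
    """
    dx = CodeType.ICD9_DX
    lab = CodeType.LAB

    def e(code, ct=dx, **kw):
        return CodeEntry(code=code, code_type=ct, **kw)

    cats = {
        "diagnostic_symptom": CodeCategory(
            "diagnostic_symptom",
            "diagnostic",
            365,
            [
                e("793.4", finding="abnormal_imaging"),
                e("569.3", finding="rectal_bleeding"),
                e("578", prefix=True, finding="other_gi_bleeding"),
                e("285.9", finding="other_anemia"),
                e("787.91", finding="diarrhea"),
                e("564.0", prefix=True, finding="constipation"),
                e("787.99", finding="change_in_bowel_habits"),
                e("564.1", finding="ibs"),
                e("789.3", prefix=True, finding="abdominal_mass"),
                e("789.0", prefix=True, finding="abdominal_pain"),
                e("569.42", finding="rectal_pain"),
                e("783.21", finding="weight_loss"),
                e("230.3", finding="suspected_crc"),
                e("555", prefix=True, finding="ibd_active"),
                e("556", prefix=True, finding="ibd_active"),
                e("558.9", finding="other_colitis"),
            ],
        ),
        "positive_fit_fobt": CodeCategory(
            "positive_fit_fobt",
            "diagnostic",
            365,
            [
                e("FIT", lab, finding="positive_fit_fobt", lab_rule="flag_positive"),
                e("FOBT", lab, finding="positive_fit_fobt", lab_rule="flag_positive"),
                e("792.1", finding="positive_fit_fobt"),
            ],
        ),
        "iron_deficiency_anemia": CodeCategory(
            "iron_deficiency_anemia",
            "diagnostic",
            180,
            [
                e("280", prefix=True, finding="iron_deficiency_anemia"),
                e("IDA", lab, finding="iron_deficiency_anemia", lab_rule="flag_positive"),
                e("HGB", lab, lab_rule="hgb_low"),
                e("FERRITIN", lab, lab_rule="ferritin"),
            ],
        ),
        "polyp_history": CodeCategory(
            "polyp_history",
            "surveillance",
            None,
            [e("V12.72", finding="hx_polyps"), e("211.3", finding="hx_polyps")],
        ),
        "ibd_history": CodeCategory(
            "ibd_history", "surveillance", None, [e("V12.79", finding="hx_ibd")]
        ),
        "crc_history": CodeCategory(
            "crc_history",
            "surveillance",
            None,
            [
                e("V10.05", finding="hx_crc"),
                e("V10.06", finding="hx_crc"),
                e("C18.9", CodeType.ICDO, finding="hx_crc"),
            ],
        ),
        "genetic_syndrome": CodeCategory(
            "genetic_syndrome", "surveillance", None, [e("V84.09", finding="hx_genetic_syndrome")]
        ),
        "incomplete_exam_marker": CodeCategory(
            "incomplete_exam_marker", None, 365, [e("V64.3")]
        ),
    }
    return CodeSetRegistry(categories=cats)
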