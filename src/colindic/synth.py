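"""Seeded synthetic EHR cohort generator with known latent indications.

The generator emulates the validation-study setting: three health-care
centers, each contributing a sample of colonoscopies whose *latent* true
indication is drawn from the center's gold-standard indication mixture,
with sign/symptom prevalences matching the published per-center margins.
For every exam it fabricates the artifacts the real study observed:

* enrollment spans (every sampled patient has a full year of history),
* coded utilization events (ICD-9-style codes drawn from the shared
  code-set registry, dated inside each category's look-back window),
* lab events (positive FIT/FOBT within 365 days, low hemoglobin within
  180 days) for the lab-driven findings,
* multi-source chart-abstraction records (referral, clinic note,
  procedure report, pre-procedure note), with configurable documentation
  discordance between sources and a configurable rate of exams with no
  usable records at all.

Code-capture noise is separate from the clinical truth: a true trigger
emits its code only with ``code_emission_sensitivity``, and spurious
category codes arrive at ``spurious_code_rate`` per exam.  All random
decisions consume RNG draws unconditionally, so two cohorts generated
from the same seed but different noise settings share coupled uniforms:
the emitted code sets are *nested* as emission sensitivity decreases,
which makes degradation experiments exactly paired.

Symptom marginals are calibrated: the per-symptom conditional rates used
inside diagnostic exams are solved (fixed point) so that, after
conditioning on "at least one finding", the cohort-level marginal
prevalence of each symptom matches the configured value in expectation.
"""

from __future__ import annotations

import dataclasses
import datetime
import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .config import CodeSetRegistry, ConfigError, WindowConfig
from .types import (
    FINDINGS,
    HISTORIES,
    SOURCES,
    AbstractionRecord,
    CodedEvent,
    CodeType,
    ColonoscopyExam,
    EnrollmentSpan,
    Indication,
)

_BASE_DATE = datetime.date(2010, 1, 1)
_N_STUDY_DAYS = 1461  # 2010-01-01 .. 2013-12-31 inclusive


@dataclass
class CenterProfile:
    """Generation parameters for one center.

    ``indication_mixture`` is normalized over the three non-missing
    classes; ``symptom_prevalence`` holds cohort-level *marginal*
    prevalences (over all exams, as the published table reports them);
    ``history_mix`` is the conditional distribution of the single history
    type carried by a surveillance exam.
    """

    center: str
    n_exams: int
    indication_mixture: dict[str, float]
    symptom_prevalence: dict[str, float]
    missingness_rate: float = 0.0
    source_discordance: float = 0.0
    history_mix: dict[str, float] = field(
        default_factory=lambda: {
            "hx_polyps": 0.80,
            "hx_ibd": 0.12,
            "hx_crc": 0.05,
            "hx_genetic_syndrome": 0.03,
        }
    )
    diag_history_rate: float = 0.15
    prior_incomplete_rate: float = 0.02
    demographics: dict[str, dict[str, float]] | None = None

    def __post_init__(self) -> None:
        if self.n_exams < 0:
            raise ConfigError("n_exams must be >= 0")
        total = sum(self.indication_mixture.get(k, 0.0) for k in ("diagnostic", "surveillance", "screening"))
        if total <= 0:
            raise ConfigError("indication mixture has no mass on any class")
        self.indication_mixture = {
            k: self.indication_mixture.get(k, 0.0) / total
            for k in ("diagnostic", "surveillance", "screening")
        }
        for name, p in self.symptom_prevalence.items():
            if name not in FINDINGS:
                raise ConfigError(f"unknown symptom {name!r} in profile")
            if not (0.0 <= p <= 1.0):
                raise ConfigError(f"symptom prevalence out of [0,1]: {name}={p}")
        for rate in (self.missingness_rate, self.source_discordance, self.prior_incomplete_rate):
            if not (0.0 <= rate <= 1.0):
                raise ConfigError("rates must lie in [0, 1]")
        h_total = sum(self.history_mix.values())
        if h_total <= 0:
            raise ConfigError("history mix has no mass")
        self.history_mix = {k: v / h_total for k, v in self.history_mix.items()}

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "CenterProfile":
        return cls(**d)


@dataclass
class NoiseModel:
    """Code-capture imperfection knobs; defaults are noise-free."""

    code_emission_sensitivity: float = 1.0
    spurious_code_rate: float = 0.0
    lab_timing_jitter_days: int | None = None

    def __post_init__(self) -> None:
        if not (0.0 <= self.code_emission_sensitivity <= 1.0):
            raise ConfigError("code_emission_sensitivity must lie in [0, 1]")
        if self.spurious_code_rate < 0:
            raise ConfigError("spurious_code_rate must be >= 0")

    @classmethod
    def realistic(cls) -> "NoiseModel":
        """A deliberately imperfect-capture setting: 85% of true triggers
        reach claims, and one exam in three acquires a stray code."""
        return cls(code_emission_sensitivity=0.85, spurious_code_rate=0.3)

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "NoiseModel":
        return cls(**d)


# ---------------------------------------------------------------------------
# Published per-center margins used to build the three bundled profiles.
# Counts are the study's abstraction-table margins; the code lists behind
# them remain the illustrative registry.

_KPWA_SYMPTOMS = (63, 10, 63, 9, 35, 18, 48, 28, 30, 2, 1, 59, 2, 9, 0, 16, 7)
_KPNCSC_SYMPTOMS = (131, 22, 96, 14, 59, 28, 28, 17, 8, 6, 0, 41, 3, 7, 0, 9, 2)
_PARKLAND_SYMPTOMS = (76, 18, 105, 22, 39, 33, 30, 84, 21, 3, 2, 110, 9, 13, 2, 10, 4)

_DEMOGRAPHICS = {
    "KPWA": {
        "age": {"50-59": 231, "60-75": 309, "76-89": 60},
        "sex": {"F": 332, "M": 268},
        "race": {"NH White": 474, "NH Black": 25, "Hispanic": 28, "Asian/PI": 33, "Other": 40},
    },
    "KPNCSC": {
        "age": {"50-59": 261, "60-75": 284, "76-89": 55},
        "sex": {"F": 322, "M": 278},
        "race": {"NH White": 315, "NH Black": 44, "Hispanic": 125, "Asian/PI": 96, "Other": 20},
    },
    "PARKLAND": {
        "age": {"50-59": 393, "60-75": 203, "76-89": 0},
        "sex": {"F": 396, "M": 200},
        "race": {"NH White": 103, "NH Black": 187, "Hispanic": 252, "Asian/PI": 47, "Other": 7},
    },
}


def _profile(center, n, counts, symptom_counts, n_total, missing) -> CenterProfile:
    d, s, sv = counts
    return CenterProfile(
        center=center,
        n_exams=n,
        indication_mixture={"diagnostic": d, "screening": s, "surveillance": sv},
        symptom_prevalence={f: c / n_total for f, c in zip(FINDINGS, symptom_counts)},
        missingness_rate=missing / n_total,
        source_discordance=0.10,
        demographics=_DEMOGRAPHICS[center],
    )


def kpwa_profile(n_exams: int = 600) -> CenterProfile:
    """KPWA-like center: 232/209/132 diagnostic/screening/surveillance
    among 577 abstracted exams, 23 of 600 with insufficient records."""
    return _profile("KPWA", n_exams, (232, 209, 132), _KPWA_SYMPTOMS, 600, 23)


def kpnc_sc_profile(n_exams: int = 600) -> CenterProfile:
    """KPNC/SC-like center: 303/190/106 mixture, one exam in 600 missing."""
    return _profile("KPNCSC", n_exams, (303, 190, 106), _KPNCSC_SYMPTOMS, 600, 1)


def parkland_profile(n_exams: int = 596) -> CenterProfile:
    """Parkland-like center: 312/246/38 mixture, no missing records."""
    return _profile("PARKLAND", n_exams, (312, 246, 38), _PARKLAND_SYMPTOMS, 596, 0)


BUILTIN_PROFILES = {
    "kpwa": kpwa_profile,
    "kpnc_sc": kpnc_sc_profile,
    "parkland": parkland_profile,
}


# ---------------------------------------------------------------------------


def conditional_symptom_rates(profile: CenterProfile) -> np.ndarray:
    """Per-symptom Bernoulli rates used *inside* diagnostic exams.

    Solves q = t · (1 − Π(1 − q)) by fixed-point iteration, where
    t_k = marginal_k / P(diagnostic ∧ non-missing): sampling symptoms
    independently at rates q and rejecting all-empty vectors then yields
    conditional prevalences t and hence cohort marginals equal to the
    configured values.
    """
    p_dx_eff = profile.indication_mixture["diagnostic"] * (1.0 - profile.missingness_rate)
    marginals = np.array([profile.symptom_prevalence.get(f, 0.0) for f in FINDINGS])
    if p_dx_eff <= 0:
        return np.zeros(len(FINDINGS))
    t = np.clip(marginals / p_dx_eff, 0.0, 0.999)
    if t.sum() == 0:
        raise ConfigError(
            "diagnostic exams are possible but every symptom prevalence is zero"
        )
    q = t.copy()
    for _ in range(500):
        p0 = float(np.prod(1.0 - q))
        q_new = t * (1.0 - p0)
        if np.max(np.abs(q_new - q)) < 1e-13:
            q = q_new
            break
        q = q_new
    if 1.0 - float(np.prod(1.0 - q)) < 0.05:
        # Degenerate target (expected findings << 1); fall back to the
        # uncalibrated rates and let rejection inflate marginals slightly.
        return t
    return q


@dataclass
class Cohort:
    """All generated entities for one center, as DataFrames."""

    patients: pd.DataFrame
    enrollment: pd.DataFrame
    events: pd.DataFrame
    exams: pd.DataFrame
    abstraction: pd.DataFrame
    true_labels: pd.DataFrame
    profile: CenterProfile
    noise: NoiseModel
    seed: int

    # -- object views ---------------------------------------------------

    def exam_objects(self) -> list[ColonoscopyExam]:
        return [
            ColonoscopyExam(r.exam_id, r.patient_id, r.exam_date, r.center)
            for r in self.exams.itertuples()
        ]

    def event_objects(self) -> list[CodedEvent]:
        return [
            CodedEvent(
                r.patient_id,
                r.date,
                r.code,
                CodeType(r.code_type),
                r.lab_value if r.lab_value != "" else None,
            )
            for r in self.events.itertuples()
        ]

    def enrollment_objects(self) -> list[EnrollmentSpan]:
        return [
            EnrollmentSpan(r.patient_id, r.start_date, r.end_date)
            for r in self.enrollment.itertuples()
        ]

    def abstraction_records(self) -> list[AbstractionRecord]:
        return abstraction_records_from_frame(self.abstraction)


_ABS_COLUMNS = (
    ["exam_id", "prior_incomplete", "prior_indication"]
    + [f"source_present.{s}" for s in SOURCES]
    + [f"{s}.{f}" for s in SOURCES for f in FINDINGS]
    + [f"{s}.{h}" for s in SOURCES for h in HISTORIES]
)


def abstraction_records_from_frame(frame: pd.DataFrame) -> list[AbstractionRecord]:
    records = []
    for _, row in frame.iterrows():
        present = {s: bool(row[f"source_present.{s}"]) for s in SOURCES}
        findings = {
            s: {f for f in FINDINGS if row[f"{s}.{f}"]} for s in SOURCES
        }
        histories = {
            s: {h for h in HISTORIES if row[f"{s}.{h}"]} for s in SOURCES
        }
        prior = bool(row["prior_incomplete"])
        records.append(
            AbstractionRecord(
                exam_id=row["exam_id"],
                source_present=present,
                findings=findings,
                histories=histories,
                prior_incomplete=prior,
                prior_indication=Indication(row["prior_indication"]) if prior else None,
            )
        )
    return records


def generate_cohort(
    profile: CenterProfile,
    noise: NoiseModel,
    registry: CodeSetRegistry,
    cfg: WindowConfig,
    seed: int,
) -> Cohort:
    """Generate one seeded center cohort (see module docstring)."""
    rng = np.random.default_rng(seed)
    q_symptom = conditional_symptom_rates(profile)
    hist_names = list(profile.history_mix)
    hist_probs = np.array([profile.history_mix[h] for h in hist_names])
    mix_order = ("diagnostic", "screening", "surveillance")
    mix_probs = np.array([profile.indication_mixture[k] for k in mix_order])

    # pre-resolve registry entries per finding/history
    entry_for: dict[str, tuple[str, object]] = {}
    for fname in FINDINGS + HISTORIES:
        pairs = registry.finding_entries(fname)
        if not pairs:
            raise ConfigError(f"registry has no entry encoding finding {fname!r}")
        entry_for[fname] = pairs[0]

    spurious_pool = [
        (name, e)
        for name, cat in sorted(registry.categories.items())
        if cat.indication_class is not None
        for e in cat.entries
        if e.lab_rule is None
    ]

    patients, enrollment, events, exams = [], [], [], []
    abs_rows, true_rows = [], []

    demo = profile.demographics or {}

    def draw_cat(margins: dict[str, float]) -> str:
        keys = list(margins)
        w = np.array([margins[k] for k in keys], dtype=float)
        if w.sum() <= 0:
            return keys[0] if keys else ""
        return keys[int(rng.choice(len(keys), p=w / w.sum()))]

    for i in range(profile.n_exams):
        pid = f"{profile.center}-P{i:05d}"
        eid = f"{profile.center}-E{i:05d}"
        exam_date = _BASE_DATE + datetime.timedelta(days=int(rng.integers(0, _N_STUDY_DAYS)))

        age = draw_cat(demo.get("age", {"60-75": 1.0}))
        sex = draw_cat(demo.get("sex", {"F": 0.5, "M": 0.5}))
        race = draw_cat(demo.get("race", {"Other": 1.0}))

        missing_record = bool(rng.random() < profile.missingness_rate)
        true_ind = Indication(mix_order[int(rng.choice(3, p=mix_probs))])
        prior_inc = bool(rng.random() < profile.prior_incomplete_rate)

        # latent clinical truth ---------------------------------------
        findings: list[str] = []
        histories: list[str] = []
        if true_ind is Indication.DIAGNOSTIC:
            mask = np.zeros(len(FINDINGS), dtype=bool)
            for _ in range(1000):
                mask = rng.random(len(FINDINGS)) < q_symptom
                if mask.any():
                    break
            if not mask.any():  # pathological rates; force the modal symptom
                mask[int(np.argmax(q_symptom))] = True
            findings = [f for f, m in zip(FINDINGS, mask) if m]
            if rng.random() < profile.diag_history_rate:
                histories = [hist_names[int(rng.choice(len(hist_names), p=hist_probs))]]
            else:
                rng.choice(len(hist_names), p=hist_probs)  # draw-count invariance
        elif true_ind is Indication.SURVEILLANCE:
            histories = [hist_names[int(rng.choice(len(hist_names), p=hist_probs))]]

        # coded events -------------------------------------------------
        exam_events: list[tuple] = []

        def emit(code, code_type, offset_days, lab_value=""):
            exam_events.append(
                (pid, exam_date - datetime.timedelta(days=int(offset_days)), code, code_type.value, lab_value)
            )

        jitter = noise.lab_timing_jitter_days
        for fname in findings:
            u_emit = rng.random()
            if fname == "positive_fit_fobt":
                w = min(jitter or cfg.fit_fobt_window_days, cfg.fit_fobt_window_days)
                off = rng.integers(1, w + 1)
                if u_emit < noise.code_emission_sensitivity:
                    emit("FIT", CodeType.LAB, off, "positive")
            elif fname == "iron_deficiency_anemia":
                w = min(jitter or cfg.ida_window_days, cfg.ida_window_days)
                off = rng.integers(1, w + 1)
                hgb = round(float(rng.uniform(8.0, cfg.hgb_threshold_g_dl - 0.5)), 1)
                if u_emit < noise.code_emission_sensitivity:
                    emit("HGB", CodeType.LAB, off, str(hgb))
            else:
                cat_name, entry = entry_for[fname]
                window = cfg.effective_window(registry.categories[cat_name]) or 365
                off = rng.integers(1, window + 1)
                if u_emit < noise.code_emission_sensitivity:
                    emit(entry.code, entry.code_type, off)
        for hname in histories:
            u_emit = rng.random()
            off = rng.integers(400, 1001)
            cat_name, entry = entry_for[hname]
            if u_emit < noise.code_emission_sensitivity:
                emit(entry.code, entry.code_type, off)

        if prior_inc and not missing_record:
            u_emit = rng.random()
            off = rng.integers(30, 366)
            if u_emit < noise.code_emission_sensitivity:
                emit("V64.3", CodeType.ICD9_DX, off)

        n_spurious = int(rng.poisson(noise.spurious_code_rate))
        for _ in range(n_spurious):
            cat_name, entry = spurious_pool[int(rng.integers(0, len(spurious_pool)))]
            window = cfg.effective_window(registry.categories[cat_name]) or 365
            off = rng.integers(1, window + 1)
            emit(entry.code, entry.code_type, off)

        if missing_record:
            exam_events = []  # insufficient data: no captured signal at all

        # abstraction --------------------------------------------------
        doc: dict[str, set[str]] = {s: set() for s in SOURCES}
        doc_hx: dict[str, set[str]] = {s: set() for s in SOURCES}
        for fname in findings + histories:
            primary = int(rng.integers(0, len(SOURCES)))
            copies = rng.random(len(SOURCES))
            for j, s in enumerate(SOURCES):
                documented = j == primary or copies[j] >= profile.source_discordance
                if documented:
                    (doc_hx if fname in HISTORIES else doc)[s].add(fname)

        if missing_record:
            present = {s: False for s in SOURCES}
            doc = {s: set() for s in SOURCES}
            doc_hx = {s: set() for s in SOURCES}
            prior_flag, prior_label = False, ""
        else:
            present = {s: True for s in SOURCES}
            prior_flag = prior_inc
            prior_label = true_ind.value if prior_inc else ""

        patients.append((pid, age, sex, race))
        enrollment.append(
            (pid, exam_date - datetime.timedelta(days=1100), exam_date + datetime.timedelta(days=30))
        )
        exams.append((eid, pid, exam_date, profile.center))
        events.extend(exam_events)
        row = {"exam_id": eid, "prior_incomplete": int(prior_flag), "prior_indication": prior_label}
        for s in SOURCES:
            row[f"source_present.{s}"] = int(present[s])
        for s in SOURCES:
            for f in FINDINGS:
                row[f"{s}.{f}"] = int(f in doc[s])
            for h in HISTORIES:
                row[f"{s}.{h}"] = int(h in doc_hx[s])
        abs_rows.append(row)
        true_rows.append(
            {
                "exam_id": eid,
                "true_indication": true_ind.value,
                "findings": ";".join(findings),
                "histories": ";".join(histories),
                "missing_record": int(missing_record),
                "prior_incomplete": int(prior_flag),
            }
        )

    return Cohort(
        patients=pd.DataFrame(patients, columns=["patient_id", "age_group", "sex", "race"]),
        enrollment=pd.DataFrame(enrollment, columns=["patient_id", "start_date", "end_date"]),
        events=pd.DataFrame(events, columns=["patient_id", "date", "code", "code_type", "lab_value"]),
        exams=pd.DataFrame(exams, columns=["exam_id", "patient_id", "exam_date", "center"]),
        abstraction=pd.DataFrame(abs_rows, columns=_ABS_COLUMNS),
        true_labels=pd.DataFrame(
            true_rows,
            columns=[
                "exam_id",
                "true_indication",
                "findings",
                "histories",
                "missing_record",
                "prior_incomplete",
            ],
        ),
        profile=profile,
        noise=noise,
        seed=seed,
    )


# ---------------------------------------------------------------------------
# Fixture I/O


_ENTITY_FILES = {
    "patients": "patients.csv",
    "enrollment": "enrollment.csv",
    "events": "events.csv",
    "exams": "exams.csv",
    "abstraction": "abstraction.csv",
    "true_labels": "true_labels.csv",
}

_DATE_COLUMNS = {
    "enrollment": ["start_date", "end_date"],
    "events": ["date"],
    "exams": ["exam_date"],
}


def cohort_hash(profile: CenterProfile, noise: NoiseModel, seed: int) -> str:
    """Stable hash over the canonical generation parameters."""
    payload = json.dumps(
        {"profile": profile.to_dict(), "noise": noise.to_dict(), "seed": seed},
        sort_keys=True,
        default=str,
    )
    return hashlib.sha256(payload.encode()).hexdigest()


def write_fixture(cohort: Cohort, directory: str | Path) -> dict:
    """Write all entity files plus a manifest; returns the manifest."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    for attr, fname in _ENTITY_FILES.items():
        frame = getattr(cohort, attr)
        frame.to_csv(directory / fname, index=False)
    manifest = {
        "seed": cohort.seed,
        "center": cohort.profile.center,
        "n_exams": cohort.profile.n_exams,
        "profile": cohort.profile.to_dict(),
        "noise": cohort.noise.to_dict(),
        "hash": cohort_hash(cohort.profile, cohort.noise, cohort.seed),
        "files": sorted(_ENTITY_FILES.values()),
    }
    (directory / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True, default=str))
    return manifest


def read_fixture(directory: str | Path) -> Cohort:
    """Re-read a written fixture; inverse of :func:`write_fixture`."""
    directory = Path(directory)
    manifest = json.loads((directory / "manifest.json").read_text())
    frames = {}
    for attr, fname in _ENTITY_FILES.items():
        df = pd.read_csv(directory / fname, keep_default_na=False, dtype=str)
        for col in _DATE_COLUMNS.get(attr, []):
            df[col] = df[col].map(datetime.date.fromisoformat)
        frames[attr] = df
    # restore non-string dtypes
    for col in frames["abstraction"].columns:
        if col not in ("exam_id", "prior_indication"):
            frames["abstraction"][col] = frames["abstraction"][col].astype(int)
    for col in ("missing_record", "prior_incomplete"):
        frames["true_labels"][col] = frames["true_labels"][col].astype(int)
    profile = CenterProfile.from_dict(manifest["profile"])
    noise = NoiseModel.from_dict(manifest["noise"])
    return Cohort(seed=manifest["seed"], profile=profile, noise=noise, **frames)
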