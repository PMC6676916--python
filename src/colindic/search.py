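"""Logistic screening-probability scorer.

A screening-probability model combines code-derived features x with
published coefficients β through a linear predictor η = β0 + Σ βj·xj and
reports p = expit(η), the probability that the exam was performed to
screen for colorectal cancer.  A cutpoint in (0, 1) optionally
dichotomizes p into screening / non-screening (boundary inclusive:
p ≥ c is called screening, which matters for ROC staircase ties).

Because the originally published coefficient set is external
configuration here, :func:`fit_reference_model` can build a working
model by L1-penalized (LASSO) logistic regression of gold-standard
screening status on the registry-derived candidate features of a
training cohort.  Any model it produces is a fixture for exercising the
machinery, not a re-derivation of published coefficients.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.special import expit
from sklearn.linear_model import LogisticRegression

from .config import CodeSetRegistry, ConfigError, SearchModel, SearchTerm, WindowConfig
from .kpnc import category_witnesses
from .types import CodedEvent, ColonoscopyExam, Indication


@dataclass
class FeatureVector:
    """Named feature values for one exam, aligned to a model's terms."""

    exam_id: str
    values: dict[str, float]


@dataclass
class ScreeningScore:
    """Linear predictor, probability, and optional dichotomized label."""

    exam_id: str
    eta: float
    probability: float
    label: Indication | None = None


def extract_features(
    exam: ColonoscopyExam,
    events: list[CodedEvent],
    model: SearchModel,
    registry: CodeSetRegistry,
    cfg: WindowConfig,
) -> FeatureVector:
    """Deterministic, event-order-independent feature extraction.

    Each term counts the qualifying events of its category inside its
    window (the term may narrow the category window); binary aggregation
    collapses the count to presence.
    """
    model.validate_against(registry)
    own = [ev for ev in events if ev.patient_id == exam.patient_id]
    values: dict[str, float] = {}
    for term in model.terms:
        cat = registry.categories[term.category]
        if term.window_days is not None:
            cat = type(cat)(
                name=cat.name,
                indication_class=cat.indication_class,
                window_days=term.window_days,
                entries=cat.entries,
            )
        n = len(category_witnesses(cat, own, exam, cfg))
        values[term.name] = float(min(n, 1) if term.aggregation == "binary" else n)
    return FeatureVector(exam_id=exam.exam_id, values=values)


def screening_probability(fv: FeatureVector, model: SearchModel) -> ScreeningScore:
    """p = expit(β0 + Σ βj·xj); errors name any term the vector lacks."""
    missing = [t.name for t in model.terms if t.name not in fv.values]
    if missing:
        raise ConfigError(f"feature vector missing terms: {', '.join(missing)}")
    eta = model.intercept + sum(t.coefficient * fv.values[t.name] for t in model.terms)
    return ScreeningScore(exam_id=fv.exam_id, eta=float(eta), probability=float(expit(eta)))


def dichotomize(score: ScreeningScore, cutpoint: float) -> Indication:
    """Screening iff p ≥ cutpoint (inclusive boundary)."""
    if not (0.0 < cutpoint < 1.0):
        raise ValueError(f"cutpoint must lie strictly inside (0, 1), got {cutpoint}")
    return Indication.SCREENING if score.probability >= cutpoint else Indication.DIAGNOSTIC


def score_exams(
    exams: list[ColonoscopyExam],
    events: list[CodedEvent],
    model: SearchModel,
    registry: CodeSetRegistry,
    cfg: WindowConfig,
    cutpoint: float | None = None,
) -> pd.DataFrame:
    """Batch scoring: exam_id, eta, probability[, label]."""
    by_patient: dict[str, list[CodedEvent]] = {}
    for ev in events:
        by_patient.setdefault(ev.patient_id, []).append(ev)
    rows = []
    cut = cutpoint if cutpoint is not None else model.cutpoint
    for exam in exams:
        fv = extract_features(exam, by_patient.get(exam.patient_id, []), model, registry, cfg)
        s = screening_probability(fv, model)
        row = {"exam_id": s.exam_id, "eta": s.eta, "probability": s.probability}
        if cut is not None:
            row["label"] = dichotomize(s, cut).value
        rows.append(row)
    return pd.DataFrame(rows)


def candidate_terms(registry: CodeSetRegistry, cfg: WindowConfig) -> list[SearchTerm]:
    """One binary candidate feature per trigger category."""
    terms = []
    for name, cat in sorted(registry.categories.items()):
        if cat.indication_class is None:
            continue
        window = cfg.effective_window(cat)
        terms.append(
            SearchTerm(
                name=f"{name}_{window}d" if window else f"{name}_hx",
                coefficient=0.0,
                category=name,
                window_days=None,
                aggregation="binary",
            )
        )
    return terms


def fit_reference_model(
    exams: list[ColonoscopyExam],
    events: list[CodedEvent],
    gold_labels: dict[str, Indication],
    registry: CodeSetRegistry,
    cfg: WindowConfig,
    penalty: float = 1.0,
    seed: int = 0,
) -> SearchModel:
    """LASSO logistic fit of screening-vs-not on candidate features.

    Builds a working coefficient fixture from a labeled training cohort;
    terms shrunk exactly to zero are dropped.  Raises if the training
    labels contain a single class.
    """
    template = SearchModel(intercept=0.0, terms=candidate_terms(registry, cfg))
    by_patient: dict[str, list[CodedEvent]] = {}
    for ev in events:
        by_patient.setdefault(ev.patient_id, []).append(ev)

    rows, y = [], []
    for exam in exams:
        lab = gold_labels.get(exam.exam_id)
        if lab is None or lab is Indication.MISSING:
            continue
        fv = extract_features(exam, by_patient.get(exam.patient_id, []), template, registry, cfg)
        rows.append([fv.values[t.name] for t in template.terms])
        y.append(1 if lab is Indication.SCREENING else 0)
    X = np.asarray(rows, dtype=float)
    y_arr = np.asarray(y)
    if len(np.unique(y_arr)) < 2:
        raise ValueError("training labels contain a single class; cannot fit")

    kwargs: dict = {"C": 1.0 / penalty, "solver": "liblinear", "random_state": seed, "max_iter": 2000}
    try:  # scikit-learn >= 1.8 spells the L1 penalty via l1_ratio
        clf = LogisticRegression(l1_ratio=1.0, **kwargs)
        clf.fit(X, y_arr)
    except (TypeError, ValueError):
        clf = LogisticRegression(penalty="l1", **kwargs)
        clf.fit(X, y_arr)
    terms = [
        SearchTerm(
            name=t.name,
            coefficient=float(b),
            category=t.category,
            window_days=t.window_days,
            aggregation=t.aggregation,
        )
        for t, b in zip(template.terms, clf.coef_[0])
        if abs(b) > 1e-10
    ]
    return SearchModel(intercept=float(clf.intercept_[0]), terms=terms)
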