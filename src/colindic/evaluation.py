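"""Algorithm-versus-gold evaluation harness.

Per center: confusion matrices (gold-missing exams excluded and
counted), per-class sensitivity and specificity with Wald 95% CIs, ROC
curves and AUC with a DeLong confidence interval, and the
matched-sensitivity comparison in which the probabilistic scorer's
cutpoint is fixed so its sensitivity meets the categorical algorithm's,
and the specificities are compared at that shared operating point.

AUC is computed two ways on every call — trapezoidal integration of the
ROC curve and the Mann–Whitney pair statistic (ties counted one half) —
and both are carried on the result so their agreement is checkable.
The Wald interval p̂ ± 1.96·√(p̂(1−p̂)/n), clipped to [0, 1], is the CI
the validation tables use; it reproduces the published worked examples
from rounded point estimates and the published denominators.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import math
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
import yaml
from scipy.stats import norm, rankdata
from sklearn.metrics import auc as _trapezoid_auc
from sklearn.metrics import roc_curve

from .config import WindowConfig, default_registry
from .gold import batch_assign_gold
from .kpnc import batch_assign, traces_to_frame
from .search import fit_reference_model, score_exams
from .synth import BUILTIN_PROFILES, CenterProfile, NoiseModel, generate_cohort
from .types import Indication, SourceMode

Z95 = norm.ppf(0.975)

CLASSES = (Indication.DIAGNOSTIC, Indication.SURVEILLANCE, Indication.SCREENING)


def wald_ci(p_hat: float, n: int, z: float = Z95) -> tuple[float, float]:
    """Wald normal-approximation CI for a proportion, clipped to [0, 1]."""
    if n <= 0:
        raise ValueError("denominator must be positive")
    half = z * math.sqrt(p_hat * (1.0 - p_hat) / n)
    return (max(0.0, p_hat - half), min(1.0, p_hat + half))


@dataclass
class ConfusionMatrix:
    """3×3 predicted-vs-gold cross-tabulation over non-missing gold."""

    labels: tuple[Indication, ...]
    matrix: np.ndarray  # rows: predicted, cols: gold
    excluded_missing: int

    @property
    def n(self) -> int:
        return int(self.matrix.sum())

    def to_frame(self) -> pd.DataFrame:
        names = [c.value for c in self.labels]
        return pd.DataFrame(self.matrix, index=names, columns=names)


@dataclass
class PerformanceMetric:
    """A proportion with its Wald 95% CI; ``undefined`` marks an empty
    denominator instead of propagating NaN."""

    name: str
    cls: Indication
    estimate: float | None
    n: int
    ci_low: float | None
    ci_high: float | None
    center: str = ""

    @property
    def undefined(self) -> bool:
        return self.estimate is None


def confusion(pred: list[Indication], gold: list[Indication]) -> ConfusionMatrix:
    """Cross-tabulate aligned label lists; gold-missing rows excluded."""
    if len(pred) != len(gold):
        raise ValueError(f"length mismatch: {len(pred)} predictions vs {len(gold)} gold")
    idx = {c: i for i, c in enumerate(CLASSES)}
    m = np.zeros((3, 3), dtype=int)
    excluded = 0
    for p, g in zip(pred, gold):
        if g is Indication.MISSING:
            excluded += 1
            continue
        m[idx[p], idx[g]] += 1
    return ConfusionMatrix(labels=CLASSES, matrix=m, excluded_missing=excluded)


def sens_spec(
    cm: ConfusionMatrix, cls: Indication, center: str = ""
) -> tuple[PerformanceMetric, PerformanceMetric]:
    """Per-class sensitivity and specificity with Wald 95% CIs.

    Sensitivity: gold members of the class predicted as the class.
    Specificity: gold non-members not predicted as the class.
    """
    i = cm.labels.index(cls)
    gold_in = int(cm.matrix[:, i].sum())
    gold_out = cm.n - gold_in
    tp = int(cm.matrix[i, i])
    fp = int(cm.matrix[i, :].sum()) - tp
    tn = gold_out - fp

    def metric(name, num, den):
        if den == 0:
            return PerformanceMetric(name, cls, None, 0, None, None, center)
        p = num / den
        lo, hi = wald_ci(p, den)
        return PerformanceMetric(name, cls, p, den, lo, hi, center)

    return metric("sensitivity", tp, gold_in), metric("specificity", tn, gold_out)


# ---------------------------------------------------------------------------
# ROC / AUC


@dataclass
class RocResult:
    points: pd.DataFrame  # threshold, fpr, tpr
    auc: float  # Mann–Whitney statistic (ties ½)
    auc_trapezoid: float
    ci_low: float
    ci_high: float
    n_pos: int
    n_neg: int


def mann_whitney_auc(scores: np.ndarray, labels: np.ndarray) -> float:
    """AUC as the pair statistic P(score⁺ > score⁻) + ½·P(tie)."""
    pos = labels == 1
    n_pos, n_neg = int(pos.sum()), int((~pos).sum())
    ranks = rankdata(scores)
    return (ranks[pos].sum() - n_pos * (n_pos + 1) / 2.0) / (n_pos * n_neg)


def _delong_variance(scores: np.ndarray, labels: np.ndarray) -> float:
    """DeLong variance of the AUC estimator via midrank placements."""
    x = scores[labels == 1]
    y = scores[labels == 0]
    m, n = len(x), len(y)
    all_ranks = rankdata(np.concatenate([x, y]))
    rx = rankdata(x)
    ry = rankdata(y)
    v10 = (all_ranks[:m] - rx) / n  # placement of each positive among negatives
    v01 = 1.0 - (all_ranks[m:] - ry) / m
    s10 = np.var(v10, ddof=1) if m > 1 else 0.0
    s01 = np.var(v01, ddof=1) if n > 1 else 0.0
    return s10 / m + s01 / n


def roc_auc(
    scores: np.ndarray | list[float],
    labels: np.ndarray | list[int],
    ci_method: str = "delong",
    n_boot: int = 2000,
    seed: int = 0,
) -> RocResult:
    """ROC curve over all distinct cutpoints, AUC, and its 95% CI.

    ``ci_method`` is "delong" (default) or "bootstrap" (seeded
    percentile bootstrap over exams).
    """
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels, dtype=int)
    n_pos = int((labels == 1).sum())
    n_neg = int((labels == 0).sum())
    if n_pos == 0 or n_neg == 0:
        raise ValueError("ROC requires both classes present")

    fpr, tpr, thresholds = roc_curve(labels, scores)
    auc_trap = float(_trapezoid_auc(fpr, tpr))
    auc_mw = float(mann_whitney_auc(scores, labels))

    if ci_method == "delong":
        se = math.sqrt(_delong_variance(scores, labels))
        lo, hi = auc_mw - Z95 * se, auc_mw + Z95 * se
    elif ci_method == "bootstrap":
        rng = np.random.default_rng(seed)
        stats = []
        idx = np.arange(len(scores))
        while len(stats) < n_boot:
            take = rng.choice(idx, size=len(idx), replace=True)
            if labels[take].min() == labels[take].max():
                continue
            stats.append(mann_whitney_auc(scores[take], labels[take]))
        lo, hi = np.percentile(stats, [2.5, 97.5])
    else:
        raise ValueError(f"unknown ci_method {ci_method!r}")

    return RocResult(
        points=pd.DataFrame({"threshold": thresholds, "fpr": fpr, "tpr": tpr}),
        auc=auc_mw,
        auc_trapezoid=auc_trap,
        ci_low=float(max(0.0, lo)),
        ci_high=float(min(1.0, hi)),
        n_pos=n_pos,
        n_neg=n_neg,
    )


# ---------------------------------------------------------------------------
# Matched-sensitivity comparison


@dataclass
class MatchedComparison:
    target_sensitivity: float
    cutpoint: float
    achieved_sensitivity: float
    specificity: PerformanceMetric


def matched_specificity(
    scores: np.ndarray | list[float],
    labels: np.ndarray | list[int],
    target_sens: float,
) -> MatchedComparison:
    """Specificity of the scorer at the categorical algorithm's sensitivity.

    The cutpoint is the *largest* c (among observed score values) whose
    sensitivity under the inclusive rule p ≥ c still meets the target —
    i.e. the operating point maximizing specificity subject to the
    sensitivity floor.
    """
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels, dtype=int)
    if not (0.0 < target_sens <= 1.0):
        raise ValueError(f"target sensitivity must lie in (0, 1], got {target_sens}")
    pos = scores[labels == 1]
    neg = scores[labels == 0]
    if len(pos) == 0:
        raise ValueError("no positive exams; target sensitivity unreachable")

    best_c = None
    for c in sorted(np.unique(scores), reverse=True):
        if (pos >= c).mean() >= target_sens:
            best_c = float(c)
            break
    assert best_c is not None  # c = min(scores) always yields sensitivity 1
    achieved = float((pos >= best_c).mean())
    spec_hat = float((neg < best_c).mean()) if len(neg) else None
    if spec_hat is None:
        spec_metric = PerformanceMetric("specificity", Indication.SCREENING, None, 0, None, None)
    else:
        lo, hi = wald_ci(spec_hat, len(neg))
        spec_metric = PerformanceMetric(
            "specificity", Indication.SCREENING, spec_hat, len(neg), lo, hi
        )
    return MatchedComparison(
        target_sensitivity=float(target_sens),
        cutpoint=best_c,
        achieved_sensitivity=achieved,
        specificity=spec_metric,
    )


# ---------------------------------------------------------------------------
# Results container and pipeline


@dataclass
class CenterEvaluation:
    """All evaluation output for one center (Results-style object)."""

    center: str
    n_exams: int
    excluded_missing: int
    confusion: ConfusionMatrix
    kpnc_metrics: list[PerformanceMetric]
    roc: RocResult
    matched: MatchedComparison

    def summary(self) -> pd.DataFrame:
        rows = [
            {
                "center": self.center,
                "algorithm": "kpnc",
                "class": m.cls.value,
                "metric": m.name,
                "estimate": m.estimate,
                "ci_low": m.ci_low,
                "ci_high": m.ci_high,
                "n": m.n,
            }
            for m in self.kpnc_metrics
        ]
        rows.append(
            {
                "center": self.center,
                "algorithm": "search",
                "class": "screening",
                "metric": "auc",
                "estimate": self.roc.auc,
                "ci_low": self.roc.ci_low,
                "ci_high": self.roc.ci_high,
                "n": self.roc.n_pos + self.roc.n_neg,
            }
        )
        sm = self.matched.specificity
        rows.append(
            {
                "center": self.center,
                "algorithm": "search",
                "class": "screening",
                "metric": "specificity_at_matched_sensitivity",
                "estimate": sm.estimate,
                "ci_low": sm.ci_low,
                "ci_high": sm.ci_high,
                "n": sm.n,
            }
        )
        return pd.DataFrame(rows)


def evaluate_center(
    center: str,
    kpnc_labels: list[Indication],
    scores: np.ndarray | list[float],
    gold: list[Indication],
) -> CenterEvaluation:
    """Evaluate one center given aligned predictions, scores, and gold."""
    cm = confusion(kpnc_labels, gold)
    metrics: list[PerformanceMetric] = []
    for cls in (Indication.SCREENING, Indication.DIAGNOSTIC, Indication.SURVEILLANCE):
        se, sp = sens_spec(cm, cls, center)
        metrics.extend([se, sp])

    keep = [g is not Indication.MISSING for g in gold]
    sc = np.asarray(scores, dtype=float)[keep]
    binary = np.array([1 if g is Indication.SCREENING else 0 for g, k in zip(gold, keep) if k])
    roc = roc_auc(sc, binary)

    kpnc_screen_sens = next(
        m for m in metrics if m.cls is Indication.SCREENING and m.name == "sensitivity"
    )
    target = kpnc_screen_sens.estimate if kpnc_screen_sens.estimate else 1.0
    matched = matched_specificity(sc, binary, target)

    return CenterEvaluation(
        center=center,
        n_exams=len(gold),
        excluded_missing=cm.excluded_missing,
        confusion=cm,
        kpnc_metrics=metrics,
        roc=roc,
        matched=matched,
    )


def _config_hash(config: dict) -> str:
    # out_dir names the destination, not the computation: exclude it so
    # the same run written to two places is recognizably the same run.
    payload = {k: v for k, v in config.items() if k != "out_dir"}
    return hashlib.sha256(
        json.dumps(payload, sort_keys=True, default=str).encode()
    ).hexdigest()


DEFAULT_PIPELINE_CONFIG = {
    "seed": 0,
    "centers": ["kpwa", "kpnc_sc", "parkland"],
    "n_exams": None,  # per-center default (the study sample sizes)
    "n_train": 2000,
    "noise": {},  # NoiseModel fields; empty → noise-free
    "lasso_penalty": 1.0,
    "mode": "comprehensive",
    "out_dir": "pipeline_out",
}


def run_pipeline(config: dict | str | Path) -> dict:
    """Full synthetic validation pipeline; returns the run log.

    For each configured center: generate an evaluation cohort and an
    independent training cohort, fit the reference screening model on
    the training cohort's gold labels, classify the evaluation cohort
    with both algorithms, assign the gold standard, and evaluate.
    Emits ``table3.csv`` (screening comparison), ``table4.csv``
    (diagnostic/surveillance), per-center ROC coordinate files, the
    long-format ``metrics.csv`` and a ``run_log.json`` with the seed and
    config hash.  Outputs are byte-identical for identical config+seed.
    """
    if not isinstance(config, dict):
        config = yaml.safe_load(Path(config).read_text())
    cfg_full = {**DEFAULT_PIPELINE_CONFIG, **config}
    out_dir = Path(cfg_full["out_dir"])
    out_dir.mkdir(parents=True, exist_ok=True)

    registry = default_registry()
    wcfg = WindowConfig()
    noise = NoiseModel.from_dict(dict(cfg_full["noise"]))
    mode = SourceMode(cfg_full["mode"])
    seed = int(cfg_full["seed"])

    evaluations: list[CenterEvaluation] = []
    log_centers = {}
    for k, name in enumerate(cfg_full["centers"]):
        profile = BUILTIN_PROFILES[name]() if name in BUILTIN_PROFILES else CenterProfile.from_dict(name)
        if cfg_full["n_exams"]:
            profile.n_exams = int(cfg_full["n_exams"])
        eval_seed = seed * 1000 + 2 * k
        train_seed = seed * 1000 + 2 * k + 1

        cohort = generate_cohort(profile, noise, registry, wcfg, eval_seed)
        train_profile = dataclasses.replace(profile, n_exams=int(cfg_full["n_train"]))
        train = generate_cohort(train_profile, noise, registry, wcfg, train_seed)

        train_gold = batch_assign_gold(
            train.abstraction_records(), train.event_objects(), train.exam_objects(),
            registry, wcfg, SourceMode.COMPREHENSIVE,
        )
        model = fit_reference_model(
            train.exam_objects(),
            train.event_objects(),
            {r.exam_id: Indication(r.gold) for r in train_gold.itertuples()},
            registry,
            wcfg,
            penalty=float(cfg_full["lasso_penalty"]),
            seed=seed,
        )

        exams = cohort.exam_objects()
        events = cohort.event_objects()
        traces = batch_assign(exams, events, registry, wcfg, cohort.enrollment_objects())
        kpnc_labels = [t.indication for t in traces]
        score_frame = score_exams(exams, events, model, registry, wcfg)
        gold_frame = batch_assign_gold(
            cohort.abstraction_records(), events, exams, registry, wcfg, mode
        )
        gold = [Indication(g) for g in gold_frame["gold"]]

        ev = evaluate_center(profile.center, kpnc_labels, score_frame["probability"].to_numpy(), gold)
        evaluations.append(ev)
        log_centers[profile.center] = {
            "n_exams": ev.n_exams,
            "excluded_missing": ev.excluded_missing,
            "n_evaluated": ev.confusion.n,
            "model_terms": len(model.terms),
        }
        ev.roc.points.to_csv(
            out_dir / f"roc_{profile.center}.csv", index=False, float_format="%.6f"
        )
        traces_to_frame(traces).to_csv(out_dir / f"kpnc_{profile.center}.csv", index=False)

    metrics = pd.concat([ev.summary() for ev in evaluations], ignore_index=True)
    metrics.to_csv(out_dir / "metrics.csv", index=False, float_format="%.6f")

    t3_rows, t4_rows = [], []
    for ev in evaluations:
        by = {(m.cls, m.name): m for m in ev.kpnc_metrics}
        se = by[(Indication.SCREENING, "sensitivity")]
        sp = by[(Indication.SCREENING, "specificity")]
        t3_rows.append(
            {
                "center": ev.center,
                "search_auc": ev.roc.auc,
                "search_auc_ci_low": ev.roc.ci_low,
                "search_auc_ci_high": ev.roc.ci_high,
                "search_spec_at_matched_sens": ev.matched.specificity.estimate,
                "search_spec_ci_low": ev.matched.specificity.ci_low,
                "search_spec_ci_high": ev.matched.specificity.ci_high,
                "kpnc_sens": se.estimate,
                "kpnc_sens_ci_low": se.ci_low,
                "kpnc_sens_ci_high": se.ci_high,
                "kpnc_spec": sp.estimate,
                "kpnc_spec_ci_low": sp.ci_low,
                "kpnc_spec_ci_high": sp.ci_high,
            }
        )
        row = {"center": ev.center}
        for cls in (Indication.DIAGNOSTIC, Indication.SURVEILLANCE):
            for name in ("sensitivity", "specificity"):
                m = by[(cls, name)]
                key = f"{cls.value}_{name}"
                row[key] = m.estimate
                row[f"{key}_ci_low"] = m.ci_low
                row[f"{key}_ci_high"] = m.ci_high
        t4_rows.append(row)
    pd.DataFrame(t3_rows).to_csv(out_dir / "table3.csv", index=False, float_format="%.6f")
    pd.DataFrame(t4_rows).to_csv(out_dir / "table4.csv", index=False, float_format="%.6f")

    run_log = {
        "seed": seed,
        "config_hash": _config_hash(cfg_full),
        "mode": mode.value,
        "centers": log_centers,
    }
    (out_dir / "run_log.json").write_text(json.dumps(run_log, indent=2, sort_keys=True))
    return run_log
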