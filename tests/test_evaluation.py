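"""Evaluation harness: confusion, Wald CIs, ROC/AUC, matched operating point."""

import math

import numpy as np
import pytest

from colindic import (
    Indication,
    confusion,
    matched_specificity,
    roc_auc,
    sens_spec,
    wald_ci,
)

D, S, V, M = (
    Indication.DIAGNOSTIC,
    Indication.SCREENING,
    Indication.SURVEILLANCE,
    Indication.MISSING,
)


# ---------------------------------------------------------------------------
# confusion matrices


def test_identity_predictions_give_diagonal_matrix():
    labels = [D] * 4 + [S] * 3 + [V] * 3
    cm = confusion(labels, labels)
    assert np.trace(cm.matrix) == 10 == cm.n
    assert cm.excluded_missing == 0


def test_gold_missing_rows_excluded_and_counted():
    pred = [D, S, V, D, S, V, D, S, V, D]
    gold = [D, S, V, M, M, M, D, S, V, D]
    cm = confusion(pred, gold)
    assert cm.n == 7
    assert cm.excluded_missing == 3


def test_length_mismatch_rejected():
    with pytest.raises(ValueError):
        confusion([D], [D, S])


def test_cell_sums_match_brute_force_tally():
    rng = np.random.default_rng(42)
    classes = [D, S, V, M]
    for _ in range(50):
        n = int(rng.integers(1, 40))
        pred = [classes[i] for i in rng.integers(0, 3, n)]
        gold = [classes[i] for i in rng.integers(0, 4, n)]
        cm = confusion(pred, gold)
        for i, p in enumerate(cm.labels):
            for j, g in enumerate(cm.labels):
                brute = sum(1 for a, b in zip(pred, gold) if a is p and b is g)
                assert cm.matrix[i, j] == brute
        assert cm.n + cm.excluded_missing == n


# ---------------------------------------------------------------------------
# sensitivity / specificity with Wald CIs


@pytest.mark.parametrize(
    "p_hat, n, expected",
    [
        (0.82, 246, (0.77, 0.87)),  # screening sensitivity worked example
        (0.89, 232, (0.85, 0.93)),  # diagnostic sensitivity worked example
        (0.67, 132, (0.59, 0.75)),  # surveillance sensitivity worked example
        (1.00, 558, (1.00, 1.00)),  # boundary estimate clips to [0, 1]
    ],
)
def test_wald_ci_reproduces_worked_examples(p_hat, n, expected):
    lo, hi = wald_ci(p_hat, n)
    assert (round(lo, 2), round(hi, 2)) == expected


def test_wald_ci_formula():
    lo, hi = wald_ci(0.6, 100)
    half = 1.959963984540054 * math.sqrt(0.6 * 0.4 / 100)
    assert lo == pytest.approx(0.6 - half)
    assert hi == pytest.approx(0.6 + half)


def test_sens_spec_counting():
    #          gold:  D  D  D  S  S  V
    pred = [D, D, S, S, S, D]
    gold = [D, D, D, S, S, V]
    cm = confusion(pred, gold)
    sens, spec = sens_spec(cm, D)
    assert sens.estimate == pytest.approx(2 / 3) and sens.n == 3
    # non-diagnostic gold: S,S,V; predicted-diagnostic among them: the V exam
    assert spec.estimate == pytest.approx(2 / 3) and spec.n == 3
    s_sens, s_spec = sens_spec(cm, S)
    assert s_sens.estimate == pytest.approx(1.0)
    assert s_spec.estimate == pytest.approx(3 / 4)


def test_zero_denominator_yields_undefined_marker():
    cm = confusion([D, D], [D, D])
    sens, spec = sens_spec(cm, S)
    assert sens.undefined and sens.estimate is None
    assert spec.estimate == pytest.approx(1.0)


# ---------------------------------------------------------------------------
# ROC / AUC


def test_perfect_separation_auc_one():
    r = roc_auc([0.9, 0.8, 0.7, 0.2, 0.1], [1, 1, 1, 0, 0])
    assert r.auc == 1.0 == r.auc_trapezoid
    assert r.ci_high <= 1.0


def test_auc_equals_exhaustive_pair_count():
    scores = [0.9, 0.8, 0.4, 0.7, 0.3, 0.2]
    labels = [1, 1, 1, 0, 0, 0]
    r = roc_auc(scores, labels)
    assert r.auc == pytest.approx(8 / 9)
    assert r.auc_trapezoid == pytest.approx(8 / 9)


def test_trapezoid_equals_mann_whitney_with_ties():
    """Dual-computation identity, including tied scores (½ credit)."""
    rng = np.random.default_rng(7)
    for _ in range(200):
        n = int(rng.integers(4, 50))
        labels = rng.integers(0, 2, n)
        if labels.min() == labels.max():
            continue
        scores = np.round(rng.random(n), 1)  # coarse grid forces ties
        r = roc_auc(scores, labels)
        # brute-force pair statistic
        pos = scores[labels == 1]
        neg = scores[labels == 0]
        pairs = [(1.0 if a > b else 0.5 if a == b else 0.0) for a in pos for b in neg]
        brute = float(np.mean(pairs))
        assert r.auc == pytest.approx(brute, abs=1e-12)
        assert r.auc_trapezoid == pytest.approx(brute, abs=1e-12)


def test_null_scores_auc_near_half():
    rng = np.random.default_rng(3)
    scores = rng.random(2000)
    labels = rng.integers(0, 2, 2000)
    r = roc_auc(scores, labels)
    assert 0.45 < r.auc < 0.55


def test_single_class_input_rejected():
    with pytest.raises(ValueError):
        roc_auc([0.5, 0.6], [1, 1])


def test_delong_ci_brackets_auc_and_shrinks_with_n():
    rng = np.random.default_rng(5)

    def width(n):
        pos = rng.normal(1.0, 1.0, n)
        neg = rng.normal(0.0, 1.0, n)
        r = roc_auc(
            np.concatenate([pos, neg]), np.r_[np.ones(n, int), np.zeros(n, int)]
        )
        assert r.ci_low <= r.auc <= r.ci_high
        return r.ci_high - r.ci_low

    assert width(500) < width(50)


def test_bootstrap_ci_close_to_delong():
    rng = np.random.default_rng(9)
    pos = rng.normal(0.8, 1.0, 120)
    neg = rng.normal(0.0, 1.0, 150)
    scores = np.concatenate([pos, neg])
    labels = np.r_[np.ones(120, int), np.zeros(150, int)]
    d = roc_auc(scores, labels, ci_method="delong")
    b = roc_auc(scores, labels, ci_method="bootstrap", n_boot=500, seed=1)
    assert d.ci_low == pytest.approx(b.ci_low, abs=0.03)
    assert d.ci_high == pytest.approx(b.ci_high, abs=0.03)


# ---------------------------------------------------------------------------
# matched-sensitivity comparison


def _brute_matched(scores, labels, target):
    """Sweep every threshold interval; return (cutpoint, specificity) of
    the highest-specificity operating point meeting the sensitivity floor."""
    scores = np.asarray(scores, float)
    labels = np.asarray(labels, int)
    pos, neg = scores[labels == 1], scores[labels == 0]
    best = None
    for c in np.unique(scores):
        sens = (pos >= c).mean()
        spec = (neg < c).mean()
        if sens >= target and (best is None or spec > best[1] or (spec == best[1] and c > best[0])):
            best = (float(c), float(spec))
    return best


def test_matched_specificity_brute_force_example():
    scores = [0.9, 0.8, 0.7, 0.4, 0.3, 0.2]
    labels = [1, 1, 0, 1, 0, 0]
    m = matched_specificity(scores, labels, 2 / 3)
    assert m.cutpoint == pytest.approx(0.8)
    assert m.achieved_sensitivity == pytest.approx(2 / 3)
    brute = _brute_matched(scores, labels, 2 / 3)
    assert (m.cutpoint, m.specificity.estimate) == pytest.approx(brute)


def test_matched_specificity_perfect_separation():
    m = matched_specificity([0.9, 0.8, 0.2, 0.1], [1, 1, 0, 0], 1.0)
    assert m.specificity.estimate == 1.0
    assert m.achieved_sensitivity == 1.0


def test_matched_agrees_with_brute_force_on_random_cohorts():
    rng = np.random.default_rng(11)
    for _ in range(100):
        n = int(rng.integers(6, 60))
        labels = rng.integers(0, 2, n)
        if labels.min() == labels.max():
            continue
        scores = np.round(rng.random(n), 2)
        target = float(rng.uniform(0.2, 1.0))
        m = matched_specificity(scores, labels, target)
        c, spec = _brute_matched(scores, labels, target)
        assert m.specificity.estimate == pytest.approx(spec)
        assert m.achieved_sensitivity >= target - 1e-12


def test_specificity_non_increasing_in_target():
    rng = np.random.default_rng(13)
    scores = rng.random(300)
    labels = (scores + rng.normal(0, 0.3, 300) > 0.5).astype(int)
    specs = [
        matched_specificity(scores, labels, t).specificity.estimate
        for t in np.linspace(0.1, 1.0, 10)
    ]
    assert all(b <= a + 1e-12 for a, b in zip(specs, specs[1:]))


def test_invalid_target_rejected():
    with pytest.raises(ValueError):
        matched_specificity([0.5, 0.6], [1, 0], 1.5)
    with pytest.raises(ValueError):
        matched_specificity([0.5, 0.6], [1, 0], 0.0)
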