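"""Synthetic cohort generator: determinism, calibration, fixtures."""

from colindic import ConfigError, NoiseModel, generate_cohort

import dataclasses

import numpy as np
import pandas as pd
import pytest

from colindic.synth import (
    CenterProfile,
    conditional_symptom_rates,
    cohort_hash,
    kpnc_sc_profile,
    kpwa_profile,
    parkland_profile,
    read_fixture,
    write_fixture,
)
from colindic.types import FINDINGS, SOURCES


def test_builtin_profiles_match_published_margins():
    """The bundled profiles carry the three-center study margins."""
    kpwa = kpwa_profile()
    assert kpwa.n_exams == 600
    # mixture normalized over the 573 non-missing gold rows
    assert kpwa.indication_mixture["diagnostic"] == pytest.approx(232 / 573)
    assert kpwa.missingness_rate == pytest.approx(23 / 600)
    assert kpwa.symptom_prevalence["rectal_bleeding"] == pytest.approx(63 / 600)
    kpnc = kpnc_sc_profile()
    assert kpnc.indication_mixture["surveillance"] == pytest.approx(106 / 599)
    assert kpnc.symptom_prevalence["positive_fit_fobt"] == pytest.approx(131 / 600)
    park = parkland_profile()
    assert park.n_exams == 596
    assert park.missingness_rate == 0.0
    assert park.symptom_prevalence["abdominal_pain"] == pytest.approx(110 / 596)


def test_unnormalizable_mixture_rejected():
    with pytest.raises(ConfigError):
        CenterProfile(
            center="X",
            n_exams=10,
            indication_mixture={"diagnostic": 0, "screening": 0, "surveillance": 0},
            symptom_prevalence={},
        )


def test_empty_cohort(registry, wcfg):
    profile = dataclasses.replace(kpnc_sc_profile(), n_exams=0)
    cohort = generate_cohort(profile, NoiseModel(), registry, wcfg, seed=1)
    for frame in (cohort.patients, cohort.events, cohort.exams, cohort.abstraction):
        assert len(frame) == 0


def test_same_seed_reproduces_byte_identical_fixture(tmp_path, registry, wcfg):
    profile = dataclasses.replace(kpwa_profile(), n_exams=60)
    for sub in ("a", "b"):
        cohort = generate_cohort(profile, NoiseModel.realistic(), registry, wcfg, seed=5)
        write_fixture(cohort, tmp_path / sub)
    for f in (tmp_path / "a").iterdir():
        assert f.read_bytes() == (tmp_path / "b" / f.name).read_bytes()


def test_different_seed_changes_output(registry, wcfg):
    profile = dataclasses.replace(kpwa_profile(), n_exams=60)
    a = generate_cohort(profile, NoiseModel(), registry, wcfg, seed=1)
    b = generate_cohort(profile, NoiseModel(), registry, wcfg, seed=2)
    assert not a.true_labels.equals(b.true_labels)


def test_fixture_roundtrip_equals_in_memory(tmp_path, registry, wcfg):
    profile = dataclasses.replace(kpnc_sc_profile(), n_exams=40)
    cohort = generate_cohort(profile, NoiseModel.realistic(), registry, wcfg, seed=9)
    manifest = write_fixture(cohort, tmp_path)
    assert len(manifest["files"]) == 6
    again = read_fixture(tmp_path)
    for attr in ("patients", "enrollment", "events", "exams", "abstraction", "true_labels"):
        pd.testing.assert_frame_equal(getattr(cohort, attr), getattr(again, attr))
    assert again.seed == cohort.seed
    assert again.profile.to_dict() == cohort.profile.to_dict()


def test_manifest_hash_tracks_parameters():
    base = kpwa_profile()
    noise = NoiseModel()
    h0 = cohort_hash(base, noise, 1)
    assert cohort_hash(base, noise, 2) != h0
    assert cohort_hash(dataclasses.replace(base, n_exams=601), noise, 1) != h0
    assert cohort_hash(base, NoiseModel(code_emission_sensitivity=0.9), 1) != h0
    assert cohort_hash(kpwa_profile(), NoiseModel(), 1) == h0


def test_structural_invariants(noise_free_cohort, wcfg):
    """Label-consistent findings; labs dated inside their windows."""
    cohort = noise_free_cohort
    tl = cohort.true_labels.set_index("exam_id")
    assert (tl.missing_record == 0).all()
    diag = tl[tl.true_indication == "diagnostic"]
    assert (diag.findings != "").all()
    surv = tl[tl.true_indication == "surveillance"]
    assert (surv.histories != "").all() and (surv.findings == "").all()
    screen = tl[tl.true_indication == "screening"]
    assert (screen.findings == "").all() and (screen.histories == "").all()

    # lab events inside their look-back windows, strictly before the exam
    exam_dates = cohort.exams.set_index("patient_id").exam_date
    labs = cohort.events[cohort.events.code_type == "LAB"]
    for r in labs.itertuples():
        delta = (exam_dates[r.patient_id] - r.date).days
        window = wcfg.fit_fobt_window_days if r.code in ("FIT", "FOBT") else wcfg.ida_window_days
        assert 1 <= delta <= window


def test_enrollment_covers_lookback(noise_free_cohort, wcfg):
    merged = noise_free_cohort.exams.merge(noise_free_cohort.enrollment, on="patient_id")
    lookback = (merged.exam_date - merged.start_date).dt.days if hasattr(
        merged.exam_date, "dt"
    ) else (merged.exam_date - merged.start_date).map(lambda d: d.days)
    assert (lookback >= wcfg.enrollment_lookback_days).all()


def test_mixture_calibration_at_scale(registry, wcfg):
    """Empirical mixture within 3 Monte-Carlo SE of configured values."""
    profile = kpnc_sc_profile(n_exams=5000)
    cohort = generate_cohort(profile, NoiseModel(), registry, wcfg, seed=11)
    n = len(cohort.true_labels)
    for cls, p_cfg in profile.indication_mixture.items():
        emp = (cohort.true_labels.true_indication == cls).mean()
        se = np.sqrt(p_cfg * (1 - p_cfg) / n)
        assert abs(emp - p_cfg) <= 3 * se, cls


def test_symptom_prevalence_calibration_at_scale(registry, wcfg):
    """Abstracted marginal prevalences converge to the configured ones."""
    profile = kpnc_sc_profile(n_exams=5000)
    cohort = generate_cohort(profile, NoiseModel(), registry, wcfg, seed=11)
    ab = cohort.abstraction
    n = len(ab)
    for f in ("rectal_bleeding", "positive_fit_fobt", "abdominal_pain", "iron_deficiency_anemia"):
        cols = [f"{s}.{f}" for s in SOURCES]
        emp = (ab[cols].sum(axis=1) > 0).mean()
        target = profile.symptom_prevalence[f]
        se = np.sqrt(target * (1 - target) / n)
        assert abs(emp - target) <= 3 * se, f


def test_conditional_rate_fixed_point_reproduces_targets():
    """The calibrated within-diagnostic rates yield the marginal targets
    under condition-on-nonempty sampling (checked analytically)."""
    profile = kpwa_profile()
    q = conditional_symptom_rates(profile)
    p0 = np.prod(1 - q)
    p_dx_eff = profile.indication_mixture["diagnostic"] * (1 - profile.missingness_rate)
    implied_marginals = q / (1 - p0) * p_dx_eff
    targets = np.array([profile.symptom_prevalence[f] for f in FINDINGS])
    np.testing.assert_allclose(implied_marginals, targets, atol=1e-9)


def test_missing_record_exams_carry_no_signal(registry, wcfg):
    profile = dataclasses.replace(kpwa_profile(), n_exams=400, missingness_rate=0.3)
    cohort = generate_cohort(profile, NoiseModel(), registry, wcfg, seed=3)
    missing_ids = set(
        cohort.true_labels[cohort.true_labels.missing_record == 1].exam_id
    )
    assert missing_ids  # 30% of 400
    missing_pats = set(
        cohort.exams[cohort.exams.exam_id.isin(missing_ids)].patient_id
    )
    assert not cohort.events.patient_id.isin(missing_pats).any()
    ab = cohort.abstraction.set_index("exam_id")
    present_cols = [f"source_present.{s}" for s in SOURCES]
    assert (ab.loc[sorted(missing_ids), present_cols] == 0).all().all()
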