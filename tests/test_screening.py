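"""Eligibility rules, risk model, screen scheduling, detection and cure."""

import math

import numpy as np
import pytest
from scipy.special import expit

from lungscreen.errors import ConfigurationError, RiskModelNotApplicable
from lungscreen.natural_history import HISTOLOGIES, STAGES, Tumor
from lungscreen.screening import (
    AdherenceModel,
    DEFAULT_PLCO_COEFFICIENTS,
    LifeHistory,
    PackyearRule,
    PLCOCovariates,
    RiskRule,
    ScreeningStrategy,
    apply_adherence,
    apply_screening,
    plco_risk,
    schedule_screens,
    uspstf_eligible,
)

from conftest import never_smoker, smoker

RULE = PackyearRule(min_packyears=20, max_quit_years=15, age_lo=50, age_hi=80)


class TestUSPSTFEligibility:
    def test_eligible_with_sufficient_exposure(self):
        # 25 packyears by 45, quit 10 years before evaluation at 55
        h = smoker(start=20, quit=45, cpd=20)
        assert uspstf_eligible(h, 55.0, RULE)

    def test_just_below_packyear_threshold(self):
        h = smoker(start=20, quit=39.9, cpd=20)  # 19.9 packyears
        assert not uspstf_eligible(h, 55.0, RULE)

    def test_quit_too_long_ago(self):
        h = smoker(start=19, quit=59, cpd=20)  # 40 packyears, quit 16 y before 75
        assert not uspstf_eligible(h, 75.0, RULE)

    def test_age_window_closed(self):
        h = smoker(start=20, quit=None, cpd=20)
        assert uspstf_eligible(h, 50.0, RULE)
        assert uspstf_eligible(h, 80.0, RULE)
        assert not uspstf_eligible(h, 49.0, RULE)
        assert not uspstf_eligible(h, 81.0, RULE)


def centered_covariates(**overrides):
    c = DEFAULT_PLCO_COEFFICIENTS
    base = dict(
        age=c.age_center,
        education=c.education_center,
        bmi=c.bmi_center,
        copd=False,
        personal_cancer_history=False,
        family_lung_cancer=False,
        smoking_status="former",
        cpd=10.0 / c.cpd_center,  # makes (cpd/10)^-1 equal its centering value
        duration_years=c.duration_center,
        quit_years=c.quit_years_center,
    )
    base.update(overrides)
    return PLCOCovariates(**base)


class TestPLCORisk:
    def test_centered_covariates_give_logistic_intercept(self):
        risk = plco_risk(centered_covariates())
        assert risk == pytest.approx(float(expit(DEFAULT_PLCO_COEFFICIENTS.intercept)))

    def test_never_smoker_rejected(self):
        with pytest.raises(RiskModelNotApplicable):
            plco_risk(centered_covariates(cpd=0.0, duration_years=0.0))

    def test_monotone_in_duration_and_cpd(self):
        """Longer or heavier smoking never decreases risk, other things fixed."""
        for dur in (5, 10, 20, 30, 50):
            r_lo = plco_risk(centered_covariates(duration_years=dur))
            r_hi = plco_risk(centered_covariates(duration_years=2 * dur))
            assert r_hi >= r_lo
        for cpd in (2, 5, 10, 20, 40):
            r_lo = plco_risk(centered_covariates(cpd=cpd))
            r_hi = plco_risk(centered_covariates(cpd=cpd * 1.5))
            assert r_hi >= r_lo

    def test_threshold_comparison_is_inclusive(self):
        cov = centered_covariates()
        risk = plco_risk(cov)
        rule = RiskRule(risk_threshold=risk, age_lo=55, age_hi=75)
        h = smoker(start=20, quit=52, cpd=cov.cpd)
        from lungscreen.screening import risk_eligible

        # construct a history whose covariates at 62 reproduce `cov` exactly
        h = smoker(start=62 - cov.duration_years - cov.quit_years,
                   quit=62 - cov.quit_years, cpd=cov.cpd)
        assert risk_eligible(h, 62.0, rule, cov)


class TestScheduling:
    def test_annual_count_over_full_window(self):
        h = smoker(start=20, quit=None, cpd=20)
        strat = ScreeningStrategy("annual", PackyearRule(age_lo=55, age_hi=75))
        assert len(schedule_screens(strat, h)) == 21

    def test_biennial_count_over_full_window(self):
        h = smoker(start=20, quit=None, cpd=20)
        strat = ScreeningStrategy(
            "biennial", PackyearRule(age_lo=55, age_hi=75), interval_years=2
        )
        assert len(schedule_screens(strat, h)) == 11

    def test_schedule_truncates_when_quit_cap_exceeded(self):
        # quit at 47 with 27 packyears: years-since-quit exceeds 15 from age 63
        h = smoker(start=20, quit=47, cpd=20)
        strat = ScreeningStrategy("annual", PackyearRule(age_lo=55, age_hi=75))
        ages = schedule_screens(strat, h)
        assert ages == list(range(55, 63))

    def test_start_age_bounds_schedule(self):
        h = smoker(start=20, quit=None, cpd=20)
        strat = ScreeningStrategy("annual", PackyearRule(age_lo=55, age_hi=75))
        assert schedule_screens(strat, h, start_age=60.0) == list(range(60, 76))

    def test_never_smoker_never_scheduled(self):
        strat = ScreeningStrategy("annual", PackyearRule())
        assert schedule_screens(strat, never_smoker()) == []


class TestAdherence:
    def test_full_adherence_keeps_schedule(self, rng):
        assert apply_adherence([55, 56, 57], AdherenceModel(), rng) == [55, 56, 57]

    def test_zero_attendance_empty(self, rng):
        model = AdherenceModel(attend_prob=0.0, structural_fraction=0.5)
        assert apply_adherence([55, 56], model, rng) == []

    def test_reduced_adherence_hits_target_attendance(self):
        """attend 0.5 / structural 0.5: a quarter attends nothing and the
        overall attended fraction is one half."""
        model = AdherenceModel(attend_prob=0.5, structural_fraction=0.5)
        rng = np.random.default_rng(9)
        schedule = list(range(55, 76))
        n = 20_000
        attended = 0
        nothing = 0
        for _ in range(n):
            got = apply_adherence(schedule, model, rng)
            attended += len(got)
            nothing += not got
        frac = attended / (n * len(schedule))
        assert frac == pytest.approx(0.5, abs=0.01)
        # structural non-attenders plus a few all-miss stochastic outcomes
        assert nothing / n == pytest.approx(0.25, abs=0.015)

    def test_infeasible_model_rejected(self):
        with pytest.raises(ConfigurationError):
            AdherenceModel(attend_prob=0.9, structural_fraction=1.5)
        with pytest.raises(ConfigurationError):
            AdherenceModel(attend_prob=-0.1, structural_fraction=0.5)


def make_tumor(onset=58.0, det=66.0):
    return Tumor(
        onset_age=onset,
        histology="AD",
        stage_entry_ages=(onset, onset + 2, onset + 3, onset + 4, onset + 5, onset + 6),
        clinical_detection_age=det,
        stage_at_clinical_detection="IV",
    )


SENS_ONE = {(s, h): 1.0 for s in STAGES for h in HISTOLOGIES}
SENS_ZERO = {(s, h): 0.0 for s in STAGES for h in HISTOLOGIES}
CURE_ONE = {s: 1.0 for s in STAGES}
CURE_ZERO = {s: 0.0 for s in STAGES}
STRATEGY = ScreeningStrategy("annual", PackyearRule(age_lo=55, age_hi=75))


def life_history(tumor=None, oc=85.0, lc=None):
    return LifeHistory(
        history=smoker(start=20, quit=None, cpd=20),
        oc_death_age=oc,
        tumor=tumor,
        lc_death_age_unscreened=lc,
    )


class TestApplyScreening:
    def test_zero_sensitivity_changes_nothing_but_screens(self, rng):
        lh = life_history(make_tumor(), lc=68.0)
        out = apply_screening(lh, STRATEGY, SENS_ZERO, CURE_ZERO, rng)
        assert out.detection_age is None
        assert out.lc_death_age == 68.0
        assert out.attended_ages  # screening still happened (and costs money)

    def test_perfect_screening_cures_preclinical_cancer(self, rng):
        lh = life_history(make_tumor(onset=58.0, det=66.0), lc=68.0)
        out = apply_screening(lh, STRATEGY, SENS_ONE, CURE_ONE, rng)
        assert out.detection_age == 58.0  # first screen after onset
        assert out.cured and out.lc_death_age is None

    def test_not_cured_keeps_unscreened_death_time_exactly(self, rng):
        lh = life_history(make_tumor(), lc=68.25)
        out = apply_screening(lh, STRATEGY, SENS_ONE, CURE_ZERO, rng)
        assert out.detection_age is not None and not out.cured
        assert out.lc_death_age == 68.25

    def test_lead_time_never_negative(self):
        rng = np.random.default_rng(3)
        sens = {(s, h): 0.5 for s in STAGES for h in HISTOLOGIES}
        for i in range(300):
            det = 60.0 + (i % 120) / 6.0
            lh = life_history(make_tumor(onset=det - 6.0, det=det), lc=det + 1.5)
            out = apply_screening(lh, STRATEGY, sens, CURE_ZERO, rng)
            if out.detection_age is not None:
                assert out.lead_time_years >= 0.0

    def test_no_screens_after_death_or_diagnosis(self, rng):
        lh = life_history(make_tumor(onset=50.0, det=58.0), oc=62.0, lc=60.0)
        out = apply_screening(lh, STRATEGY, SENS_ZERO, CURE_ZERO, rng)
        assert all(a < 58.0 for a in out.attended_ages)

    def test_missing_sensitivity_cell_raises(self, rng):
        lh = life_history(make_tumor())
        bad = dict(SENS_ONE)
        del bad[("IV", "AD")]
        # tumor reaches stage IV while preclinical at later screens
        lh2 = life_history(make_tumor(onset=50.0, det=70.0))
        with pytest.raises(ConfigurationError):
            apply_screening(lh2, STRATEGY, {}, CURE_ONE, rng)

    def test_overdiagnosis_flagged(self, rng):
        # clinical surfacing would occur only after other-cause death
        lh = life_history(make_tumor(onset=58.0, det=80.0), oc=70.0, lc=None)
        out = apply_screening(lh, STRATEGY, SENS_ONE, CURE_ONE, rng)
        assert out.detection_age is not None
        assert out.overdiagnosed
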