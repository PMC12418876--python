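"""Screening strategies: eligibility, scheduling, CT detection and cure.

Two eligibility families are supported: packyear rules (USPSTF-style: minimum
packyears smoked and a cap on years since cessation) and risk rules
(TLHC-style: a 6-year lung cancer risk threshold under the PLCOm2012
logistic model). Screens are placed on an integer-age grid from the first
eligible age, stepping by the screening interval, with eligibility
re-evaluated at every screen age.

Screen detection uses a CT sensitivity specific to the stage and histology
of the cancer at the time of the screen. A detected cancer is cured with a
stage-specific probability (one cure draw per tumor, at first detection);
if not cured, the lung cancer death time of the no-screening counterfactual
is carried over unchanged.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
from scipy.special import expit

from .errors import ConfigurationError, RiskModelNotApplicable
from .natural_history import Tumor, stage_at, STAGES, HISTOLOGIES
from .population import SmokingHistory, packyears, years_since_quit, CURRENT


# ---------------------------------------------------------------------------
# PLCOm2012 risk model (reduced form: no race/ethnicity terms)
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class PLCOCoefficients:
    """Logistic coefficients of the PLCOm2012 6-year risk model.

    Defaults are the published model coefficients with their centering
    constants; the race/ethnicity terms are omitted in this reduced form.
    All values are editable so a locally recalibrated model can be dropped in.
    """

    intercept: float = -4.532506
    age: float = 0.0778868
    age_center: float = 62.0
    education: float = -0.0812744
    education_center: float = 4.0
    bmi: float = -0.0274194
    bmi_center: float = 27.0
    copd: float = 0.3553063
    personal_cancer: float = 0.4589971
    family_lung_cancer: float = 0.587185
    current_smoker: float = 0.2597431
    cpd: float = -1.822606
    cpd_center: float = 0.4021541613  # centering of (cpd/10)^-1
    duration: float = 0.0317321
    duration_center: float = 27.0
    quit_years: float = -0.0308572
    quit_years_center: float = 10.0


DEFAULT_PLCO_COEFFICIENTS = PLCOCoefficients()


@dataclass(frozen=True)
class PLCOCovariates:
    """Covariates of the PLCOm2012 model for one ever-smoker."""

    age: float
    education: float  # 1 (< high school) .. 6 (postgraduate)
    bmi: float
    copd: bool
    personal_cancer_history: bool
    family_lung_cancer: bool
    smoking_status: str  # "current" or "former"
    cpd: float
    duration_years: float
    quit_years: float


def plco_risk(
    cov: PLCOCovariates, coefs: PLCOCoefficients = DEFAULT_PLCO_COEFFICIENTS
) -> float:
    """6-year lung cancer probability under the PLCOm2012 logistic model."""
    if cov.cpd <= 0 or cov.duration_years <= 0:
        raise RiskModelNotApplicable("PLCOm2012 is defined for ever-smokers only")
    x = (
        coefs.intercept
        + coefs.age * (cov.age - coefs.age_center)
        + coefs.education * (cov.education - coefs.education_center)
        + coefs.bmi * (cov.bmi - coefs.bmi_center)
        + coefs.copd * float(cov.copd)
        + coefs.personal_cancer * float(cov.personal_cancer_history)
        + coefs.family_lung_cancer * float(cov.family_lung_cancer)
        + coefs.current_smoker * float(cov.smoking_status == CURRENT)
        + coefs.cpd * ((cov.cpd / 10.0) ** -1 - coefs.cpd_center)
        + coefs.duration * (cov.duration_years - coefs.duration_center)
        + coefs.quit_years * (cov.quit_years - coefs.quit_years_center)
    )
    return float(expit(x))


# ---------------------------------------------------------------------------
# Strategies
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class PackyearRule:
    min_packyears: float = 20.0
    max_quit_years: float = 15.0
    age_lo: int = 50
    age_hi: int = 80

    def __post_init__(self):
        if self.age_lo >= self.age_hi:
            raise ConfigurationError("age_lo must be below age_hi")


@dataclass(frozen=True)
class RiskRule:
    risk_threshold: float = 0.0151
    age_lo: int = 55
    age_hi: int = 75
    coefficients: PLCOCoefficients = DEFAULT_PLCO_COEFFICIENTS

    def __post_init__(self):
        if not 0.0 < self.risk_threshold < 1.0:
            raise ConfigurationError("risk threshold must lie in (0, 1)")
        if self.age_lo >= self.age_hi:
            raise ConfigurationError("age_lo must be below age_hi")


@dataclass(frozen=True)
class AdherenceModel:
    """Screening attendance: full, or reduced with structural non-attendance.

    With ``attend_prob`` p and ``structural_fraction`` s, a share s*(1-p) of
    eligible individuals never attends; the remainder attends each screen
    independently with probability p / (1 - s*(1-p)) so that the expected
    overall attended fraction equals p.
    """

    attend_prob: float = 1.0
    structural_fraction: float = 0.0

    def __post_init__(self):
        if not 0.0 <= self.attend_prob <= 1.0:
            raise ConfigurationError("attend_prob must lie in [0, 1]")
        if not 0.0 <= self.structural_fraction <= 1.0:
            raise ConfigurationError("structural_fraction must lie in [0, 1]")
        if self.attend_prob > 0 and self.per_screen_prob > 1.0 + 1e-12:
            raise ConfigurationError(
                "infeasible adherence model: implied per-screen probability > 1"
            )

    @property
    def structural_share(self) -> float:
        return self.structural_fraction * (1.0 - self.attend_prob)

    @property
    def per_screen_prob(self) -> float:
        denom = 1.0 - self.structural_fraction * (1.0 - self.attend_prob)
        return self.attend_prob / denom if denom > 0 else math.inf

    @property
    def full(self) -> bool:
        return self.attend_prob >= 1.0


FULL_ADHERENCE = AdherenceModel()


@dataclass(frozen=True)
class ScreeningStrategy:
    name: str
    rule: PackyearRule | RiskRule
    interval_years: int = 1
    adherence: AdherenceModel = FULL_ADHERENCE

    def __post_init__(self):
        if self.interval_years not in (1, 2):
            raise ConfigurationError("screening interval must be 1 or 2 years")

    def with_adherence(self, adherence: AdherenceModel) -> "ScreeningStrategy":
        return replace(self, adherence=adherence)


# ---------------------------------------------------------------------------
# Eligibility and scheduling
# ---------------------------------------------------------------------------

def uspstf_eligible(history: SmokingHistory, age: float, rule: PackyearRule) -> bool:
    """Packyear eligibility: age window, minimum packyears, quit-year cap."""
    if not rule.age_lo <= age <= rule.age_hi:
        return False
    if packyears(history, age) < rule.min_packyears:
        return False
    ysq = years_since_quit(history, age)
    return ysq is not None and ysq <= rule.max_quit_years


def _covariates_at(
    history: SmokingHistory, age: float, base: PLCOCovariates
) -> PLCOCovariates:
    ysq = years_since_quit(history, age)
    return replace(
        base,
        age=age,
        smoking_status=history.status(age),
        cpd=history.mean_cpd(),
        duration_years=history.duration(age),
        quit_years=ysq if ysq is not None else 0.0,
    )


def risk_eligible(
    history: SmokingHistory,
    age: float,
    rule: RiskRule,
    covariates: PLCOCovariates,
) -> bool:
    """Risk-rule eligibility: 6-year PLCOm risk at or above the threshold."""
    if not rule.age_lo <= age <= rule.age_hi:
        return False
    if not history.ever_smoker or age < (history.start_age or math.inf):
        return False
    cov = _covariates_at(history, age, covariates)
    try:
        risk = plco_risk(cov, rule.coefficients)
    except RiskModelNotApplicable:
        return False
    return risk >= rule.risk_threshold


def eligible(
    strategy: ScreeningStrategy,
    history: SmokingHistory,
    age: float,
    covariates: PLCOCovariates | None = None,
) -> bool:
    if isinstance(strategy.rule, PackyearRule):
        return uspstf_eligible(history, age, strategy.rule)
    if covariates is None:
        raise ConfigurationError("risk-rule eligibility requires PLCO covariates")
    return risk_eligible(history, age, strategy.rule, covariates)


def schedule_screens(
    strategy: ScreeningStrategy,
    history: SmokingHistory,
    covariates: PLCOCovariates | None = None,
    start_age: float | None = None,
) -> list[int]:
    """Integer screen ages: from first eligible age, stepping by the interval.

    Eligibility is re-evaluated at every screen age; ages where it no longer
    holds are dropped. ``start_age`` bounds the schedule from below (e.g. the
    person's age when the programme starts).
    """
    rule = strategy.rule
    lo = rule.age_lo
    if start_age is not None:
        lo = max(lo, int(math.ceil(start_age)))
    first = None
    for a in range(lo, rule.age_hi + 1):
        if eligible(strategy, history, a, covariates):
            first = a
            break
    if first is None:
        return []
    return [
        a
        for a in range(first, rule.age_hi + 1, strategy.interval_years)
        if eligible(strategy, history, a, covariates)
    ]


def apply_adherence(
    schedule: list[int],
    model: AdherenceModel,
    rng: np.random.Generator | int,
) -> list[int]:
    """Attended subset of a screen schedule under the adherence model."""
    if model.full:
        return list(schedule)
    if model.attend_prob <= 0.0:
        return []
    if isinstance(rng, (int, np.integer)):
        rng = np.random.default_rng(rng)
    if rng.random() < model.structural_share:
        return []
    q = model.per_screen_prob
    return [a for a in schedule if rng.random() < q]


# ---------------------------------------------------------------------------
# Applying screening to a life history
# ---------------------------------------------------------------------------

@dataclass
class LifeHistory:
    """A person's simulated course, before any screening is applied."""

    history: SmokingHistory
    oc_death_age: float
    tumor: Tumor | None = None
    lc_death_age_unscreened: float | None = None  # unconditional on oc death
    covariates: PLCOCovariates | None = None


@dataclass
class ScreenEvent:
    age: float
    result: str  # "negative" | "screen_detected"
    stage: str | None = None
    histology: str | None = None
    cured: bool = False


@dataclass
class ScreeningOutcome:
    """Result of running one strategy over one life history."""

    invited: bool
    scheduled_ages: list[int]
    attended_ages: list[float]  # screens that actually took place
    events: list[ScreenEvent]
    detection_age: float | None
    detection_stage: str | None
    detection_histology: str | None
    cured: bool
    lc_death_age: float | None  # in the screened scenario (unconditional)
    lead_time_years: float | None
    overdiagnosed: bool


def _table_cell(table: dict, key, what: str):
    try:
        return table[key]
    except KeyError:
        raise ConfigurationError(f"missing {what} entry for {key!r}") from None


def apply_screening(
    life_history: LifeHistory,
    strategy: ScreeningStrategy,
    sensitivity_table: dict[tuple[str, str], float],
    cure_table: dict[str, float],
    rng: np.random.Generator | int,
    start_age: float | None = None,
) -> ScreeningOutcome:
    """Run a screening strategy over one life history.

    Requires the unscreened counterfactual (clinical detection and lung
    cancer death time) to be simulated already. Screens occur while the
    person is alive and not yet clinically diagnosed. The first positive
    screen triggers a single cure draw; a cured case loses its lung cancer
    death (dies of other causes at the counterfactual other-cause age), a
    not-cured case retains the unscreened lung cancer death time exactly.
    """
    if isinstance(rng, (int, np.integer)):
        rng = np.random.default_rng(rng)

    schedule = schedule_screens(
        strategy, life_history.history, life_history.covariates, start_age
    )
    attended = apply_adherence(schedule, strategy.adherence, rng)

    tumor = life_history.tumor
    lc_unscr = life_history.lc_death_age_unscreened
    death_unscr = life_history.oc_death_age
    if lc_unscr is not None:
        death_unscr = min(death_unscr, lc_unscr)
    clin_det = tumor.clinical_detection_age if tumor is not None else math.inf

    events: list[ScreenEvent] = []
    happened: list[float] = []
    detection_age = detection_stage = detection_histology = None
    cured = False
    for a in attended:
        if a >= death_unscr or a >= clin_det:
            break  # dead or already a clinically diagnosed case
        happened.append(float(a))
        if tumor is not None and tumor.onset_age <= a < clin_det:
            stg = stage_at(tumor, a)
            sens = _table_cell(sensitivity_table, (stg, tumor.histology), "sensitivity")
            if rng.random() < sens:
                cure_p = _table_cell(cure_table, stg, "cure probability")
                cured = rng.random() < cure_p
                detection_age, detection_stage = float(a), stg
                detection_histology = tumor.histology
                events.append(
                    ScreenEvent(float(a), "screen_detected", stg, tumor.histology, cured)
                )
                break
        events.append(ScreenEvent(float(a), "negative"))

    if detection_age is not None:
        lc_death = None if cured else lc_unscr
        lead = clin_det - detection_age if math.isfinite(clin_det) else math.inf
        overdx = clin_det > life_history.oc_death_age
    else:
        lc_death = lc_unscr
        lead = None
        overdx = False

    return ScreeningOutcome(
        invited=bool(schedule),
        scheduled_ages=schedule,
        attended_ages=happened,
        events=events,
        detection_age=detection_age,
        detection_stage=detection_stage,
        detection_histology=detection_histology,
        cured=cured,
        lc_death_age=lc_death,
        lead_time_years=lead,
        overdiagnosed=overdx,
    )
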