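"""Default parameter fixtures for the simulation.

These fixtures stand in for estimates that would in practice be fitted to
national survey, trial and registry microdata: smoking behaviour gradients
by sex and birth cohort, natural-history dwell times and detection hazards,
CT sensitivity and cure probabilities, phase-of-care cost levels with
era-specific multipliers, and norm utilities. Values are synthetic but
qualitatively realistic for a Western European population; the relative
structure of the cost schedule (which phases and stages became more
expensive after the introduction of targeted- and immunotherapies) follows
observed registry/claims patterns, while absolute euro levels are
documented placeholders. All fixtures are plain data and editable.
"""

from __future__ import annotations

import numpy as np

from .costs import CostSchedule
from .economics import UtilitySet
from .natural_history import (
    HISTOLOGIES,
    NaturalHistoryParams,
    STAGES,
    StageParams,
)
from .population import FEMALE, MALE, SEXES, SmokingParamSet, SmokingParams
from .registry import GeneratorSpec, GompertzSpec, SubgroupHazard, rs3_to_monthly_hazard
from .screening import (
    AdherenceModel,
    PackyearRule,
    RiskRule,
    ScreeningStrategy,
)

BIRTH_COHORTS = tuple(range(1945, 1980))


# ---------------------------------------------------------------------------
# Smoking behaviour
# ---------------------------------------------------------------------------

def default_smoking_params(sex: str, cohort_band: int) -> SmokingParams:
    """Synthetic initiation/cessation/intensity parameters for one stratum.

    Male ever-smoking prevalence declines over cohorts (roughly 0.65 for the
    late-1940s cohorts to 0.45 for the 1970s); female prevalence rises for
    1950s cohorts then declines. Initiation concentrates at ages 14-25;
    cessation hazard increases with age.
    """
    decades = (cohort_band - 1945) / 10.0
    if sex == MALE:
        target_ever = max(0.30, 0.65 - 0.06 * decades)
    else:
        target_ever = max(0.25, 0.42 + 0.04 * decades - 0.02 * decades**2)

    ages = np.arange(100)
    shape = np.zeros(100)
    shape[12:31] = np.exp(-0.5 * ((ages[12:31] - 17.0) / 3.5) ** 2)
    # scale per-age conditional probabilities so P(ever) hits the target
    lo, hi = 0.0, 1.0
    for _ in range(40):
        mid = 0.5 * (lo + hi)
        p_ever = 1.0 - np.prod(1.0 - np.clip(mid * shape, 0, 0.95))
        if p_ever < target_ever:
            lo = mid
        else:
            hi = mid
    init = np.clip(0.5 * (lo + hi) * shape, 0, 0.95)

    cess = np.zeros(100)
    cess[16:40] = 0.02
    cess[40:60] = 0.035
    cess[60:] = 0.05

    cpd_mean = 19.0 if sex == MALE else 15.0
    return SmokingParams(
        initiation_prob=init,
        cessation_hazard=cess,
        cpd_log_mean=float(np.log(cpd_mean) - 0.5 * 0.45**2),
        cpd_log_sd=0.45,
    )


def default_smoking_param_set() -> SmokingParamSet:
    strata = {}
    for sex in SEXES:
        for band in range(1945, 1980, 5):
            strata[(sex, band)] = default_smoking_params(sex, band)
    return SmokingParamSet(strata=strata, band_width=5)


#: All-cause mortality relative risks by smoking status (single multiplier
#: on non-lung-cancer mortality; no latency after quitting).
DEFAULT_SMOKING_RR = {"never": 1.0, "current": 2.2, "former": 1.5}


def default_life_table():
    """Deterministic synthetic cohort life table (Gompertz-like)."""
    from .registry import generate_life_table

    return generate_life_table(GompertzSpec(), cohorts=tuple(range(1945, 1980, 5)))


# ---------------------------------------------------------------------------
# Natural history
# ---------------------------------------------------------------------------

def default_natural_history_params() -> NaturalHistoryParams:
    """Parametric natural-history fixture.

    Onset: background term exp(-13.5 + 0.085 a) plus packyears times
    exp(-14.1 + 0.075 a) per year. Dwell times are Weibull (shape 1.5) with
    means of roughly 2 years in stage IA shrinking along the stage sequence;
    small cell tumors progress about 2.5x faster (screening is known to
    benefit SCLC least). Clinical detection hazards rise steeply with stage.
    """
    dwell_means = {"IA": 2.0, "IB": 1.2, "II": 1.0, "IIIA": 0.9, "IIIB": 0.8}
    detect = {"IA": 0.10, "IB": 0.18, "II": 0.35, "IIIA": 0.65, "IIIB": 1.1, "IV": 2.5}
    shape = 1.5
    from math import gamma

    mean_factor = gamma(1.0 + 1.0 / shape)  # scale = mean / Gamma(1 + 1/shape)
    cells = {}
    for hist in HISTOLOGIES:
        speed = 2.5 if hist == "SCLC" else 1.0
        det_mult = 1.6 if hist == "SCLC" else 1.0
        for stage in STAGES:
            if stage == "IV":
                cells[(stage, hist)] = StageParams(1.0, 1.0, detect[stage] * det_mult)
            else:
                mean = dwell_means[stage] / speed
                cells[(stage, hist)] = StageParams(
                    shape, mean / mean_factor, detect[stage] * det_mult
                )
    return NaturalHistoryParams(
        onset_background_log=(-13.5, 0.085),
        onset_smoking_log=(-14.1, 0.075),
        histology_probs={
            "never": {"AD": 0.55, "SQ": 0.10, "ONSCLC": 0.25, "SCLC": 0.10},
            "ever": {"AD": 0.38, "SQ": 0.22, "ONSCLC": 0.22, "SCLC": 0.18},
        },
        stage_params=cells,
    )


# ---------------------------------------------------------------------------
# Screening effectiveness
# ---------------------------------------------------------------------------

def default_sensitivity_table() -> dict[tuple[str, str], float]:
    """CT sensitivity by stage and histology (lower for early-stage and SCLC)."""
    base = {"IA": 0.62, "IB": 0.75, "II": 0.84, "IIIA": 0.90, "IIIB": 0.93, "IV": 0.95}
    table = {}
    for hist in HISTOLOGIES:
        factor = 0.85 if hist == "SCLC" else 1.0
        for stage in STAGES:
            table[(stage, hist)] = min(base[stage] * factor, 0.99)
    return table


def default_cure_table() -> dict[str, float]:
    """Probability a screen-detected cancer is cured, by stage at detection."""
    return {"IA": 0.55, "IB": 0.45, "II": 0.30, "IIIA": 0.17, "IIIB": 0.10, "IV": 0.03}


STRATEGY_A_TLHC = ScreeningStrategy("A-TLHC", RiskRule(), interval_years=1)
STRATEGY_B_TLHC = ScreeningStrategy("B-TLHC", RiskRule(), interval_years=2)
STRATEGY_A_USPSTF = ScreeningStrategy("A-USPSTF", PackyearRule(), interval_years=1)
STRATEGY_B_USPSTF = ScreeningStrategy("B-USPSTF", PackyearRule(), interval_years=2)
STRATEGIES = {
    s.name: s
    for s in (STRATEGY_A_TLHC, STRATEGY_B_TLHC, STRATEGY_A_USPSTF, STRATEGY_B_USPSTF)
}

REDUCED_ADHERENCE = AdherenceModel(attend_prob=0.5, structural_fraction=0.5)


# ---------------------------------------------------------------------------
# Costs
# ---------------------------------------------------------------------------

def default_cost_schedule() -> CostSchedule:
    """Phase-of-care cost fixture (euro per patient-month, 2021 price level).

    The post-era entries encode the observed direction of change after the
    introduction of targeted- and immunotherapies: late-stage initial care
    about 55% more expensive, late-stage continuing care 148% more expensive
    (x2.48), early-stage continuing care up roughly 77%. Absolute levels are
    placeholders; the price index factor rescales to the 2023 level.
    """
    t = {
        ("I-II", "initial", "pre"): 5000.0,
        ("I-II", "continuing", "pre"): 700.0,
        ("I-II", "terminal_lc", "pre"): 8000.0,
        ("I-II", "terminal_oc", "pre"): 4000.0,
        ("III-IV", "initial", "pre"): 9000.0,
        ("III-IV", "continuing", "pre"): 1500.0,
        ("III-IV", "terminal_lc", "pre"): 11000.0,
        ("III-IV", "terminal_oc", "pre"): 5000.0,
        ("I-II", "initial", "post"): 5500.0,
        ("I-II", "continuing", "post"): 1239.0,  # x1.77
        ("I-II", "terminal_lc", "post"): 8800.0,
        ("I-II", "terminal_oc", "post"): 4400.0,
        ("III-IV", "initial", "post"): 13950.0,  # x1.55
        ("III-IV", "continuing", "post"): 3720.0,  # x2.48
        ("III-IV", "terminal_lc", "post"): 12650.0,
        ("III-IV", "terminal_oc", "post"): 5500.0,
    }
    return CostSchedule(
        treatment=t,
        ct_screen=140.0,
        admin_overhead=21.0,
        followup_per_participant=35.0,
        risk_assessment_per_invitee=6.0,
        price_index_factor=1.05,
    )


# ---------------------------------------------------------------------------
# Utilities
# ---------------------------------------------------------------------------

_BAND_EDGES = (0, 40, 50, 60, 70, 80)
_EQ5D = {0: 0.93, 40: 0.90, 50: 0.86, 60: 0.84, 70: 0.81, 80: 0.74}
_VAS = {0: 0.87, 40: 0.83, 50: 0.79, 60: 0.77, 70: 0.74, 80: 0.68}
_DISUTILITY = {
    ("I-II", "initial"): 0.20,
    ("I-II", "continuing"): 0.10,
    ("I-II", "terminal_lc"): 0.40,
    ("I-II", "terminal_oc"): 0.30,
    ("III-IV", "initial"): 0.30,
    ("III-IV", "continuing"): 0.18,
    ("III-IV", "terminal_lc"): 0.45,
    ("III-IV", "terminal_oc"): 0.35,
}


def _norm_map(values: dict[int, float], female_gap: float = 0.02) -> dict:
    out = {}
    for band, val in values.items():
        out[(band, MALE)] = val
        out[(band, FEMALE)] = max(val - female_gap, 0.0)
    return out


def default_utilities(instrument: str = "eq5d") -> UtilitySet:
    """EQ-5D (default) or VAS norm utilities by 10-year age band and sex."""
    values = _EQ5D if instrument == "eq5d" else _VAS
    return UtilitySet(
        band_edges=_BAND_EDGES,
        norm=_norm_map(values),
        disutility=dict(_DISUTILITY),
        name=instrument,
    )


# ---------------------------------------------------------------------------
# Population composition
# ---------------------------------------------------------------------------

def default_composition() -> dict[tuple[str, int], float]:
    """Relative population weight by (sex, birth year), 1945-1979 cohorts.

    Approximates the size structure of a Western European population at the
    start of 2023: post-war baby-boom cohorts are larger, with gradual
    attrition of the oldest cohorts.
    """
    weights = {}
    for by in BIRTH_COHORTS:
        base = 1.0 + 0.3 * np.exp(-0.5 * ((by - 1962) / 10.0) ** 2)
        attrition = 1.0 - 0.012 * max(0, 1965 - by)
        for sex in SEXES:
            weights[(sex, by)] = float(base * max(attrition, 0.5))
    return weights


# ---------------------------------------------------------------------------
# Synthetic registry ground truth
# ---------------------------------------------------------------------------

#: Era-specific 3-year relative survival by stage x histology used to
#: generate the synthetic registry. The stage IV adenocarcinoma pair
#: (6.5% -> 14.1%) reflects the more-than-doubling of late-stage survival
#: after novel-therapy introduction; small cell gains are smallest.
RS3_TRUTH: dict[tuple[str, str], tuple[float, float]] = {}
_RS3_BASE = {
    "IA": (0.85, 0.88), "IB": (0.73, 0.78), "II": (0.58, 0.64),
    "IIIA": (0.38, 0.48), "IIIB": (0.24, 0.34), "IV": (0.065, 0.141),
}
_HIST_FACTORS = {"AD": 1.0, "SQ": 0.85, "ONSCLC": 0.9, "SCLC": 0.55}
for _stage, (_r1, _r2) in _RS3_BASE.items():
    for _hist, _f in _HIST_FACTORS.items():
        r1 = _r1 * _f if _stage != "IA" else min(_r1 * (0.8 + 0.2 * _f), 0.95)
        if _hist == "SCLC":
            r2 = min(r1 * 1.1, 0.95)  # no novel therapies approved for SCLC
        else:
            r2 = min(_r2 * _f if _stage != "IA" else _r2 * (0.8 + 0.2 * _f), 0.96)
        RS3_TRUTH[(_stage, _hist)] = (max(r1, 0.01), max(r2, 0.01))
RS3_TRUTH[("IV", "AD")] = (0.065, 0.141)


def default_generator_spec(n: int = 20_000, with_costs: bool = False) -> GeneratorSpec:
    """Registry generator emulating the pre/post-era survival structure."""
    hazards = {}
    for (stage, hist), (r1, r2) in RS3_TRUTH.items():
        lam1 = rs3_to_monthly_hazard(r1)
        lam2 = rs3_to_monthly_hazard(r2)
        hazards[(stage, hist)] = SubgroupHazard(
            monthly_excess_hazard=lam1,
            era_multiplier=lam2 / lam1 if lam1 > 0 else 1.0,
        )
    cost_means = {
        ("I-II", "initial"): 5000.0, ("I-II", "continuing"): 700.0,
        ("I-II", "terminal_lc"): 8000.0, ("I-II", "terminal_oc"): 4000.0,
        ("III-IV", "initial"): 9000.0, ("III-IV", "continuing"): 1500.0,
        ("III-IV", "terminal_lc"): 11000.0, ("III-IV", "terminal_oc"): 5000.0,
    }
    cost_mult = {
        ("I-II", "initial"): 1.10, ("I-II", "continuing"): 1.77,
        ("I-II", "terminal_lc"): 1.10, ("I-II", "terminal_oc"): 1.10,
        ("III-IV", "initial"): 1.55, ("III-IV", "continuing"): 2.48,
        ("III-IV", "terminal_lc"): 1.15, ("III-IV", "terminal_oc"): 1.10,
    }
    return GeneratorSpec(
        n=n,
        hazards=hazards,
        with_costs=with_costs,
        cost_means=cost_means,
        cost_era_multipliers=cost_mult,
    )
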