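"""Synthetic registry-like patient records and life tables with known truth.

This module is the test bed for the estimation layers: it emits diagnosed
lung cancer cohorts whose excess-hazard processes, calendar-period survival
shifts and phase-structured monthly costs are fully specified, so that the
Ederer-II / GLM / costing pipeline can be validated by parameter recovery.

Era effects are generated as calendar-period effects by default: the excess
hazard acting in a given follow-up month depends on the calendar date of
that month, which is the estimand of a period analysis. A cohort-of-
diagnosis mode (the multiplier keyed to the diagnosis date instead) is
provided for robustness checks.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .costs import phase_decompose, stage_group
from .errors import ConfigurationError
from .natural_history import HISTOLOGIES, STAGES
from .population import FEMALE, MALE, LifeTable, SEXES
from .survival import AGE_BANDS, age_band

AGE_BAND_RANGES = {"<65": (50, 65), "65-75": (65, 75), "75+": (75, 90)}


def rs3_to_monthly_hazard(rs3: float) -> float:
    """Constant monthly excess hazard implying a 3-year relative survival."""
    if not 0.0 < rs3 <= 1.0:
        raise ConfigurationError("3-year relative survival must lie in (0, 1]")
    return -math.log(rs3) / 36.0


@dataclass(frozen=True)
class SubgroupHazard:
    """Excess-hazard process of one subgroup: era-1 level and era multiplier."""

    monthly_excess_hazard: float
    era_multiplier: float = 1.0

    def __post_init__(self):
        if self.monthly_excess_hazard < 0 or self.era_multiplier < 0:
            raise ConfigurationError("hazards must be non-negative")


@dataclass
class GompertzSpec:
    """Deterministic background mortality: h(a) = c0 * exp(b * a) + floor."""

    c0: dict[str, float] = field(
        default_factory=lambda: {MALE: 3.5e-5, FEMALE: 2.2e-5}
    )
    b: float = 0.095
    floor: float = 2e-4
    cohort_improvement: float = 0.004  # hazard reduction per birth year vs 1950
    max_age: int = 100


@dataclass
class GeneratorSpec:
    """Declarative description of the synthetic registry to generate."""

    n: int = 10_000
    stage_probs: dict[str, float] = field(
        default_factory=lambda: {
            "IA": 0.12, "IB": 0.08, "II": 0.08, "IIIA": 0.12, "IIIB": 0.10, "IV": 0.50,
        }
    )
    histology_probs: dict[str, float] = field(
        default_factory=lambda: {"AD": 0.42, "SQ": 0.22, "ONSCLC": 0.18, "SCLC": 0.18}
    )
    sex_probs: dict[str, float] = field(
        default_factory=lambda: {MALE: 0.55, FEMALE: 0.45}
    )
    age_band_probs: dict[str, float] = field(
        default_factory=lambda: {"<65": 0.30, "65-75": 0.42, "75+": 0.28}
    )
    diagnosis_start: str = "2012-01"
    diagnosis_end: str = "2021-12"
    era_break: str = "2018-01"
    censor_date: str = "2023-02"
    hazards: dict[tuple[str, str], SubgroupHazard] = field(default_factory=dict)
    era_mode: str = "period"  # "period" | "cohort"
    gompertz: GompertzSpec = field(default_factory=GompertzSpec)
    # phase cost generation (optional)
    with_costs: bool = False
    cost_means: dict[tuple[str, str], float] = field(default_factory=dict)
    cost_era_multipliers: dict[tuple[str, str], float] = field(default_factory=dict)
    cost_gamma_shape: float = 4.0

    def __post_init__(self):
        for name, probs in (
            ("stage", self.stage_probs), ("histology", self.histology_probs),
            ("sex", self.sex_probs), ("age_band", self.age_band_probs),
        ):
            total = sum(probs.values())
            if abs(total - 1.0) > 1e-9:
                raise ConfigurationError(f"{name} proportions must sum to 1")
        if self.era_mode not in ("period", "cohort"):
            raise ConfigurationError("era_mode must be 'period' or 'cohort'")

    def hazard_cell(self, stage: str, histology: str) -> SubgroupHazard:
        try:
            return self.hazards[(stage, histology)]
        except KeyError:
            raise ConfigurationError(
                f"generator spec missing hazard for stage {stage}, "
                f"histology {histology}"
            ) from None


def generate_life_table(
    spec: GompertzSpec,
    cohorts: tuple[int, ...] = tuple(range(1945, 1980, 5)),
) -> LifeTable:
    """Deterministic Gompertz-like cohort life table.

    Annual death probabilities integrate the continuous hazard exactly over
    each year of age, so the table is hazard-consistent with the generating
    process.
    """
    rows = []
    ages = np.arange(spec.max_age + 1)
    for sex in SEXES:
        for cohort in cohorts:
            c0 = spec.c0[sex] * math.exp(-spec.cohort_improvement * (cohort - 1950))
            cum = c0 / spec.b * (np.exp(spec.b * (ages + 1)) - np.exp(spec.b * ages))
            q = 1.0 - np.exp(-(cum + spec.floor))
            rows.append(
                pd.DataFrame(
                    {"sex": sex, "birth_cohort": cohort, "age": ages,
                     "q_annual": np.clip(q, 0, 1)}
                )
            )
    return LifeTable(pd.concat(rows, ignore_index=True))


def _sample_categorical(rng, probs: dict, n: int) -> np.ndarray:
    keys = list(probs)
    p = np.array([probs[k] for k in keys], dtype=float)
    p = p / p.sum()
    return np.array(keys)[rng.choice(len(keys), size=n, p=p)]


def _oc_death_months(
    rng: np.random.Generator,
    life_table: LifeTable,
    sexes: np.ndarray,
    cohorts: np.ndarray,
    ages_dx: np.ndarray,
) -> np.ndarray:
    """Months from diagnosis to background (other-cause) death."""
    n = len(sexes)
    out = np.empty(n)
    for i in range(n):
        h = life_table.hazard_array(sexes[i], int(cohorts[i]))
        a0 = ages_dx[i] - life_table.age_min
        k0 = int(math.floor(a0))
        frac = a0 - k0
        # cumulative hazard from exact age of diagnosis
        seg = np.concatenate([[h[k0] * (1 - frac)], h[k0 + 1:]])
        cum = np.concatenate([[0.0], np.cumsum(seg)])
        e = rng.exponential()
        if e >= cum[-1]:
            years = float(life_table.age_max + 1 - a0 - life_table.age_min)
        else:
            k = int(np.searchsorted(cum, e, side="right")) - 1
            within = (e - cum[k]) / seg[k] if seg[k] > 0 else 0.0
            if k == 0:
                years = within * (1 - frac)
            else:
                years = (1 - frac) + (k - 1) + within
        out[i] = years * 12.0
    return out


def generate_registry(
    spec: GeneratorSpec, rng: np.random.Generator | int
) -> tuple[pd.DataFrame, pd.DataFrame | None]:
    """Generate registry patient records (and optional monthly cost streams).

    Lung cancer death times are drawn from the era-dependent excess hazard
    active in each calendar month; other-cause deaths from the background
    life table; follow-up is censored at the spec's censoring date. Returns
    ``(records, costs)`` where ``costs`` is ``None`` unless
    ``spec.with_costs`` is set.
    """
    if isinstance(rng, (int, np.integer)):
        rng = np.random.default_rng(rng)
    n = spec.n
    stage = _sample_categorical(rng, spec.stage_probs, n)
    histology = _sample_categorical(rng, spec.histology_probs, n)
    sex = _sample_categorical(rng, spec.sex_probs, n)
    band = _sample_categorical(rng, spec.age_band_probs, n)
    lo = np.array([AGE_BAND_RANGES[b][0] for b in band], dtype=float)
    hi = np.array([AGE_BAND_RANGES[b][1] for b in band], dtype=float)
    age_dx = lo + rng.random(n) * (hi - lo)

    d0 = pd.Period(spec.diagnosis_start, freq="M").ordinal
    d1 = pd.Period(spec.diagnosis_end, freq="M").ordinal
    diag = rng.integers(d0, d1 + 1, size=n)
    brk = pd.Period(spec.era_break, freq="M").ordinal
    cens = pd.Period(spec.censor_date, freq="M").ordinal
    t_cens = (cens - diag).astype(float)  # fully observed months

    lam1 = np.empty(n)
    mult = np.empty(n)
    for i in range(n):
        cell = spec.hazard_cell(stage[i], histology[i])
        lam1[i] = cell.monthly_excess_hazard
        mult[i] = cell.era_multiplier
    lam2 = lam1 * mult

    e = rng.exponential(size=n)
    if spec.era_mode == "cohort":
        lam = np.where(diag >= brk, lam2, lam1)
        with np.errstate(divide="ignore"):
            t_lc = np.where(lam > 0, e / np.clip(lam, 1e-300, None), np.inf)
    else:
        k = np.clip(brk - diag, 0, None).astype(float)  # months before era break
        h_at_break = lam1 * k
        with np.errstate(divide="ignore", invalid="ignore"):
            t_before = np.where(lam1 > 0, e / np.clip(lam1, 1e-300, None), np.inf)
            t_after = k + np.where(
                lam2 > 0, (e - h_at_break) / np.clip(lam2, 1e-300, None), np.inf
            )
        t_lc = np.where(e < h_at_break, t_before, t_after)
        t_lc = np.where((lam1 == 0) & (lam2 == 0), np.inf, t_lc)

    diag_year = np.array([pd.Period(ordinal=o, freq="M").year for o in diag])
    cohort = diag_year - np.floor(age_dx).astype(int)
    bg_lt = generate_life_table(spec.gompertz)
    t_oc = _oc_death_months(rng, bg_lt, sex, cohort, age_dx)

    t_event = np.minimum(t_lc, t_oc)
    died = t_event < t_cens
    event = np.where(died, np.where(t_lc <= t_oc, "lc_death", "oc_death"), "censored")
    follow_up = np.where(died, np.floor(t_event) + 1, np.floor(t_cens)).astype(int)
    follow_up = np.maximum(follow_up, 1)

    records = pd.DataFrame(
        {
            "id": np.arange(n),
            "sex": sex,
            "age_at_diagnosis": np.round(age_dx, 2),
            "diagnosis_date": [str(pd.Period(ordinal=o, freq="M")) for o in diag],
            "stage": stage,
            "histology": histology,
            "follow_up_months": follow_up,
            "event": event,
        }
    )

    costs = None
    if spec.with_costs:
        costs = _generate_costs(spec, rng, records, diag, brk)
    return records, costs


def _generate_costs(
    spec: GeneratorSpec,
    rng: np.random.Generator,
    records: pd.DataFrame,
    diag: np.ndarray,
    brk: int,
) -> pd.DataFrame:
    shape = spec.cost_gamma_shape
    rows = []
    for i, rec in records.iterrows():
        cause = {"lc_death": "lc", "oc_death": "oc", "censored": "alive"}[rec["event"]]
        death_m = int(rec["follow_up_months"]) if cause != "alive" else None
        decomp = phase_decompose(0, death_m, cause)
        sg = stage_group(rec["stage"])
        for iv in decomp.intervals:
            end = min(iv.end_month, int(rec["follow_up_months"]))
            for mth in range(iv.start_month, end + 1):
                mean = spec.cost_means.get((sg, iv.phase))
                if mean is None:
                    raise ConfigurationError(
                        f"generator cost mean missing for ({sg}, {iv.phase})"
                    )
                if diag[i] + mth - 1 >= brk:
                    mean *= spec.cost_era_multipliers.get((sg, iv.phase), 1.0)
                val = rng.gamma(shape, mean / shape) if mean > 0 else 0.0
                rows.append(
                    {"id": rec["id"], "month": mth, "phase": iv.phase, "cost": val}
                )
    return pd.DataFrame(rows, columns=["id", "month", "phase", "cost"])
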