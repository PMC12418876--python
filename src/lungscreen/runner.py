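"""End-to-end scenario orchestration.

Builds a birth-cohort population, simulates natural history once (common
random numbers), applies screening strategies and treatment-era survival
curves, and aggregates discounted life years, QALYs and itemized costs into
incremental cost-effectiveness comparisons against no screening, plus the
univariate sensitivity grid.

Era effects enter only through the survival curve set and the cost
schedule; smoking histories, tumor trajectories, other-cause deaths and the
per-tumor survival draws are shared across all scenarios of a run, so
scenario deltas are person-paired.
"""

from __future__ import annotations

import hashlib
import json
import logging
import math
from dataclasses import asdict, dataclass, field, replace

import numpy as np
import pandas as pd

from . import defaults
from .costs import CostSchedule, accrue_treatment_cost, phase_decompose, stage_group
from .economics import (
    COST_ITEMS,
    CEComparison,
    ScenarioResult,
    UtilitySet,
    compare_scenarios,
    discounted_stream,
    population_hash,
)
from .errors import ConfigurationError
from .natural_history import NaturalHistoryParams, Tumor, simulate_tumor
from .population import (
    LifeTable,
    SmokingParamSet,
    sample_other_cause_death_age,
    simulate_smoking_history,
    split_life_table_by_smoking,
)
from .registry import generate_registry
from .screening import (
    LifeHistory,
    PLCOCovariates,
    ScreeningStrategy,
    apply_screening,
)
from .survival import CurveSet, age_band, assign_lc_death, fit_curve_set

logger = logging.getLogger(__name__)

ERAS = ("pre", "post")
REFERENCE_YEAR = 2023.0
MAX_MONTHS = 720  # person-time horizon from the reference date


# ---------------------------------------------------------------------------
# Configuration and inputs
# ---------------------------------------------------------------------------

@dataclass
class ScenarioConfig:
    """Declarative description of one scenario run."""

    n: int = 20_000
    seed: int = 0
    strategy: str | None = "A-TLHC"  # name in defaults.STRATEGIES, or None
    survival_era: str = "post"
    cost_era: str = "post"
    discount_rate_cost: float = 0.03
    discount_rate_effects: float = 0.03
    utility_instrument: str = "eq5d"
    wtp: float = 20_000.0
    reference_year: float = REFERENCE_YEAR
    birth_years: tuple[int, int] = (1945, 1979)
    registry_n: int = 20_000
    adherence: tuple[float, float] | None = None  # (attend_prob, structural_fraction)

    def __post_init__(self):
        if self.n < 1:
            raise ConfigurationError("n must be >= 1")
        if self.survival_era not in ERAS or self.cost_era not in ERAS:
            raise ConfigurationError("era must be 'pre' or 'post'")

    def config_hash(self) -> str:
        payload = json.dumps(asdict(self), sort_keys=True, default=str)
        return hashlib.sha1(payload.encode()).hexdigest()[:12]

    def resolve_strategy(self) -> ScreeningStrategy | None:
        if self.strategy is None:
            return None
        try:
            strat = defaults.STRATEGIES[self.strategy]
        except KeyError:
            raise ConfigurationError(f"unknown strategy {self.strategy!r}") from None
        if self.adherence is not None:
            from .screening import AdherenceModel

            strat = strat.with_adherence(AdherenceModel(*self.adherence))
        return strat


@dataclass
class ModelInputs:
    """All fixtures and fitted inputs a scenario run needs."""

    smoking_params: SmokingParamSet
    life_table: LifeTable  # all-cause
    smoking_rr: dict[str, float]
    nh_params: NaturalHistoryParams
    sensitivity: dict
    cure: dict
    curves: CurveSet
    cost_schedule: CostSchedule
    utilities: dict[str, UtilitySet]
    composition: dict[tuple[str, int], float]


def build_default_inputs(seed: int = 0, registry_n: int = 20_000) -> ModelInputs:
    """Assemble default inputs, fitting survival curves to a synthetic registry."""
    spec = defaults.default_generator_spec(n=registry_n)
    records, _ = generate_registry(spec, np.random.default_rng(
        np.random.SeedSequence([seed, 91])
    ))
    life_table = defaults.default_life_table()
    curves = fit_curve_set(records, life_table)
    return ModelInputs(
        smoking_params=defaults.default_smoking_param_set(),
        life_table=life_table,
        smoking_rr=dict(defaults.DEFAULT_SMOKING_RR),
        nh_params=defaults.default_natural_history_params(),
        sensitivity=defaults.default_sensitivity_table(),
        cure=defaults.default_cure_table(),
        curves=curves,
        cost_schedule=defaults.default_cost_schedule(),
        utilities={
            "eq5d": defaults.default_utilities("eq5d"),
            "vas": defaults.default_utilities("vas"),
        },
        composition=defaults.default_composition(),
    )


# ---------------------------------------------------------------------------
# Population
# ---------------------------------------------------------------------------

@dataclass
class Person:
    idx: int
    sex: str
    birth_year: int
    history: object
    covariates: PLCOCovariates
    oc_death_age: float = math.nan
    tumor: Tumor | None = None
    lc_exp_draw: float = math.nan
    lc_death_age: dict = field(default_factory=dict)  # era -> age | None


@dataclass
class Population:
    persons: list[Person]
    seed: int
    n: int
    pop_hash: str
    baseline_life_table: LifeTable  # never-smoker baseline after the split


def _person_rng(seed: int, idx: int, stream: int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence([seed, idx, stream]))


_EDU_P = np.array([0.08, 0.22, 0.28, 0.22, 0.13, 0.07])


def build_population(
    n: int,
    seed: int,
    inputs: ModelInputs,
    birth_years: tuple[int, int] = (1945, 1979),
) -> Population:
    """Simulate the shared natural-history layer for ``n`` persons.

    Per-person substreams are derived from the master seed and person index,
    so results are invariant to execution order.
    """
    comp = {
        k: w
        for k, w in inputs.composition.items()
        if birth_years[0] <= k[1] <= birth_years[1]
    }
    keys = list(comp)
    w = np.array([comp[k] for k in keys], dtype=float)
    w /= w.sum()
    rng0 = np.random.default_rng(np.random.SeedSequence([seed, 0]))
    assignment = rng0.choice(len(keys), size=n, p=w)

    persons: list[Person] = []
    for i in range(n):
        sex, by = keys[assignment[i]]
        rng = _person_rng(seed, i, 1)
        hist = simulate_smoking_history(inputs.smoking_params, sex, by, rng)
        edu = 1 + int(rng.choice(6, p=_EDU_P))
        bmi = float(np.clip(rng.normal(26.0, 4.0), 16.0, 45.0))
        cov = PLCOCovariates(
            age=0.0,
            education=edu,
            bmi=bmi,
            copd=bool(rng.random() < (0.15 if hist.ever_smoker else 0.04)),
            personal_cancer_history=bool(rng.random() < 0.05),
            family_lung_cancer=bool(rng.random() < 0.12),
            smoking_status=hist.status(50.0),
            cpd=hist.mean_cpd(),
            duration_years=hist.duration(50.0),
            quit_years=0.0,
        )
        tumor = simulate_tumor(hist, inputs.nh_params, rng)
        lc_exp = float(rng.exponential())
        persons.append(
            Person(
                idx=i, sex=sex, birth_year=by, history=hist, covariates=cov,
                tumor=tumor, lc_exp_draw=lc_exp,
            )
        )

    baseline = split_life_table_by_smoking(
        inputs.life_table, [p.history for p in persons], inputs.smoking_rr
    )
    for p in persons:
        rng = _person_rng(seed, p.idx, 2)
        p.oc_death_age = sample_other_cause_death_age(
            p.history, baseline, inputs.smoking_rr, rng
        )

    pop = Population(
        persons=persons,
        seed=seed,
        n=n,
        pop_hash=population_hash(seed, n, f"{birth_years}"),
        baseline_life_table=baseline,
    )
    assign_survival(pop, inputs.curves)
    return pop


def assign_survival(pop: Population, curves: CurveSet, eras=ERAS) -> None:
    """Draw counterfactual lung cancer death times per era for every tumor.

    The same Exp(1) draw is inverted against each era's curve (monotone
    coupling), so a higher survival curve can only postpone the death.
    """
    for p in pop.persons:
        t = p.tumor
        p.lc_death_age = {}
        if t is None or not math.isfinite(t.clinical_detection_age):
            for era in eras:
                p.lc_death_age[era] = None
            continue
        case = {
            "stage": t.stage_at_clinical_detection,
            "histology": t.histology,
            "age_band": age_band(t.clinical_detection_age),
            "sex": p.sex,
        }
        for era in eras:
            months = assign_lc_death(
                {**case, "period": era}, curves, exp_draw=p.lc_exp_draw
            )
            p.lc_death_age[era] = (
                None if months is None else t.clinical_detection_age + months / 12.0
            )


# ---------------------------------------------------------------------------
# Scenario arms
# ---------------------------------------------------------------------------

@dataclass
class ArmOutcome:
    """Per-person event layer of one scenario arm (pre-economics)."""

    strategy_name: str
    survival_era: str
    reference_year: float
    alive: np.ndarray
    dx: np.ndarray
    dx_age: np.ndarray
    dx_stage: np.ndarray
    dx_histology: np.ndarray
    dx_mode: np.ndarray  # "clinical" | "screen" | ""
    death_age: np.ndarray
    death_cause: np.ndarray  # "lc" | "oc"
    screen_ages: list
    invited: np.ndarray
    invite_age: np.ndarray
    overdiagnosed: np.ndarray


def simulate_arm(
    pop: Population,
    strategy: ScreeningStrategy | None,
    survival_era: str,
    inputs: ModelInputs,
    reference_year: float = REFERENCE_YEAR,
) -> ArmOutcome:
    n = pop.n
    alive = np.zeros(n, dtype=bool)
    dx = np.zeros(n, dtype=bool)
    dx_age = np.full(n, math.nan)
    dx_stage = np.empty(n, dtype=object)
    dx_hist = np.empty(n, dtype=object)
    dx_mode = np.empty(n, dtype=object)
    death_age = np.full(n, math.nan)
    death_cause = np.empty(n, dtype=object)
    screen_ages: list = [[] for _ in range(n)]
    invited = np.zeros(n, dtype=bool)
    invite_age = np.full(n, math.nan)
    overdx = np.zeros(n, dtype=bool)

    for p in pop.persons:
        i = p.idx
        age_ref = reference_year - p.birth_year
        lc_unscr = p.lc_death_age.get(survival_era)
        death_unscr = p.oc_death_age
        if lc_unscr is not None:
            death_unscr = min(death_unscr, lc_unscr)
        if death_unscr <= age_ref:
            continue
        alive[i] = True
        tumor = p.tumor
        clin_det = tumor.clinical_detection_age if tumor else math.inf

        det_age = det_stage = det_hist = None
        cured = False
        lc_death = lc_unscr
        if strategy is not None:
            lh = LifeHistory(
                history=p.history,
                oc_death_age=p.oc_death_age,
                tumor=tumor,
                lc_death_age_unscreened=lc_unscr,
                covariates=p.covariates,
            )
            rng = _person_rng(pop.seed, i, 3)
            out = apply_screening(
                lh, strategy, inputs.sensitivity, inputs.cure, rng,
                start_age=age_ref,
            )
            screen_ages[i] = out.attended_ages
            invited[i] = out.invited
            if out.invited:
                invite_age[i] = float(out.scheduled_ages[0])
            overdx[i] = out.overdiagnosed
            if out.detection_age is not None:
                det_age, det_stage = out.detection_age, out.detection_stage
                det_hist = out.detection_histology
                cured = out.cured
                lc_death = out.lc_death_age

        if det_age is not None:
            dx[i] = True
            dx_age[i], dx_stage[i], dx_hist[i] = det_age, det_stage, det_hist
            dx_mode[i] = "screen"
        elif tumor is not None and clin_det < p.oc_death_age:
            dx[i] = True
            dx_age[i] = clin_det
            dx_stage[i] = tumor.stage_at_clinical_detection
            dx_hist[i] = tumor.histology
            dx_mode[i] = "clinical"
        else:
            dx_mode[i] = ""

        d_age = p.oc_death_age
        cause = "oc"
        if lc_death is not None and lc_death <= d_age:
            d_age, cause = lc_death, "lc"
        death_age[i], death_cause[i] = d_age, cause

    return ArmOutcome(
        strategy_name=strategy.name if strategy else "none",
        survival_era=survival_era,
        reference_year=reference_year,
        alive=alive, dx=dx, dx_age=dx_age, dx_stage=dx_stage,
        dx_histology=dx_hist, dx_mode=dx_mode, death_age=death_age,
        death_cause=death_cause, screen_ages=screen_ages, invited=invited,
        invite_age=invite_age, overdiagnosed=overdx,
    )


# ---------------------------------------------------------------------------
# Economics pass
# ---------------------------------------------------------------------------

@dataclass
class EconSettings:
    cost_schedule: CostSchedule
    cost_era: str
    utilities: UtilitySet
    rate_cost: float = 0.03
    rate_effects: float = 0.03


def economics_pass(
    arm: ArmOutcome,
    pop: Population,
    settings: EconSettings,
    config_hash: str = "",
) -> ScenarioResult:
    """Convert an arm's event layer into discounted LY/QALY/cost arrays."""
    n = pop.n
    ref = arm.reference_year
    df_eff = (1.0 + settings.rate_effects) ** (
        -(np.arange(MAX_MONTHS) + 0.5) / 12.0
    )
    ly_cum = np.concatenate([[0.0], np.cumsum(df_eff / 12.0)])

    # per (sex, birth_year) cumulative discounted QALY and monthly norm value
    util = settings.utilities
    norm_month: dict[tuple[str, int], np.ndarray] = {}
    qaly_cum: dict[tuple[str, int], np.ndarray] = {}
    for p in pop.persons:
        key = (p.sex, p.birth_year)
        if key in norm_month:
            continue
        age_ref = ref - p.birth_year
        ages = age_ref + (np.arange(MAX_MONTHS) + 0.5) / 12.0
        idx = np.clip(
            np.searchsorted(util.band_edges, ages, side="right") - 1, 0, None
        )
        nm = np.array([util.norm[(util.band_edges[j], p.sex)] for j in idx])
        norm_month[key] = nm
        qaly_cum[key] = np.concatenate([[0.0], np.cumsum(nm * df_eff / 12.0)])

    ly = np.zeros(n)
    qaly = np.zeros(n)
    costs = {item: np.zeros(n) for item in COST_ITEMS}
    lc_death = np.zeros(n, dtype=bool)
    screens = np.zeros(n, dtype=int)
    detected = np.zeros(n, dtype=bool)

    sched = settings.cost_schedule
    for p in pop.persons:
        i = p.idx
        if not arm.alive[i]:
            continue
        key = (p.sex, p.birth_year)
        age_ref = ref - p.birth_year
        months_alive = int(
            np.clip(math.ceil((arm.death_age[i] - age_ref) * 12.0), 1, MAX_MONTHS)
        )
        ly[i] = ly_cum[months_alive]
        qaly[i] = qaly_cum[key][months_alive]
        lc_death[i] = arm.death_cause[i] == "lc"

        if arm.dx[i]:
            detected[i] = arm.dx_mode[i] == "screen"
            dx_month_ref = int(round((arm.dx_age[i] - age_ref) * 12.0))
            death_m = max(1, math.ceil((arm.death_age[i] - arm.dx_age[i]) * 12.0))
            decomp = phase_decompose(0, death_m, arm.death_cause[i])
            m_dx, vals = accrue_treatment_cost(
                decomp, arm.dx_stage[i], arm.dx_histology[i],
                settings.cost_era, sched,
            )
            m_ref = dx_month_ref + m_dx - 1
            keep = m_ref >= 0
            sg = stage_group(arm.dx_stage[i])
            item = "care_I_II" if sg == "I-II" else "care_III_IV"
            costs[item][i] = discounted_stream(
                m_ref[keep], vals[keep], settings.rate_cost
            )
            # proportional care disutility on the QALY stream
            penalty = 0.0
            for iv in decomp.intervals:
                dis = util.care_disutility(sg, iv.phase)
                if dis <= 0:
                    continue
                lo = dx_month_ref + iv.start_month - 1
                hi = dx_month_ref + iv.end_month - 1
                lo = max(lo, 0)
                hi = min(hi, months_alive - 1, MAX_MONTHS - 1)
                if hi < lo:
                    continue
                span = np.arange(lo, hi + 1)
                penalty += float(
                    (norm_month[key][span] * df_eff[span]).sum() / 12.0 * dis
                )
            qaly[i] -= penalty

        if arm.screen_ages[i]:
            s_months = np.array(
                [(a - age_ref) * 12.0 for a in arm.screen_ages[i]], dtype=float
            )
            screens[i] = len(s_months)
            per_screen = (sched.ct_screen + sched.admin_overhead) * sched.price_index_factor
            costs["ct"][i] = discounted_stream(
                s_months, np.full(len(s_months), per_screen), settings.rate_cost
            )
            costs["followup"][i] = discounted_stream(
                s_months[:1],
                [sched.followup_per_participant * sched.price_index_factor],
                settings.rate_cost,
            )
        if arm.invited[i]:
            inv_month = max((arm.invite_age[i] - age_ref) * 12.0, 0.0)
            costs["risk_assessment"][i] = discounted_stream(
                [inv_month],
                [sched.risk_assessment_per_invitee * sched.price_index_factor],
                settings.rate_cost,
            )

    return ScenarioResult(
        name=arm.strategy_name,
        n_simulated=n,
        n_alive_at_start=int(arm.alive.sum()),
        population_hash=pop.pop_hash,
        seed=pop.seed,
        config_hash=config_hash,
        ly=ly,
        qaly=qaly,
        costs=costs,
        lc_death=lc_death,
        screens_attended=screens,
        screen_detected=detected,
        overdiagnosed=arm.overdiagnosed.copy(),
        meta={"era": arm.survival_era},
    )


# ---------------------------------------------------------------------------
# Top-level entry points
# ---------------------------------------------------------------------------

def econ_settings_from_config(config: ScenarioConfig, inputs: ModelInputs) -> EconSettings:
    return EconSettings(
        cost_schedule=inputs.cost_schedule,
        cost_era=config.cost_era,
        utilities=inputs.utilities[config.utility_instrument],
        rate_cost=config.discount_rate_cost,
        rate_effects=config.discount_rate_effects,
    )


def run_scenario(
    config: ScenarioConfig,
    inputs: ModelInputs | None = None,
    population: Population | None = None,
) -> ScenarioResult:
    """Run one scenario (screening strategy or none) end to end."""
    if inputs is None:
        inputs = build_default_inputs(config.seed, config.registry_n)
    if population is None:
        population = build_population(
            config.n, config.seed, inputs, config.birth_years
        )
    arm = simulate_arm(
        population, config.resolve_strategy(), config.survival_era, inputs,
        config.reference_year,
    )
    return economics_pass(
        arm, population, econ_settings_from_config(config, inputs),
        config.config_hash(),
    )


def run_comparison(
    config: ScenarioConfig,
    inputs: ModelInputs | None = None,
    population: Population | None = None,
) -> tuple[CEComparison, ScenarioResult, ScenarioResult]:
    """Run the strategy and its no-screening counterfactual, then compare."""
    if config.strategy is None:
        raise ConfigurationError("comparison needs a screening strategy")
    if inputs is None:
        inputs = build_default_inputs(config.seed, config.registry_n)
    if population is None:
        population = build_population(
            config.n, config.seed, inputs, config.birth_years
        )
    base = run_scenario(replace(config, strategy=None), inputs, population)
    alt = run_scenario(config, inputs, population)
    comp = compare_scenarios(base, alt, wtp=config.wtp)
    return comp, base, alt


SENSITIVITY_ROWS = (
    "before_novel_treatment",
    "baseline",
    "updating_survival_only",
    "updating_cost_only",
    "discount_0pct",
    "discount_6pct",
    "differential_discounting",
    "stage_iv_terminal_cost_to_early",
    "early_stage_cost_plus30",
    "early_stage_cost_minus30",
    "late_stage_cost_plus30",
    "late_stage_cost_minus30",
    "ct_admin_cost_plus30",
    "ct_admin_cost_minus30",
    "attendance_50pct",
    "vas_utility",
)


def run_sensitivity(
    config: ScenarioConfig,
    inputs: ModelInputs | None = None,
    population: Population | None = None,
) -> pd.DataFrame:
    """Univariate sensitivity grid around the configured strategy.

    Cost, utility and discount toggles reuse the baseline arms (no
    re-simulation); survival-era and adherence toggles re-simulate the
    affected arm. Each row reports incremental outcomes against a matching
    no-screening arm and the percent difference of the cost-effectiveness
    ratios against the baseline row.
    """
    if inputs is None:
        inputs = build_default_inputs(config.seed, config.registry_n)
    if population is None:
        population = build_population(
            config.n, config.seed, inputs, config.birth_years
        )
    strategy = config.resolve_strategy()
    if strategy is None:
        raise ConfigurationError("sensitivity analysis needs a screening strategy")

    arms: dict[tuple[str, str], ArmOutcome] = {}

    def arm(strat, era):
        key = (strat.name if strat else "none",
               strat.adherence if strat else None, era)
        if key not in arms:
            arms[key] = simulate_arm(
                population, strat, era, inputs, config.reference_year
            )
        return arms[key]

    base_sched = inputs.cost_schedule
    eq5d = inputs.utilities["eq5d"]
    vas = inputs.utilities["vas"]
    rc, re_ = config.discount_rate_cost, config.discount_rate_effects

    def settings(sched=base_sched, cost_era="post", util=eq5d, rate_cost=rc,
                 rate_eff=re_):
        return EconSettings(sched, cost_era, util, rate_cost, rate_eff)

    def row(name, strat, era, st):
        base = economics_pass(arm(None, era), population, st)
        alt = economics_pass(arm(strat, era), population, st)
        comp = compare_scenarios(base, alt, wtp=config.wtp)
        return name, comp

    reduced = strategy.with_adherence(defaults.REDUCED_ADHERENCE)
    grid = [
        row("before_novel_treatment", strategy, "pre", settings(cost_era="pre")),
        row("baseline", strategy, "post", settings()),
        row("updating_survival_only", strategy, "post", settings(cost_era="pre")),
        row("updating_cost_only", strategy, "pre", settings(cost_era="post")),
        row("discount_0pct", strategy, "post",
            settings(rate_cost=0.0, rate_eff=0.0)),
        row("discount_6pct", strategy, "post",
            settings(rate_cost=0.06, rate_eff=0.06)),
        row("differential_discounting", strategy, "post",
            settings(rate_cost=0.03, rate_eff=0.015)),
        row("stage_iv_terminal_cost_to_early", strategy, "post",
            settings(sched=base_sched.substitute_terminal_cost())),
        row("early_stage_cost_plus30", strategy, "post",
            settings(sched=base_sched.scale_treatment({"I-II": 1.3}))),
        row("early_stage_cost_minus30", strategy, "post",
            settings(sched=base_sched.scale_treatment({"I-II": 0.7}))),
        row("late_stage_cost_plus30", strategy, "post",
            settings(sched=base_sched.scale_treatment({"III-IV": 1.3}))),
        row("late_stage_cost_minus30", strategy, "post",
            settings(sched=base_sched.scale_treatment({"III-IV": 0.7}))),
        row("ct_admin_cost_plus30", strategy, "post",
            settings(sched=base_sched.scale_screening(1.3))),
        row("ct_admin_cost_minus30", strategy, "post",
            settings(sched=base_sched.scale_screening(0.7))),
        row("attendance_50pct", reduced, "post", settings()),
        row("vas_utility", strategy, "post", settings(util=vas)),
    ]

    baseline_comp = dict(grid)["baseline"]
    rows = []
    for name, comp in grid:
        r = {
            "analysis": name,
            "qaly_gained": comp.delta_qaly,
            "ly_gained": comp.delta_ly,
            "cost_total": comp.delta_cost_total,
            "cost_per_qaly": comp.cost_per_qaly,
            "cost_per_ly": comp.cost_per_ly,
        }
        r["diff_cost_per_qaly_pct"] = (
            100.0 * (comp.cost_per_qaly / baseline_comp.cost_per_qaly - 1.0)
        )
        r["diff_cost_per_ly_pct"] = (
            100.0 * (comp.cost_per_ly / baseline_comp.cost_per_ly - 1.0)
        )
        rows.append(r)
    return pd.DataFrame(rows)


def report(
    comparisons: list[CEComparison],
    out_dir,
    sensitivity: pd.DataFrame | None = None,
    meta: dict | None = None,
) -> dict:
    """Write tidy result tables and a machine-readable run manifest."""
    import pathlib

    out = pathlib.Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    table1 = pd.DataFrame([c.to_row() for c in comparisons])
    table1.to_csv(out / "strategy_comparison.csv", index=False)
    paths = {"strategy_comparison": str(out / "strategy_comparison.csv")}
    if sensitivity is not None:
        sensitivity.to_csv(out / "sensitivity.csv", index=False)
        paths["sensitivity"] = str(out / "sensitivity.csv")
    manifest = {"outputs": paths, **(meta or {})}
    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, default=str)
    return manifest
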