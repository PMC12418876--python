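"""Discounting, utilities, QALY accounting and scenario comparison.

Person-time is discounted at mid-month (each month of life counts at its
midpoint); event costs are discounted at the event month. Quality
adjustment multiplies each month of life by the population norm utility of
the attained age band and sex, reduced proportionally while the person is
in a lung cancer care phase. Scenario comparisons are person-paired under
common random numbers and scaled per 100,000 individuals alive at the
start of screening.
"""

from __future__ import annotations

import hashlib
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import ConfigurationError, PopulationMismatchError

DEFAULT_WTP = 20_000.0


# ---------------------------------------------------------------------------
# Discounting
# ---------------------------------------------------------------------------

def discount(amount: float, annual_rate: float, years_from_reference: float) -> float:
    """Present value of ``amount`` occurring ``years_from_reference`` ahead."""
    if annual_rate < 0:
        raise ValueError("discount rate must be non-negative")
    return amount / (1.0 + annual_rate) ** years_from_reference


def annuity_factor(years: int, annual_rate: float) -> float:
    """Present value of a unit payment at the end of each of ``years`` years."""
    if annual_rate == 0:
        return float(years)
    return (1.0 - (1.0 + annual_rate) ** -years) / annual_rate


def month_discount_factors(
    start_month: int, n_months: int, annual_rate: float
) -> np.ndarray:
    """Mid-month discount factors for months ``start_month .. +n_months``.

    Month ``m`` (0-based from the reference date) is discounted at time
    ``(m + 0.5) / 12`` years.
    """
    if n_months <= 0:
        return np.zeros(0)
    m = np.arange(start_month, start_month + n_months, dtype=float)
    return (1.0 + annual_rate) ** (-(m + 0.5) / 12.0)


def discounted_stream(
    months: np.ndarray, values: np.ndarray, annual_rate: float
) -> float:
    """Present value of event values occurring at given months (mid-month)."""
    months = np.asarray(months, dtype=float)
    values = np.asarray(values, dtype=float)
    return float((values * (1.0 + annual_rate) ** (-(months + 0.5) / 12.0)).sum())


# ---------------------------------------------------------------------------
# Utilities
# ---------------------------------------------------------------------------

@dataclass
class UtilitySet:
    """Norm utilities by age band x sex, plus proportional care disutilities.

    ``norm`` maps (band_lower_age, sex) to a utility in [0, 1]; bands are
    defined by their lower edges in ``band_edges``. ``disutility`` maps
    (stage_group, phase) to the proportional reduction applied to the norm
    utility while in that care phase.
    """

    band_edges: tuple[int, ...]
    norm: dict[tuple[int, str], float]
    disutility: dict[tuple[str, str], float]
    name: str = "eq5d"

    def __post_init__(self):
        for key, val in self.norm.items():
            if not 0.0 <= val <= 1.0:
                raise ConfigurationError(f"norm utility out of [0,1] at {key!r}")
        for key, val in self.disutility.items():
            if not 0.0 <= val <= 1.0:
                raise ConfigurationError(f"disutility out of [0,1] at {key!r}")

    def norm_utility(self, age: float, sex: str) -> float:
        edges = self.band_edges
        idx = int(np.searchsorted(edges, age, side="right")) - 1
        idx = max(idx, 0)
        try:
            return self.norm[(edges[idx], sex)]
        except KeyError:
            raise ConfigurationError(
                f"no norm utility for age band {edges[idx]}, sex {sex!r}"
            ) from None

    def norm_vector(self, age_at_ref: float, sex: str, n_months: int) -> np.ndarray:
        """Norm utility per month of life from the reference date."""
        ages = age_at_ref + (np.arange(n_months) + 0.5) / 12.0
        idx = np.clip(
            np.searchsorted(self.band_edges, ages, side="right") - 1, 0, None
        )
        return np.array([self.norm[(self.band_edges[i], sex)] for i in idx])

    def care_disutility(self, sg: str, phase: str) -> float:
        try:
            return self.disutility[(sg, phase)]
        except KeyError:
            raise ConfigurationError(
                f"no disutility for stage group {sg!r}, phase {phase!r}"
            ) from None


def qaly_stream(
    age_at_ref: float,
    sex: str,
    months_alive: int,
    utilities: UtilitySet,
    care_months: dict[int, float] | None = None,
) -> np.ndarray:
    """Monthly utility weights (undiscounted, years) from reference to death.

    ``care_months`` maps month index (0-based from reference) to the
    proportional disutility applying in that month.
    """
    w = utilities.norm_vector(age_at_ref, sex, months_alive) / 12.0
    if care_months:
        for mth, dis in care_months.items():
            if 0 <= mth < months_alive:
                w[mth] *= 1.0 - dis
    return w


# ---------------------------------------------------------------------------
# Scenario comparison
# ---------------------------------------------------------------------------

COST_ITEMS = ("ct", "followup", "risk_assessment", "care_I_II", "care_III_IV")


@dataclass
class ScenarioResult:
    """Aggregated per-person outcomes of one scenario run."""

    name: str
    n_simulated: int
    n_alive_at_start: int
    population_hash: str
    seed: int
    config_hash: str
    ly: np.ndarray  # discounted, per person
    qaly: np.ndarray
    costs: dict[str, np.ndarray]  # per item, per person
    lc_death: np.ndarray  # bool, per person
    screens_attended: np.ndarray
    screen_detected: np.ndarray
    overdiagnosed: np.ndarray
    meta: dict = field(default_factory=dict)

    @property
    def total_cost(self) -> np.ndarray:
        return sum(self.costs[item] for item in COST_ITEMS)

    def aggregate(self) -> dict:
        out = {
            "n_simulated": self.n_simulated,
            "n_alive_at_start": self.n_alive_at_start,
            "ly": float(self.ly.sum()),
            "qaly": float(self.qaly.sum()),
            "lc_deaths": int(self.lc_death.sum()),
            "screens": int(self.screens_attended.sum()),
            "screen_detected": int(self.screen_detected.sum()),
            "overdiagnosed": int(self.overdiagnosed.sum()),
            "cost_total": float(self.total_cost.sum()),
        }
        for item in COST_ITEMS:
            out[f"cost_{item}"] = float(self.costs[item].sum())
        return out


@dataclass
class CEComparison:
    """Incremental outcomes of a screening scenario against no screening.

    All quantities are discounted and scaled per ``scale_to`` individuals
    alive at the start of screening.
    """

    strategy: str
    era: str
    scale_to: float
    delta_ly: float
    delta_qaly: float
    delta_costs: dict[str, float]
    deaths_prevented: float
    deaths_prevented_pct: float
    wtp: float

    @property
    def delta_cost_total(self) -> float:
        return float(sum(self.delta_costs.values()))

    @property
    def icer_defined(self) -> bool:
        return self.delta_qaly > 0

    @property
    def cost_per_qaly(self) -> float:
        return self.delta_cost_total / self.delta_qaly if self.icer_defined else math.nan

    @property
    def cost_per_ly(self) -> float:
        return self.delta_cost_total / self.delta_ly if self.delta_ly > 0 else math.nan

    @property
    def nmb(self) -> float:
        return self.wtp * self.delta_qaly - self.delta_cost_total

    def to_row(self) -> dict:
        row = {
            "strategy": self.strategy,
            "era": self.era,
            "deaths_prevented": self.deaths_prevented,
            "deaths_prevented_pct": self.deaths_prevented_pct,
            "ly_gained": self.delta_ly,
            "qaly_gained": self.delta_qaly,
        }
        for item in COST_ITEMS:
            row[f"cost_{item}"] = self.delta_costs[item]
        row["cost_total"] = self.delta_cost_total
        row["cost_per_ly"] = self.cost_per_ly
        row["cost_per_qaly"] = self.cost_per_qaly
        row["nmb"] = self.nmb
        return row


def compare_scenarios(
    base: ScenarioResult,
    alt: ScenarioResult,
    wtp: float = DEFAULT_WTP,
    scale_to: float = 100_000.0,
) -> CEComparison:
    """Person-paired incremental comparison (alt minus base).

    Both results must come from the identical simulated population (common
    random numbers); a mismatch is a hard error.
    """
    if (
        base.n_simulated != alt.n_simulated
        or base.population_hash != alt.population_hash
    ):
        raise PopulationMismatchError(
            "scenario results were not produced on the same population"
        )
    n_alive = base.n_alive_at_start
    factor = scale_to / n_alive if n_alive else math.nan
    base_deaths = int(base.lc_death.sum())
    prevented = base_deaths - int(alt.lc_death.sum())
    return CEComparison(
        strategy=alt.name,
        era=alt.meta.get("era", ""),
        scale_to=scale_to,
        delta_ly=float((alt.ly - base.ly).sum()) * factor,
        delta_qaly=float((alt.qaly - base.qaly).sum()) * factor,
        delta_costs={
            item: float((alt.costs[item] - base.costs[item]).sum()) * factor
            for item in COST_ITEMS
        },
        deaths_prevented=prevented * factor,
        deaths_prevented_pct=100.0 * prevented / base_deaths if base_deaths else math.nan,
        wtp=wtp,
    )


def population_hash(seed: int, n: int, extra: str = "") -> str:
    h = hashlib.sha1(f"{seed}|{n}|{extra}".encode())
    return h.hexdigest()[:16]
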