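"""Phase-of-care treatment costs and screening programme costs.

Post-diagnosis months are split into an initial phase (first 6 months of
treatment), a terminal phase (final 6 months of life, tagged by cause of
death) and a continuing phase (any intermittent care in between, capped at
5 years post-diagnosis; months beyond the cap carry zero treatment cost).
For short survivors the terminal phase takes precedence over the initial
phase (SEER-style convention). Costs per patient-month are read from a
schedule keyed by stage group (I-II vs III-IV), phase and treatment era.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .errors import ConfigurationError

PHASE_INITIAL = "initial"
PHASE_CONTINUING = "continuing"
PHASE_TERMINAL_LC = "terminal_lc"
PHASE_TERMINAL_OC = "terminal_oc"
PHASES = (PHASE_INITIAL, PHASE_CONTINUING, PHASE_TERMINAL_LC, PHASE_TERMINAL_OC)

STAGE_GROUPS = ("I-II", "III-IV")
ERAS = ("pre", "post")

INITIAL_MONTHS = 6
TERMINAL_MONTHS = 6
CONTINUING_CAP_MONTHS = 60  # continuing care capped at 5 years post-diagnosis


def stage_group(stage: str) -> str:
    """Map a TNM stage to the early (I-II) / late (III-IV) cost group."""
    if stage in ("IA", "IB", "II"):
        return "I-II"
    if stage in ("IIIA", "IIIB", "IV"):
        return "III-IV"
    raise ConfigurationError(f"unknown stage {stage!r}")


@dataclass
class CostSchedule:
    """Euro per patient-month by stage group x phase x era, plus unit costs.

    ``treatment`` maps ``(stage_group, phase, era)`` to a monthly cost;
    era entries are independent (no implied ratio). Screening unit costs
    cover the CT scan itself, administrative overhead per attended screen,
    a one-off risk assessment per invitee and an aggregate follow-up cost
    per participant. ``price_index_factor`` rescales all costs to the
    reporting price level.
    """

    treatment: dict[tuple[str, str, str], float]
    ct_screen: float = 0.0
    admin_overhead: float = 0.0
    followup_per_participant: float = 0.0
    risk_assessment_per_invitee: float = 0.0
    price_index_factor: float = 1.0

    def __post_init__(self):
        for cell, val in self.treatment.items():
            if val < 0:
                raise ConfigurationError(f"negative cost in cell {cell!r}")
        for name in ("ct_screen", "admin_overhead", "followup_per_participant",
                     "risk_assessment_per_invitee"):
            if getattr(self, name) < 0:
                raise ConfigurationError(f"negative screening cost {name}")

    def monthly_cost(self, sg: str, phase: str, era: str) -> float:
        try:
            return self.treatment[(sg, phase, era)] * self.price_index_factor
        except KeyError:
            raise ConfigurationError(
                f"cost schedule missing cell (stage_group={sg!r}, "
                f"phase={phase!r}, era={era!r})"
            ) from None

    # -- sensitivity-analysis helpers -------------------------------------
    def scale_treatment(self, factors: dict[str, float]) -> "CostSchedule":
        """Scale treatment costs per stage group (e.g. {"I-II": 1.3})."""
        new = {
            cell: val * factors.get(cell[0], 1.0)
            for cell, val in self.treatment.items()
        }
        return replace(self, treatment=new)

    def scale_screening(self, factor: float) -> "CostSchedule":
        """Scale CT and administration unit costs."""
        return replace(
            self,
            ct_screen=self.ct_screen * factor,
            admin_overhead=self.admin_overhead * factor,
        )

    def substitute_terminal_cost(self) -> "CostSchedule":
        """Apply stage III-IV terminal lung cancer cost to stage I-II cases."""
        new = dict(self.treatment)
        for era in ERAS:
            if ("III-IV", PHASE_TERMINAL_LC, era) in new:
                new[("I-II", PHASE_TERMINAL_LC, era)] = new[
                    ("III-IV", PHASE_TERMINAL_LC, era)
                ]
        return replace(self, treatment=new)

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {"stage_group": sg, "phase": ph, "era": era, "cost_per_month": v}
            for (sg, ph, era), v in sorted(self.treatment.items())
        ]
        return pd.DataFrame(rows)


@dataclass(frozen=True)
class PhaseInterval:
    phase: str
    start_month: int  # 1-based months since diagnosis, inclusive
    end_month: int

    @property
    def n_months(self) -> int:
        return self.end_month - self.start_month + 1


@dataclass
class PhaseDecomposition:
    intervals: list[PhaseInterval]

    def __post_init__(self):
        last_end = 0
        for iv in self.intervals:
            if iv.start_month <= last_end:
                raise ValueError("phase intervals must be disjoint and ordered")
            last_end = iv.end_month


def phase_decompose(
    diagnosis_month: int, death_month: int | None, cause: str
) -> PhaseDecomposition:
    """Split post-diagnosis months into care phases.

    ``death_month`` counts months survived from diagnosis (death during
    month M, 1-based); ``None`` with cause ``"alive"`` means alive at the
    horizon. The terminal phase is the final 6 months of life and takes
    precedence over the initial phase for short survivors; continuing care
    is the remainder, capped 5 years after diagnosis.
    """
    if cause not in ("lc", "oc", "alive"):
        raise ValueError(f"unknown cause {cause!r}")
    if death_month is not None and death_month < 1:
        raise ValueError("death month must be >= 1")
    intervals: list[PhaseInterval] = []
    if death_month is None or cause == "alive":
        intervals.append(PhaseInterval(PHASE_INITIAL, 1, INITIAL_MONTHS))
        intervals.append(
            PhaseInterval(PHASE_CONTINUING, INITIAL_MONTHS + 1, CONTINUING_CAP_MONTHS)
        )
        return PhaseDecomposition(intervals)

    terminal_phase = PHASE_TERMINAL_LC if cause == "lc" else PHASE_TERMINAL_OC
    term_start = max(1, death_month - TERMINAL_MONTHS + 1)
    init_end = min(INITIAL_MONTHS, term_start - 1)
    if init_end >= 1:
        intervals.append(PhaseInterval(PHASE_INITIAL, 1, init_end))
    cont_start = init_end + 1
    cont_end = min(term_start - 1, CONTINUING_CAP_MONTHS)
    if cont_end >= cont_start:
        intervals.append(PhaseInterval(PHASE_CONTINUING, cont_start, cont_end))
    intervals.append(PhaseInterval(terminal_phase, term_start, death_month))
    return PhaseDecomposition(intervals)


def accrue_treatment_cost(
    decomposition: PhaseDecomposition,
    stage: str,
    histology: str,
    era: str,
    schedule: CostSchedule,
) -> tuple[np.ndarray, np.ndarray]:
    """Undiscounted monthly treatment cost stream for one case.

    Returns (month indices since diagnosis, cost per month). Histology is
    accepted for interface completeness; the default schedules are keyed by
    stage group only.
    """
    sg = stage_group(stage)
    months, values = [], []
    for iv in decomposition.intervals:
        c = schedule.monthly_cost(sg, iv.phase, era)
        for mth in range(iv.start_month, iv.end_month + 1):
            months.append(mth)
            values.append(c)
    return np.asarray(months, dtype=int), np.asarray(values, dtype=float)


def accrue_screening_cost(
    attended_months: np.ndarray,
    invited: bool,
    schedule: CostSchedule,
    invitation_month: int | None = None,
) -> pd.DataFrame:
    """Screening cost events for one person, by month from reference.

    Per attended screen: CT plus administrative overhead. Per invitee: one
    risk-assessment cost at the invitation month. Per participant (one or
    more attended screens): one aggregate follow-up cost line at the first
    attended screen.
    """
    f = schedule.price_index_factor
    rows = []
    for mth in np.asarray(attended_months, dtype=int):
        rows.append({"month": int(mth), "item": "ct", "cost": schedule.ct_screen * f})
        rows.append(
            {"month": int(mth), "item": "admin", "cost": schedule.admin_overhead * f}
        )
    if invited:
        m0 = invitation_month
        if m0 is None:
            m0 = int(attended_months[0]) if len(attended_months) else 0
        rows.append(
            {
                "month": m0,
                "item": "risk_assessment",
                "cost": schedule.risk_assessment_per_invitee * f,
            }
        )
    if len(attended_months):
        rows.append(
            {
                "month": int(attended_months[0]),
                "item": "followup",
                "cost": schedule.followup_per_participant * f,
            }
        )
    return pd.DataFrame(rows, columns=["month", "item", "cost"])
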