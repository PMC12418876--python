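"""Birth-cohort population layer: smoking histories and other-cause mortality.

Smoking behaviour is simulated per sex and birth cohort from three primitives:
an age-indexed initiation probability (conditional on never having smoked),
an age-indexed cessation hazard (conditional on currently smoking) and a
cigarettes-per-day (CPD) distribution. Other-cause (non-lung-cancer) death
ages are drawn from cohort life tables whose hazard is multiplied by a
smoking-status relative risk, with the status evaluated dynamically along the
life course: the multiplier changes at the ages smoking starts and stops.

Because published life tables are all-cause tables for the whole population,
:func:`split_life_table_by_smoking` solves for the never-smoker baseline
hazard such that the prevalence-weighted hazard over the simulated smoking
statuses reproduces the input table.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from functools import cached_property

import numpy as np
import pandas as pd
from scipy.special import ndtri

from .errors import ConfigurationError

MALE = "male"
FEMALE = "female"
SEXES = (MALE, FEMALE)

NEVER = "never"
CURRENT = "current"
FORMER = "former"
SMOKING_STATUSES = (NEVER, CURRENT, FORMER)


@dataclass(frozen=True)
class IntensitySegment:
    """Piecewise-constant smoking intensity over an age interval."""

    age_from: float
    age_to: float  # math.inf while still smoking
    cpd: float

    def __post_init__(self):
        if self.age_to <= self.age_from:
            raise ValueError("segment must span a positive age interval")
        if self.cpd <= 0:
            raise ValueError("segment intensity must be positive")


@dataclass(frozen=True)
class SmokingHistory:
    """One person's smoking trajectory.

    ``start_age is None`` encodes a never-smoker; ``quit_age is None`` with a
    start age encodes a smoker who never quits (current smoker for life).
    """

    sex: str
    birth_year: int
    start_age: float | None = None
    quit_age: float | None = None
    segments: tuple[IntensitySegment, ...] = ()

    def __post_init__(self):
        if self.sex not in SEXES:
            raise ValueError(f"unknown sex {self.sex!r}")
        if self.start_age is None:
            if self.quit_age is not None or self.segments:
                raise ValueError("never-smokers carry no quit age or intensity")
        else:
            if self.quit_age is not None and self.quit_age <= self.start_age:
                raise ValueError("quit age must exceed start age")
            for seg in self.segments:
                if seg.age_from < self.start_age - 1e-9:
                    raise ValueError("intensity before start age")
                end = self.quit_age if self.quit_age is not None else math.inf
                if seg.age_to > end + 1e-9:
                    raise ValueError("intensity after quit age")

    @property
    def ever_smoker(self) -> bool:
        return self.start_age is not None

    def status(self, age: float) -> str:
        """Smoking status attained at ``age``."""
        if self.start_age is None or age < self.start_age:
            return NEVER
        if self.quit_age is not None and age >= self.quit_age:
            return FORMER
        return CURRENT

    def duration(self, age: float) -> float:
        """Years actively smoked up to ``age``."""
        if self.start_age is None:
            return 0.0
        stop = age if self.quit_age is None else min(age, self.quit_age)
        return max(0.0, stop - self.start_age)

    def mean_cpd(self) -> float:
        """Exposure-time-weighted mean cigarettes per day."""
        if not self.segments:
            return 0.0
        num = den = 0.0
        for seg in self.segments:
            span = min(seg.age_to, 200.0) - seg.age_from
            num += seg.cpd * span
            den += span
        return num / den if den > 0 else 0.0


def packyears(history: SmokingHistory, age: float) -> float:
    """Cumulative packyears smoked up to ``age`` (CPD/20 integrated over time)."""
    if age < 0:
        raise ValueError("age must be non-negative")
    total = 0.0
    for seg in history.segments:
        span = min(age, seg.age_to) - seg.age_from
        if span > 0:
            total += seg.cpd / 20.0 * span
    return total


def packyears_grid(history: SmokingHistory, ages: np.ndarray) -> np.ndarray:
    """Vectorised :func:`packyears` over an array of ages."""
    out = np.zeros_like(ages, dtype=float)
    for seg in history.segments:
        span = np.clip(np.minimum(ages, seg.age_to) - seg.age_from, 0.0, None)
        out += seg.cpd / 20.0 * span
    return out


def years_since_quit(history: SmokingHistory, age: float) -> float | None:
    """Years since cessation: 0 for current smokers, ``None`` for never-smokers."""
    if history.start_age is None:
        return None
    if history.quit_age is None or age < history.quit_age:
        return 0.0
    return age - history.quit_age


@dataclass
class SmokingParams:
    """Initiation/cessation/intensity primitives for one sex x cohort stratum.

    initiation_prob[a]
        probability of starting to smoke during age ``a`` given never having
        smoked before.
    cessation_hazard[a]
        probability of quitting during age ``a`` given currently smoking.
    cpd_log_mean, cpd_log_sd
        log-normal parameters of the CPD distribution (clipped to bounds).
    """

    initiation_prob: np.ndarray
    cessation_hazard: np.ndarray
    cpd_log_mean: float
    cpd_log_sd: float
    cpd_bounds: tuple[float, float] = (1.0, 80.0)

    def __post_init__(self):
        self.initiation_prob = np.asarray(self.initiation_prob, dtype=float)
        self.cessation_hazard = np.asarray(self.cessation_hazard, dtype=float)
        for arr in (self.initiation_prob, self.cessation_hazard):
            if np.any((arr < 0) | (arr > 1)):
                raise ConfigurationError("smoking probabilities must lie in [0, 1]")

    @cached_property
    def _init_cdf(self) -> np.ndarray:
        p = self.initiation_prob
        never = np.concatenate([[1.0], np.cumprod(1.0 - p)])[:-1]
        return np.cumsum(p * never)

    @cached_property
    def _log_no_quit(self) -> np.ndarray:
        # cumulative log-probability of not having quit through each age
        with np.errstate(divide="ignore"):
            return np.cumsum(np.log1p(-np.clip(self.cessation_hazard, 0, 1 - 1e-12)))


@dataclass
class SmokingParamSet:
    """Smoking parameters keyed by sex and birth-cohort band."""

    strata: dict[tuple[str, int], SmokingParams]
    band_width: int = 5

    def get(self, sex: str, birth_year: int) -> SmokingParams:
        starts = sorted(b for s, b in self.strata if s == sex)
        if not starts:
            raise ConfigurationError(f"no smoking parameters for sex {sex!r}")
        for b in reversed(starts):
            if b <= birth_year < b + self.band_width:
                return self.strata[(sex, b)]
        raise ConfigurationError(
            f"no smoking parameters for sex {sex!r}, birth year {birth_year}"
        )


def simulate_smoking_history(
    params: SmokingParamSet | SmokingParams,
    sex: str,
    birth_year: int,
    rng: np.random.Generator | int,
) -> SmokingHistory:
    """Draw one complete smoking history; reproducible given the rng state."""
    if isinstance(rng, (int, np.integer)):
        rng = np.random.default_rng(rng)
    p = params.get(sex, birth_year) if isinstance(params, SmokingParamSet) else params

    u_init, u_quit, u_cpd = rng.random(3)

    cdf = p._init_cdf
    if cdf.size == 0 or u_init >= cdf[-1]:
        return SmokingHistory(sex=sex, birth_year=birth_year)
    start = int(np.searchsorted(cdf, u_init, side="right"))

    # cessation: hazard applies from the year after initiation
    lnq = p._log_no_quit
    base = lnq[start] if start < lnq.size else lnq[-1]
    target = base + math.log1p(-u_quit)
    quit_age: float | None = None
    idx = np.searchsorted(-lnq, -target, side="left")
    if idx < lnq.size and lnq[idx] <= target:
        quit_age = float(max(idx, start + 1))
        if quit_age >= lnq.size:
            quit_age = None

    z = ndtri(min(max(u_cpd, 1e-12), 1 - 1e-12))
    cpd = math.exp(p.cpd_log_mean + p.cpd_log_sd * z)
    cpd = min(max(cpd, p.cpd_bounds[0]), p.cpd_bounds[1])

    seg_end = quit_age if quit_age is not None else math.inf
    return SmokingHistory(
        sex=sex,
        birth_year=birth_year,
        start_age=float(start),
        quit_age=quit_age,
        segments=(IntensitySegment(float(start), seg_end, cpd),),
    )


class LifeTable:
    """Cohort life table: annual all-cause death probability by sex, cohort, age.

    Backed by a tidy frame with columns ``sex, birth_cohort, age, q_annual``;
    ages must be contiguous integers and shared across strata.
    """

    COLUMNS = ("sex", "birth_cohort", "age", "q_annual")

    def __init__(self, frame: pd.DataFrame):
        missing = set(self.COLUMNS) - set(frame.columns)
        if missing:
            raise ConfigurationError(f"life table missing columns {sorted(missing)}")
        frame = frame.sort_values(["sex", "birth_cohort", "age"]).reset_index(drop=True)
        q = frame["q_annual"].to_numpy(dtype=float)
        if np.any((q < 0) | (q > 1)):
            raise ConfigurationError("life table probabilities must lie in [0, 1]")
        self._frame = frame
        self._q: dict[tuple[str, int], np.ndarray] = {}
        self._age0: int | None = None
        for (sex, cohort), grp in frame.groupby(["sex", "birth_cohort"], sort=True):
            ages = grp["age"].to_numpy(dtype=int)
            if not np.array_equal(ages, np.arange(ages[0], ages[0] + len(ages))):
                raise ConfigurationError("life table ages must be contiguous integers")
            if self._age0 is None:
                self._age0 = int(ages[0])
            elif self._age0 != ages[0]:
                raise ConfigurationError("life table strata must share the age range")
            self._q[(sex, int(cohort))] = grp["q_annual"].to_numpy(dtype=float)
        self._cohorts = {
            s: np.array(sorted(c for (sx, c) in self._q if sx == s)) for s in SEXES
        }
        k = next(iter(self._q))
        self._n_ages = len(self._q[k])

    # -- accessors ---------------------------------------------------------
    @property
    def age_min(self) -> int:
        return self._age0 or 0

    @property
    def age_max(self) -> int:
        return (self._age0 or 0) + self._n_ages - 1

    def to_frame(self) -> pd.DataFrame:
        return self._frame.copy()

    def to_csv(self, path) -> None:
        self._frame.to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path) -> "LifeTable":
        return cls(pd.read_csv(path))

    def nearest_cohort(self, sex: str, birth_year: int) -> int:
        cohorts = self._cohorts.get(sex)
        if cohorts is None or cohorts.size == 0:
            raise ConfigurationError(f"life table has no cohorts for sex {sex!r}")
        return int(cohorts[np.argmin(np.abs(cohorts - birth_year))])

    def q_array(self, sex: str, birth_year: int) -> np.ndarray:
        return self._q[(sex, self.nearest_cohort(sex, birth_year))]

    def hazard_array(self, sex: str, birth_year: int) -> np.ndarray:
        q = np.clip(self.q_array(sex, birth_year), 0.0, 1.0 - 1e-12)
        return -np.log1p(-q)

    def annual_q(self, sex: str, birth_year: int, age: float) -> float:
        q = self.q_array(sex, birth_year)
        idx = int(math.floor(age)) - self.age_min
        idx = min(max(idx, 0), len(q) - 1)
        return float(q[idx])

    def expected_monthly_survival(self, sex: str, birth_year: int, age: float) -> float:
        """One-month survival probability of a general-population peer."""
        return (1.0 - self.annual_q(sex, birth_year, age)) ** (1.0 / 12.0)


def _status_multipliers(
    history: SmokingHistory, rr: dict[str, float], n_ages: int, age0: int
) -> np.ndarray:
    m = np.full(n_ages, rr.get(NEVER, 1.0))
    if history.start_age is not None:
        s = max(int(math.floor(history.start_age)) - age0, 0)
        m[s:] = rr[CURRENT]
        if history.quit_age is not None:
            qi = max(int(math.floor(history.quit_age)) - age0, 0)
            m[qi:] = rr[FORMER]
    return m


def sample_other_cause_death_age(
    history: SmokingHistory,
    life_table: LifeTable,
    rr: dict[str, float],
    rng: np.random.Generator | int,
) -> float:
    """Sample a death age from the smoking-status-adjusted hazard.

    ``life_table`` is interpreted as the never-smoker baseline (see
    :func:`split_life_table_by_smoking`); with ``rr`` identically 1 the draw
    follows the table unadjusted. The relative risk applies from the age the
    status is attained.
    """
    if isinstance(rng, (int, np.integer)):
        rng = np.random.default_rng(rng)
    h = life_table.hazard_array(history.sex, history.birth_year)
    m = _status_multipliers(history, rr, len(h), life_table.age_min)
    hm = h * m
    cum = np.concatenate([[0.0], np.cumsum(hm)])
    e = rng.exponential()
    if e >= cum[-1]:
        return float(life_table.age_max + 1)
    k = int(np.searchsorted(cum, e, side="right")) - 1
    frac = (e - cum[k]) / hm[k] if hm[k] > 0 else 0.0
    return float(life_table.age_min + k + frac)


def split_life_table_by_smoking(
    life_table: LifeTable,
    histories: list[SmokingHistory],
    rr: dict[str, float],
    tol: float = 1e-8,
    max_iter: int = 200,
) -> LifeTable:
    """Solve for the never-smoker baseline table.

    Finds per-stratum baseline hazards ``h_n`` such that the simulated-status
    prevalence-weighted hazard ``sum_s p_s(a) * rr_s * h_n(a)`` reproduces the
    input all-cause hazard. Prevalence weights are survival-adjusted inside
    the fixed-point iteration (differential mortality thins smokers at old
    ages), iterated to relative tolerance ``tol``.
    """
    by_stratum: dict[tuple[str, int], list[SmokingHistory]] = {}
    for hcur in histories:
        key = (hcur.sex, life_table.nearest_cohort(hcur.sex, hcur.birth_year))
        by_stratum.setdefault(key, []).append(hcur)

    ages = np.arange(life_table.age_min, life_table.age_max + 1)
    rows = []
    for (sex, cohort), q in life_table._q.items():
        h_all = -np.log1p(-np.clip(q, 0, 1 - 1e-12))
        group = by_stratum.get((sex, cohort))
        if not group:
            h_n = h_all.copy()
        else:
            mids = ages + 0.5
            p0 = np.zeros((3, len(ages)))  # never, current, former shares at each age
            for hist in group:
                start = hist.start_age if hist.start_age is not None else math.inf
                quit = hist.quit_age if hist.quit_age is not None else math.inf
                p0[0] += mids < start
                p0[1] += (mids >= start) & (mids < quit)
                p0[2] += mids >= quit
            p0 /= len(group)
            rr_vec = np.array([rr.get(NEVER, 1.0), rr[CURRENT], rr[FORMER]])
            h_n = h_all.copy()
            for _ in range(max_iter):
                surv = np.exp(-np.cumsum(h_n[None, :] * rr_vec[:, None], axis=1))
                surv = np.concatenate([np.ones((3, 1)), surv[:, :-1]], axis=1)
                w = p0 * surv
                denom = (w * rr_vec[:, None]).sum(axis=0) / np.clip(
                    w.sum(axis=0), 1e-300, None
                )
                h_new = h_all / np.clip(denom, 1e-12, None)
                delta = np.max(np.abs(h_new - h_n) / np.clip(h_all, 1e-12, None))
                h_n = h_new
                if delta < tol:
                    break
        q_n = 1.0 - np.exp(-h_n)
        rows.append(
            pd.DataFrame(
                {"sex": sex, "birth_cohort": cohort, "age": ages, "q_annual": q_n}
            )
        )
    return LifeTable(pd.concat(rows, ignore_index=True))
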