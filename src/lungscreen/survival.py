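"""Relative survival estimation and application.

Monthly relative survival is estimated from registry-style patient records
with the Ederer-II convention: at each monthly interval the expected
survival is computed among the patients still at risk, from the life-table
hazard at their attained age; the relative survival is the cumulated ratio
of observed to expected conditional survival. Person-time is allocated to
calendar periods by the calendar month in which it is lived (period
analysis), so recent treatment effects surface in recent-period estimates.

Each empirical curve is smoothed by a Poisson GLM of monthly excess deaths
(observed minus expected) with a log link, offset log(effective
person-months at risk), and a natural cubic spline basis in log time. The
smoothed excess hazard is what simulated cases sample their lung cancer
death times from.
"""

from __future__ import annotations

import logging
import math
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm

from .errors import ConfigurationError
from .population import LifeTable

logger = logging.getLogger(__name__)

AGE_BANDS = ("<65", "65-75", "75+")
EVENTS = ("lc_death", "oc_death", "censored")

#: Default calendar periods: before and after widespread novel-therapy use.
DEFAULT_PERIODS = {"pre": ("2012-01", "2017-12"), "post": ("2018-01", "2023-01")}

RECORD_COLUMNS = (
    "id",
    "sex",
    "age_at_diagnosis",
    "diagnosis_date",
    "stage",
    "histology",
    "follow_up_months",
    "event",
)


def age_band(age: float) -> str:
    if age < 65:
        return "<65"
    if age < 75:
        return "65-75"
    return "75+"


def _period_ordinals(period: tuple[str, str]) -> tuple[int, int]:
    lo = pd.Period(period[0], freq="M").ordinal
    hi = pd.Period(period[1], freq="M").ordinal
    if hi < lo:
        raise ConfigurationError("period end precedes period start")
    return lo, hi


def split_person_time(
    records: pd.DataFrame, periods: dict[str, tuple[str, str]]
) -> tuple[pd.DataFrame, int]:
    """Allocate each record's follow-up months to calendar periods.

    Month ``t`` of follow-up (t = 1..follow_up_months) is lived in calendar
    month ``diagnosis_date + (t - 1)`` and is assigned to the period
    containing that calendar month. Returns a tidy frame ``(id, period,
    months)`` and the count of follow-up months falling outside all periods.
    """
    diag = pd.PeriodIndex(records["diagnosis_date"], freq="M").asi8
    f = records["follow_up_months"].to_numpy(dtype=int)
    out = []
    assigned = np.zeros(len(records), dtype=int)
    for name, bounds in periods.items():
        lo, hi = _period_ordinals(bounds)
        first = np.maximum(1, lo - diag + 1)
        last = np.minimum(f, hi - diag + 1)
        months = np.clip(last - first + 1, 0, None)
        assigned += months
        out.append(
            pd.DataFrame(
                {"id": records["id"].to_numpy(), "period": name, "months": months}
            )
        )
    excluded = int((f - assigned).sum())
    if excluded:
        logger.warning("%d follow-up months fall outside all periods", excluded)
    return pd.concat(out, ignore_index=True), excluded


@dataclass
class EmpiricalCurve:
    """Monthly Ederer-II relative survival for one subgroup x period."""

    table: pd.DataFrame  # month, n_risk, n_eff, deaths, censored, expected_deaths,
    #                      p_obs, p_exp, r
    subgroup: dict
    period: str | None
    truncated: bool = False

    @property
    def horizon(self) -> int:
        return 0 if self.table.empty else int(self.table["month"].iloc[-1])

    def r(self, month: int) -> float:
        """Cumulative relative survival at end of ``month`` (r(0) = 1)."""
        if month <= 0:
            return 1.0
        tab = self.table
        sel = tab[tab["month"] <= month]
        return float(sel["r"].iloc[-1]) if len(sel) else 1.0


def ederer2(
    records: pd.DataFrame,
    life_table: LifeTable,
    subgroup: dict | None = None,
    period: tuple[str, str] | str | None = None,
    horizon_months: int = 60,
    periods: dict[str, tuple[str, str]] = DEFAULT_PERIODS,
) -> EmpiricalCurve:
    """Empirical monthly relative survival (Ederer-II) for one subgroup.

    ``subgroup`` filters on record columns (``age_band`` is derived from age
    at diagnosis). ``period`` restricts person-time to a calendar window —
    either a period name from ``periods`` or an explicit ("YYYY-MM",
    "YYYY-MM") pair; ``None`` uses all follow-up. Deaths are taken at end of
    month, censored patients contribute half a month (actuarial adjustment).
    """
    df = records
    if subgroup:
        for key, val in subgroup.items():
            if key == "age_band":
                bands = df["age_at_diagnosis"].map(age_band)
                df = df[bands == val]
            else:
                df = df[df[key] == val]
    df = df.reset_index(drop=True)

    period_name = None
    bounds = None
    if isinstance(period, str):
        period_name = period
        bounds = _period_ordinals(periods[period])
    elif period is not None:
        bounds = _period_ordinals(period)

    n = len(df)
    if n == 0:
        return EmpiricalCurve(
            pd.DataFrame(
                columns=[
                    "month", "n_risk", "n_eff", "deaths", "censored",
                    "expected_deaths", "person_months", "p_obs", "p_exp", "r",
                ]
            ),
            subgroup or {}, period_name, truncated=True,
        )

    diag = pd.PeriodIndex(df["diagnosis_date"], freq="M").asi8
    f = df["follow_up_months"].to_numpy(dtype=int)
    is_death = df["event"].isin(["lc_death", "oc_death"]).to_numpy()
    is_censor = (df["event"] == "censored").to_numpy()
    age_dx = df["age_at_diagnosis"].to_numpy(dtype=float)
    sexes = df["sex"].to_numpy()
    diag_year = pd.PeriodIndex(df["diagnosis_date"], freq="M").year.to_numpy()
    cohort = diag_year - np.floor(age_dx).astype(int)

    # pre-resolve each record to a life-table stratum row for fast lookup
    strata: dict[tuple[str, int], int] = {}
    q_rows = []
    row_idx = np.empty(n, dtype=int)
    for i in range(n):
        key = (sexes[i], life_table.nearest_cohort(sexes[i], int(cohort[i])))
        if key not in strata:
            strata[key] = len(q_rows)
            q_rows.append(life_table._q[key])
        row_idx[i] = strata[key]
    q_matrix = np.vstack(q_rows)
    n_table_ages = q_matrix.shape[1]

    rows = []
    r_cum = 1.0
    truncated = False
    for t in range(1, horizon_months + 1):
        at_risk = f >= t
        if bounds is not None:
            cal = diag + (t - 1)
            at_risk &= (cal >= bounds[0]) & (cal <= bounds[1])
        n_t = int(at_risk.sum())
        if n_t == 0:
            truncated = True
            break
        ends = at_risk & (f == t)
        d_t = int((ends & is_death).sum())
        c_t = int((ends & is_censor).sum())
        n_eff = n_t - 0.5 * c_t
        if n_eff <= 0:
            truncated = True
            break
        ages_t = np.clip(
            np.floor(age_dx[at_risk] + (t - 0.5) / 12.0).astype(int)
            - life_table.age_min,
            0,
            n_table_ages - 1,
        )
        q_t = q_matrix[row_idx[at_risk], ages_t]
        p_exp_i = (1.0 - q_t) ** (1.0 / 12.0)
        p_exp = float(p_exp_i.mean())
        expected_deaths = float((1.0 - p_exp) * n_eff)
        p_obs = 1.0 - d_t / n_eff
        r_cum *= p_obs / p_exp if p_exp > 0 else 1.0
        rows.append(
            dict(
                month=t, n_risk=n_t, n_eff=n_eff, deaths=d_t, censored=c_t,
                expected_deaths=expected_deaths, person_months=n_eff,
                p_obs=p_obs, p_exp=p_exp, r=r_cum,
            )
        )
    return EmpiricalCurve(pd.DataFrame(rows), subgroup or {}, period_name, truncated)


# ---------------------------------------------------------------------------
# GLM smoothing
# ---------------------------------------------------------------------------

def natural_spline_basis(x: np.ndarray, df: int, knots: np.ndarray | None = None):
    """Natural cubic spline basis with ``df`` columns (intercept excluded).

    Knots (df + 1 of them, boundary + interior) default to quantiles of
    ``x``. Returns (basis matrix, knots) so the basis can be re-evaluated at
    prediction points.
    """
    x = np.asarray(x, dtype=float)
    if knots is None:
        knots = np.quantile(np.unique(x), np.linspace(0, 1, df + 1))
    k = len(knots)

    def d(j, v):
        num = np.clip(v - knots[j], 0, None) ** 3 - np.clip(v - knots[-1], 0, None) ** 3
        return num / (knots[-1] - knots[j])

    cols = [x]
    for j in range(k - 2):
        cols.append(d(j, x) - d(k - 2, x))
    return np.column_stack(cols), knots


FALLBACK_BINS = ((1, 6), (7, 12), (13, 36), (37, 10**6))


@dataclass
class SmoothedCurve:
    """GLM-smoothed monthly excess hazard and implied relative survival."""

    months: np.ndarray  # 1..horizon
    excess_hazard: np.ndarray  # per person-month, per month
    r_hat: np.ndarray
    method: str  # "glm" | "piecewise" | "null"
    deviance: float
    subgroup: dict = field(default_factory=dict)
    period: str | None = None

    @property
    def horizon(self) -> int:
        return int(self.months[-1]) if len(self.months) else 0

    @property
    def final_hazard(self) -> float:
        return float(self.excess_hazard[-1]) if len(self.excess_hazard) else 0.0

    def r(self, t_months: float) -> float:
        """Smoothed relative survival at continuous time ``t_months``."""
        return math.exp(-self.cumulative_excess_hazard(t_months))

    def cumulative_excess_hazard(self, t_months: float) -> float:
        cum = np.concatenate([[0.0], np.cumsum(self.excess_hazard)])
        if t_months <= 0:
            return 0.0
        h = self.horizon
        if t_months >= h:
            return float(cum[-1] + (t_months - h) * self.final_hazard)
        k = int(math.floor(t_months))
        return float(cum[k] + (t_months - k) * self.excess_hazard[k])

    def invert(self, cumhaz: float) -> float | None:
        """Excess death time (months) at cumulative-hazard draw ``cumhaz``."""
        cum = np.concatenate([[0.0], np.cumsum(self.excess_hazard)])
        if cumhaz < cum[-1]:
            k = int(np.searchsorted(cum, cumhaz, side="right")) - 1
            return float(k + (cumhaz - cum[k]) / self.excess_hazard[k])
        if self.final_hazard <= 0:
            return None
        return float(self.horizon + (cumhaz - cum[-1]) / self.final_hazard)


def smooth_curve(
    curve: EmpiricalCurve, df: int = 4, horizon_months: int | None = None
) -> SmoothedCurve:
    """Fit a Poisson GLM to the monthly excess deaths of an empirical curve.

    Response: observed minus expected deaths per month (clipped at zero);
    offset: log effective person-months; covariates: natural cubic spline
    with ``df`` degrees of freedom in log(month + 0.5). Falls back to a
    piecewise-constant excess hazard over 0-6 / 7-12 / 13-36 / 37+ months
    when the GLM does not converge.
    """
    tab = curve.table
    if tab.empty:
        raise ConfigurationError("cannot smooth an empty curve")
    horizon = horizon_months or curve.horizon
    m = tab["month"].to_numpy(dtype=float)
    y = np.clip(
        tab["deaths"].to_numpy(dtype=float) - tab["expected_deaths"].to_numpy(),
        0.0,
        None,
    )
    exposure = tab["person_months"].to_numpy(dtype=float)
    months_out = np.arange(1, horizon + 1)

    if y.sum() <= 1e-9:
        lam = np.zeros(horizon)
        return SmoothedCurve(
            months_out, lam, np.ones(horizon), "null", 0.0, curve.subgroup, curve.period
        )

    x = np.log(m + 0.5)
    try:
        basis, knots = natural_spline_basis(x, df)
        design = sm.add_constant(basis, has_constant="add")
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            model = sm.GLM(y, design, family=sm.families.Poisson(), offset=np.log(exposure))
            fit = model.fit(maxiter=200)
        if not np.all(np.isfinite(fit.params)):
            raise RuntimeError("non-finite GLM coefficients")
        x_out = np.log(months_out + 0.5)
        b_out, _ = natural_spline_basis(x_out, df, knots=knots)
        eta = sm.add_constant(b_out, has_constant="add") @ fit.params
        rate = np.exp(np.clip(eta, -30, 5))
        method, deviance = "glm", float(fit.deviance)
    except Exception:  # pragma: no cover - exercised via degenerate inputs
        warnings.warn("excess-hazard GLM failed; using piecewise-constant fallback")
        rate = np.zeros(horizon)
        for lo, hi in FALLBACK_BINS:
            mask = (m >= lo) & (m <= hi)
            r_bin = y[mask].sum() / exposure[mask].sum() if exposure[mask].sum() > 0 else 0.0
            rate[(months_out >= lo) & (months_out <= hi)] = r_bin
        method, deviance = "piecewise", float("nan")

    # the GLM models the per-month excess death probability; convert to a
    # continuous-time monthly hazard so cumulation is discretisation-free
    lam = -np.log1p(-np.clip(rate, 0.0, 0.99))

    r_hat = np.exp(-np.cumsum(lam))
    r_hat = np.clip(r_hat, 1e-12, 1.05)
    return SmoothedCurve(
        months_out, lam, r_hat, method, deviance, curve.subgroup, curve.period
    )


# ---------------------------------------------------------------------------
# Curve sets and death-time assignment
# ---------------------------------------------------------------------------

_FALLBACK_ORDER = ((), ("histology",), ("histology", "age_band"),
                   ("histology", "age_band", "sex"))


class CurveSet:
    """Smoothed curves keyed by subgroup dict + period, with fallback lookup.

    When no curve matches a case's full subgroup, matching requirements are
    relaxed in order: histology first, then age band, then sex (a warning is
    logged once per relaxed key).
    """

    def __init__(self):
        self._curves: list[tuple[dict, SmoothedCurve]] = []
        self._warned: set = set()

    def add(self, key: dict, curve: SmoothedCurve) -> None:
        self._curves.append((dict(key), curve))

    def __len__(self) -> int:
        return len(self._curves)

    def keys(self) -> list[dict]:
        return [dict(k) for k, _ in self._curves]

    def lookup(self, case: dict) -> SmoothedCurve:
        for relaxed in _FALLBACK_ORDER:
            for key, curve in self._curves:
                ok = True
                for kf, kv in key.items():
                    if kf in relaxed:
                        continue
                    if kf not in case or case[kf] != kv:
                        ok = False
                        break
                if ok:
                    if relaxed:
                        tag = (tuple(sorted(case.items())), relaxed)
                        if tag not in self._warned:
                            self._warned.add(tag)
                            logger.warning(
                                "no exact survival curve for %s; relaxed %s",
                                case, relaxed,
                            )
                    return curve
        raise ConfigurationError(f"no survival curve available for case {case!r}")


#: Drawn excess death times beyond this horizon count as statistical cure.
CURE_HORIZON_MONTHS = 300


def assign_lc_death(
    case: dict,
    curves: CurveSet,
    rng: np.random.Generator | int | None = None,
    exp_draw: float | None = None,
) -> float | None:
    """Draw a lung cancer (excess) death time in months for a simulated case.

    ``case`` carries the subgroup keys (stage, histology, age_band, sex) plus
    ``period``. The excess-hazard process of the matched smoothed curve is
    inverted at an Exp(1) draw (pass ``exp_draw`` to reuse a common random
    number across scenario/era variants). Times beyond 25 years are treated
    as no lung cancer death.
    """
    if exp_draw is None:
        if rng is None:
            raise ValueError("provide rng or exp_draw")
        if isinstance(rng, (int, np.integer)):
            rng = np.random.default_rng(rng)
        exp_draw = float(rng.exponential())
    curve = curves.lookup(case)
    t = curve.invert(exp_draw)
    if t is None or t > CURE_HORIZON_MONTHS:
        return None
    return t


def fit_curve_set(
    records: pd.DataFrame,
    life_table: LifeTable,
    periods: dict[str, tuple[str, str]] = DEFAULT_PERIODS,
    stratify: tuple[str, ...] = ("stage", "histology"),
    horizon_months: int = 60,
    min_months: int = 12,
    glm_df: int = 4,
) -> CurveSet:
    """Estimate and smooth curves for every subgroup x period in the records."""
    curves = CurveSet()
    combo_cols = []
    df = records.copy()
    for col in stratify:
        if col == "age_band":
            df["age_band"] = df["age_at_diagnosis"].map(age_band)
        combo_cols.append(col)
    combos = df[combo_cols].drop_duplicates().to_dict("records") if combo_cols else [{}]
    for combo in combos:
        for pname in periods:
            emp = ederer2(
                df, life_table, subgroup=combo, period=pname,
                horizon_months=horizon_months, periods=periods,
            )
            if len(emp.table) < min_months:
                logger.warning(
                    "skipping %s period %s: only %d usable months",
                    combo, pname, len(emp.table),
                )
                continue
            sm_curve = smooth_curve(emp, df=glm_df, horizon_months=horizon_months)
            curves.add({**combo, "period": pname}, sm_curve)
    return curves
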