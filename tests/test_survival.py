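"""Ederer-II estimation, period splitting, GLM smoothing, death assignment."""

import math

import numpy as np
import pandas as pd
import pytest

from lungscreen.errors import ConfigurationError
from lungscreen.survival import (
    CurveSet,
    EmpiricalCurve,
    SmoothedCurve,
    assign_lc_death,
    ederer2,
    fit_curve_set,
    smooth_curve,
    split_person_time,
)

from conftest import flat_life_table


def records_frame(rows):
    """rows: (id, diagnosis 'YYYY-MM', follow-up months, event)."""
    return pd.DataFrame(
        [
            {
                "id": rid,
                "sex": "male",
                "age_at_diagnosis": 68.0,
                "diagnosis_date": diag,
                "stage": "IV",
                "histology": "AD",
                "follow_up_months": f,
                "event": event,
            }
            for rid, diag, f, event in rows
        ]
    )


PERIODS = {"pre": ("2012-01", "2017-12"), "post": ("2018-01", "2023-01")}


class TestSplitPersonTime:
    def test_straddling_diagnosis_splits_evenly(self):
        rec = records_frame([(0, "2016-01", 48, "censored")])
        out, excluded = split_person_time(rec, PERIODS)
        by_period = out.set_index("period")["months"]
        assert by_period["pre"] == 24
        assert by_period["post"] == 24
        assert excluded == 0

    def test_late_diagnosis_all_in_second_period(self):
        rec = records_frame([(0, "2019-06", 30, "lc_death")])
        out, _ = split_person_time(rec, PERIODS)
        assert out.set_index("period")["months"]["pre"] == 0
        assert out.set_index("period")["months"]["post"] == 30

    def test_person_months_conserved(self):
        rec = records_frame(
            [(i, d, f, "censored") for i, (d, f) in
             enumerate([("2012-01", 60), ("2015-07", 100), ("2021-12", 14)])]
        )
        out, excluded = split_person_time(rec, PERIODS)
        assert out["months"].sum() + excluded == rec["follow_up_months"].sum()


class TestEderer2:
    def test_equals_kaplan_meier_without_background_mortality(
        self, zero_mortality_table
    ):
        """With zero expected mortality the estimate is the observed KM curve."""
        from lifelines import KaplanMeierFitter

        rows = [(i, "2013-01", f, "lc_death") for i, f in
                enumerate([2, 3, 3, 5, 8, 9, 12, 12, 15, 20])]
        rec = records_frame(rows)
        curve = ederer2(rec, zero_mortality_table, horizon_months=20)
        km = KaplanMeierFitter().fit(rec["follow_up_months"],
                                     event_observed=np.ones(len(rec)))
        for month in range(1, 21):
            assert curve.r(month) == pytest.approx(
                float(km.predict(month)), abs=1e-9
            )

    def test_five_patient_hand_oracle(self):
        """Matches a spreadsheet-style month-by-month hand computation."""
        rows = [
            (0, "2013-01", 2, "lc_death"),
            (1, "2013-01", 4, "oc_death"),
            (2, "2013-01", 4, "censored"),
            (3, "2013-01", 6, "lc_death"),
            (4, "2013-01", 8, "censored"),
        ]
        q_annual = 0.06
        lt = flat_life_table(q_annual)
        rec = records_frame(rows)
        curve = ederer2(rec, lt, horizon_months=8)

        # independent hand computation with the same conventions:
        # deaths at end of month, censored get half-month weight, expected
        # survival is the monthly table survival among patients at risk
        p_exp = (1 - q_annual) ** (1 / 12)
        follow = [2, 4, 4, 6, 8]
        death = [True, True, False, True, False]
        r_hand = []
        r = 1.0
        for t in range(1, 9):
            at_risk = [i for i in range(5) if follow[i] >= t]
            d = sum(1 for i in at_risk if follow[i] == t and death[i])
            c = sum(1 for i in at_risk if follow[i] == t and not death[i])
            n_eff = len(at_risk) - 0.5 * c
            p_obs = 1 - d / n_eff
            r *= p_obs / p_exp
            r_hand.append(r)
        for month, expected in enumerate(r_hand, start=1):
            assert curve.r(month) == pytest.approx(expected, abs=1e-12)

    def test_null_excess_hazard_gives_unit_relative_survival(self):
        """Deaths occurring at exactly the background rate leave r near 1."""
        rng = np.random.default_rng(21)
        q = 1 - math.exp(-0.18)  # high background so deaths accumulate
        lam_m = 0.18 / 12
        n = 4000
        t = rng.exponential(1 / lam_m, size=n)
        rows = [
            (i, "2013-01", max(1, min(int(t[i]) + 1, 60)),
             "oc_death" if t[i] < 60 else "censored")
            for i in range(n)
        ]
        curve = ederer2(records_frame(rows), flat_life_table(q), horizon_months=36)
        assert curve.r(36) == pytest.approx(1.0, abs=0.05)

    def test_period_restriction_uses_calendar_person_time(self):
        # one early and one late diagnosis; the pre-period curve must only
        # see months lived before 2018
        rows = [(0, "2016-01", 48, "lc_death"), (1, "2020-01", 30, "lc_death")]
        rec = records_frame(rows)
        lt = flat_life_table(0.0)
        pre = ederer2(rec, lt, period="pre", horizon_months=48)
        assert pre.table["month"].max() <= 24  # only patient 0's 2016-2017 months
        post = ederer2(rec, lt, period="post", horizon_months=48)
        assert post.table["n_risk"].max() >= 1

    def test_empty_subgroup_is_truncated(self, zero_mortality_table):
        rec = records_frame([(0, "2013-01", 5, "lc_death")])
        curve = ederer2(
            rec, zero_mortality_table, subgroup={"stage": "IA"}, horizon_months=12
        )
        assert curve.truncated and curve.table.empty


def curve_from_excess_deaths(times, horizon, life_table, censor=None):
    n = len(times)
    censor = censor or horizon
    rows = []
    for i, t in enumerate(times):
        if t < censor:
            rows.append((i, "2013-01", max(1, int(t) + 1), "lc_death"))
        else:
            rows.append((i, "2013-01", censor, "censored"))
    return ederer2(records_frame(rows), life_table, horizon_months=horizon)


class TestSmoothing:
    def test_zero_excess_deaths_gives_unit_curve(self, zero_mortality_table):
        rows = [(i, "2013-01", 60, "censored") for i in range(50)]
        emp = ederer2(records_frame(rows), zero_mortality_table, horizon_months=60)
        sm = smooth_curve(emp)
        assert sm.method == "null"
        np.testing.assert_allclose(sm.r_hat, 1.0)

    def test_recovers_constant_excess_hazard(self, zero_mortality_table):
        lam = 0.05  # per month
        rng = np.random.default_rng(8)
        times = rng.exponential(1 / lam, size=5000)
        emp = curve_from_excess_deaths(times, 60, zero_mortality_table)
        sm = smooth_curve(emp)
        # cumulative survival at 36 months within 2 percentage points
        assert sm.r(36.0) == pytest.approx(math.exp(-36 * lam), abs=0.02)
        # and the fitted hazard is roughly flat over the bulk of the data
        mid = sm.excess_hazard[5:40]
        assert np.all(np.abs(mid - lam) < 0.35 * lam)

    def test_recovers_weibull_excess_hazard(self, zero_mortality_table):
        k, theta = 0.7, 30.0  # decreasing hazard, median ~ 18 months
        rng = np.random.default_rng(9)
        times = theta * rng.weibull(k, size=10_000)
        emp = curve_from_excess_deaths(times, 60, zero_mortality_table)
        sm = smooth_curve(emp)
        truth = math.exp(-((36.0 / theta) ** k))
        assert sm.r(36.0) == pytest.approx(truth, abs=0.02)

    def test_scaling_both_hazards_leaves_relative_survival(self):
        """Ederer-II consistency: r is invariant to a shared background factor."""
        rng = np.random.default_rng(15)
        lam_exc = 0.03
        n = 6000
        out = {}
        for factor in (1.0, 2.0):
            q = 1 - math.exp(-0.04 * factor)
            lam_bg = 0.04 * factor / 12
            t_exc = rng.exponential(1 / lam_exc, size=n)
            t_bg = rng.exponential(1 / lam_bg, size=n)
            t = np.minimum(t_exc, t_bg)
            rows = [
                (i, "2013-01", max(1, min(int(t[i]) + 1, 48)),
                 "lc_death" if t[i] < 48 else "censored")
                for i in range(n)
            ]
            curve = ederer2(records_frame(rows), flat_life_table(q),
                            horizon_months=36)
            out[factor] = curve.r(36)
        assert out[2.0] == pytest.approx(out[1.0], abs=0.05)


def constant_curve(lam, horizon=60, **key):
    months = np.arange(1, horizon + 1)
    lam_arr = np.full(horizon, lam)
    return SmoothedCurve(
        months, lam_arr, np.exp(-np.cumsum(lam_arr)), "glm", 0.0,
        key, key.get("period"),
    )


class TestAssignment:
    def test_unit_curve_never_assigns_death(self):
        curves = CurveSet()
        curves.add({"stage": "IV", "period": "pre"}, constant_curve(0.0))
        rng = np.random.default_rng(1)
        for _ in range(100):
            assert assign_lc_death({"stage": "IV", "period": "pre"}, curves, rng) is None

    def test_exponential_curve_gives_exponential_draws(self):
        from scipy import stats

        lam = 0.06
        curves = CurveSet()
        curves.add({"stage": "IV", "period": "pre"}, constant_curve(lam))
        rng = np.random.default_rng(2)
        draws = [
            assign_lc_death({"stage": "IV", "period": "pre"}, curves, rng)
            for _ in range(10_000)
        ]
        finite = np.array([d for d in draws if d is not None])
        # the 25-year guard truncates the far tail; condition the oracle on it
        cap = 300.0
        norm = 1 - math.exp(-lam * cap)
        ks = stats.ks_1samp(
            finite, lambda x: (1 - np.exp(-lam * np.asarray(x))) / norm
        )
        assert ks.pvalue > 0.01

    def test_better_curve_postpones_death_for_every_draw(self):
        """Monotone coupling: same Exp(1) draw, higher survival, later death."""
        c1, c2 = constant_curve(0.08), constant_curve(0.04)
        rng = np.random.default_rng(3)
        for _ in range(2000):
            e = rng.exponential()
            t1, t2 = c1.invert(e), c2.invert(e)
            assert t2 >= t1

    def test_fallback_drops_histology_first(self):
        curves = CurveSet()
        curves.add(
            {"stage": "IV", "histology": "AD", "period": "pre"}, constant_curve(0.05)
        )
        got = curves.lookup(
            {"stage": "IV", "histology": "SQ", "age_band": "65-75",
             "sex": "male", "period": "pre"}
        )
        assert got.excess_hazard[0] == pytest.approx(0.05)

    def test_no_curve_at_all_raises(self):
        curves = CurveSet()
        curves.add({"stage": "IV", "period": "pre"}, constant_curve(0.05))
        with pytest.raises(ConfigurationError):
            curves.lookup({"stage": "IA", "period": "pre"})
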