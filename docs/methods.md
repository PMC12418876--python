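# Methods

This note documents the model, its assumptions, the default parameters and
the numerical conventions. It is the companion to the code: nothing here
states a result that the test suite or `scripts/acceptance.py` does not
itself compute.

## Overview

The package answers one question: how do treatment-era shifts in survival
and cost of (especially late-stage) lung cancer change the incremental
cost-effectiveness of CT screening? The architecture separates three
layers that communicate through narrow interfaces:

1. **Natural history** — per-person smoking trajectories, other-cause
   death ages and tumor trajectories, simulated once per population and
   shared across every scenario (common random numbers);
2. **Estimation** — period-specific relative-survival curves and
   phase-of-care costs, fitted from (synthetic) registry records;
3. **Economics** — discounted life years, QALYs, itemized costs and
   incremental comparisons, recomputed cheaply for sensitivity analyses
   without re-simulating layer 1.

## Population layer

Smoking histories are generated from an age-indexed initiation
probability (conditional on never having smoked), an age-indexed
cessation hazard, and a log-normal cigarettes-per-day (CPD) distribution,
per sex and 5-year birth-cohort band. The default fixture encodes the
qualitative Western European pattern — male ever-smoking prevalence
declining from ~65% (1945–49 cohorts) to ~45% (1970s), female prevalence
rising then declining, initiation concentrated at ages 14–25 — but is
synthetic: it is not fitted to survey microdata, and all downstream tests
treat it as ground truth.

Other-cause mortality uses cohort life tables with a smoking-status
relative risk (never 1.0, current 2.2, former 1.5 by default) applied as
a single multiplier on the all-cause hazard, switching at the ages the
status changes. Dose dependence and post-cessation latency are
deliberately not modelled. Because published tables are population
averages, `split_life_table_by_smoking` solves for the never-smoker
baseline hazard such that the survival-weighted prevalence mixture
reproduces the input table (fixed-point iteration, relative tolerance
1e-8). Ages are continuous internally; hazards are piecewise-constant on
annual grids, and draws invert the exact cumulative hazard (no
probability-linear interpolation).

## Natural history

Onset follows a two-term hazard: a background term `exp(b0 + b1*age)`
plus a cumulative-exposure term `packyears(age) * exp(s0 + s1*age)`.
Defaults (b0, b1 = −13.5, 0.085; s0, s1 = −14.1, 0.075) give a heavy
smoker (40 CPD from age 20) roughly a 15% cumulative onset probability to
age 80 and a never-smoker well under 1% — plausible magnitudes, chosen
once and not calibrated to trial data. Histology is drawn from a
smoking-status-dependent categorical distribution (squamous and small
cell enriched in ever-smokers). Tumors progress IA → IB → II → IIIA →
IIIB → IV with Weibull dwell times (shape 1.5; mean 2.0 years in IA
shrinking to 0.8 in IIIB; small cell 2.5× faster, reflecting its lower
screen-detectability) and surface clinically via per-stage exponential
detection hazards rising from 0.10/year (IA) to 2.5/year (IV).

Tumor events are generated unconditionally on other-cause death and
censored at scenario assembly. This keeps the natural history bitwise
identical across screening scenarios and eras, which is what makes
person-paired deltas meaningful.

## Screening

Eligibility is either a packyear rule (default: ≥20 packyears, ≤15 years
since cessation, ages 50–80) or a risk rule (PLCOm2012 6-year risk ≥
1.51%, ages 55–75). Threshold comparisons are inclusive and age windows
closed. The PLCOm2012 logistic uses the published coefficient set without
the race/ethnicity terms; the non-smoking covariates are synthesized from
documented distributions at population build. Eligibility is re-evaluated
at every screen age, so a person ages out of a quit-year cap mid-schedule.

At each attended screen, a preclinical tumor is detected with a CT
sensitivity specific to its current stage and histology (0.62 in IA
rising to 0.95 in IV; ×0.85 for small cell). A detected cancer receives
one cure draw at first detection (0.55 in IA down to 0.03 in IV): cured
cases die at their other-cause age; not-cured cases keep the lung cancer
death time of the no-screening counterfactual unchanged. There are no
repeat cure chances at later screens. False positives are not simulated
as events; their cost is an aggregate per-participant follow-up line.
Reduced adherence assigns a share of the no-show mass to structural
non-attenders (default sensitivity analysis: attendance 50% with half of
no-shows structural, so 25% of invitees attend nothing) and solves the
per-screen attendance probability so the expected attended fraction hits
the target.

## Relative survival estimation

The Ederer-II convention: monthly intervals, deaths at end of month,
censored patients contributing half a month; expected survival computed
among the patients still at risk from their attained age, sex and cohort.
Follow-up months are allocated to calendar periods by the month in which
they are lived (period analysis), so treatment-era effects appear in the
era in which care was actually delivered — the default periods are
2012-01–2017-12 and 2018-01–2023-01, both config-driven.

Smoothing fits monthly excess deaths (observed minus expected, clipped at
zero) with a Poisson GLM: log link, offset log(effective person-months),
natural cubic spline with 4 df in log(month + 0.5). The fitted per-month
excess death probability is converted to a continuous hazard via
−log(1−p) before cumulation; without that conversion a constant-hazard
test case shows a visible discretisation bias (~0.7 pp on 3-year
survival), which is how the need for it was found. Non-convergence falls
back to a piecewise-constant hazard over 0–6 / 7–12 / 13–36 / 37+ months
with a warning. Curves are estimated to a 60-month horizon; beyond it the
final fitted hazard is held constant. A drawn excess death time beyond
25 years is treated as no lung cancer death (statistical cure guard;
negligible mass). Missing subgroup curves fall back by dropping histology
first, then age band, then sex, with a logged warning.

Death times are assigned by inverting the cumulative excess hazard at an
Exp(1) draw. The same draw is reused across eras, so a uniformly better
curve can only postpone a death (monotone coupling) — this is what makes
the era contrast noise-free at the person level.

## Costs and utilities

Phase-of-care decomposition: terminal = final 6 months of life (tagged by
cause of death), initial = first 6 months after diagnosis minus any
overlap (terminal precedence for short survivors, the SEER-style
convention), continuing = the remainder capped at 5 years post-diagnosis;
months beyond the cap carry no treatment cost. Costing stage and era are
fixed at detection. The default schedule encodes the observed era
structure — stage III–IV initial care ×1.55 and continuing care ×2.48 in
the post era, early-stage continuing care ×1.77 — around placeholder
absolute levels (e.g. €9,000/month late-stage initial care, 2021 price
level, ×1.05 to 2023). Screening unit costs: €140 per CT, €21
administration per screen, €6 risk assessment per invitee (once), €35
follow-up per participant (once).

Utilities are population norms by 10-year age band and sex (EQ-5D default,
VAS alternative) with a proportional disutility while in a care phase
(e.g. 30% during late-stage initial care). QALYs can therefore never
exceed life years.

Discounting: 3%/year for both costs and effects by default; person-time
and event costs use a mid-month convention ((1+r)^(−(m+0.5)/12) for month
m from the 2023 reference). The `annuity_factor` helper prices an annual
unit stream at end-of-year, the standard annuity closed form.

## Scenario runner

The reference date is 2023-01; the analysis population is everyone alive
then, and all outputs are scaled per 100,000 alive at that date. The
master seed spawns per-person substreams keyed by (seed, person index,
stream id), so results do not depend on execution order. Sensitivity rows
that only touch costs, utilities or discount rates reuse the simulated
arms; survival-era and adherence rows re-simulate the affected arm. Every
row compares against a no-screening arm evaluated under the same settings.

## Synthetic registry

The generator emits diagnosed cases (2012–2021, censored 2023-02) with
constant monthly excess hazards per stage × histology and a calendar-era
multiplier active from 2018-01 — a period effect, matching the
period-analysis estimand; a cohort-of-diagnosis mode exists for
robustness checks. Ground-truth 3-year relative survival spans 85%/88%
(stage IA) to 6.5%/14.1% (stage IV adenocarcinoma, pre/post); small cell
gains are smallest, since no novel therapies were approved for it in the
emulated window. Other-cause deaths come from a deterministic
Gompertz-like life table (annual probabilities integrate the continuous
hazard exactly); optional monthly cost streams are gamma-distributed
(shape 4) around phase means with era multipliers.

What the generator does *not* emulate: non-constant (e.g. cure-mixture)
excess-hazard shapes within an era, covariate-dependent censoring,
claims-linkage artefacts, or correlation between a person's survival and
their cost level. Passing recovery tests therefore demonstrate estimator
correctness under the stated model, not robustness to real registry
messiness.

## Problem sizes and tolerances

Estimator recovery uses n = 10,000 (hazard-shape recovery, ±2 pp on
3-year cumulative survival) and n = 20,000 (era-shift round trip,
±1.5 pp); simulator invariants run on 100,000 persons. These sizes give
Monte-Carlo noise comfortably inside the stated tolerances while keeping
the full suite around a minute and a half of CPU.

## Known limitations

Absolute population outputs (deaths prevented, QALYs gained, net cost per
100,000) are **uncalibrated**: they inherit the synthetic smoking,
natural-history and cost fixtures, and should be read as internally
consistent magnitudes, not forecasts. Nodule-management protocols,
radiation risk, multiple synchronous tumors, recurrence, personalised
intervals, probabilistic sensitivity analysis and socioeconomic
stratification are out of scope. Relative survival proxies cause-specific
survival and shares its known vulnerability to comorbidity-mismatched
reference life tables.
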