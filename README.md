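# lungscreen

A microsimulation of lung cancer natural history and low-dose CT screening,
with survival and treatment-cost layers estimated from registry-like
patient records split into treatment eras — before and after the
widespread introduction of targeted- and immunotherapies. It is aimed at
health-economic modellers who want to study how changing treatment
patterns for late-stage disease feed back into the cost-effectiveness of
early detection.

## What it computes

The model simulates complete individual life histories from birth for
1945–1979 birth cohorts: smoking initiation, cessation and intensity;
smoking-adjusted other-cause mortality from cohort life tables; lung
cancer onset, histology (AD / SQ / other NSCLC / SCLC) and preclinical
stage progression IA → IB → II → IIIA → IIIB → IV; and clinical detection.
Screening strategies (annual or biennial; packyear-based USPSTF
eligibility or a PLCOm2012 risk threshold as in the UK Targeted Lung
Health Check) are applied on top: a screen may detect a preclinical cancer
with stage- and histology-specific CT sensitivity; a detected cancer is
cured with a stage-specific probability, and otherwise retains the lung
cancer death time of the no-screening counterfactual.

Survival after diagnosis comes from monthly **relative survival** curves
estimated with the Ederer-II method,

r(t) = Π_{u≤t} p_obs(u) / p_exp(u),

where p_exp is the expected one-month survival of the patients still at
risk, taken from the life table at their attained age. Person-time is
allocated to calendar periods (period analysis), so the 2018+ curves
reflect recent treatment. Each subgroup curve is smoothed with a Poisson
GLM of monthly excess deaths (log link, offset = log person-months,
natural cubic spline in log time); the smoothed excess hazard λ̂(t) is
what simulated cases sample their lung cancer death times from.

Costs are attributed by phase of care — initial (first 6 months),
continuing (intermittent, capped at 5 years) and terminal (last 6 months
of life, by cause) — per stage group and era. Outcomes are discounted
(3% default, mid-month convention) and reported per 100,000 individuals
alive at the start of screening: ΔLY, ΔQALY, itemized net cost,
ICER = ΔC/ΔQALY and net monetary benefit NMB = λ·ΔQALY − ΔC.

Because the registry microdata behind the original estimates are not
public, the package ships a first-class synthetic registry generator with
known ground truth (era-specific excess hazards, phase-structured costs);
the estimation pipeline is validated by parameter recovery against it.
Absolute population-level outputs therefore depend on documented synthetic
fixtures; relative and directional results are the meaningful outputs.

## Worked example

```python
from lungscreen import ScenarioConfig, run_comparison

config = ScenarioConfig(n=20_000, seed=1, strategy="A-TLHC",
                        survival_era="post", cost_era="post")
comparison, base, screened = run_comparison(config)
print(comparison.to_row())
```

Output (per 100,000 alive at the start of screening, discounted at 3%):

```
        deaths_prevented: 369.3
    deaths_prevented_pct: 10.5
               ly_gained: 2,046.0
             qaly_gained: 1,477.4
                 cost_ct: 23,327,129.1
           cost_followup: 604,993.3
    cost_risk_assessment: 110,668.2
          cost_care_I_II: 52,555,957.7
        cost_care_III_IV: -57,549,453.1
              cost_total: 19,049,295.1
             cost_per_ly: 9,310.4
           cost_per_qaly: 12,894.2
                     nmb: 10,497,880.3
```

Annual risk-based screening prevents about a tenth of lung cancer deaths
in this synthetic population. The main costs are CT scans and the
additional early-stage treatment of screen-detected cancers; savings come
from late-stage treatment avoided (negative `cost_care_III_IV`). At about
€12,900 per QALY the strategy is cost-effective against a €20,000
willingness-to-pay, with a positive net monetary benefit.

A command-line interface wraps the same entry points:

```
lungscreen run --strategy A-TLHC --era post --n 20000 --seed 1
lungscreen sensitivity --strategy A-TLHC --n 20000
lungscreen synth --n 20000 --out registry.csv
lungscreen fit registry.csv --out curves.csv
```

## Layout

- `src/lungscreen/population.py` — smoking histories, life tables,
  smoking-adjusted other-cause mortality
- `src/lungscreen/natural_history.py` — onset, histology, stage dwell
  times, clinical detection
- `src/lungscreen/screening.py` — eligibility rules, PLCOm2012 risk model,
  scheduling, adherence, CT detection and cure
- `src/lungscreen/survival.py` — Ederer-II estimation, period splitting,
  Poisson-GLM smoothing, death-time assignment
- `src/lungscreen/costs.py` — phase-of-care decomposition and cost accrual
- `src/lungscreen/economics.py` — discounting, utilities, QALYs, ICER/NMB
- `src/lungscreen/registry.py` — synthetic registry and life-table
  generator with known ground truth
- `src/lungscreen/runner.py` — scenario orchestration and sensitivity grid
- `src/lungscreen/defaults.py` — all parameter fixtures

See `docs/methods.md` for the modelling assumptions and their rationale.
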