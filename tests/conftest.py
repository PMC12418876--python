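import numpy as np
import pandas as pd
import pytest

from lungscreen.population import LifeTable, SmokingHistory, IntensitySegment


def flat_life_table(q: float, cohorts=(1950,), max_age=100) -> LifeTable:
    """Life table with a constant annual death probability at every age."""
    rows = []
    ages = np.arange(max_age + 1)
    for sex in ("male", "female"):
        for cohort in cohorts:
            rows.append(
                pd.DataFrame(
                    {"sex": sex, "birth_cohort": cohort, "age": ages, "q_annual": q}
                )
            )
    return LifeTable(pd.concat(rows, ignore_index=True))


def smoker(start=20.0, quit=None, cpd=20.0, sex="male", birth_year=1950):
    end = quit if quit is not None else float("inf")
    return SmokingHistory(
        sex=sex,
        birth_year=birth_year,
        start_age=start,
        quit_age=quit,
        segments=(IntensitySegment(start, end, cpd),),
    )


def never_smoker(sex="male", birth_year=1950):
    return SmokingHistory(sex=sex, birth_year=birth_year)


@pytest.fixture
def zero_mortality_table():
    return flat_life_table(0.0)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
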