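import numpy as np
import pandas as pd
import pytest

from lifehorizon.lifetable import LifeTable
from lifehorizon.survival import PatientRecord


def make_life_table(rows, terminal_age=110):
    """rows: iterable of (sex, year, age, qx)."""
    return LifeTable(
        pd.DataFrame(rows, columns=["sex", "year", "age", "qx"]),
        terminal_age=terminal_age,
    )


def flat_table(q, sexes=("F",), years=(2000,), age_max=110, terminal_age=110):
    """Life table with constant annual death probability q at every age."""
    rows = []
    for s in sexes:
        for y in years:
            for a in range(age_max + 1):
                rows.append((s, y, a, 1.0 if a == terminal_age else q))
    return make_life_table(rows, terminal_age=terminal_age)


def record(i=0, fu=12, event=0, sex="F", age=60, year=2000, month=1, **kw):
    return PatientRecord(
        id=f"r{i}", sex=sex, age_at_dx=age, dx_year=year, dx_month=month,
        follow_up_months=fu, event=event, **kw,
    )


@pytest.fixture
def toy_lt():
    return flat_table(0.12, age_max=110)


@pytest.fixture
def rng():
    return np.random.default_rng(20230711)
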