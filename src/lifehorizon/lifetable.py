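"""National life tables and demographically matched reference survival curves.

A :class:`LifeTable` holds annual death probabilities ``q`` indexed by
(sex, calendar year, age in completed years). Reference ("general
population") survival for a cohort of referents matched on sex, age and
calendar date at an index event is obtained either exactly, by averaging the
per-referent products of monthly survival probabilities
(:func:`expected_reference_survival`), or empirically, by Monte-Carlo
simulation of individual referent lifetimes
(:func:`simulate_reference_cohort`). Both agree in expectation; the exact
form serves as the internal oracle for the simulation.

Conventions
-----------
* Annual ``q`` is converted to a monthly survival probability under a
  constant hazard within the year of age: ``p = (1 - q)**(1/12)``.
* Attained age increments every 12 months after the index date; calendar
  year increments at January.
* Calendar years outside the table's range clamp to the nearest covered
  year; ages above the covered maximum carry ``q = 1``, so every referent's
  survival reaches zero by the terminal age (default 110).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

TERMINAL_AGE = 110

_SEX_CODES = {"F": 0, "M": 1}


class LifeTableError(ValueError):
    """Raised when a life table violates its schema or invariants."""


@dataclass(frozen=True)
class ReferentProfile:
    """A matched referent: sex, age and calendar date at the index event."""

    sex: str
    age_at_index: int
    index_year: int
    index_month: int = 1

    def __post_init__(self) -> None:
        if self.sex not in _SEX_CODES:
            raise ValueError(f"sex must be 'F' or 'M', got {self.sex!r}")
        if self.age_at_index < 0:
            raise ValueError("age_at_index must be >= 0")
        if not 1 <= self.index_month <= 12:
            raise ValueError("index_month must be in 1..12")


@dataclass
class SurvivalCurve:
    """Survival probabilities on a monthly grid t = 0, 1, 2, … since index.

    ``kind`` distinguishes observed (Kaplan-Meier), reference (life-table)
    and extrapolated curves. At-risk/event/censor counts are populated for
    observed curves only.
    """

    survival: np.ndarray
    kind: str = "observed"
    n_at_risk: np.ndarray | None = None
    n_events: np.ndarray | None = None
    n_censored: np.ndarray | None = None

    def __post_init__(self) -> None:
        s = np.asarray(self.survival, dtype=float)
        if s.ndim != 1 or s.size == 0:
            raise ValueError("survival must be a non-empty 1-d array")
        if abs(s[0] - 1.0) > 1e-12:
            raise ValueError(f"S(0) must be 1, got {s[0]}")
        if np.any(s < -1e-12) or np.any(s > 1 + 1e-12):
            raise ValueError("survival probabilities must lie in [0, 1]")
        if np.any(np.diff(s) > 1e-12):
            raise ValueError("survival curve must be nonincreasing")
        self.survival = np.clip(s, 0.0, 1.0)

    def __len__(self) -> int:
        return self.survival.size

    @property
    def times(self) -> np.ndarray:
        """Months since index, 0..T."""
        return np.arange(self.survival.size)

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame({"month": self.times, "survival": self.survival})
        if self.n_at_risk is not None:
            df["n_at_risk"] = self.n_at_risk
        if self.n_events is not None:
            df["n_events"] = self.n_events
        return df

    def to_csv(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, index=False)


class LifeTable:
    """Annual death probabilities q(sex, year, age).

    Age coverage must be contiguous from 0 for every (sex, year) present and
    identical across them. Lookups clamp the calendar year into the covered
    range and return q = 1 for ages above the covered maximum.
    """

    def __init__(self, frame: pd.DataFrame, terminal_age: int = TERMINAL_AGE):
        required = {"sex", "year", "age", "qx"}
        missing = required - set(frame.columns)
        if missing:
            raise LifeTableError(f"missing column(s): {sorted(missing)}")
        df = frame[["sex", "year", "age", "qx"]].copy()
        bad_sex = ~df["sex"].isin(_SEX_CODES)
        if bad_sex.any():
            row = df.index[bad_sex][0]
            raise LifeTableError(f"row {row}: sex must be 'F' or 'M'")
        bad_q = (df["qx"] < 0) | (df["qx"] > 1) | df["qx"].isna()
        if bad_q.any():
            row = df.index[bad_q][0]
            raise LifeTableError(f"row {row}: qx={df.loc[row, 'qx']} outside [0, 1]")
        if df.duplicated(["sex", "year", "age"]).any():
            row = df.index[df.duplicated(["sex", "year", "age"])][0]
            raise LifeTableError(f"row {row}: duplicate (sex, year, age) key")

        self.terminal_age = int(terminal_age)
        years = np.sort(df["year"].unique())
        if len(years) > 1 and np.any(np.diff(years) != 1):
            raise LifeTableError("calendar years must be contiguous")
        self.year_min, self.year_max = int(years[0]), int(years[-1])

        ages = np.sort(df["age"].unique())
        if ages[0] != 0 or np.any(np.diff(ages) != 1):
            raise LifeTableError("ages must be contiguous from 0")
        self.age_max = int(ages[-1])

        sexes = sorted(df["sex"].unique(), key=_SEX_CODES.get)
        self._sexes = set(sexes)
        # dense array, NaN-filled then validated complete per (sex, year)
        n_years = self.year_max - self.year_min + 1
        q = np.full((2, n_years, self.age_max + 1), np.nan)
        q[
            df["sex"].map(_SEX_CODES).to_numpy(),
            df["year"].to_numpy() - self.year_min,
            df["age"].to_numpy(),
        ] = df["qx"].to_numpy(dtype=float)
        for sx in sexes:
            block = q[_SEX_CODES[sx]]
            if np.isnan(block).any():
                yr, age = np.argwhere(np.isnan(block))[0]
                raise LifeTableError(
                    f"non-contiguous ages: missing ({sx}, {self.year_min + yr}, age {age})"
                )
        if self.age_max >= self.terminal_age:
            for sx in sexes:
                if not np.all(q[_SEX_CODES[sx], :, self.terminal_age] == 1.0):
                    raise LifeTableError(
                        f"qx must equal 1 at the terminal age {self.terminal_age}"
                    )
        self._q = q

    def __len__(self) -> int:
        n_years = self.year_max - self.year_min + 1
        return len(self._sexes) * n_years * (self.age_max + 1)

    @classmethod
    def from_csv(cls, path: str | Path, terminal_age: int = TERMINAL_AGE) -> "LifeTable":
        return cls(pd.read_csv(path), terminal_age=terminal_age)

    def to_csv(self, path: str | Path) -> None:
        rows = []
        for sx in sorted(self._sexes, key=_SEX_CODES.get):
            si = _SEX_CODES[sx]
            for yi in range(self._q.shape[1]):
                for age in range(self.age_max + 1):
                    rows.append((sx, self.year_min + yi, age, self._q[si, yi, age]))
        pd.DataFrame(rows, columns=["sex", "year", "age", "qx"]).to_csv(path, index=False)

    def q(self, sex: str, year: int, age: int) -> float:
        """Annual death probability, with year-clamping and q=1 above age_max."""
        return float(self.q_array(np.array([_SEX_CODES[sex]]), np.array([year]), np.array([age]))[0])

    def q_array(
        self, sex_idx: np.ndarray, year: np.ndarray, age: np.ndarray
    ) -> np.ndarray:
        """Vectorized lookup on integer sex codes (F=0, M=1)."""
        yi = np.clip(year, self.year_min, self.year_max) - self.year_min
        age_c = np.minimum(age, self.age_max)
        out = self._q[sex_idx, yi, age_c]
        out = np.where(age > self.age_max, 1.0, out)
        if age.size and np.isnan(np.min(out)):
            raise LifeTableError("lookup hit a sex not present in the table")
        return out


def load_life_table(path: str | Path, terminal_age: int = TERMINAL_AGE) -> LifeTable:
    """Read a life-table CSV with columns ``sex,year,age,qx``."""
    return LifeTable.from_csv(path, terminal_age=terminal_age)


def monthly_survival_prob(q_annual):
    """Per-month survival probability under constant hazard within the year.

    ``p = (1 - q)**(1/12)``; accepts scalars or arrays.
    """
    q = np.asarray(q_annual, dtype=float)
    if np.any(q < 0) or np.any(q > 1):
        raise ValueError("annual death probability must lie in [0, 1]")
    p = (1.0 - q) ** (1.0 / 12.0)
    return float(p) if np.isscalar(q_annual) else p


def _profile_arrays(profiles: list[ReferentProfile]):
    if not profiles:
        raise ValueError("profile list is empty")
    sex = np.array([_SEX_CODES[p.sex] for p in profiles])
    age = np.array([p.age_at_index for p in profiles])
    year = np.array([p.index_year for p in profiles])
    month = np.array([p.index_month for p in profiles])
    # collapse duplicates: registry cohorts repeat (sex, age, year, month) heavily
    key = np.stack([sex, age, year, month], axis=1)
    uniq, counts = np.unique(key, axis=0, return_counts=True)
    return uniq[:, 0], uniq[:, 1], uniq[:, 2], uniq[:, 3], counts


def _monthly_p_matrix(lt: LifeTable, sex, age0, year0, month0, horizon: int) -> np.ndarray:
    """Monthly survival probabilities, one row per profile, columns m=0..horizon-1."""
    m = np.arange(horizon)
    age = age0[:, None] + m[None, :] // 12
    year = year0[:, None] + (month0[:, None] - 1 + m[None, :]) // 12
    q = lt.q_array(sex[:, None], year, age)
    return (1.0 - q) ** (1.0 / 12.0)


def default_horizon(profiles: list[ReferentProfile], lt: LifeTable) -> int:
    """Months until the youngest referent passes the table's last covered age."""
    youngest = min(p.age_at_index for p in profiles)
    return 12 * max(1, lt.age_max + 2 - youngest)


def expected_reference_survival(
    profiles: list[ReferentProfile], lt: LifeTable, horizon_months: int
) -> SurvivalCurve:
    """Exact expected survival of the matched reference cohort.

    S_ref(t) = (1/N) Σ_i Π_{m<t} p_i(m), with p_i(m) the monthly survival
    probability at referent i's attained age and calendar year in month m.
    """
    if horizon_months < 1:
        raise ValueError("horizon_months must be >= 1")
    sex, age0, year0, month0, counts = _profile_arrays(profiles)
    p = _monthly_p_matrix(lt, sex, age0, year0, month0, horizon_months)
    s_i = np.cumprod(p, axis=1)
    s = np.concatenate([[1.0], (counts @ s_i) / counts.sum()])
    return SurvivalCurve(s, kind="reference")


def simulate_reference_cohort(
    profiles: list[ReferentProfile],
    lt: LifeTable,
    replicates_per_profile: int = 100,
    seed: int | np.random.Generator | None = None,
    horizon_months: int | None = None,
) -> SurvivalCurve:
    """Monte-Carlo reference cohort: simulate each referent's lifetime.

    For every profile, ``replicates_per_profile`` lifetimes are drawn by
    sequential monthly Bernoulli thinning with the same probabilities the
    exact expectation uses; individuals are pooled into one empirical curve
    (no censoring). Deterministic given the seed.
    """
    if replicates_per_profile < 1:
        raise ValueError("replicates_per_profile must be >= 1")
    if seed is None:
        raise ValueError("a seed is required for reproducibility")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    # simulate to the natural horizon (certain death past the terminal age),
    # then truncate to the requested horizon so no artificial deaths appear
    sim_months = default_horizon(profiles, lt)
    if horizon_months is not None:
        sim_months = max(sim_months, horizon_months)
    sex, age0, year0, month0, counts = _profile_arrays(profiles)
    p = _monthly_p_matrix(lt, sex, age0, year0, month0, sim_months)
    p[:, -1] = 0.0  # backstop: every replicate must have a death month

    death_counts = np.zeros(sim_months, dtype=np.int64)
    total = 0
    chunk = max(1, int(2e6) // sim_months)
    for i in range(len(counts)):
        reps = replicates_per_profile * int(counts[i])
        total += reps
        done = 0
        while done < reps:
            k = min(chunk, reps - done)
            u = rng.random((k, sim_months))
            # months survived = index of first Bernoulli failure
            died = np.argmax(u >= p[i], axis=1)
            death_counts += np.bincount(died, minlength=sim_months)
            done += k
    s = 1.0 - np.concatenate([[0], np.cumsum(death_counts)]) / total
    if horizon_months is not None:
        s = s[: horizon_months + 1]
    return SurvivalCurve(s, kind="reference")
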