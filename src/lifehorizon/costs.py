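"""Survival-weighted discounted lifetime healthcare cost.

Monthly mean cost among surviving, still-observed patients is CPI-adjusted
to base-year (2017) currency, converted TWD -> USD at the study constant
1 USD = 30.44 TWD, smoothed with a trailing precision-weighted window (no
future leakage — late-life cost escalation means the recent past is the
relevant predictor), extended over the extrapolated horizon by carrying the
last observed smoothed value forward, and integrated against the lifetime
survival curve with annual discounting:

    lifetime_cost = sum_t S(t) * c_hat(t) * (1 + r)^(-t/12)

Cost per life-year is reported under both conventions (divide by LE, and by
discounted LE); all monetary outputs are tagged with their currency and
mixing unadjusted TWD into estimation raises a units error.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from pathlib import Path
from typing import Callable, Sequence

import numpy as np
import pandas as pd

from .survival import PatientRecord, _select

TWD_PER_USD = 30.44
BASE_YEAR = 2017
USD_2017 = "USD2017"


class UnitsError(ValueError):
    """Raised when currencies are mixed or costs are not in base-year USD."""


@dataclass
class CPISeries:
    """Consumer-price-index values by calendar year (base year must be present)."""

    values: dict[int, float]
    base_year: int = BASE_YEAR

    def __post_init__(self) -> None:
        if self.base_year not in self.values:
            raise ValueError(f"CPI series must include the base year {self.base_year}")
        if any(v <= 0 for v in self.values.values()):
            raise ValueError("CPI values must be positive")

    @classmethod
    def from_csv(cls, path: str | Path, base_year: int = BASE_YEAR) -> "CPISeries":
        df = pd.read_csv(path)
        if not {"year", "index"} <= set(df.columns):
            raise ValueError("CPI CSV needs columns year,index")
        return cls({int(y): float(v) for y, v in zip(df["year"], df["index"])}, base_year)

    def factor(self, year: int) -> float:
        """Multiplier taking a nominal amount in ``year`` to base-year value."""
        if year not in self.values:
            raise ValueError(f"no CPI value for calendar year {year}")
        return self.values[self.base_year] / self.values[year]


def cpi_adjust_amount(
    amount: float, year: int, cpi: CPISeries, twd_per_usd: float = TWD_PER_USD
) -> float:
    """Nominal TWD in ``year`` -> base-year TWD -> USD."""
    return amount * cpi.factor(year) / twd_per_usd


def cpi_adjust(
    records: Sequence[PatientRecord],
    cpi: CPISeries,
    twd_per_usd: float = TWD_PER_USD,
) -> list[PatientRecord]:
    """Convert every patient's nominal-TWD cost vector to base-year USD.

    The calendar year of spend advances with the months since diagnosis.
    """
    out = []
    for r in records:
        if r.costs is None:
            out.append(r)
            continue
        if r.cost_currency != "TWD":
            raise UnitsError(
                f"patient {r.id}: cpi_adjust expects nominal TWD costs, "
                f"got {r.cost_currency}"
            )
        months = np.arange(r.costs.size)
        years = r.dx_year + (r.dx_month - 1 + months) // 12
        factors = np.array([cpi.factor(int(y)) for y in years])
        out.append(
            replace(r, costs=r.costs * factors / twd_per_usd, cost_currency=USD_2017)
        )
    return out


@dataclass
class CostCurve:
    """Monthly mean cost among survivors, raw and (optionally) smoothed.

    ``c_raw(t)`` is NaN where no patient is alive and under observation;
    ``n_contributing(t)`` is the surviving-and-observed headcount.
    """

    c_raw: np.ndarray
    n_contributing: np.ndarray
    smoothed: np.ndarray | None = None
    currency: str = USD_2017

    def __post_init__(self) -> None:
        with np.errstate(invalid="ignore"):
            if np.any(self.c_raw[~np.isnan(self.c_raw)] < 0):
                raise ValueError("mean monthly costs must be non-negative")

    def __len__(self) -> int:
        return self.c_raw.size


def mean_monthly_cost(
    records: Sequence[PatientRecord],
    stratum: Callable[[PatientRecord], bool] | None = None,
) -> CostCurve:
    """c_raw(t) = sum of observed month-t costs / number alive and observed at t.

    A patient with follow-up m contributes to (and is counted in) months
    0..m-1 only. All cost vectors must already be in base-year USD.
    """
    sel = _select(records, stratum)
    sel = [r for r in sel if r.costs is not None]
    if not sel:
        raise ValueError("empty stratum: no records with cost vectors")
    bad = [r.id for r in sel if r.cost_currency != USD_2017]
    if bad:
        raise UnitsError(
            f"costs must be CPI-adjusted {USD_2017} before averaging; "
            f"patient(s) {bad[:3]} carry another currency"
        )
    tmax = max(r.follow_up_months for r in sel)
    total = np.zeros(tmax)
    n = np.zeros(tmax, dtype=np.int64)
    for r in sel:
        m = min(r.costs.size, r.follow_up_months)
        total[:m] += r.costs[:m]
        n[: r.follow_up_months] += 1
    with np.errstate(invalid="ignore", divide="ignore"):
        c_raw = np.where(n > 0, total / np.maximum(n, 1), np.nan)
    return CostCurve(c_raw=c_raw, n_contributing=n)


def smooth_and_extend_cost(
    cost_curve: CostCurve,
    lifetime_months: int,
    window_months: int = 12,
) -> CostCurve:
    """Trailing precision-weighted smoothing, then carry-forward extension.

    c_hat(t) averages the defined raw means over (t-window+1 .. t) weighted
    by the contributing headcount (precision weighting stabilises the sparse
    late tail); months beyond the observed span take the last observed
    smoothed value. ``lifetime_months`` is the last month of the lifetime
    grid (inclusive), so the smoothed curve has lifetime_months + 1 entries.
    """
    c = cost_curve.c_raw
    n = cost_curve.n_contributing.astype(float)
    defined = ~np.isnan(c) & (n > 0)
    if defined.sum() < window_months:
        raise ValueError(
            f"window of {window_months} months exceeds the {int(defined.sum())} "
            "defined months of observed cost"
        )
    wsum = np.where(defined, n, 0.0)
    csum = np.where(defined, n * c, 0.0)
    cum_w = np.concatenate([[0.0], np.cumsum(wsum)])
    cum_c = np.concatenate([[0.0], np.cumsum(csum)])
    t = np.arange(c.size)
    lo = np.maximum(t - window_months + 1, 0)
    w_win = cum_w[t + 1] - cum_w[lo]
    c_win = cum_c[t + 1] - cum_c[lo]
    smoothed_obs = np.full(c.size, np.nan)
    ok = w_win > 0
    smoothed_obs[ok] = c_win[ok] / w_win[ok]
    # fill any undefined early months by carrying the next defined value back,
    # then carry forward across undefined gaps
    idx_ok = np.nonzero(ok)[0]
    last = idx_ok[-1]
    filled = pd.Series(smoothed_obs).ffill().bfill().to_numpy()
    smoothed = np.empty(lifetime_months + 1)
    m = min(last + 1, lifetime_months + 1)
    smoothed[:m] = filled[:m]
    smoothed[m:] = filled[last]
    return CostCurve(
        c_raw=cost_curve.c_raw,
        n_contributing=cost_curve.n_contributing,
        smoothed=smoothed,
        currency=cost_curve.currency,
    )


@dataclass
class LifetimeCostResult:
    """Discounted survival-weighted lifetime cost and cost per life-year."""

    lifetime_cost: float
    discount_rate: float
    le: float
    discounted_le: float
    cost_per_life_year: float
    cost_per_discounted_life_year: float
    currency: str = USD_2017


def lifetime_cost(
    s_index: np.ndarray,
    cost_curve: CostCurve,
    discount_rate: float = 0.03,
) -> LifetimeCostResult:
    """Integrate cost against survival with annual discounting from diagnosis.

    lifetime_cost = sum_t S(t) * c_hat(t) * (1+r)^(-t/12) over the lifetime
    grid. LE (and its discounted analogue) use the trapezoidal rule on the
    same grid; cost per life-year is reported under both divisions.
    """
    if cost_curve.smoothed is None:
        raise ValueError("cost curve has no smoothed lifetime component")
    if cost_curve.currency != USD_2017:
        raise UnitsError("lifetime cost requires CPI-adjusted base-year USD")
    s = np.asarray(s_index, dtype=float)
    c = cost_curve.smoothed
    if s.size != c.size:
        raise ValueError(
            f"grid mismatch: survival has {s.size} months, cost has {c.size}"
        )
    if discount_rate < 0:
        raise ValueError("discount rate must be >= 0")
    t = np.arange(s.size)
    disc = (1.0 + discount_rate) ** (-t / 12.0)
    total = float(np.sum(s * c * disc))
    le = float(np.trapezoid(s)) / 12.0
    dle = float(np.trapezoid(s * disc)) / 12.0
    return LifetimeCostResult(
        lifetime_cost=total,
        discount_rate=discount_rate,
        le=le,
        discounted_le=dle,
        cost_per_life_year=total / le if le > 0 else np.nan,
        cost_per_discounted_life_year=total / dle if dle > 0 else np.nan,
    )
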