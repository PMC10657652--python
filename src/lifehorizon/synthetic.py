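"""Synthetic registry cohorts with known ground truth.

Real catastrophic-illness registry extracts are access-restricted, so every
pipeline stage is exercised against generated cohorts whose statistical
structure mirrors a national diagnosis registry: staggered diagnosis years,
a realistic age/sex mix, administrative censoring at a fixed calendar date,
group-specific proportional *excess* mortality on top of a national
life-table law, and right-skewed monthly costs that escalate near the end
of life.

The mortality law of the reference population is Gompertz in age with a sex
multiplier and a mild calendar improvement drift; the diseased cohort adds
a constant excess hazard per month scaled by a group hazard ratio (the
additive relative-survival convention — the estimand the extrapolation
method targets). Truth (uncensored death months, quadrature LE, analytic
lifetime cost) lives in a sidecar, never on the estimation path.
"""

from __future__ import annotations

from dataclasses import asdict, dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd
import yaml
from scipy.stats import truncnorm

from .lifetable import LifeTable, TERMINAL_AGE
from .survival import PatientRecord

_SEX_CODES = {"F": 0, "M": 1}


@dataclass
class GompertzLaw:
    """Reference-population mortality: hazard a * m(sex) * d(year) * exp(b*age).

    ``a`` is the annual baseline hazard at age 0, ``b`` the log-hazard slope
    per year of age, ``male_mult`` the male hazard multiplier, and mortality
    improves by ``annual_improvement`` per calendar year after ``ref_year``.
    """

    a: float = 4.4e-5
    b: float = 0.09
    male_mult: float = 1.6
    annual_improvement: float = 0.01
    ref_year: int = 2008
    terminal_age: int = TERMINAL_AGE

    def annual_q(self, sex_idx, year, age):
        mult = np.where(np.asarray(sex_idx) == 1, self.male_mult, 1.0)
        drift = (1.0 - self.annual_improvement) ** (np.asarray(year) - self.ref_year)
        h = self.a * mult * drift * np.exp(self.b * np.asarray(age))
        return np.clip(1.0 - np.exp(-h), 0.0, 1.0)


@dataclass
class CohortSpec:
    """Registry cohort structure: size, demographics, diagnosis calendar."""

    n: int = 10_000
    age_mean: float = 52.7
    age_sd: float = 14.1
    age_min: int = 16
    age_max: int = 100
    male_frac: float = 0.233
    dx_year_min: int = 1999
    dx_year_max: int = 2017
    censor_year: int = 2017
    censor_month: int = 12


@dataclass
class ExcessSpec:
    """Additive excess mortality: baseline per-month hazard x group HR."""

    baseline: float = 0.001
    group_hr: dict = field(
        default_factory=lambda: {"none": 1.0, "minor": 1.38, "major": 1.38}
    )
    group_prevalence: dict = field(
        default_factory=lambda: {"none": 0.962, "minor": 0.0266, "major": 0.0114}
    )


@dataclass
class CostSpec:
    """Monthly cost law: Gamma noise around an age-tilted mean with
    end-of-life escalation over the final months before (true) death."""

    base: float = 300.0
    age_slope: float = 0.005
    eol_mult: float = 2.0
    eol_months: int = 6
    gamma_shape: float | None = 2.0
    currency: str = "USD2017"


@dataclass
class SyntheticScenario:
    law: GompertzLaw = field(default_factory=GompertzLaw)
    cohort: CohortSpec = field(default_factory=CohortSpec)
    excess: ExcessSpec = field(default_factory=ExcessSpec)
    cost: CostSpec = field(default_factory=CostSpec)
    seed: int = 20170101

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(asdict(self), sort_keys=False))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "SyntheticScenario":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        return cls(
            law=GompertzLaw(**raw.get("law", {})),
            cohort=CohortSpec(**raw.get("cohort", {})),
            excess=ExcessSpec(**raw.get("excess", {})),
            cost=CostSpec(**raw.get("cost", {})),
            seed=int(raw.get("seed", 20170101)),
        )

    def with_seed(self, seed: int) -> "SyntheticScenario":
        return replace(self, seed=seed)


def make_life_table(scenario: SyntheticScenario) -> LifeTable:
    """Materialise the Gompertz law as a life-table CSV frame (ages 0..terminal)."""
    law = scenario.law
    if law.a < 0 or law.b < 0:
        raise ValueError("Gompertz parameters must be non-negative")
    years = np.arange(scenario.cohort.dx_year_min, scenario.cohort.censor_year + 1)
    ages = np.arange(law.terminal_age + 1)
    rows = []
    for sex, si in _SEX_CODES.items():
        for year in years:
            q = law.annual_q(np.full_like(ages, si), np.full_like(ages, year), ages)
            q[-1] = 1.0  # terminal age
            rows.append(
                pd.DataFrame({"sex": sex, "year": int(year), "age": ages, "qx": q})
            )
    return LifeTable(pd.concat(rows, ignore_index=True), terminal_age=law.terminal_age)


def _excess_lambda(scenario: SyntheticScenario, groups: np.ndarray) -> np.ndarray:
    hr = scenario.excess.group_hr
    return scenario.excess.baseline * np.array([hr[g] for g in groups])


def _monthly_p_total(
    lt: LifeTable,
    sex_idx: np.ndarray,
    age0: np.ndarray,
    year0: np.ndarray,
    month0: np.ndarray,
    lam: np.ndarray,
    horizon: int,
) -> np.ndarray:
    """Per-patient monthly survival probabilities under reference + excess hazard."""
    m = np.arange(horizon)
    age = age0[:, None] + m[None, :] // 12
    year = year0[:, None] + (month0[:, None] - 1 + m[None, :]) // 12
    q = lt.q_array(sex_idx[:, None], year, age)
    return (1.0 - q) ** (1.0 / 12.0) * np.exp(-lam)[:, None]


def draw_cohort(
    scenario: SyntheticScenario, lt: LifeTable | None = None
) -> tuple[list[PatientRecord], pd.DataFrame]:
    """Draw a registry cohort; returns (records, truth sidecar).

    Death months come from sequential monthly Bernoulli thinning under the
    patient's reference-plus-excess hazard; follow-up applies administrative
    censoring at the scenario's cutoff date. The sidecar records each
    patient's uncensored death month and excess hazard — estimation code
    must never read it.
    """
    if lt is None:
        lt = make_life_table(scenario)
    cs = scenario.cohort
    if cs.n < 1:
        raise ValueError("cohort size must be >= 1")
    rng = np.random.default_rng(np.random.SeedSequence(scenario.seed).spawn(1)[0])

    if cs.age_min == cs.age_max or cs.age_sd <= 0:
        ages = np.full(cs.n, int(round(cs.age_mean)))
    else:
        a = (cs.age_min - cs.age_mean) / cs.age_sd
        b = (cs.age_max - cs.age_mean) / cs.age_sd
        ages = truncnorm.rvs(
            a, b, loc=cs.age_mean, scale=cs.age_sd, size=cs.n, random_state=rng
        )
    ages = np.clip(np.round(ages).astype(int), cs.age_min, cs.age_max)
    sex_idx = (rng.random(cs.n) < cs.male_frac).astype(int)
    dx_year = rng.integers(cs.dx_year_min, cs.dx_year_max + 1, size=cs.n)
    dx_month = rng.integers(1, 13, size=cs.n)
    names = list(scenario.excess.group_prevalence)
    probs = np.array([scenario.excess.group_prevalence[g] for g in names], dtype=float)
    groups = np.array(names)[rng.choice(len(names), size=cs.n, p=probs / probs.sum())]
    lam = _excess_lambda(scenario, groups)

    horizon = 12 * max(1, lt.age_max + 2 - int(ages.min()))
    death_interval = np.empty(cs.n, dtype=np.int64)
    chunk = max(1, int(4e6) // horizon)
    for lo in range(0, cs.n, chunk):
        hi = min(lo + chunk, cs.n)
        p = _monthly_p_total(
            lt, sex_idx[lo:hi], ages[lo:hi], dx_year[lo:hi], dx_month[lo:hi],
            lam[lo:hi], horizon,
        )
        p[:, -1] = 0.0
        u = rng.random(p.shape)
        death_interval[lo:hi] = np.argmax(u >= p, axis=1)

    true_death_month = death_interval + 1  # death recorded at the end of its interval
    admin = (cs.censor_year - dx_year) * 12 + (cs.censor_month - dx_month) + 1
    admin = np.maximum(admin, 1)
    event = (true_death_month <= admin).astype(int)
    fu = np.where(event == 1, true_death_month, admin)

    sexes = np.array(["F", "M"])
    records = [
        PatientRecord(
            id=f"P{i:06d}",
            sex=sexes[sex_idx[i]],
            age_at_dx=int(ages[i]),
            dx_year=int(dx_year[i]),
            dx_month=int(dx_month[i]),
            follow_up_months=int(fu[i]),
            event=int(event[i]),
            labels={"depression": str(groups[i])},
        )
        for i in range(cs.n)
    ]
    truth = pd.DataFrame(
        {
            "id": [r.id for r in records],
            "true_death_month": true_death_month,
            "excess_lambda": lam,
            "group": groups,
        }
    )
    return records, truth


def draw_costs(
    records: list[PatientRecord],
    truth: pd.DataFrame,
    scenario: SyntheticScenario,
) -> list[PatientRecord]:
    """Attach observed monthly cost vectors (months 0..follow_up-1 only).

    Mean cost is base * (1 + age_slope * (age_at_dx - 50)), multiplied by
    ``eol_mult`` in the final ``eol_months`` months before the true death;
    Gamma noise with the scenario's shape (``gamma_shape=None`` means
    noiseless). Costs never leak past censoring.
    """
    spec = scenario.cost
    rng = np.random.default_rng(np.random.SeedSequence(scenario.seed).spawn(2)[1])
    death = dict(zip(truth["id"], truth["true_death_month"]))
    out = []
    for r in records:
        m_obs = r.follow_up_months
        if m_obs == 0:
            out.append(replace(r, costs=np.zeros(0), cost_currency=spec.currency))
            continue
        t = np.arange(m_obs)
        mu = spec.base * (1.0 + spec.age_slope * (r.age_at_dx - 50.0))
        # month t lies in the final eol_months intervals before death when
        # t >= death_interval - eol_months + 1, death_interval = death_month - 1
        eol = t >= (death[r.id] - 1) - spec.eol_months + 1
        mean = np.where(eol, mu * spec.eol_mult, mu)
        if spec.gamma_shape is None or not np.isfinite(spec.gamma_shape):
            costs = mean.astype(float)
        else:
            costs = rng.gamma(spec.gamma_shape, mean / spec.gamma_shape)
        out.append(replace(r, costs=costs, cost_currency=spec.currency))
    return out


def simulate_registry(
    scenario: SyntheticScenario,
) -> tuple[list[PatientRecord], LifeTable, pd.DataFrame]:
    """Life table + cohort + costs + truth sidecar in one call."""
    lt = make_life_table(scenario)
    records, truth = draw_cohort(scenario, lt)
    records = draw_costs(records, truth, scenario)
    return records, lt, truth


# ---------------------------------------------------------------------------
# Ground truth by quadrature (sidecar utilities; not on the estimation path)
# ---------------------------------------------------------------------------

def _true_survival_matrix(records, lt, scenario, horizon):
    sex_idx = np.array([_SEX_CODES[r.sex] for r in records])
    age0 = np.array([r.age_at_dx for r in records])
    year0 = np.array([r.dx_year for r in records])
    month0 = np.array([r.dx_month for r in records])
    lam = _excess_lambda(scenario, np.array([r.depression for r in records]))
    p = _monthly_p_total(lt, sex_idx, age0, year0, month0, lam, horizon)
    s = np.empty((len(records), horizon + 1))
    s[:, 0] = 1.0
    np.cumprod(p, axis=1, out=s[:, 1:])
    return s


def true_cohort_survival(
    records: list[PatientRecord],
    lt: LifeTable,
    scenario: SyntheticScenario,
    horizon: int | None = None,
) -> np.ndarray:
    """Exact mean survival of the cohort under its generating law."""
    if horizon is None:
        horizon = 12 * max(1, lt.age_max + 2 - min(r.age_at_dx for r in records))
    return _true_survival_matrix(records, lt, scenario, horizon).mean(axis=0)


def true_le(
    records: list[PatientRecord],
    lt: LifeTable,
    scenario: SyntheticScenario,
    horizon: int | None = None,
) -> dict:
    """Quadrature LE, reference LE and loss-of-LE for the cohort's covariates."""
    from .lifetable import expected_reference_survival
    from .survival import profiles_for

    if horizon is None:
        horizon = 12 * max(1, lt.age_max + 2 - min(r.age_at_dx for r in records))
    s_true = true_cohort_survival(records, lt, scenario, horizon)
    s_ref = expected_reference_survival(profiles_for(records), lt, horizon).survival
    le = float(np.trapezoid(s_true)) / 12.0
    le_ref = float(np.trapezoid(s_ref)) / 12.0
    return {"le": le, "le_ref": le_ref, "loss_of_le": le_ref - le}


def true_lifetime_cost(
    records: list[PatientRecord],
    lt: LifeTable,
    scenario: SyntheticScenario,
    discount_rate: float = 0.03,
    horizon: int | None = None,
) -> float:
    """Analytic survival-weighted discounted lifetime cost under the cost law.

    The expected cost among survivors at month t applies the end-of-life
    multiplier with probability P(die within eol_months | alive at t) =
    1 - S_i(t + k)/S_i(t), matching how the generator assigns it.
    """
    spec = scenario.cost
    if horizon is None:
        horizon = 12 * max(1, lt.age_max + 2 - min(r.age_at_dx for r in records))
    s = _true_survival_matrix(records, lt, scenario, horizon)
    k = spec.eol_months
    s_fwd = np.concatenate([s[:, k:], np.zeros((s.shape[0], k))], axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        p_eol = np.where(s > 0, 1.0 - s_fwd / np.maximum(s, 1e-300), 1.0)
    mu = spec.base * (
        1.0 + spec.age_slope * (np.array([r.age_at_dx for r in records]) - 50.0)
    )
    cost_i = mu[:, None] * (1.0 + (spec.eol_mult - 1.0) * p_eol)
    s_bar = s.mean(axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        c_bar = np.where(s_bar > 0, (s * cost_i).mean(axis=0) / np.maximum(s_bar, 1e-300), 0.0)
    t = np.arange(s.shape[1])
    disc = (1.0 + discount_rate) ** (-t / 12.0)
    return float(np.sum(s_bar * c_bar * disc))
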