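"""Patient records and monthly-grid Kaplan-Meier estimation.

The registry extract is one row per patient: demographics, diagnosis date,
follow-up in whole months, a death/censor flag, stratum labels (e.g.
depression status) and, optionally, an observed monthly cost vector.

Time origin is the diagnosis month (month 0). A death during the diagnosis
month is recorded as ``follow_up_months = 1, event = 1`` so there are no
zero-length event intervals; censoring at month 0 is allowed. Within a
month, deaths are taken to precede censorings (the usual product-limit tie
rule), so the risk set at month t is everyone with follow-up >= t.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Callable, Iterable, Sequence

import numpy as np
import pandas as pd

from .lifetable import ReferentProfile, SurvivalCurve

DEPRESSION_LEVELS = ("none", "minor", "major")


@dataclass
class PatientRecord:
    """One registry subject.

    ``labels`` maps stratum names to values; the ``depression`` label takes
    one of ``none | minor | major`` (major has priority when both subtypes
    ever applied — resolved upstream at label assignment). ``costs`` holds
    observed monthly amounts, month 0 = diagnosis month; its length never
    exceeds the observed months.
    """

    id: str
    sex: str
    age_at_dx: int
    dx_year: int
    dx_month: int
    follow_up_months: int
    event: int
    labels: dict = field(default_factory=dict)
    costs: np.ndarray | None = None
    cost_currency: str = "USD2017"

    def __post_init__(self) -> None:
        if self.sex not in ("F", "M"):
            raise ValueError(f"patient {self.id}: sex must be 'F' or 'M'")
        if self.follow_up_months < 0:
            raise ValueError(f"patient {self.id}: follow_up_months must be >= 0")
        if self.event not in (0, 1):
            raise ValueError(f"patient {self.id}: event must be 0 or 1")
        if self.event == 1 and self.follow_up_months == 0:
            raise ValueError(
                f"patient {self.id}: a death in the diagnosis month is recorded "
                "as follow_up_months=1"
            )
        if not 1 <= self.dx_month <= 12:
            raise ValueError(f"patient {self.id}: dx_month must be in 1..12")
        dep = self.labels.get("depression")
        if dep is not None and dep not in DEPRESSION_LEVELS:
            raise ValueError(f"patient {self.id}: unknown depression label {dep!r}")
        if self.costs is not None:
            self.costs = np.asarray(self.costs, dtype=float)
            if self.costs.size > self.follow_up_months + 1:
                raise ValueError(
                    f"patient {self.id}: cost vector longer than observed months"
                )
            if np.any(self.costs < 0):
                raise ValueError(f"patient {self.id}: negative cost entry")

    @property
    def depression(self) -> str:
        return self.labels.get("depression", "none")

    def profile(self) -> ReferentProfile:
        """The matched referent for this patient (sex, age, calendar date at dx)."""
        return ReferentProfile(self.sex, self.age_at_dx, self.dx_year, self.dx_month)


@dataclass
class KMCurve(SurvivalCurve):
    """Kaplan-Meier curve with at-risk/event/censor counts on the month grid."""


def _select(records: Sequence[PatientRecord], stratum) -> list[PatientRecord]:
    if stratum is None:
        return list(records)
    return [r for r in records if stratum(r)]


def fit_km(
    records: Sequence[PatientRecord],
    stratum: Callable[[PatientRecord], bool] | None = None,
) -> KMCurve:
    """Product-limit estimate on the monthly grid.

    S(t) = prod_{u<=t} (1 - d_u/n_u) with n_u = #{follow-up >= u} (deaths
    precede censorings within a month). Defined up to the largest follow-up
    in the stratum.
    """
    sel = _select(records, stratum)
    if not sel:
        raise ValueError("empty stratum: no records to fit")
    fu = np.array([r.follow_up_months for r in sel])
    ev = np.array([r.event for r in sel])
    tmax = int(fu.max())
    d = np.bincount(fu[ev == 1], minlength=tmax + 1)
    c = np.bincount(fu[ev == 0], minlength=tmax + 1)
    exits = d + c
    n_at_risk = len(sel) - np.concatenate([[0], np.cumsum(exits)[:-1]])
    with np.errstate(invalid="ignore"):
        factors = np.where(n_at_risk > 0, 1.0 - d / np.maximum(n_at_risk, 1), 1.0)
    s = np.cumprod(factors)
    return KMCurve(
        survival=s,
        kind="observed",
        n_at_risk=n_at_risk,
        n_events=d,
        n_censored=c,
    )


def restrict_cohort(
    records: Sequence[PatientRecord], min_dx_year: int
) -> list[PatientRecord]:
    """Keep patients diagnosed in ``min_dx_year`` or later (order preserved)."""
    return [r for r in records if r.dx_year >= min_dx_year]


def profiles_for(records: Sequence[PatientRecord]) -> list[ReferentProfile]:
    """Matched referent profiles, one per patient."""
    return [r.profile() for r in records]


# ---------------------------------------------------------------------------
# CSV interchange
# ---------------------------------------------------------------------------

_PATIENT_COLS = [
    "id", "sex", "age_at_dx", "dx_year", "dx_month",
    "follow_up_months", "event",
]


def records_to_frame(records: Sequence[PatientRecord]) -> pd.DataFrame:
    label_keys = sorted({k for r in records for k in r.labels})
    rows = []
    for r in records:
        row = {
            "id": r.id, "sex": r.sex, "age_at_dx": r.age_at_dx,
            "dx_year": r.dx_year, "dx_month": r.dx_month,
            "follow_up_months": r.follow_up_months, "event": r.event,
        }
        for k in label_keys:
            row[k] = r.labels.get(k, "")
        rows.append(row)
    return pd.DataFrame(rows, columns=_PATIENT_COLS + label_keys)


def write_patients(records: Sequence[PatientRecord], path: str | Path) -> None:
    records_to_frame(records).to_csv(path, index=False)


def costs_to_frame(records: Sequence[PatientRecord]) -> pd.DataFrame:
    """Long-format cost matrix: one row per (id, month) with an observed cost."""
    ids, months, costs = [], [], []
    for r in records:
        if r.costs is None:
            continue
        ids.extend([r.id] * r.costs.size)
        months.extend(range(r.costs.size))
        costs.extend(r.costs.tolist())
    return pd.DataFrame({"id": ids, "month": months, "cost": costs})


def write_costs(records: Sequence[PatientRecord], path: str | Path) -> None:
    costs_to_frame(records).to_csv(path, index=False)


def load_patients(
    path: str | Path,
    costs_path: str | Path | None = None,
    cost_currency: str = "USD2017",
) -> list[PatientRecord]:
    """Read the patient CSV (and optionally attach the long-format cost CSV)."""
    df = pd.read_csv(path, dtype={"id": str})
    missing = set(_PATIENT_COLS) - set(df.columns)
    if missing:
        raise ValueError(f"patient CSV missing column(s): {sorted(missing)}")
    label_keys = [c for c in df.columns if c not in _PATIENT_COLS]
    cost_map: dict[str, np.ndarray] = {}
    if costs_path is not None:
        cdf = pd.read_csv(costs_path, dtype={"id": str})
        for pid, grp in cdf.groupby("id", sort=False):
            vec = np.zeros(int(grp["month"].max()) + 1)
            vec[grp["month"].to_numpy()] = grp["cost"].to_numpy()
            cost_map[pid] = vec
    records = []
    for row in df.itertuples(index=False):
        labels = {
            k: getattr(row, k)
            for k in label_keys
            if isinstance(getattr(row, k), str) and getattr(row, k)
        }
        records.append(
            PatientRecord(
                id=row.id, sex=row.sex, age_at_dx=int(row.age_at_dx),
                dx_year=int(row.dx_year), dx_month=int(row.dx_month),
                follow_up_months=int(row.follow_up_months), event=int(row.event),
                labels=labels, costs=cost_map.get(row.id),
                cost_currency=cost_currency,
            )
        )
    return records
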