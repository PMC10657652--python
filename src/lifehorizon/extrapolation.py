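"""Lifetime-horizon extrapolation of cohort survival and loss of LE.

The estimand is life expectancy (LE) after diagnosis — the area under the
cohort survival curve out to the lifetime horizon — and loss-of-LE, the area
between the matched reference curve and the cohort curve.

Follow-up rarely reaches the horizon, so the observed Kaplan-Meier curve is
extended with a semiparametric relative-survival extrapolation: the logit of
the relative survival ratio W(t) = logit(S_index(t)/S_ref(t)) is close to
linear in t under a constant proportional excess hazard, which licenses
restricted-cubic-spline (RCS) smoothing with linear tails. A *rolling*
scheme predicts one month ahead, treats the prediction as an observation,
drops the oldest point of the fitting window, and refits — repeated until
reference survival is effectively zero.

Uncertainty is by patient-level nonparametric bootstrap (matched referents
are regenerated inside every resample); group contrasts use a normal z-test
on the bootstrap standard errors.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable, Sequence

import numpy as np
from scipy.special import expit, logit
from scipy.stats import norm

from .lifetable import SurvivalCurve
from .survival import KMCurve, PatientRecord, profiles_for

LOGIT_EPS = 1e-6
DEFAULT_KNOTS = 7
DEFAULT_STOP_EPS = 1e-4
MIN_OBSERVED_MONTHS = 24


class FitError(RuntimeError):
    """Raised when a spline fit is rank-deficient or otherwise degenerate."""


@dataclass
class LogitRelSurvSeries:
    """W(t) = logit(S_index(t) / S_ref(t)) on the months where both are positive."""

    t: np.ndarray
    w: np.ndarray

    def __post_init__(self) -> None:
        self.t = np.asarray(self.t, dtype=float)
        self.w = np.asarray(self.w, dtype=float)
        if self.t.shape != self.w.shape:
            raise ValueError("t and w must have the same shape")
        if not np.all(np.isfinite(self.w)):
            raise ValueError("W must be finite everywhere it is defined")

    def __len__(self) -> int:
        return self.t.size


def logit_relative_survival(km: KMCurve, ref: SurvivalCurve) -> LogitRelSurvSeries:
    """Logit-transformed relative survival over the observed window.

    The ratio is clipped into [eps, 1-eps] (eps = 1e-6) before the logit, so
    W(0) = logit(1-eps) and months where the cohort curve hits zero map to
    logit(eps).
    """
    if len(ref) < len(km):
        raise ValueError(
            f"grid mismatch: reference curve ({len(ref)} months) shorter than "
            f"observed curve ({len(km)} months)"
        )
    s_ref = ref.survival[: len(km)]
    if np.any(s_ref <= 0):
        raise ValueError("reference survival must be positive over the observed window")
    r = np.clip(km.survival / s_ref, LOGIT_EPS, 1.0 - LOGIT_EPS)
    return LogitRelSurvSeries(t=np.arange(len(km)), w=logit(r))


# ---------------------------------------------------------------------------
# Restricted cubic splines (natural cubic: linear tails, C2 at the knots)
# ---------------------------------------------------------------------------

def rcs_knots(tpoints: np.ndarray, n_knots: int) -> np.ndarray:
    """Boundary knots at the 5th/95th percentiles of the time points,
    interior knots equally spaced between them."""
    if n_knots < 3:
        raise ValueError("a restricted cubic spline needs >= 3 knots")
    lo, hi = np.percentile(tpoints, [5, 95])
    knots = np.linspace(lo, hi, n_knots)
    if np.any(np.diff(knots) <= 0):
        raise FitError("knots are not strictly increasing (too few distinct times)")
    return knots


def rcs_design(t: np.ndarray, knots: np.ndarray) -> np.ndarray:
    """Design matrix of the restricted cubic basis: [1, t, b_1..b_{K-2}].

    The truncated-cubic combinations enforce linearity beyond the boundary
    knots; columns are scaled by the squared knot span for conditioning.
    """
    t = np.asarray(t, dtype=float)
    k = np.asarray(knots, dtype=float)
    K = k.size
    span2 = (k[-1] - k[0]) ** 2
    cub = lambda x: np.maximum(x, 0.0) ** 3
    cols = [np.ones_like(t), t]
    for j in range(K - 2):
        b = (
            cub(t - k[j])
            - cub(t - k[-2]) * (k[-1] - k[j]) / (k[-1] - k[-2])
            + cub(t - k[-1]) * (k[-2] - k[j]) / (k[-1] - k[-2])
        )
        cols.append(b / span2)
    return np.column_stack(cols)


@dataclass
class SplineModel:
    """A fitted restricted cubic spline: knots plus basis coefficients."""

    knots: np.ndarray
    coef: np.ndarray

    def predict(self, t) -> np.ndarray:
        t = np.atleast_1d(np.asarray(t, dtype=float))
        return rcs_design(t, self.knots) @ self.coef


def fit_rcs(series: LogitRelSurvSeries, n_knots: int = DEFAULT_KNOTS) -> SplineModel:
    """Least-squares RCS fit of W(t); knots at quantiles of the series' times."""
    if len(series) < n_knots + 2:
        raise FitError(
            f"series has {len(series)} points; need >= n_knots + 2 = {n_knots + 2}"
        )
    if np.unique(series.t).size < 4:
        raise FitError("need at least 4 distinct time points")
    knots = rcs_knots(series.t, n_knots)
    X = rcs_design(series.t, knots)
    coef, _, rank, _ = np.linalg.lstsq(X, series.w, rcond=None)
    if rank < X.shape[1]:
        raise FitError("rank-deficient spline design")
    return SplineModel(knots=knots, coef=coef)


def _one_step_weights(window_len: int, n_knots: int) -> np.ndarray:
    """Fixed linear functional giving the one-month-ahead RCS prediction.

    The rolling window always holds ``window_len`` consecutive integer
    months, so in window-local coordinates the quantile knots and the design
    matrix never change; prediction at the next month is x(L) @ pinv(X) @ y,
    i.e. a constant weight vector applied to the window's W values. This is
    exactly the per-step refit, computed once.
    """
    t_local = np.arange(window_len, dtype=float)
    knots = rcs_knots(t_local, n_knots)
    X = rcs_design(t_local, knots)
    x_next = rcs_design(np.array([float(window_len)]), knots)
    return (x_next @ np.linalg.pinv(X)).ravel()


@dataclass
class ExtrapolationResult:
    """Lifetime-horizon curves and the LE / loss-of-LE areas (years)."""

    s_index: np.ndarray
    s_ref: np.ndarray
    observed_months: int
    le: float
    le_ref: float
    loss_of_le: float
    stop_month: int
    stop_reason: str

    @property
    def index_curve(self) -> SurvivalCurve:
        return SurvivalCurve(self.s_index, kind="extrapolated")

    @property
    def reference_curve(self) -> SurvivalCurve:
        return SurvivalCurve(self.s_ref, kind="reference")


def area_in_years(s: np.ndarray) -> float:
    """Trapezoidal area under a monthly survival curve, in years."""
    return float(np.trapezoid(s)) / 12.0


def rolling_extrapolate(
    km: KMCurve,
    ref_full: SurvivalCurve,
    n_knots: int = DEFAULT_KNOTS,
    stop_eps: float = DEFAULT_STOP_EPS,
) -> ExtrapolationResult:
    """Extend the observed curve to the lifetime horizon and integrate.

    Each step fits the RCS to the current W window, predicts W at the next
    month, converts it to survival via S(t+1) = expit(W) * S_ref(t+1),
    clamps monotone, appends the prediction and drops the window's oldest
    point. Stops when S_ref < ``stop_eps`` or the reference curve (which
    ends at the terminal-age cap) runs out.
    """
    s_ref = ref_full.survival
    t_obs = len(km) - 1
    if len(s_ref) <= t_obs:
        raise ValueError("ref_full shorter than the observed window")

    below = np.nonzero(s_ref < stop_eps)[0]
    if below.size:
        stop_month = int(below[0])
        stop_reason = "reference_survival_below_eps"
    else:
        stop_month = len(s_ref) - 1
        stop_reason = "age_cap"
    stop_month = max(stop_month, t_obs)

    s_obs = km.survival
    if s_obs[-1] == 0.0:
        # everyone observed to die: nothing to extrapolate
        s_index = np.concatenate([s_obs, np.zeros(stop_month - t_obs)])
    else:
        if t_obs + 1 < MIN_OBSERVED_MONTHS:
            raise ValueError(
                f"observed window of {t_obs + 1} months is too short to "
                f"extrapolate (need >= {MIN_OBSERVED_MONTHS})"
            )
        series = logit_relative_survival(km, ref_full)
        L = len(series)
        wts = _one_step_weights(L, n_knots)
        n_steps = stop_month - t_obs
        w_buf = np.concatenate([series.w, np.empty(n_steps)])
        s_index = np.concatenate([s_obs, np.empty(n_steps)])
        for k in range(n_steps):
            t_next = t_obs + 1 + k
            w_next = wts @ w_buf[k : k + L]
            s_next = expit(w_next) * s_ref[t_next]
            s_next = min(s_next, s_index[t_next - 1])
            w_buf[L + k] = w_next
            s_index[t_next] = s_next

    s_ref_grid = s_ref[: stop_month + 1]
    le = area_in_years(s_index)
    le_ref = area_in_years(s_ref_grid)
    return ExtrapolationResult(
        s_index=s_index,
        s_ref=s_ref_grid,
        observed_months=t_obs,
        le=le,
        le_ref=le_ref,
        loss_of_le=le_ref - le,
        stop_month=stop_month,
        stop_reason=stop_reason,
    )


# ---------------------------------------------------------------------------
# Resampling uncertainty and group contrasts
# ---------------------------------------------------------------------------

@dataclass
class UncertaintyResult:
    """Bootstrap point estimate, SE and percentile 95% CI.

    ``estimate``/``se``/``ci_low``/``ci_high`` are scalars for scalar-valued
    analyses and aligned arrays for vector-valued ones; ``replicates`` holds
    the per-resample estimates (failed resamples excluded, counted in
    ``n_failed``).
    """

    estimate: np.ndarray | float
    se: np.ndarray | float
    ci_low: np.ndarray | float
    ci_high: np.ndarray | float
    n_resamples: int
    n_failed: int
    seed: int | None
    replicates: np.ndarray


def resample_ci(
    analysis: Callable,
    records: Sequence[PatientRecord],
    profiles=None,
    B: int = 200,
    seed: int | None = None,
) -> UncertaintyResult:
    """Patient-level nonparametric bootstrap of an analysis of the cohort.

    ``analysis(records, profiles)`` must return a float or a 1-d array and
    be deterministic given its inputs. Patients are resampled with
    replacement; the matched referent profiles are regenerated for each
    resample so the reference curve tracks the resampled demographics.
    Resamples where the analysis raises are excluded and counted.
    """
    if B < 2:
        raise ValueError("B must be >= 2")
    rng = np.random.default_rng(seed)
    records = list(records)
    if profiles is None:
        profiles = profiles_for(records)
    point = np.atleast_1d(np.asarray(analysis(records, profiles), dtype=float))
    reps = []
    n_failed = 0
    n = len(records)
    for _ in range(B):
        idx = rng.integers(0, n, size=n)
        sub = [records[i] for i in idx]
        sub_prof = [profiles[i] for i in idx]
        try:
            reps.append(np.atleast_1d(np.asarray(analysis(sub, sub_prof), dtype=float)))
        except (ValueError, FitError, np.linalg.LinAlgError, FloatingPointError):
            n_failed += 1
    if not reps:
        raise RuntimeError("all bootstrap resamples failed")
    reps = np.vstack(reps)
    se = reps.std(axis=0, ddof=1)
    lo, hi = np.percentile(reps, [2.5, 97.5], axis=0)
    squeeze = point.size == 1
    unpack = (lambda a: float(a[0])) if squeeze else (lambda a: a)
    return UncertaintyResult(
        estimate=unpack(point),
        se=unpack(se),
        ci_low=unpack(lo),
        ci_high=unpack(hi),
        n_resamples=len(reps),
        n_failed=n_failed,
        seed=seed,
        replicates=reps[:, 0] if squeeze else reps,
    )


def z_test(est1: float, se1: float, est2: float, se2: float) -> tuple[float, float]:
    """Two-sided normal test of est1 - est2 = 0 given the two SEs."""
    if se1 <= 0 or se2 <= 0:
        raise ValueError("standard errors must be positive")
    z = (est1 - est2) / np.hypot(se1, se2)
    p = 2.0 * norm.sf(abs(z))
    return float(z), float(p)
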