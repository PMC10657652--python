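"""Logit relative survival, restricted cubic splines, rolling extrapolation,
bootstrap uncertainty and the group z-test."""

import numpy as np
import pytest
from scipy.linalg import null_space
from scipy.special import expit, logit

import lifehorizon as lh
from lifehorizon.extrapolation import (
    LOGIT_EPS,
    FitError,
    LogitRelSurvSeries,
    _one_step_weights,
    fit_rcs,
    logit_relative_survival,
    rcs_design,
    rcs_knots,
    resample_ci,
    rolling_extrapolate,
    z_test,
)
from lifehorizon.lifetable import ReferentProfile, SurvivalCurve, expected_reference_survival
from lifehorizon.survival import KMCurve, fit_km, profiles_for

from .conftest import flat_table, record


def natural_spline_ls(t, w, knots, t_new):
    """Independent natural-cubic-spline least squares: full truncated-power
    cubic basis with the natural constraints imposed through a null-space
    projection (sum of cubic coefficients and their knot-weighted sum vanish,
    no global quadratic/cubic terms)."""
    knots = np.asarray(knots, dtype=float)

    def basis(x):
        cols = [np.ones_like(x), x] + [np.maximum(x - kj, 0.0) ** 3 for kj in knots]
        return np.column_stack(cols)

    C = np.zeros((2, knots.size + 2))
    C[0, 2:] = 1.0
    C[1, 2:] = knots
    Z = null_space(C)
    g, *_ = np.linalg.lstsq(basis(np.asarray(t, float)) @ Z, w, rcond=None)
    return (basis(np.atleast_1d(np.asarray(t_new, float))) @ (Z @ g)).item()


class TestLogitRelativeSurvival:
    def test_identity_cohort_sits_at_the_clip_ceiling(self):
        s = np.exp(-0.01 * np.arange(30))
        km = KMCurve(s, kind="observed")
        ref = SurvivalCurve(s.copy(), kind="reference")
        series = logit_relative_survival(km, ref)
        assert np.allclose(series.w, logit(1 - LOGIT_EPS))

    def test_half_reference_gives_zero(self):
        ref = SurvivalCurve(np.ones(5), kind="reference")
        km = KMCurve(np.array([1.0] + [0.5] * 4), kind="observed")
        series = logit_relative_survival(km, ref)
        assert series.w[1] == pytest.approx(0.0)

    def test_constant_excess_closed_form(self):
        # S_index = exp(-0.01 t) * S_ref: at t=60, r = e^{-0.6},
        # W = ln(0.5488/0.4512) = 0.19567
        t = np.arange(61)
        s_ref = np.exp(-0.004 * t)
        s_idx = np.exp(-0.01 * t) * s_ref
        series = logit_relative_survival(
            KMCurve(s_idx, kind="observed"), SurvivalCurve(s_ref, kind="reference")
        )
        expected = np.log(np.exp(-0.6) / (1 - np.exp(-0.6)))
        assert series.w[60] == pytest.approx(expected, rel=1e-9)
        assert expected == pytest.approx(0.1959, abs=5e-5)

    def test_reference_shorter_than_observed_is_grid_mismatch(self):
        km = KMCurve(np.ones(10), kind="observed")
        ref = SurvivalCurve(np.ones(5), kind="reference")
        with pytest.raises(ValueError, match="grid mismatch"):
            logit_relative_survival(km, ref)


class TestFitRCS:
    def test_linear_functions_are_reproduced_exactly(self):
        t = np.arange(40.0)
        w = 3.0 - 0.25 * t
        m = fit_rcs(LogitRelSurvSeries(t=t, w=w), n_knots=5)
        assert np.allclose(m.predict(t), w, atol=1e-9)
        assert m.predict(41.0).item() == pytest.approx(3.0 - 0.25 * 41, abs=1e-8)

    def test_constant_series_predicts_the_constant(self):
        t = np.arange(30.0)
        m = fit_rcs(LogitRelSurvSeries(t=t, w=np.full(30, 2.5)), n_knots=4)
        assert m.predict(35.0).item() == pytest.approx(2.5, abs=1e-9)

    @pytest.mark.parametrize("n_knots", [4, 5, 7])
    def test_agrees_with_independent_natural_spline_fit(self, n_knots):
        t = np.arange(60.0)
        w = t ** 2
        m = fit_rcs(LogitRelSurvSeries(t=t, w=w), n_knots=n_knots)
        knots = rcs_knots(t, n_knots)
        oracle = natural_spline_ls(t, w, knots, 60.0)
        assert m.predict(60.0).item() == pytest.approx(oracle, rel=1e-9)

    def test_prediction_beyond_boundary_lies_on_a_line(self):
        t = np.arange(50.0)
        rng = np.random.default_rng(1)
        m = fit_rcs(LogitRelSurvSeries(t=t, w=rng.normal(size=50)), n_knots=5)
        far = m.predict(np.array([60.0, 70.0, 80.0]))
        slopes = np.diff(far) / 10.0
        assert slopes[0] == pytest.approx(slopes[1], rel=1e-9)

    def test_too_few_points_raise(self):
        t = np.arange(5.0)
        with pytest.raises(FitError):
            fit_rcs(LogitRelSurvSeries(t=t, w=t), n_knots=5)

    def test_too_few_distinct_times_raise(self):
        t = np.array([0.0, 0.0, 1.0, 1.0, 2.0, 2.0])
        with pytest.raises(FitError):
            fit_rcs(LogitRelSurvSeries(t=t, w=t), n_knots=3)

    def test_one_step_weights_equal_explicit_refit(self):
        # the rolling loop's precomputed predictor must equal fitting the
        # spline on the window and predicting the next month
        rng = np.random.default_rng(7)
        L, nk = 48, 5
        y = np.cumsum(rng.normal(size=L))
        wts = _one_step_weights(L, nk)
        m = fit_rcs(LogitRelSurvSeries(t=np.arange(float(L)), w=y), n_knots=nk)
        assert (wts @ y) == pytest.approx(m.predict(float(L)).item(), rel=1e-9)

    def test_fit_is_translation_invariant(self):
        # same window shifted in time -> same prediction (the rolling loop
        # relies on this to reuse one design matrix)
        rng = np.random.default_rng(8)
        y = np.cumsum(rng.normal(size=60))
        t0 = np.arange(60.0)
        m0 = fit_rcs(LogitRelSurvSeries(t=t0, w=y), n_knots=5)
        m1 = fit_rcs(LogitRelSurvSeries(t=t0 + 137.0, w=y), n_knots=5)
        assert m0.predict(60.0).item() == pytest.approx(
            m1.predict(197.0).item(), rel=1e-9
        )


class TestRollingExtrapolate:
    def _ref(self, lam=0.004, months=600):
        t = np.arange(months + 1)
        return SurvivalCurve(np.exp(-lam * t), kind="reference")

    def test_conservation_identity(self):
        ref = self._ref()
        t = np.arange(121)
        km = KMCurve(np.exp(-0.006 * t), kind="observed")
        ext = rolling_extrapolate(km, ref)
        assert ext.le_ref - ext.le == ext.loss_of_le
        assert np.all(np.diff(ext.s_index) <= 1e-12)
        assert ext.s_index.size == ext.s_ref.size

    def test_everyone_dead_in_month_one(self):
        recs = [record(i, fu=1, event=1) for i in range(30)]
        km = fit_km(recs)
        ext = rolling_extrapolate(km, self._ref(lam=0.01, months=1200))
        assert ext.le == pytest.approx(1 / 24, rel=1e-9)
        assert ext.loss_of_le == pytest.approx(ext.le_ref - 1 / 24, rel=1e-9)

    def test_short_window_rejected(self):
        t = np.arange(13)
        km = KMCurve(np.exp(-0.01 * t), kind="observed")
        with pytest.raises(ValueError, match="too short"):
            rolling_extrapolate(km, self._ref())

    def test_reference_must_cover_extrapolation(self):
        km = KMCurve(np.ones(40), kind="observed")
        ref = SurvivalCurve(np.ones(30), kind="reference")
        with pytest.raises(ValueError, match="shorter"):
            rolling_extrapolate(km, ref)

    def test_constant_excess_hazard_recovery_on_exact_inputs(self):
        # toy reference law + constant excess hazard: LE matches the
        # quadrature truth of S_ref(t) e^{-lambda t}
        lam = 0.02
        ref = self._ref(lam=0.004, months=3000)
        t = np.arange(3001)
        s_true = ref.survival * np.exp(-lam * t)
        km = KMCurve(s_true[:121], kind="observed")
        ext = rolling_extrapolate(km, ref)
        le_truth = np.trapezoid(s_true[: ext.stop_month + 1]) / 12
        assert ext.le == pytest.approx(le_truth, rel=0.05)

    def test_zero_excess_cohort_recovers_zero_loss(self):
        # cohort drawn from the reference law itself: loss-of-LE ~ 0
        sc = lh.SyntheticScenario(seed=99)
        sc.cohort.n = 2000
        sc.cohort.dx_year_min = sc.cohort.dx_year_max = 2003
        sc.excess.baseline = 0.0
        lt = lh.make_life_table(sc)
        recs, _ = lh.draw_cohort(sc, lt)
        km = fit_km(recs)
        ref = expected_reference_survival(
            profiles_for(recs), lt, 12 * (lt.age_max + 2 - min(r.age_at_dx for r in recs))
        )
        ext = rolling_extrapolate(km, ref)
        assert abs(ext.loss_of_le) < 0.3


class TestResampleCI:
    def test_bootstrap_se_tracks_analytic_se(self, rng):
        fu = rng.integers(1, 120, size=200)
        recs = [record(i, fu=int(f)) for i, f in enumerate(fu)]

        def mean_fu(rs, _):
            return float(np.mean([r.follow_up_months for r in rs]))

        unc = resample_ci(mean_fu, recs, B=1000, seed=11)
        analytic = fu.std(ddof=1) / np.sqrt(len(fu))
        assert unc.se == pytest.approx(analytic, rel=0.15)
        assert unc.ci_low < unc.estimate < unc.ci_high

    def test_fixed_seed_reproducible(self):
        recs = [record(i, fu=i + 1) for i in range(10)]
        f = lambda rs, _: float(np.mean([r.follow_up_months for r in rs]))
        a = resample_ci(f, recs, B=2, seed=5)
        b = resample_ci(f, recs, B=2, seed=5)
        assert np.array_equal(a.replicates, b.replicates)

    def test_degenerate_cohort_has_zero_se(self):
        recs = [record(i, fu=7) for i in range(20)]
        f = lambda rs, _: float(np.mean([r.follow_up_months for r in rs]))
        assert resample_ci(f, recs, B=50, seed=1).se == 0.0

    def test_all_resample_failures_raise(self):
        calls = {"n": 0}

        def boom(rs, _):
            calls["n"] += 1
            if calls["n"] == 1:  # point estimate succeeds
                return 1.0
            raise ValueError("no")

        with pytest.raises(RuntimeError, match="all bootstrap"):
            resample_ci(boom, [record(0)], B=3, seed=0)

    def test_vector_valued_analysis(self):
        recs = [record(i, fu=i + 1) for i in range(30)]

        def two(rs, _):
            fus = [r.follow_up_months for r in rs]
            return np.array([np.mean(fus), np.max(fus)])

        unc = resample_ci(two, recs, B=50, seed=2)
        assert np.asarray(unc.se).shape == (2,)
        assert np.asarray(unc.ci_low)[1] <= 30


class TestZTest:
    def test_equal_estimates(self):
        z, p = z_test(3.0, 1.0, 3.0, 1.0)
        assert z == 0.0 and p == pytest.approx(1.0)

    def test_critical_value(self):
        se = np.hypot(0.5, 0.8)
        z, p = z_test(1.96 * se, 0.5, 0.0, 0.8)
        assert p == pytest.approx(0.05, abs=1e-4)

    def test_loss_of_le_contrast_worked_example(self):
        # loss-of-LE 5.60 (SEM 1.85) vs 4.76 (SEM 0.60):
        # z = 0.84/1.9449 = 0.4319, two-sided p = 0.666
        z, p = z_test(5.60, 1.85, 4.76, 0.60)
        assert z == pytest.approx(0.4319, abs=2e-4)
        assert p == pytest.approx(0.666, abs=1e-3)

    def test_nonpositive_se_rejected(self):
        with pytest.raises(ValueError):
            z_test(1.0, 0.0, 2.0, 1.0)
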