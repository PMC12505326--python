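import numpy as np
import pytest

from htefuse import (
    Cohort,
    CoxConditionalSurvival,
    KnownConditionalSurvival,
    fit_conditional_survival,
    predict_survival,
)
from htefuse.nuisance import estimate_mu


def _exp_known(rate=0.2):
    return KnownConditionalSurvival(
        lambda t, X, a: np.exp(-rate * np.atleast_1d(np.asarray(t, float)))[:, None]
        * np.ones((1, np.atleast_2d(X).shape[0]))
    )


def _step_model(times, dl0, beta=None, arm=0):
    m = CoxConditionalSurvival()
    m.set_stratum(arm, np.zeros(1) if beta is None else np.asarray(beta),
                  np.asarray(times, float), np.asarray(dl0, float))
    return m


class TestPredictSurvival:
    def test_known_function_closed_form(self):
        m = _exp_known(0.2)
        assert predict_survival(m, 1.0, (0.0,), 0, floor=0.0) == pytest.approx(
            np.exp(-0.2), abs=1e-6
        )

    def test_survival_at_zero_is_one(self):
        m = _step_model([1.0], [0.5])
        assert predict_survival(m, 0.0, (0.0,), 0, floor=0.0) == 1.0

    def test_left_continuous_step_evaluation(self):
        # single jump dLambda=0.5 at t=1, x'beta=0: left limit at 1 is 1,
        # just after it is the product-limit value 1 - 0.5
        m = _step_model([1.0], [0.5])
        assert predict_survival(m, 1.0, (0.0,), 0, floor=0.0) == 1.0
        assert predict_survival(m, 1.0 + 1e-9, (0.0,), 0, floor=0.0) == pytest.approx(0.5)

    def test_monotone_nonincreasing(self):
        m = _step_model([0.5, 1.2, 2.0], [0.1, 0.2, 0.3], beta=[0.4])
        ts = np.linspace(0, 3, 50)
        vals = [predict_survival(m, t, (0.7,), 0, floor=0.0) for t in ts]
        assert all(v2 <= v1 + 1e-12 for v1, v2 in zip(vals, vals[1:]))

    def test_floor_applied(self):
        m = _step_model([1.0], [0.999])
        assert predict_survival(m, 2.0, (0.0,), 0) == pytest.approx(0.05)


class TestRestrictedMean:
    def test_no_failures_gives_L(self):
        m = _step_model([], [])
        assert estimate_mu(m, (0.0,), 0, 3.0) == pytest.approx(3.0)

    def test_exponential_closed_form(self):
        m = _exp_known(0.2)
        assert estimate_mu(m, (0.0,), 0, 3.0) == pytest.approx(
            (1 - np.exp(-0.6)) / 0.2, abs=1e-6
        )

    def test_step_model_exact_integral(self):
        # S = 1 on [0,1), 0.6 on [1,2), 0.6*0.5 on [2,3): mu = 1 + 0.6 + 0.3
        m = _step_model([1.0, 2.0], [0.4, 0.5])
        assert estimate_mu(m, (0.0,), 0, 3.0) == pytest.approx(1.9, abs=1e-12)

    def test_mu_within_bounds(self, case2_cohort):
        gt = fit_conditional_survival(case2_cohort, "failure")
        X = case2_cohort.x[:50]
        for arm in (0, 1):
            mu = np.clip(gt.restricted_mean_vec(X, arm, 3.0), 0, None)
            assert np.all(mu >= 0) and np.all(mu <= 3.0)


class TestCoxFit:
    def test_requires_events(self, case2_cohort):
        df = case2_cohort.df.copy()
        df["delta"] = 1  # no censorings anywhere
        with pytest.raises(ValueError, match="no censoring events"):
            fit_conditional_survival(Cohort(df, 3.0), "censoring")

    def test_coefficient_recovery_exponential_ph(self):
        # T ~ exponential with hazard exp(0.5 x1): Cox slope should be ~0.5
        rng = np.random.default_rng(5)
        n = 5000
        x = rng.normal(0, 1, n)
        t = rng.exponential(1.0, n) / np.exp(0.5 * x)
        c = rng.exponential(3.0, n)
        y = np.minimum(t, c)
        delta = (t <= c).astype(int)
        cohort = Cohort.from_arrays(y, delta, x[:, None], np.zeros(n, int),
                                    np.ones(n, int), L=3.0)
        cohort.df.loc[:1, "a"] = 1  # both arms present for validation elsewhere
        m = fit_conditional_survival(cohort, "failure", strata_key="pooled")
        beta = m._strata["pooled"]["beta"]
        assert abs(beta[0] - 0.5) < 0.1

    def test_stratified_fit_has_both_arms(self, case2_cohort):
        m = fit_conditional_survival(case2_cohort, "failure", strata_key="a")
        assert len(m.jump_times(0)) > 0 and len(m.jump_times(1)) > 0

    def test_serialization_round_trip(self, case2_cohort):
        m = fit_conditional_survival(case2_cohort, "failure")
        back = CoxConditionalSurvival.from_dict(m.to_dict())
        X = case2_cohort.x[:10]
        ts = np.array([0.5, 1.5, 2.5])
        np.testing.assert_allclose(
            back.survival_before_times(ts, X, 1), m.survival_before_times(ts, X, 1)
        )


def test_integral_tail_matches_quadrature():
    m = _step_model([0.7, 1.4, 2.1], [0.2, 0.3, 0.25], beta=[0.3])
    X = np.array([[0.5]])
    ts = np.array([0.0, 0.6, 1.0, 2.5])
    tails = m.integral_tail(ts, X, 0, 3.0)[:, 0]
    grid = np.linspace(0, 3, 200001)
    S = m.survival_before_times(grid, X, 0)[:, 0]
    for t, tail in zip(ts, tails):
        brute = np.trapezoid(S[grid >= t], grid[grid >= t])
        assert tail == pytest.approx(brute, abs=2e-4)
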