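import numpy as np
import pytest

from htefuse import (
    CoxConditionalSurvival,
    KnownConditionalSurvival,
    SubjectRecord,
    aipcw_transform,
    build_pseudo_response,
    fit_nuisances,
    pseudo_ite,
    residual_restricted_life,
    restrict_outcome,
)
from htefuse.nuisance import NuisanceSet


def _step(times, dl0, arm=0):
    m = CoxConditionalSurvival()
    m.set_stratum(arm, np.zeros(1), np.asarray(times, float), np.asarray(dl0, float))
    return m


def _exp_known(rate):
    return KnownConditionalSurvival(
        lambda t, X, a: np.exp(-rate * np.atleast_1d(np.asarray(t, float)))[:, None]
        * np.ones((1, np.atleast_2d(X).shape[0]))
    )


class TestResidualRestrictedLife:
    def test_no_failure_mass_gives_L(self):
        m = _step([], [])
        assert residual_restricted_life(m, 1.0, (0.0,), 0, 3.0) == pytest.approx(3.0)

    def test_exponential_closed_form(self):
        m = _exp_known(0.2)
        expected = 1 + 5 * (np.exp(-0.2) - np.exp(-0.6)) / np.exp(-0.2)
        assert residual_restricted_life(m, 1.0, (0.0,), 0, 3.0) == pytest.approx(
            expected, abs=1e-5
        )

    def test_boundary_t_equals_L(self):
        m = _exp_known(0.2)
        assert residual_restricted_life(m, 3.0, (0.0,), 0, 3.0) == pytest.approx(3.0)
        with pytest.raises(ValueError):
            residual_restricted_life(m, 3.5, (0.0,), 0, 3.0)


class TestAipcwTransform:
    """The two-branch discrete censoring oracle: failure time degenerate at
    2 given (x, a), L = 3, C in {1, 5} with probability 1/2 each.  The
    censoring product-limit has a single jump of hazard 1/2 at t = 1, and
    B(t) = 2 below 2.  The uncensored branch gives 2/0.5 − 2·0.5/1 = 3, the
    censored branch gives the imputation 2/1 − 2·0.5/1 = 1, and enumerating
    both branches returns the true restricted mean E[T_L] = 2 exactly."""

    gt = _step([2.0], [1.0])
    gc = _step([1.0], [0.5])

    def test_uncensored_branch(self):
        r = SubjectRecord(2.0, 1, (0.0,), 0, 1)
        ro = restrict_outcome(2.0, 1, 3.0)
        assert aipcw_transform(r, ro, self.gt, self.gc, 3.0) == pytest.approx(3.0, abs=1e-12)

    def test_censored_branch(self):
        r = SubjectRecord(1.0, 0, (0.0,), 0, 1)
        ro = restrict_outcome(1.0, 0, 3.0)
        assert aipcw_transform(r, ro, self.gt, self.gc, 3.0) == pytest.approx(1.0, abs=1e-12)

    def test_mean_preservation_exact(self):
        vals = []
        for y, d in [(2.0, 1), (1.0, 0)]:
            r = SubjectRecord(y, d, (0.0,), 0, 1)
            vals.append(aipcw_transform(r, restrict_outcome(y, d, 3.0), self.gt, self.gc, 3.0))
        assert abs(0.5 * (vals[0] + vals[1]) - 2.0) < 1e-12

    def test_no_censoring_reduction(self):
        # G_C = 1 everywhere: the transform returns Y_L exactly
        gc_one = _step([], [])
        for y, d in [(2.0, 1), (0.7, 1), (4.0, 0)]:
            r = SubjectRecord(y, d, (0.0,), 0, 1)
            ro = restrict_outcome(y, d, 3.0)
            out = aipcw_transform(r, ro, self.gt, gc_one, 3.0)
            assert out == pytest.approx(ro.y_L, abs=1e-12)

    def test_linearity_in_scale(self):
        # scaling the time axis (Y_L and B) by c scales t_tilde by c
        c = 0.5
        gt2 = _step([2.0 * c], [1.0])
        gc2 = _step([1.0 * c], [0.5])
        r = SubjectRecord(2.0 * c, 1, (0.0,), 0, 1)
        ro = restrict_outcome(2.0 * c, 1, 3.0 * c)
        assert aipcw_transform(r, ro, gt2, gc2, 3.0 * c) == pytest.approx(3.0 * c, abs=1e-12)


class TestPseudoIte:
    @pytest.mark.parametrize(
        "a, t_tilde, e, mu0, mu1, expected",
        [
            (1, 4.0, 0.5, 2.0, 2.0, 4.0),  # R1 = 8-2 = 6, R0 = 2
            (0, 2.0, 0.5, 3.0, 1.0, 0.0),  # R1 = 1, R0 = 4-3 = 1
        ],
    )
    def test_printed_formula(self, a, t_tilde, e, mu0, mu1, expected):
        assert pseudo_ite(a, t_tilde, e, mu0, mu1) == pytest.approx(expected)

    def test_invalid_propensity(self):
        with pytest.raises(ValueError):
            pseudo_ite(1, 2.0, 1.0, 0.0, 0.0)

    def test_aipw_unbiasedness_monte_carlo(self):
        # with e known and exact arm means, E[r_tilde | x] = mu1 - mu0
        rng = np.random.default_rng(8)
        n = 100_000
        mu0, mu1 = 1.4, 2.1
        a = rng.binomial(1, 0.5, n)
        t_L = np.where(a == 1, rng.normal(mu1, 0.5, n), rng.normal(mu0, 0.5, n))
        r = pseudo_ite(a, t_L, 0.5, mu0, mu1)
        se = r.std(ddof=1) / np.sqrt(n)
        assert abs(r.mean() - (mu1 - mu0)) < 3 * se


class TestBuildPseudoResponse:
    def test_rwd_rows_get_y_L(self, case2_cohort):
        nuis = fit_nuisances(case2_cohort)
        pr = build_pseudo_response(case2_cohort, nuis)
        rwd = case2_cohort.s == 0
        np.testing.assert_allclose(pr.dhat[rwd], pr.y_L[rwd])
        assert np.all(np.isnan(pr.r_tilde[rwd]))

    def test_weights_positive_finite(self, case2_cohort):
        nuis = fit_nuisances(case2_cohort)
        pr = build_pseudo_response(case2_cohort, nuis)
        assert np.all(pr.weight > 0) and np.all(np.isfinite(pr.weight))

    def test_audit_frame_columns(self, case2_cohort):
        nuis = fit_nuisances(case2_cohort)
        pr = build_pseudo_response(case2_cohort, nuis, weights="unit")
        df = pr.to_frame()
        assert set(df.columns) >= {"y_L", "delta_tilde", "t_tilde", "r_tilde", "dhat", "weight"}
        assert len(df) == case2_cohort.n


def test_double_robustness_wrong_censoring_model():
    """With G_T exact and G_C (badly) wrong, the trial pseudo-outcome mean
    at fixed x still recovers tau(x): the failure-model augmentation
    restores the mean."""
    from htefuse.simulation import _eta

    rng = np.random.default_rng(21)
    n = 40_000
    x0 = np.array([0.5, -0.5])
    rate1 = 0.2 * np.exp(_eta(x0[0], x0[1], 1))
    rate0 = 0.2 * np.exp(_eta(x0[0], x0[1], 0))
    L = 3.0
    tau = (1 - np.exp(-rate1 * L)) / rate1 - (1 - np.exp(-rate0 * L)) / rate0

    a = rng.binomial(1, 0.5, n)
    rate = np.where(a == 1, rate1, rate0)
    t = rng.exponential(1.0, n) / rate
    c = rng.exponential(1.0 / 0.3, n)  # true censoring: exponential rate 0.3
    y = np.minimum(t, c)
    delta = (t <= c).astype(int)

    def gt_surv(tt, X, arm):
        r = rate1 if arm == 1 else rate0
        return np.exp(-r * np.atleast_1d(np.asarray(tt, float)))[:, None] * np.ones(
            (1, np.atleast_2d(X).shape[0])
        )

    def gc_wrong(tt, X, arm):  # pretends censoring is much lighter
        return np.exp(-0.05 * np.atleast_1d(np.asarray(tt, float)))[:, None] * np.ones(
            (1, np.atleast_2d(X).shape[0])
        )

    def gc_haz(tt, X, arm):
        tt = np.atleast_1d(np.asarray(tt, float))
        return np.full((len(tt), np.atleast_2d(X).shape[0]), 0.05)

    from htefuse import Cohort

    cohort = Cohort.from_arrays(y, delta, np.tile(x0, (n, 1)), a, np.ones(n, int), L)
    nuis = NuisanceSet(
        propensity=lambda X: np.full(np.atleast_2d(X).shape[0], 0.5),
        g_t=KnownConditionalSurvival(gt_surv),
        g_c=KnownConditionalSurvival(gc_wrong, hazard=gc_haz),
        L=L,
    )
    pr = build_pseudo_response(cohort, nuis, weights="unit")
    se = pr.dhat.std(ddof=1) / np.sqrt(n)
    assert abs(pr.dhat.mean() - tau) < 3 * se
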