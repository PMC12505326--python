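"""Fitting the integrative, trial-only and real-world-only HTE estimators.

``fit_integrative`` runs the full pipeline on a fused cohort: nuisance
fits on the trial, AIPCW/AIPW pseudo-responses, tensor B-spline bases for
the effect surface τ(x) (all subjects) and the bias surface λ(x)
(real-world rows), joint GCV selection of the penalty parameters, and a
penalized weighted least-squares solve.  ``fit_rct_only`` runs the same
machinery on the trial rows with no bias block; ``fit_rwd_only`` applies
the trial machinery to the real-world rows as if they were a trial (its
target is τ + λ, biased for τ by construction — it exists as a
comparator).

Pointwise standard errors use the empirical sandwich
se(x)² = b(x)' A⁻¹ M A⁻¹ b(x) treating pseudo-responses and weights as
fixed; a stratified subject-level bootstrap is available as an
alternative that propagates nuisance-estimation variability.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import norm

from .cohort import Cohort, validate_cohort
from .nuisance import NuisanceSet, fit_nuisances
from .pseudo import PseudoResponse, build_pseudo_response
from .sieve import SieveSpec, TensorBasis, build_basis, gcv_select, penalized_wls
from .survival import GFLOOR

__all__ = [
    "HTEEstimate",
    "fit_integrative",
    "fit_rct_only",
    "fit_rwd_only",
    "predict_grid",
    "bootstrap_se",
]


@dataclass
class HTEEstimate:
    """Fitted HTE (and optional bias) surfaces with pointwise inference."""

    basis_tau: TensorBasis
    basis_lambda: TensorBasis | None
    fit: object  # PenalizedFit
    ci_level: float = 0.95
    nuisances: NuisanceSet | None = None
    pseudo: PseudoResponse | None = None
    estimand: str = "tau"  # "tau" or "tau_plus_lambda" (RWD-only comparator)

    def __post_init__(self):
        self._cov = self.fit.covariance()
        self._r1 = len(self.fit.beta)

    def tau_at(self, x) -> np.ndarray:
        return self.basis_tau.design(np.atleast_2d(x)) @ self.fit.beta

    def lambda_at(self, x) -> np.ndarray:
        if self.basis_lambda is None:
            raise ValueError("this estimate has no bias-surface block")
        return self.basis_lambda.design(np.atleast_2d(x)) @ self.fit.alpha

    def se_tau_at(self, x) -> np.ndarray:
        Phi = self.basis_tau.design(np.atleast_2d(x))
        V = self._cov[: self._r1, : self._r1]
        return np.sqrt(np.maximum(np.einsum("ij,jk,ik->i", Phi, V, Phi), 0.0))

    def se_lambda_at(self, x) -> np.ndarray:
        if self.basis_lambda is None:
            raise ValueError("this estimate has no bias-surface block")
        Psi = self.basis_lambda.design(np.atleast_2d(x))
        V = self._cov[self._r1 :, self._r1 :]
        return np.sqrt(np.maximum(np.einsum("ij,jk,ik->i", Psi, V, Psi), 0.0))

    def ci_tau_at(self, x) -> tuple[np.ndarray, np.ndarray]:
        z = norm.ppf(0.5 + self.ci_level / 2)
        est, se = self.tau_at(x), self.se_tau_at(x)
        return est - z * se, est + z * se

    def ci_lambda_at(self, x) -> tuple[np.ndarray, np.ndarray]:
        z = norm.ppf(0.5 + self.ci_level / 2)
        est, se = self.lambda_at(x), self.se_lambda_at(x)
        return est - z * se, est + z * se


def _check_valid(cohort: Cohort, need_rwd: bool):
    rep = validate_cohort(cohort)
    if not rep.ok:
        raise ValueError(f"cohort failed validation: {rep}")
    if need_rwd and not (cohort.s == 0).any():
        raise ValueError(
            "cohort has no real-world rows (s=0); use fit_rct_only for trial-only data"
        )


def fit_integrative(
    cohort: Cohort,
    spec: SieveSpec | None = None,
    propensity_mode=("known", 0.5),
    weights: str = "inverse-variance",
    g_floor: float = GFLOOR,
    ci_level: float = 0.95,
) -> HTEEstimate:
    """Integrative estimator of (τ, λ) from a fused RCT + RWD cohort."""
    spec = spec or SieveSpec()
    _check_valid(cohort, need_rwd=True)
    nuis = fit_nuisances(cohort, propensity_mode=propensity_mode, g_floor=g_floor)
    pr = build_pseudo_response(cohort, nuis, weights=weights)

    s = cohort.s
    basis_tau = build_basis(cohort.x, spec, "tau")
    basis_lam = build_basis(cohort.x[s == 0], spec, "lambda")
    Z_tau = basis_tau.design(cohort.x)
    Z_lam = basis_lam.design(cohort.x)
    P1 = basis_tau.penalty(spec.penalty_order)
    P0 = basis_lam.penalty(spec.penalty_order)

    (g1, g0), P1s, P0s, gcv = gcv_select(
        pr.dhat, s, Z_tau, Z_lam, pr.weight, P1, P0, grid=spec.gamma_grid
    )
    fit = penalized_wls(pr.dhat, s, Z_tau, Z_lam, pr.weight, g1, g0, P1s, P0s)
    fit.gcv = gcv
    return HTEEstimate(basis_tau, basis_lam, fit, ci_level, nuis, pr)


def _fit_single_block(
    cohort: Cohort, spec: SieveSpec, propensity_mode, weights, g_floor, ci_level, estimand
) -> HTEEstimate:
    nuis = fit_nuisances(cohort, propensity_mode=propensity_mode, g_floor=g_floor)
    pr = build_pseudo_response(cohort, nuis, weights=weights)
    basis_tau = build_basis(cohort.x, spec, "tau")
    Z_tau = basis_tau.design(cohort.x)
    P1 = basis_tau.penalty(spec.penalty_order)
    (g1, _), P1s, _, gcv = gcv_select(
        pr.dhat, cohort.s, Z_tau, None, pr.weight, P1, None, grid=spec.gamma_grid
    )
    fit = penalized_wls(pr.dhat, cohort.s, Z_tau, None, pr.weight, g1, None, P1s, None)
    fit.gcv = gcv
    return HTEEstimate(basis_tau, None, fit, ci_level, nuis, pr, estimand=estimand)


def fit_rct_only(
    cohort: Cohort,
    spec: SieveSpec | None = None,
    propensity_mode=("known", 0.5),
    weights: str = "inverse-variance",
    g_floor: float = GFLOOR,
    ci_level: float = 0.95,
) -> HTEEstimate:
    """Trial-only estimator of τ (no bias block)."""
    spec = spec or SieveSpec()
    trial = cohort.trial()
    if trial.n == 0:
        raise ValueError("no trial rows (s=1) in cohort")
    _check_valid(trial, need_rwd=False)
    return _fit_single_block(
        trial, spec, propensity_mode, weights, g_floor, ci_level, "tau"
    )


def fit_rwd_only(
    cohort: Cohort,
    spec: SieveSpec | None = None,
    weights: str = "inverse-variance",
    g_floor: float = GFLOOR,
    ci_level: float = 0.95,
) -> HTEEstimate:
    """Real-world-only comparator: the trial machinery applied to the RWD.

    The propensity is a logistic fit (treatment is not randomized in the
    RWD) and the conditional mean it recovers is τ(x) + λ(x), so the
    estimate is biased for τ whenever the RWD carries bias.
    """
    spec = spec or SieveSpec()
    rwd = cohort.rwd()
    if rwd.n == 0:
        raise ValueError("no real-world rows (s=0) in cohort")
    if len(np.unique(rwd.a)) < 2:
        raise ValueError("real-world rows contain a single treatment arm")
    relabeled = Cohort(rwd.df.assign(s=1), rwd.L)
    return _fit_single_block(
        relabeled, spec, "logistic", weights, g_floor, ci_level, "tau_plus_lambda"
    )


def predict_grid(est: HTEEstimate, X_grid: np.ndarray) -> pd.DataFrame:
    """Tabulate τ̂ (and λ̂ if present) with SEs and CIs on covariate points.

    Points outside the observed covariate hull are flagged, not refused.
    """
    X_grid = np.atleast_2d(np.asarray(X_grid, dtype=float))
    out = {f"x{j + 1}": X_grid[:, j] for j in range(X_grid.shape[1])}
    out["tau_hat"] = est.tau_at(X_grid)
    out["se_tau"] = est.se_tau_at(X_grid)
    lo, hi = est.ci_tau_at(X_grid)
    out["ci_lo"], out["ci_hi"] = lo, hi
    if est.basis_lambda is not None:
        out["lambda_hat"] = est.lambda_at(X_grid)
        out["se_lambda"] = est.se_lambda_at(X_grid)
    out["flagged_extrapolation"] = (~est.basis_tau.in_hull(X_grid)).astype(int)
    return pd.DataFrame(out)


def bootstrap_se(
    cohort: Cohort,
    X_grid: np.ndarray,
    fitter=fit_integrative,
    n_boot: int = 100,
    seed: int = 0,
    **fit_kwargs,
) -> np.ndarray:
    """Pointwise bootstrap SEs of τ̂ on a grid, resampling subjects with
    replacement within source strata (propagates nuisance estimation)."""
    rng = np.random.default_rng(seed)
    X_grid = np.atleast_2d(X_grid)
    idx1 = np.flatnonzero(cohort.s == 1)
    idx0 = np.flatnonzero(cohort.s == 0)
    ests = []
    for _ in range(n_boot):
        take = np.concatenate(
            [
                rng.choice(idx1, size=len(idx1), replace=True),
                rng.choice(idx0, size=len(idx0), replace=True) if len(idx0) else [],
            ]
        ).astype(int)
        boot = Cohort(cohort.df.iloc[take].reset_index(drop=True), cohort.L)
        est = fitter(boot, **fit_kwargs)
        ests.append(est.tau_at(X_grid))
    return np.std(np.asarray(ests), axis=0, ddof=1)
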