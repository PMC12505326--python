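"""Doubly robust pseudo-outcomes for censored treatment-effect regression.

For a trial subject the restricted outcome Y_L = Y ∧ L with indicator
Δ̃ = I(T_L ≤ C) is transformed into the AIPCW pseudo-outcome

    T̃_L = Δ̃ Y_L / G_C(Y_L-)  +  ∫_0^L B(t) G_C(t-)^{-1} dM_C(t),

where B(t) = E(T_L | T_L > t, X, A) is the residual restricted life,
M_C = N_C − ∫ I(Y_L ≥ u) dΛ_C is the censoring martingale, and all
censoring-survival evaluations are left-continuous and floored.  Expanding
the martingale, the implementation computes

    T̃_L = Δ̃ Y_L / G_C(Y_L-) + (1−Δ̃) B(Y_L) / G_C(Y_L-)
           − Σ_{t_k ≤ Y_L, t_k < L} B(t_k) ΔΛ_C(t_k | x, a) / G_C(t_k-),

an exact finite sum over the Breslow jump times of the fitted censoring
model (for smooth known censoring models the sum becomes an integral,
evaluated by composite trapezoid on a dense grid).  The sign of the
augmentation matters: a censored subject is *imputed* its conditional
residual life (+B), and the compensator sum is subtracted.  This is the
orientation under which the transform is doubly robust — exactly unbiased
for any censoring model when B comes from the true failure law, and
mean-zero-augmented when the censoring model is true regardless of B.
The opposite orientation preserves the mean only under a correct
censoring model and loses the double robustness.

T̃_L has the same conditional mean as T_L whenever either the failure-time
model or the censoring model is correct.  The AIPW pseudo-ITE R̃ then has
conditional mean τ(x) on the trial; the fused response is D̂ = R̃ for trial
subjects and Y_L for real-world subjects, with conditional mean
τ(x) + (1−S) λ(x).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .cohort import Cohort, RestrictedOutcome, SubjectRecord, restrict_outcome_arrays
from .nuisance import NuisanceSet, estimate_variance_function
from .survival import CoxConditionalSurvival, FloorCounter, KnownConditionalSurvival

__all__ = [
    "PseudoResponse",
    "residual_restricted_life",
    "aipcw_transform",
    "pseudo_ite",
    "build_pseudo_response",
]

_BATCH = 1024
_SMOOTH_GRID = 513


def residual_restricted_life(g_t, t, x, a, L, floor=None, counter=None) -> float:
    """B(t) = E(T_L | T_L > t, x, a) = t + ∫_t^L G_T(u|x,a) du / G_T(t-|x,a)."""
    from .survival import GFLOOR

    return g_t.residual_restricted_life(
        t, x, a, L, floor=GFLOOR if floor is None else floor, counter=counter
    )


def _tilde_arrays(y_L, delta_tilde, X, a: int, g_t, g_c, L, g_floor, counter):
    """Vectorized AIPCW transform for all subjects in one treatment arm."""
    n = len(y_L)
    t_tilde = np.empty(n)

    # G_C(Y_L- | x), floored
    gc_at_y = np.empty(n)
    for lo in range(0, n, _BATCH):
        sl = slice(lo, min(lo + _BATCH, n))
        idx = np.arange(sl.stop - sl.start)
        S = g_c.survival_before_times(y_L[sl], X[sl], a)
        gc_at_y[sl] = S[idx, idx]
    _apply_floor(gc_at_y, g_floor, counter)

    # leading terms: observed outcome, or imputed residual life if censored
    b_at_y = _b_values(g_t, y_L, X, a, L, g_floor, counter)
    lead = np.where(delta_tilde == 1, y_L / gc_at_y, b_at_y / gc_at_y)

    # martingale correction
    if isinstance(g_c, CoxConditionalSurvival):
        corr = _correction_step(y_L, X, a, g_t, g_c, L, g_floor, counter)
    elif isinstance(g_c, KnownConditionalSurvival):
        corr = _correction_smooth(y_L, X, a, g_t, g_c, L, g_floor, counter)
    else:
        raise TypeError(f"unsupported censoring model type {type(g_c)!r}")

    t_tilde[:] = lead - corr
    return t_tilde


def _b_values(g_t, times, X, a, L, g_floor, counter):
    """B(t_i | x_i, a) evaluated pairwise (one time per subject)."""
    n = len(times)
    out = np.empty(n)
    for lo in range(0, n, _BATCH):
        sl = slice(lo, min(lo + _BATCH, n))
        idx = np.arange(sl.stop - sl.start)
        tail = g_t.integral_tail(times[sl], X[sl], a, L)[idx, idx]
        st = g_t.survival_before_times(times[sl], X[sl], a)[idx, idx].copy()
        _apply_floor(st, g_floor, counter)
        out[sl] = times[sl] + tail / st
    return np.minimum(out, L)


def _correction_step(y_L, X, a, g_t, g_c, L, g_floor, counter):
    """Σ_{t_k ≤ Y_L, t_k < L} B(t_k|x) ΔΛ_C(t_k|x) / G_C(t_k-|x)."""
    tk = g_c.jump_times(a)
    dl0 = g_c.cumhaz_increments(a)
    inside = tk < L
    tk, dl0 = tk[inside], dl0[inside]
    n = len(y_L)
    out = np.zeros(n)
    if len(tk) == 0:
        return out
    for lo in range(0, n, _BATCH):
        sl = slice(lo, min(lo + _BATCH, n))
        Xb = X[sl]
        gc_tk = g_c.survival_before_times(tk, Xb, a)  # (K, b)
        _apply_floor(gc_tk, g_floor, counter)
        gt_tk = g_t.survival_before_times(tk, Xb, a)
        _apply_floor(gt_tk, g_floor, counter)
        tail = g_t.integral_tail(tk, Xb, a, L)
        B = np.minimum(tk[:, None] + tail / gt_tk, L)
        dlam = np.outer(dl0, g_c.risk_score(Xb, a))
        mask = tk[:, None] <= y_L[sl][None, :]
        out[sl] = (B * dlam / gc_tk * mask).sum(axis=0)
    return out


def _correction_smooth(y_L, X, a, g_t, g_c, L, g_floor, counter):
    """∫_0^{Y_L} B(t|x) λ_C(t|x) / G_C(t|x) dt on a dense grid."""
    grid = np.linspace(0.0, L, _SMOOTH_GRID)
    h = grid[1] - grid[0]
    n = len(y_L)
    out = np.zeros(n)
    for lo in range(0, n, _BATCH):
        sl = slice(lo, min(lo + _BATCH, n))
        Xb = X[sl]
        gc = g_c.survival_before_times(grid, Xb, a)
        _apply_floor(gc, g_floor, counter)
        lam = g_c.hazard_grid(grid, Xb, a)
        gt = g_t.survival_before_times(grid, Xb, a)
        _apply_floor(gt, g_floor, counter)
        tail = g_t.integral_tail(grid, Xb, a, L)
        B = np.minimum(grid[:, None] + tail / gt, L)
        integrand = B * lam / gc  # (G, b)
        seg = 0.5 * (integrand[:-1] + integrand[1:]) * h
        cum = np.vstack([np.zeros((1, Xb.shape[0])), np.cumsum(seg, axis=0)])
        yb = np.clip(y_L[sl], 0.0, L)
        j = np.clip(np.searchsorted(grid, yb, side="right") - 1, 0, len(grid) - 2)
        idx = np.arange(len(yb))
        frac = (yb - grid[j]) / h
        out[sl] = cum[j, idx] + seg[j, idx] * frac
    return out


def _apply_floor(arr, floor, counter):
    below = arr < floor
    if counter is not None:
        counter.add(below.sum())
    np.copyto(arr, floor, where=below)


def aipcw_transform(
    record: SubjectRecord,
    ro: RestrictedOutcome,
    g_t,
    g_c,
    L: float,
    g_floor: float = None,
    counter: FloorCounter | None = None,
) -> float:
    """AIPCW pseudo-outcome T̃_L for one subject (scalar convenience)."""
    from .survival import GFLOOR

    g_floor = GFLOOR if g_floor is None else g_floor
    X = np.atleast_2d(np.asarray(record.x, dtype=float))
    out = _tilde_arrays(
        np.array([ro.y_L]),
        np.array([ro.delta_tilde]),
        X,
        record.a,
        g_t,
        g_c,
        L,
        g_floor,
        counter,
    )
    return float(out[0])


def pseudo_ite(a, t_tilde, e, mu0, mu1):
    """AIPW pseudo-ITE R̃ = R̃_1 − R̃_0 with

    R̃_1 = A T̃_L / e − (A − e)/e · μ_1,
    R̃_0 = (1−A) T̃_L / (1−e) + (A − e)/(1−e) · μ_0.

    Accepts scalars or aligned arrays; requires 0 < e < 1.
    """
    a = np.asarray(a, dtype=float)
    e = np.asarray(e, dtype=float)
    if np.any(e <= 0) or np.any(e >= 1):
        raise ValueError("propensity values must lie strictly in (0, 1)")
    r1 = a * t_tilde / e - (a - e) / e * mu1
    r0 = (1.0 - a) * t_tilde / (1.0 - e) + (a - e) / (1.0 - e) * mu0
    out = r1 - r0
    return float(out) if out.ndim == 0 else out


@dataclass
class PseudoResponse:
    """Per-subject pseudo-responses aligned with the cohort rows.

    ``t_tilde`` and ``r_tilde`` are NaN for real-world rows (they are
    trial-only constructions); ``dhat`` is R̃ on the trial and Y_L on the
    real-world source; ``weight`` is the inverse estimated conditional
    variance of D̂ within the source stratum.
    """

    y_L: np.ndarray
    delta_tilde: np.ndarray
    t_tilde: np.ndarray
    r_tilde: np.ndarray
    dhat: np.ndarray
    sigma2: np.ndarray
    weight: np.ndarray

    def to_frame(self):
        import pandas as pd

        return pd.DataFrame(
            {
                "y_L": self.y_L,
                "delta_tilde": self.delta_tilde,
                "t_tilde": self.t_tilde,
                "r_tilde": self.r_tilde,
                "dhat": self.dhat,
                "sigma2": self.sigma2,
                "weight": self.weight,
            }
        )


def build_pseudo_response(
    cohort: Cohort,
    nuis: NuisanceSet,
    weights: str = "inverse-variance",
) -> PseudoResponse:
    """Construct the fused pseudo-response D̂ and its weights for a cohort.

    Trial rows get the AIPCW/AIPW pseudo-ITE; real-world rows get Y_L.
    With ``weights="inverse-variance"`` (default) the conditional variance
    of D̂ is estimated by kernel regression within each source stratum from
    the first-pass D̂ values; ``weights="unit"`` skips that step.
    """
    y_L, delta_tilde = cohort.restricted()
    s = cohort.s
    a = cohort.a
    X = cohort.x
    n = cohort.n

    t_tilde = np.full(n, np.nan)
    r_tilde = np.full(n, np.nan)
    trial = s == 1
    if trial.any():
        for arm in (0, 1):
            m = trial & (a == arm)
            if not m.any():
                continue
            t_tilde[m] = _tilde_arrays(
                y_L[m],
                delta_tilde[m],
                X[m],
                arm,
                nuis.g_t,
                nuis.g_c,
                nuis.L,
                nuis.g_floor,
                nuis.floor_counter,
            )
        e = nuis.propensity(X[trial])
        mu0 = nuis.mu(X[trial], 0)
        mu1 = nuis.mu(X[trial], 1)
        r_tilde[trial] = pseudo_ite(a[trial], t_tilde[trial], e, mu0, mu1)

    dhat = np.where(trial, r_tilde, y_L)

    sigma2 = np.ones(n)
    if weights == "inverse-variance":
        for stratum in (0, 1):
            m = s == stratum
            if m.any():
                var_fn = estimate_variance_function(X[m], dhat[m])
                nuis.var_s[stratum] = var_fn
                sigma2[m] = var_fn(X[m])
    elif weights != "unit":
        raise ValueError("weights must be 'inverse-variance' or 'unit'")

    weight = 1.0 / sigma2
    if not np.all(np.isfinite(dhat)):
        raise ValueError("non-finite pseudo-responses produced")
    return PseudoResponse(y_L, delta_tilde, t_tilde, r_tilde, dhat, sigma2, weight)
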