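"""Penalized tensor B-spline sieve regression.

The treatment-effect surface τ(x) and the bias surface λ(x) are expanded in
tensor-product B-spline bases; coefficients minimize the inverse-variance
weighted least-squares loss

    (2n)^{-1} Σ_i w_i { D̂_i − τ(X_i) − (1 − S_i) λ(X_i) }²
        + γ₁/2 · J₁(τ, τ) + γ₀/2 · J₀(λ, λ),

where J₁ and J₀ are order-m thin-plate roughness functionals (integrated
squared m-th partial derivatives over the standardized covariate box) and
(γ₁, γ₀) are selected jointly by generalized cross-validation on a log
grid, ties broken toward heavier smoothing.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import product as iproduct
from math import factorial

import numpy as np
from scipy.interpolate import BSpline
from scipy.linalg import cho_factor, cho_solve

__all__ = [
    "SieveSpec",
    "TensorBasis",
    "PenalizedFit",
    "build_basis",
    "roughness_penalty",
    "penalized_wls",
    "gcv_select",
]

_MAX_P = 4


@dataclass
class SieveSpec:
    """Configuration of the sieve spaces and penalties.

    ``df_tau`` / ``df_lambda`` are basis functions per covariate dimension
    (tensor-product totals are df**p); the bias surface borrows strength
    from the trial so it gets a slightly coarser basis by default.
    """

    degree: int = 3
    df_tau: int = 6
    df_lambda: int = 5
    penalty_order: int = 2
    gamma_grid: np.ndarray = field(
        default_factory=lambda: np.logspace(-6, 2, 8)
    )

    def __post_init__(self):
        order = self.degree + 1
        for name, df in (("df_tau", self.df_tau), ("df_lambda", self.df_lambda)):
            if df < max(order, self.penalty_order):
                raise ValueError(f"{name}={df} too small for degree {self.degree}")
        if self.penalty_order > max(self.degree, 1):
            raise ValueError("penalty_order must not exceed the spline degree")


class TensorBasis:
    """Tensor-product B-spline basis on standardized covariates.

    Interior knots sit at empirical quantiles of the training data; each
    dimension is standardized to zero mean and unit variance first.  The
    basis extrapolates polynomially outside the training range (callers
    flag such points rather than refusing them).
    """

    def __init__(self, x_data: np.ndarray, df: int, degree: int = 3):
        X = np.atleast_2d(np.asarray(x_data, dtype=float))
        n, p = X.shape
        if p > _MAX_P:
            raise ValueError(f"covariate dimension {p} > {_MAX_P}: tensor basis too large")
        self.p = p
        self.df = df
        self.degree = degree
        self.loc = X.mean(axis=0)
        scale = X.std(axis=0, ddof=1)
        if np.any(scale == 0):
            raise ValueError("degenerate covariate dimension (zero variance)")
        self.scale = scale
        Z = (X - self.loc) / self.scale
        order = degree + 1
        n_interior = df - order
        self.knots = []
        for d in range(p):
            zd = Z[:, d]
            lo, hi = zd.min(), zd.max()
            if n_interior > 0:
                qs = np.quantile(zd, np.linspace(0, 1, n_interior + 2)[1:-1])
            else:
                qs = np.array([])
            if len(np.unique(np.concatenate([[lo], qs, [hi]]))) != n_interior + 2:
                raise ValueError("duplicate knots: data too discrete for requested df")
            t = np.concatenate([[lo] * order, qs, [hi] * order])
            self.knots.append(t)
        self.r = df**p

    def _dim_design(self, z: np.ndarray, d: int, deriv: int = 0) -> np.ndarray:
        t = self.knots[d]
        spl = BSpline(t, np.eye(self.df), self.degree, extrapolate=True)
        if deriv:
            spl = spl.derivative(deriv)
        return spl(z)

    def design(self, X: np.ndarray) -> np.ndarray:
        """Tensor design matrix, shape (n, df**p)."""
        X = np.atleast_2d(np.asarray(X, dtype=float))
        Z = (X - self.loc) / self.scale
        mats = [self._dim_design(Z[:, d], d) for d in range(self.p)]
        out = mats[0]
        for d in range(1, self.p):
            out = np.einsum("ij,ik->ijk", out, mats[d]).reshape(X.shape[0], -1)
        return out

    def in_hull(self, X: np.ndarray) -> np.ndarray:
        """True where x lies inside the per-dimension training range."""
        X = np.atleast_2d(np.asarray(X, dtype=float))
        Z = (X - self.loc) / self.scale
        ok = np.ones(X.shape[0], dtype=bool)
        for d in range(self.p):
            t = self.knots[d]
            ok &= (Z[:, d] >= t[0]) & (Z[:, d] <= t[-1])
        return ok

    def penalty(self, m: int | None = None) -> np.ndarray:
        """Order-m thin-plate roughness matrix P with
        θ'Pθ = Σ_{|α|=m} (m!/Πα_d!) ∫ (∂^α f_θ)² dz over the knot box,
        assembled by per-span Gauss–Legendre quadrature (exact for the
        piecewise-polynomial integrands)."""
        m = self.penalty_order if m is None else m
        # per-dimension quadrature nodes/weights over each knot span
        q = self.degree + 1
        gl_x, gl_w = np.polynomial.legendre.leggauss(q)
        pts, wts = [], []
        for d in range(self.p):
            t = self.knots[d]
            spans = np.unique(t)
            nodes, weights = [], []
            for a, b in zip(spans[:-1], spans[1:]):
                nodes.append(0.5 * (b - a) * gl_x + 0.5 * (a + b))
                weights.append(0.5 * (b - a) * gl_w)
            pts.append(np.concatenate(nodes))
            wts.append(np.concatenate(weights))

        P = np.zeros((self.r, self.r))
        for alpha in _multi_indices(self.p, m):
            coef = factorial(m) / np.prod([factorial(k) for k in alpha])
            mats = [self._dim_design(pts[d], d, deriv=alpha[d]) for d in range(self.p)]
            D = mats[0]
            W = wts[0]
            for d in range(1, self.p):
                D = np.einsum("ij,kl->ikjl", D, mats[d]).reshape(
                    D.shape[0] * mats[d].shape[0], -1
                )
                W = np.outer(W, wts[d]).ravel()
            P += coef * (D * W[:, None]).T @ D
        return 0.5 * (P + P.T)

    # default used by penalty() when called without an order
    penalty_order: int = 2


def _multi_indices(p: int, m: int):
    """All multi-indices alpha >= 0 of length p with |alpha| = m."""
    return [alpha for alpha in iproduct(range(m + 1), repeat=p) if sum(alpha) == m]


def build_basis(x_data: np.ndarray, spec: SieveSpec, which: str = "tau") -> TensorBasis:
    """Fit the tensor B-spline basis for τ or λ to the covariate data."""
    if which not in ("tau", "lambda"):
        raise ValueError("which must be 'tau' or 'lambda'")
    df = spec.df_tau if which == "tau" else spec.df_lambda
    basis = TensorBasis(x_data, df, degree=spec.degree)
    basis.penalty_order = spec.penalty_order
    Z = basis.design(np.atleast_2d(np.asarray(x_data, float)))
    if np.linalg.matrix_rank(Z) < Z.shape[1]:
        raise ValueError(
            f"rank-deficient {which} design ({Z.shape[1]} columns): use fewer df"
        )
    return basis


def roughness_penalty(basis: TensorBasis, m: int | None = None) -> np.ndarray:
    return basis.penalty(m)


@dataclass
class PenalizedFit:
    """Solution of the penalized weighted least-squares problem."""

    beta: np.ndarray  # τ coefficients (r1,)
    alpha: np.ndarray | None  # λ coefficients (r0,) or None
    gamma1: float
    gamma0: float | None
    gram: np.ndarray  # A = n^{-1} Z'WZ + Γ
    meat: np.ndarray  # M = n^{-2} Σ w_i² r̂_i² z_i z_i'
    hat_trace: float
    gcv: float | None = None

    @property
    def theta(self) -> np.ndarray:
        return self.beta if self.alpha is None else np.concatenate([self.beta, self.alpha])

    def covariance(self) -> np.ndarray:
        """Sandwich covariance A^{-1} M A^{-1} of the coefficient vector."""
        Ainv = np.linalg.inv(self.gram)
        return Ainv @ self.meat @ Ainv


def _assemble(dhat, s_vec, Z_tau, Z_lambda, weights):
    dhat = np.asarray(dhat, float)
    w = np.asarray(weights, float)
    if np.any(w <= 0):
        raise ValueError("weights must be strictly positive")
    if Z_lambda is not None:
        mask = (1.0 - np.asarray(s_vec, float))[:, None]
        Z = np.hstack([Z_tau, mask * Z_lambda])
    else:
        Z = Z_tau
    return dhat, w, Z


def _solve(dhat, w, Z, Gamma, n):
    ZW = Z * w[:, None]
    G0 = (ZW.T @ Z) / n
    A = G0 + Gamma
    b = (ZW.T @ dhat) / n
    try:
        c = cho_factor(A)
    except np.linalg.LinAlgError as exc:
        raise ValueError(f"singular penalized system: {exc}") from exc
    theta = cho_solve(c, b)
    hat_trace = float(np.trace(cho_solve(c, G0)))
    return theta, A, G0, hat_trace, c


def penalized_wls(
    dhat,
    s_vec,
    Z_tau,
    Z_lambda,
    weights,
    gamma1: float,
    gamma0: float | None,
    P1: np.ndarray,
    P0: np.ndarray | None,
) -> PenalizedFit:
    """Solve (n^{-1}Z'WZ + Γ) θ = n^{-1}Z'W D̂ with Γ = diag(γ₁P₁, γ₀P₀).

    ``Z_lambda`` may be None for the single-block (trial-only) problem.
    The returned fit carries the normal-equation matrix and the empirical
    "meat" matrix for sandwich standard errors.
    """
    dhat, w, Z = _assemble(dhat, s_vec, Z_tau, Z_lambda, weights)
    n = len(dhat)
    r1 = Z_tau.shape[1]
    if Z_lambda is not None:
        r0 = Z_lambda.shape[1]
        Gamma = np.zeros((r1 + r0, r1 + r0))
        Gamma[:r1, :r1] = gamma1 * P1
        Gamma[r1:, r1:] = gamma0 * P0
    else:
        Gamma = gamma1 * P1
    theta, A, G0, hat_trace, _ = _solve(dhat, w, Z, Gamma, n)
    resid = dhat - Z @ theta
    ZWr = Z * (w * resid)[:, None]
    meat = (ZWr.T @ ZWr) / n**2
    beta = theta[:r1]
    alpha = theta[r1:] if Z_lambda is not None else None
    return PenalizedFit(
        beta=beta,
        alpha=alpha,
        gamma1=gamma1,
        gamma0=gamma0 if Z_lambda is not None else None,
        gram=A,
        meat=meat,
        hat_trace=hat_trace,
    )


def gcv_select(
    dhat,
    s_vec,
    Z_tau,
    Z_lambda,
    weights,
    P1,
    P0,
    grid=None,
    refine: bool = True,
    gamma_cap="auto",
):
    """Joint GCV selection of (γ₁, γ₀) over a 2-D log grid.

    GCV(γ) = [n^{-1} Σ w_i (D̂_i − fit_i)²] / [1 − tr(H)/n]² with
    H = Z (n^{-1}Z'WZ + Γ)^{-1} n^{-1} Z'W.  Penalty matrices are scaled to
    unit spectral norm first; after the grid pass a one-decade refinement
    around the optimum is searched.  Ties go to heavier smoothing
    (larger γ₁ + γ₀).

    ``gamma_cap`` bounds the search from above.  The default ``"auto"``
    caps each γ at 1/n, the undersmoothing regime n(γ₁ + γ₀) = O(1) in
    which the pointwise confidence intervals are asymptotically centered
    (heavier smoothing biases the estimator toward the penalty null space
    and invalidates them); pass ``None`` to search the raw grid.
    Returns ((γ₁, γ₀), P1s, P0s, gcv_value) on the scaled-penalty scale.
    """
    if grid is None:
        grid = np.logspace(-6, 2, 8)
    grid = np.asarray(grid, float)
    if grid.size == 0:
        raise ValueError("gamma grid must be nonempty")
    if gamma_cap == "auto":
        gamma_cap = 1.0 / len(np.asarray(dhat))
    if gamma_cap is not None:
        grid = np.unique(np.minimum(grid, gamma_cap))

    P1s = P1 / _specnorm(P1)
    P0s = P0 / _specnorm(P0) if P0 is not None else None
    dhat_, w, Z = _assemble(dhat, s_vec, Z_tau, Z_lambda, weights)
    n = len(dhat_)
    r1 = Z_tau.shape[1]

    def gcv_at(g1, g0):
        if Z_lambda is not None:
            Gamma = np.zeros((Z.shape[1], Z.shape[1]))
            Gamma[:r1, :r1] = g1 * P1s
            Gamma[r1:, r1:] = g0 * P0s
        else:
            Gamma = g1 * P1s
        try:
            theta, _, _, trH, _ = _solve(dhat_, w, Z, Gamma, n)
        except ValueError:
            return np.inf
        if trH >= n:
            return np.inf
        rss = np.mean(w * (dhat_ - Z @ theta) ** 2)
        return rss / (1.0 - trH / n) ** 2

    pairs = (
        [(g1, g0) for g1 in grid for g0 in grid]
        if Z_lambda is not None
        else [(g1, None) for g1 in grid]
    )
    best = _argmin_ties_smooth(pairs, gcv_at)
    if best is None:
        raise ValueError("tr(H) >= n on the whole grid: use smaller bases")

    if refine:
        g1, g0 = best[0]
        f1 = g1 * np.logspace(-0.5, 0.5, 5)
        if gamma_cap is not None:
            f1 = np.unique(np.minimum(f1, gamma_cap))
        if Z_lambda is not None:
            f0 = g0 * np.logspace(-0.5, 0.5, 5)
            if gamma_cap is not None:
                f0 = np.unique(np.minimum(f0, gamma_cap))
            pairs = [(a, b) for a in f1 for b in f0]
        else:
            pairs = [(a, None) for a in f1]
        refined = _argmin_ties_smooth(pairs, gcv_at)
        if refined is not None and refined[1] <= best[1]:
            best = refined
    (g1, g0), val = best
    return (g1, g0), P1s, P0s, val


def _specnorm(P):
    s = np.linalg.norm(P, 2)
    return s if s > 0 else 1.0


def _argmin_ties_smooth(pairs, fn):
    best_pair, best_val = None, np.inf
    for g1, g0 in pairs:
        v = fn(g1, g0)
        if not np.isfinite(v):
            continue
        tol = 1e-10 * max(1.0, abs(best_val)) if np.isfinite(best_val) else 0.0
        heavier = best_pair is not None and (g1 + (g0 or 0.0)) > (
            best_pair[0] + (best_pair[1] or 0.0)
        )
        if v < best_val - tol or (abs(v - best_val) <= tol and heavier):
            best_pair, best_val = (g1, g0), v
    if best_pair is None:
        return None
    return best_pair, best_val
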