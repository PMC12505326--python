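"""Conditional survival models for failure and censoring times.

Two implementations share one evaluation API:

* :class:`CoxConditionalSurvival` — semiparametric proportional-hazards fit
  (partial likelihood via lifelines, Breslow step baseline cumulative hazard
  recomputed here on the original covariate scale so that jump times and jump
  sizes are directly available for martingale sums);
* :class:`KnownConditionalSurvival` — wraps a user-supplied survival function
  S(t | x, a), used when the data-generating law is known (oracle checks,
  double-robustness experiments).

All survival evaluations use the left-continuous convention P(· >= t), i.e.
the step function's value just before any jump at t, and are floored at
``g_floor`` wherever they enter a denominator.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "GFLOOR",
    "FloorCounter",
    "CoxConditionalSurvival",
    "KnownConditionalSurvival",
    "predict_survival",
]

#: default positivity floor for estimated survival probabilities in denominators
GFLOOR = 0.05

#: grid size used to tabulate smooth (known-function) models on [0, L]
_SMOOTH_GRID = 2049


@dataclass
class FloorCounter:
    """Counts how often a survival evaluation had to be floored."""

    count: int = 0

    def add(self, k: int) -> None:
        self.count += int(k)


def _floor_inplace(values: np.ndarray, floor: float, counter: FloorCounter | None):
    if floor > 0:
        below = values < floor
        if counter is not None:
            counter.add(below.sum())
        np.copyto(values, floor, where=below)
    return values


class _BaseSurvival:
    """Shared scalar-call conveniences over the vectorized API."""

    kind: str = "base"

    def survival(self, t, x, a, floor: float = 0.0, counter=None) -> float:
        """P(· >= t | x, a), left-continuous, optionally floored."""
        X = np.atleast_2d(np.asarray(x, dtype=float))
        out = self.survival_before_times(np.atleast_1d(float(t)), X, int(a))
        return float(_floor_inplace(out, floor, counter)[0, 0])

    def restricted_mean(self, x, a, L: float) -> float:
        """mu_a(x) = integral of S(t | x, a) over [0, L]."""
        X = np.atleast_2d(np.asarray(x, dtype=float))
        return float(self.restricted_mean_vec(X, int(a), L)[0])

    def residual_restricted_life(
        self, t, x, a, L: float, floor: float = GFLOOR, counter=None
    ) -> float:
        """B(t) = E(T_L | T_L > t, x, a) = t + int_t^L S(u) du / S(t)."""
        if not (0.0 <= t <= L):
            raise ValueError(f"t must lie in [0, L], got {t}")
        X = np.atleast_2d(np.asarray(x, dtype=float))
        tail = self.integral_tail(np.atleast_1d(float(t)), X, int(a), L)[0, 0]
        st = self.survival_before_times(np.atleast_1d(float(t)), X, int(a))
        st = _floor_inplace(st, floor, counter)[0, 0]
        return float(t + tail / st)

    # subclasses: survival_before_times, integral_tail, restricted_mean_vec


class CoxConditionalSurvival(_BaseSurvival):
    """Proportional-hazards conditional survival with Breslow step baseline.

    ``strata_key`` is ``"a"`` (separate baseline and coefficients per arm,
    the default) or ``"pooled"`` (one fit with treatment as a covariate).
    For each stratum the model stores the coefficient vector, the event-time
    jump grid and the Breslow baseline cumulative-hazard increments.
    Survival is evaluated by the product-limit convention,
    S(t- | x, a) = prod_{t_k < t} {1 - dLambda0(t_k) exp(x' beta)},
    which reduces to Kaplan-Meier at x'beta = 0 and makes the martingale
    identity behind the AIPCW transform exact on discrete censoring laws
    (exp(-Lambda) only matches it to first order in the jump sizes).
    """

    kind = "proportional-hazards"

    def __init__(self, strata_key: str = "a"):
        if strata_key not in ("a", "pooled"):
            raise ValueError("strata_key must be 'a' or 'pooled'")
        self.strata_key = strata_key
        # stratum -> dict(beta, times, dlambda0)
        self._strata: dict = {}

    def set_stratum(self, key, beta: np.ndarray, times: np.ndarray, dlambda0: np.ndarray):
        times = np.asarray(times, dtype=float)
        dlambda0 = np.asarray(dlambda0, dtype=float)
        order = np.argsort(times)
        self._strata[key] = {
            "beta": np.asarray(beta, dtype=float),
            "times": times[order],
            "dlambda0": dlambda0[order],
        }

    def _stratum(self, a: int) -> dict:
        key = "pooled" if self.strata_key == "pooled" else int(a)
        if key not in self._strata:
            raise ValueError(f"no fitted stratum for treatment arm {a}")
        return self._strata[key]

    def _risk(self, X: np.ndarray, a: int, st: dict) -> np.ndarray:
        beta = st["beta"]
        if self.strata_key == "pooled":
            # pooled fits carry the treatment coefficient last
            lp = X @ beta[:-1] + a * beta[-1]
        else:
            lp = X @ beta
        return np.exp(lp)

    def jump_times(self, a: int) -> np.ndarray:
        return self._stratum(a)["times"]

    def cumhaz_increments(self, a: int) -> np.ndarray:
        """Breslow baseline increments dLambda0 at :meth:`jump_times`."""
        return self._stratum(a)["dlambda0"]

    def risk_score(self, X: np.ndarray, a: int) -> np.ndarray:
        return self._risk(np.atleast_2d(X), a, self._stratum(a))

    def _cumlog_surv(self, dlambda0: np.ndarray, risk: np.ndarray) -> np.ndarray:
        """Cumulative log product-limit survival per subject after each jump:
        row j holds sum_{k <= j} log(1 - dLambda0_k * risk_i); row 0 is 0."""
        frac = 1.0 - np.outer(dlambda0, risk)
        logs = np.log(np.clip(frac, 1e-300, None))
        return np.vstack([np.zeros((1, len(risk))), np.cumsum(logs, axis=0)])

    def survival_before_times(self, times: np.ndarray, X: np.ndarray, a: int) -> np.ndarray:
        """S(t- | x, a) on a grid: shape (len(times), n_subjects)."""
        st = self._stratum(a)
        times = np.asarray(times, dtype=float)
        risk = self._risk(np.atleast_2d(X), a, st)
        cum = self._cumlog_surv(st["dlambda0"], risk)
        # left-continuous: only jumps strictly before t count
        idx = np.searchsorted(st["times"], times, side="left")
        return np.exp(cum[idx])

    def _segments(self, a: int, L: float, X: np.ndarray):
        """Breakpoints 0 = s_0 < s_1 < ... < s_m < L, segment survival values
        (constant on [s_j, s_{j+1})) per subject, and segment lengths."""
        st = self._stratum(a)
        inside = st["times"] < L
        s = np.concatenate([[0.0], st["times"][inside]])
        risk = self._risk(np.atleast_2d(X), a, st)
        cum = self._cumlog_surv(st["dlambda0"][inside], risk)
        seg_surv = np.exp(cum)  # (m+1, n)
        lengths = np.diff(np.concatenate([s, [L]]))
        return s, seg_surv, lengths

    def restricted_mean_vec(self, X: np.ndarray, a: int, L: float) -> np.ndarray:
        """Exact step-sum of int_0^L S(u | x, a) du, shape (n_subjects,)."""
        _, seg_surv, lengths = self._segments(a, L, X)
        return lengths @ seg_surv

    def integral_tail(self, times: np.ndarray, X: np.ndarray, a: int, L: float) -> np.ndarray:
        """int_t^L S(u | x, a) du for each t in ``times``: shape (len(times), n)."""
        times = np.asarray(times, dtype=float)
        s, seg_surv, lengths = self._segments(a, L, X)
        contrib = seg_surv * lengths[:, None]
        # tail[j] = integral from s_j to L
        tail = np.flip(np.cumsum(np.flip(contrib, axis=0), axis=0), axis=0)
        tail = np.vstack([tail, np.zeros_like(tail[:1])])
        j = np.clip(np.searchsorted(s, times, side="right") - 1, 0, len(s) - 1)
        out = tail[j] - seg_surv[j] * (np.clip(times, None, L) - s[j])[:, None]
        return np.clip(out, 0.0, None)

    def to_dict(self) -> dict:
        return {
            "kind": self.kind,
            "strata_key": self.strata_key,
            "strata": {
                str(k): {
                    "beta": v["beta"].tolist(),
                    "times": v["times"].tolist(),
                    "dlambda0": v["dlambda0"].tolist(),
                }
                for k, v in self._strata.items()
            },
        }

    @classmethod
    def from_dict(cls, d: dict) -> "CoxConditionalSurvival":
        m = cls(strata_key=d["strata_key"])
        for k, v in d["strata"].items():
            key = k if k == "pooled" else int(k)
            m.set_stratum(key, np.array(v["beta"]), np.array(v["times"]), np.array(v["dlambda0"]))
        return m


class KnownConditionalSurvival(_BaseSurvival):
    """Wraps a known conditional survival function S(t | x, a).

    ``surv`` is a callable ``surv(t, X, a)`` accepting a scalar or 1-D array
    of times and an (n, p) covariate matrix, returning survival probabilities
    broadcast to shape (len(t), n).  An optional ``hazard`` callable with the
    same signature supplies the hazard rate; otherwise the hazard is obtained
    numerically from -d log S / dt on a dense grid.
    """

    kind = "known-function"

    def __init__(self, surv, hazard=None):
        self._surv = surv
        self._hazard = hazard

    def survival_before_times(self, times: np.ndarray, X: np.ndarray, a: int) -> np.ndarray:
        times = np.atleast_1d(np.asarray(times, dtype=float))
        X = np.atleast_2d(X)
        out = np.asarray(self._surv(times, X, a), dtype=float)
        return np.broadcast_to(out, (len(times), X.shape[0])).copy()

    def restricted_mean_vec(self, X: np.ndarray, a: int, L: float) -> np.ndarray:
        X = np.atleast_2d(X)
        return self.integral_tail(np.zeros(1), X, a, L)[0]

    def restricted_mean(self, x, a, L: float) -> float:
        from scipy.integrate import quad

        X = np.atleast_2d(np.asarray(x, dtype=float))

        def f(t):
            return float(self.survival_before_times(np.atleast_1d(t), X, a)[0, 0])

        return quad(f, 0.0, L, limit=200)[0]

    def integral_tail(self, times: np.ndarray, X: np.ndarray, a: int, L: float) -> np.ndarray:
        """Tail integrals by composite trapezoid on a dense grid."""
        times = np.atleast_1d(np.asarray(times, dtype=float))
        X = np.atleast_2d(X)
        grid = np.linspace(0.0, L, _SMOOTH_GRID)
        S = self.survival_before_times(grid, X, a)  # (G, n)
        h = grid[1] - grid[0]
        mid = 0.5 * (S[:-1] + S[1:]) * h
        tail = np.vstack([np.flip(np.cumsum(np.flip(mid, axis=0), axis=0), axis=0), np.zeros((1, X.shape[0]))])
        # linear interpolation of the tail integral at the requested times
        tt = np.clip(times, 0.0, L)
        j = np.clip(np.searchsorted(grid, tt, side="right") - 1, 0, len(grid) - 2)
        frac = (tt - grid[j]) / h
        out = tail[j] - mid[j] * frac[:, None]
        return np.clip(out, 0.0, None)

    def hazard_grid(self, grid: np.ndarray, X: np.ndarray, a: int) -> np.ndarray:
        """Hazard rate on a grid (analytic if supplied, else numeric)."""
        X = np.atleast_2d(X)
        if self._hazard is not None:
            out = np.asarray(self._hazard(grid, X, a), dtype=float)
            return np.broadcast_to(out, (len(grid), X.shape[0])).copy()
        S = np.clip(self.survival_before_times(grid, X, a), 1e-12, None)
        logS = np.log(S)
        lam = -np.gradient(logS, grid, axis=0)
        return np.clip(lam, 0.0, None)


def predict_survival(model, t, x, a, floor: float = GFLOOR, counter=None) -> float:
    """P(· >= t | x, a) under ``model`` (left-continuous, floored)."""
    if t < 0:
        raise ValueError(f"t must be >= 0, got {t}")
    return model.survival(t, x, a, floor=floor, counter=counter)
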