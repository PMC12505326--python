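"""Nuisance-function estimation.

The fused estimator needs, on the trial arm (and, for the RWD-only
comparator, on the real-world arm treated as if it were a trial):

* the treatment propensity e(x) = P(A=1 | X=x) — known constant in a
  randomized trial, logistic otherwise;
* conditional survival of the failure time, G_T(t | x, a), and of the
  censoring time, G_C(t | x, a) — Cox proportional-hazards fits with a
  Breslow step baseline, fitted per treatment arm by default;
* the restricted arm means mu_a(x) = int_0^L G_T(t | x, a) dt;
* conditional variance functions sigma^2_s(x) of the fused pseudo-response
  within each source stratum — local-constant (Nadaraya-Watson) kernel
  regression with a product Gaussian kernel whose bandwidth is twice the
  GCV-optimal bandwidth.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field

import numpy as np

from .cohort import Cohort
from .survival import GFLOOR, CoxConditionalSurvival, FloorCounter

__all__ = [
    "NuisanceSet",
    "fit_conditional_survival",
    "estimate_propensity",
    "estimate_mu",
    "estimate_variance_function",
    "fit_nuisances",
    "save_nuisances",
    "load_nuisances",
]

_PROPENSITY_CLIP = (0.01, 0.99)
_VAR_FLOOR_FRAC = 1e-3
_MIN_STRATUM = 20


def fit_conditional_survival(
    cohort: Cohort,
    target: str = "failure",
    source: int = 1,
    strata_key: str = "a",
) -> CoxConditionalSurvival:
    """Fit a proportional-hazards conditional survival model.

    ``target`` selects the modelled time: ``"failure"`` uses the event
    indicator delta, ``"censoring"`` uses 1 - delta (censoring treated as
    the event, with the tie convention reversed so censorings at a failure
    time are still at risk).  ``source`` restricts to s == source.
    ``strata_key="a"`` fits separate baselines and coefficients per arm;
    ``"pooled"`` fits once with treatment as a covariate.

    The censoring model is fitted on the L-restricted time scale: follow-up
    is truncated at L and only censorings strictly before L count as
    events.  G_C is only ever evaluated on [0, L), and administrative
    study-end censoring beyond L would otherwise contaminate the
    proportional-hazards fit with a point mass carrying no covariate
    signal.
    """
    if target not in ("failure", "censoring"):
        raise ValueError("target must be 'failure' or 'censoring'")
    sub = cohort.subset(cohort.s == source)
    if target == "failure":
        y = sub.y
        event = sub.delta
    else:
        y = np.minimum(sub.y, cohort.L)
        event = ((sub.delta == 0) & (sub.y < cohort.L)).astype(int)
    X = sub.x
    a = sub.a

    model = CoxConditionalSurvival(strata_key=strata_key)
    if strata_key == "a":
        for arm in (0, 1):
            m = a == arm
            if not m.any():
                raise ValueError(f"no subjects in arm a={arm} of source s={source}")
            beta, times, dl0 = _fit_cox_stratum(y[m], event[m], X[m], target)
            model.set_stratum(arm, beta, times, dl0)
    else:
        Xa = np.column_stack([X, a])
        beta, times, dl0 = _fit_cox_stratum(y, event, Xa, target)
        model.set_stratum("pooled", beta, times, dl0)
    return model


def _fit_cox_stratum(y, event, X, target):
    """Partial-likelihood coefficients via lifelines, then the Breslow
    baseline cumulative-hazard increments on the original covariate scale."""
    import pandas as pd
    from lifelines import CoxPHFitter
    from lifelines.exceptions import ConvergenceError

    if event.sum() == 0:
        raise ValueError(f"no {target} events in the requested subset")
    df = pd.DataFrame(X, columns=[f"x{j + 1}" for j in range(X.shape[1])])
    df["y"] = y
    df["event"] = event
    cph = CoxPHFitter()
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            cph.fit(df, duration_col="y", event_col="event")
    except ConvergenceError as exc:
        raise ValueError(
            f"proportional-hazards fit for the {target} model did not converge: {exc}"
        ) from exc
    beta = cph.params_.to_numpy()

    risk = np.exp(X @ beta)
    order = np.argsort(y, kind="stable")
    ys, es, rs = y[order], event[order], risk[order]
    # risk set {y_j >= t}: cumulative risk from the right
    at_risk = np.cumsum(rs[::-1])[::-1]
    times, dl0 = [], []
    i = 0
    n = len(ys)
    while i < n:
        j = i
        d = 0.0
        while j < n and ys[j] == ys[i]:
            d += es[j]
            j += 1
        if d > 0:
            times.append(ys[i])
            dl0.append(d / at_risk[i])
        i = j
    return beta, np.array(times), np.array(dl0)


def estimate_propensity(cohort: Cohort, mode="logistic", source: int = 1):
    """Return the propensity function x -> P(A=1 | X=x, S=source).

    ``mode`` is ``("known", c0)`` / ``"known:c0"`` for a known constant
    (the randomized-trial case) or ``"logistic"`` for a binomial GLM fit on
    the selected source.  Logistic fitted values are clipped to [0.01, 0.99].
    """
    if isinstance(mode, tuple) and mode[0] == "known":
        c0 = float(mode[1])
    elif isinstance(mode, str) and mode.startswith("known"):
        c0 = float(mode.split(":")[1]) if ":" in mode else 0.5
    elif mode == "logistic":
        c0 = None
    else:
        raise ValueError(f"unknown propensity mode {mode!r}")

    if c0 is not None:
        if not 0 < c0 < 1:
            raise ValueError("known propensity must lie in (0, 1)")

        def e_known(X):
            X = np.atleast_2d(X)
            return np.full(X.shape[0], c0)

        e_known.params = {"mode": "known", "value": c0}
        return e_known

    import statsmodels.api as sm

    sub = cohort.subset(cohort.s == source)
    a = sub.a
    if a.min() == a.max():
        raise ValueError("logistic propensity needs both treatment arms present")
    exog = sm.add_constant(sub.x)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        res = sm.GLM(a, exog, family=sm.families.Binomial()).fit()
    coefs = np.asarray(res.params)
    fitted = res.predict(exog)
    lo, hi = _PROPENSITY_CLIP
    if (fitted < lo).any() or (fitted > hi).any():
        warnings.warn(
            "fitted propensities outside [%.2f, %.2f] were clipped" % (lo, hi),
            stacklevel=2,
        )

    def e_logistic(X):
        X = np.atleast_2d(X)
        lp = coefs[0] + X @ coefs[1:]
        return np.clip(1.0 / (1.0 + np.exp(-lp)), lo, hi)

    e_logistic.params = {"mode": "logistic", "coef": coefs.tolist()}
    return e_logistic


def estimate_mu(g_t, x, a: int, L: float) -> float:
    """Restricted arm mean mu_a(x) = int_0^L G_T(t | x, a) dt."""
    if L <= 0:
        raise ValueError("L must be > 0")
    return float(np.clip(g_t.restricted_mean(x, a, L), 0.0, L))


class KernelVariance:
    """sigma^2_s(x) by local-constant kernel regression.

    Product Gaussian kernel on per-dimension standardized covariates; a
    single bandwidth multiplier of the Silverman reference is chosen by GCV
    over a log-spaced grid, then doubled.  The conditional variance is the
    same-bandwidth local-constant fit of the squared residuals, floored at
    a small fraction of the stratum sample variance so inverse-variance
    weights stay finite.
    """

    #: bandwidth selection runs on at most this many (evenly strided) points
    _GCV_SUBSET = 800

    def __init__(self, x_data: np.ndarray, dhat: np.ndarray, n_grid: int = 10):
        x_data = np.atleast_2d(np.asarray(x_data, dtype=float))
        if x_data.shape[0] < _MIN_STRATUM:
            raise ValueError(
                f"variance stratum too small ({x_data.shape[0]} < {_MIN_STRATUM})"
            )
        dhat = np.asarray(dhat, dtype=float)
        self._loc = x_data.mean(axis=0)
        scale = x_data.std(axis=0, ddof=1)
        self._scale = np.where(scale > 0, scale, 1.0)
        self._Z = (x_data - self._loc) / self._scale
        self._d = dhat
        n, p = self._Z.shape

        sub = np.unique(np.linspace(0, n - 1, min(n, self._GCV_SUBSET)).astype(int))
        Zs, ds = self._Z[sub], dhat[sub]
        m = len(sub)
        D2 = self._sqdist(Zs, Zs)
        # Silverman reference on the standardized scale (unit sd per dim)
        h_ref = (4.0 / (p + 2.0)) ** (1.0 / (p + 4.0)) * n ** (-1.0 / (p + 4.0))
        grid = h_ref * np.logspace(np.log10(0.1), np.log10(2.0), n_grid)
        best, best_gcv = None, np.inf
        for h in grid:
            K = np.exp(-0.5 * D2 / h**2)
            rowsum = K.sum(axis=1)
            fit = (K @ ds) / rowsum
            tr_h = (1.0 / rowsum).sum()
            if tr_h >= m:
                continue
            gcv = np.mean((ds - fit) ** 2) / (1.0 - tr_h / m) ** 2
            if gcv < best_gcv:
                best, best_gcv = h, gcv
        if best is None:
            best = grid[-1]
        self.bandwidth = 2.0 * best

        K = np.exp(-0.5 * self._sqdist(self._Z, self._Z) / self.bandwidth**2)
        mhat = (K @ dhat) / K.sum(axis=1)
        self._resid2 = (dhat - mhat) ** 2
        self.floor = _VAR_FLOOR_FRAC * max(np.var(dhat, ddof=1), 1e-12)

    @staticmethod
    def _sqdist(A, B):
        aa = (A**2).sum(axis=1)[:, None]
        bb = (B**2).sum(axis=1)[None, :]
        return np.maximum(aa + bb - 2.0 * (A @ B.T), 0.0)

    def __call__(self, x) -> np.ndarray:
        X = np.atleast_2d(np.asarray(x, dtype=float))
        Z = (X - self._loc) / self._scale
        K = np.exp(-0.5 * self._sqdist(Z, self._Z) / self.bandwidth**2)
        var = (K @ self._resid2) / K.sum(axis=1)
        return np.maximum(var, self.floor)


def estimate_variance_function(x_data, dhat, **kwargs) -> KernelVariance:
    """Fit sigma^2(x) within one source stratum (see :class:`KernelVariance`)."""
    return KernelVariance(x_data, dhat, **kwargs)


@dataclass
class NuisanceSet:
    """All fitted nuisance functions for one analysis."""

    propensity: object
    g_t: object
    g_c: object
    L: float
    g_floor: float = GFLOOR
    var_s: dict = field(default_factory=dict)  # stratum s -> KernelVariance
    floor_counter: FloorCounter = field(default_factory=FloorCounter)

    def mu(self, X, a: int) -> np.ndarray:
        """mu_a(x) for rows of X (evaluated in batches)."""
        X = np.atleast_2d(X)
        out = np.empty(X.shape[0])
        step = 1024
        for lo in range(0, X.shape[0], step):
            sl = slice(lo, min(lo + step, X.shape[0]))
            out[sl] = self.g_t.restricted_mean_vec(X[sl], a, self.L)
        return np.clip(out, 0.0, self.L)


def fit_nuisances(
    cohort: Cohort,
    propensity_mode=("known", 0.5),
    source: int = 1,
    strata_key: str = "a",
    g_floor: float = GFLOOR,
) -> NuisanceSet:
    """Fit propensity, G_T and G_C on one source of a cohort."""
    g_t = fit_conditional_survival(cohort, "failure", source=source, strata_key=strata_key)
    g_c = fit_conditional_survival(cohort, "censoring", source=source, strata_key=strata_key)
    e = estimate_propensity(cohort, mode=propensity_mode, source=source)
    return NuisanceSet(propensity=e, g_t=g_t, g_c=g_c, L=cohort.L, g_floor=g_floor)


def save_nuisances(nuis: NuisanceSet, path) -> None:
    """Serialize fitted Cox models and the propensity to a JSON text file."""
    doc = {
        "L": nuis.L,
        "g_floor": nuis.g_floor,
        "propensity": getattr(nuis.propensity, "params", {"mode": "unknown"}),
        "g_t": nuis.g_t.to_dict(),
        "g_c": nuis.g_c.to_dict(),
    }
    with open(path, "w") as fh:
        json.dump(doc, fh, indent=1)


def load_nuisances(path) -> NuisanceSet:
    with open(path) as fh:
        doc = json.load(fh)
    prop = doc["propensity"]
    if prop["mode"] == "known":
        c0 = prop["value"]

        def e_known(X):
            X = np.atleast_2d(X)
            return np.full(X.shape[0], c0)

        e_known.params = prop
        e = e_known
    elif prop["mode"] == "logistic":
        coefs = np.array(prop["coef"])

        def e_logistic(X):
            X = np.atleast_2d(X)
            lp = coefs[0] + X @ coefs[1:]
            return np.clip(1.0 / (1.0 + np.exp(-lp)), *_PROPENSITY_CLIP)

        e_logistic.params = prop
        e = e_logistic
    else:
        raise ValueError("cannot reconstruct propensity of unknown mode")
    return NuisanceSet(
        propensity=e,
        g_t=CoxConditionalSurvival.from_dict(doc["g_t"]),
        g_c=CoxConditionalSurvival.from_dict(doc["g_c"]),
        L=doc["L"],
        g_floor=doc["g_floor"],
    )
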