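"""Subject-level data model for fused trial + real-world cohorts.

A cohort holds one row per subject: observed time ``y``, event indicator
``delta`` (1 = failure observed), covariates ``x`` (p continuous columns),
binary treatment ``a`` and binary source ``s`` (1 = randomized trial,
0 = real-world data), together with the restriction time ``L`` that defines
the restricted mean survival time scale of the analysis.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "SubjectRecord",
    "RestrictedOutcome",
    "Cohort",
    "ValidationReport",
    "restrict_outcome",
    "validate_cohort",
    "read_cohort_csv",
    "write_cohort_csv",
]


@dataclass(frozen=True)
class SubjectRecord:
    """One subject: (y, delta, x, a, s)."""

    y: float
    delta: int
    x: tuple[float, ...]
    a: int
    s: int

    def __post_init__(self):
        if self.y < 0:
            raise ValueError(f"observed time must be >= 0, got {self.y}")
        for name in ("delta", "a", "s"):
            v = getattr(self, name)
            if v not in (0, 1):
                raise ValueError(f"{name} must be 0 or 1, got {v}")
        if not all(np.isfinite(self.x)):
            raise ValueError("covariates must be finite")


@dataclass(frozen=True)
class RestrictedOutcome:
    """Outcome after restriction at L: y_L = min(y, L) and the restricted
    event indicator (survival past L counts as an observed event at L)."""

    y_L: float
    delta_tilde: int


def restrict_outcome(y: float, delta: int, L: float) -> RestrictedOutcome:
    """Transform (y, delta) to the L-restricted scale.

    If follow-up reaches L without failure, T∧L = L is known to be <= C,
    so the restricted outcome is an observed event at L; otherwise the
    original indicator carries over.
    """
    if L <= 0:
        raise ValueError(f"restriction time L must be > 0, got {L}")
    if y < 0:
        raise ValueError(f"observed time must be >= 0, got {y}")
    if y >= L:
        return RestrictedOutcome(float(L), 1)
    return RestrictedOutcome(float(y), int(delta))


def restrict_outcome_arrays(
    y: np.ndarray, delta: np.ndarray, L: float
) -> tuple[np.ndarray, np.ndarray]:
    """Vectorized :func:`restrict_outcome`: returns (y_L, delta_tilde)."""
    if L <= 0:
        raise ValueError(f"restriction time L must be > 0, got {L}")
    y = np.asarray(y, dtype=float)
    if np.any(y < 0):
        raise ValueError("observed times must be >= 0")
    y_L = np.minimum(y, L)
    delta_tilde = np.where(y >= L, 1, np.asarray(delta, dtype=int))
    return y_L, delta_tilde


@dataclass
class Cohort:
    """Fused dataset: subject-level frame plus restriction time L.

    The frame has columns ``y``, ``delta``, ``a``, ``s`` and covariate
    columns ``x1..xp``.  Covariates are stored unscaled; basis construction
    standardizes internally.
    """

    df: pd.DataFrame
    L: float

    COLUMNS = ("y", "delta", "a", "s")

    def __post_init__(self):
        if self.L <= 0:
            raise ValueError(f"restriction time L must be > 0, got {self.L}")
        missing = [c for c in self.COLUMNS if c not in self.df.columns]
        if missing:
            raise ValueError(f"cohort frame missing columns: {missing}")
        if not self.covariate_columns:
            raise ValueError("cohort frame has no covariate columns x1..xp")
        self.df = self.df.reset_index(drop=True)

    @property
    def covariate_columns(self) -> list[str]:
        return [c for c in self.df.columns if c.startswith("x") and c[1:].isdigit()]

    @property
    def p(self) -> int:
        return len(self.covariate_columns)

    @property
    def n(self) -> int:
        return len(self.df)

    @property
    def x(self) -> np.ndarray:
        return self.df[self.covariate_columns].to_numpy(dtype=float)

    @property
    def y(self) -> np.ndarray:
        return self.df["y"].to_numpy(dtype=float)

    @property
    def delta(self) -> np.ndarray:
        return self.df["delta"].to_numpy(dtype=int)

    @property
    def a(self) -> np.ndarray:
        return self.df["a"].to_numpy(dtype=int)

    @property
    def s(self) -> np.ndarray:
        return self.df["s"].to_numpy(dtype=int)

    def restricted(self) -> tuple[np.ndarray, np.ndarray]:
        """(y_L, delta_tilde) for every subject."""
        return restrict_outcome_arrays(self.y, self.delta, self.L)

    def subset(self, mask: np.ndarray) -> "Cohort":
        return Cohort(self.df.loc[np.asarray(mask, bool)].reset_index(drop=True), self.L)

    def trial(self) -> "Cohort":
        return self.subset(self.s == 1)

    def rwd(self) -> "Cohort":
        return self.subset(self.s == 0)

    @classmethod
    def from_arrays(cls, y, delta, x, a, s, L) -> "Cohort":
        x = np.atleast_2d(np.asarray(x, dtype=float))
        if x.shape[0] != len(y):
            x = x.T
        df = pd.DataFrame({"y": y, "delta": delta, "a": a, "s": s})
        for j in range(x.shape[1]):
            df[f"x{j + 1}"] = x[:, j]
        return cls(df, L)

    @classmethod
    def from_records(cls, records: list[SubjectRecord], L: float) -> "Cohort":
        y = [r.y for r in records]
        return cls.from_arrays(
            y,
            [r.delta for r in records],
            np.array([r.x for r in records], dtype=float),
            [r.a for r in records],
            [r.s for r in records],
            L,
        )


@dataclass
class ValidationReport:
    """Violations found in a cohort; empty means clean.  This is a reporting
    operation — callers decide whether to abort."""

    issues: list[str] = field(default_factory=list)
    flagged_rows: dict[str, list[int]] = field(default_factory=dict)

    @property
    def ok(self) -> bool:
        return not self.issues

    def __str__(self) -> str:
        return "clean cohort" if self.ok else "; ".join(self.issues)


def validate_cohort(cohort: Cohort) -> ValidationReport:
    """Check a cohort for analysis-blocking problems.

    Flags: no trial subjects, a trial arm missing, non-binary codes,
    non-finite values, and zero survival times (invalid follow-up; such
    rows are conventionally removed before analysis).
    """
    rep = ValidationReport()
    df = cohort.df
    s = df["s"].to_numpy()
    a = df["a"].to_numpy()

    for col in ("delta", "a", "s"):
        bad = ~df[col].isin([0, 1]).to_numpy()
        if bad.any():
            rep.issues.append(f"non-binary values in column '{col}'")
            rep.flagged_rows[f"nonbinary_{col}"] = list(np.flatnonzero(bad))

    num = df[["y", *cohort.covariate_columns]].to_numpy(dtype=float)
    nonfinite = ~np.isfinite(num).all(axis=1)
    if nonfinite.any():
        rep.issues.append("non-finite values present")
        rep.flagged_rows["nonfinite"] = list(np.flatnonzero(nonfinite))

    zero_y = df["y"].to_numpy() == 0
    if zero_y.any():
        rep.issues.append(
            f"{int(zero_y.sum())} row(s) with survival time equal to 0 "
            "(survival time should be greater than 0)"
        )
        rep.flagged_rows["zero_time"] = list(np.flatnonzero(zero_y))

    neg_y = df["y"].to_numpy() < 0
    if neg_y.any():
        rep.issues.append("negative observed times present")
        rep.flagged_rows["negative_time"] = list(np.flatnonzero(neg_y))

    trial = s == 1
    if not trial.any():
        rep.issues.append("no trial subjects (s=1)")
    else:
        if not (a[trial] == 1).any():
            rep.issues.append("no treated subjects (a=1) in the trial")
        if not (a[trial] == 0).any():
            rep.issues.append("no control subjects (a=0) in the trial")
    return rep


_DEFAULT_MAPPING = {"y": "y", "delta": "delta", "a": "a", "s": "s"}


def read_cohort_csv(
    path,
    L: float,
    covariates: list[str] | None = None,
    column_mapping: dict[str, str] | None = None,
) -> Cohort:
    """Read a subject-level CSV with header into a :class:`Cohort`.

    ``column_mapping`` maps the canonical names (y, delta, a, s) to the
    file's column names; ``covariates`` names the covariate columns in
    order (default: x1..xp as found).  Missing values are a hard error.
    """
    raw = pd.read_csv(path)
    mapping = dict(_DEFAULT_MAPPING)
    if column_mapping:
        mapping.update(column_mapping)
    for canon, col in mapping.items():
        if col not in raw.columns:
            raise ValueError(f"required column '{col}' (for '{canon}') not in CSV")
    if covariates is None:
        covariates = [c for c in raw.columns if c.startswith("x") and c[1:].isdigit()]
        if not covariates:
            raise ValueError("no covariate columns found (expected x1..xp)")
    else:
        missing = [c for c in covariates if c not in raw.columns]
        if missing:
            raise ValueError(f"covariate column(s) {missing} not in CSV")
    used = raw[[mapping[k] for k in ("y", "delta", "a", "s")] + list(covariates)]
    if used.isna().any().any():
        bad = used.columns[used.isna().any()].tolist()
        raise ValueError(f"missing values in column(s) {bad}; not allowed")
    df = pd.DataFrame(
        {
            "y": raw[mapping["y"]].astype(float),
            "delta": raw[mapping["delta"]].astype(int),
            "a": raw[mapping["a"]].astype(int),
            "s": raw[mapping["s"]].astype(int),
        }
    )
    for j, c in enumerate(covariates):
        df[f"x{j + 1}"] = raw[c].astype(float)
    return Cohort(df, L)


def write_cohort_csv(cohort: Cohort, path) -> None:
    cohort.df.to_csv(path, index=False)
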