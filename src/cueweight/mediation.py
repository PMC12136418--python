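"""Multilevel mediation with subject-level bootstrap inference.

Tests whether a trial-level mediator M (in the study, a brain signature
score) carries the effect of a manipulated variable X (the cue-based
expectation, or the stimulus intensity) on the outcome rating Y. Two
levels: within each subject, path a (X -> M) and paths b, c' (M, X -> Y)
are estimated by OLS, optionally controlling a covariate in both stages;
across subjects, the mean paths and the mean per-subject indirect effect
ab_j = a_j * b_j are tested by resampling subjects with replacement.

Following the usual convention for trial-level mediation, X, M and Y are
z-scored across the full sample (all subjects pooled) before the
within-subject regressions, so paths are on comparable standardized
scales. The bootstrap two-sided p is the symmetric tail proportion
``min(P(theta* <= 0), P(theta* >= 0)) * 2`` capped at 1; point estimates
always come from the observed (non-resampled) sample.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = ["MediationPaths", "subject_paths", "bootstrap_mediation"]


@dataclass(frozen=True)
class PathStats:
    estimate: float
    se: float
    z: float
    p: float


@dataclass(frozen=True)
class MediationPaths:
    """Group-level path estimates with bootstrap SE/z/p."""

    a: PathStats
    b: PathStats
    ab: PathStats
    c_prime: PathStats
    n_subjects: int
    n_boot: int

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for name in ("a", "b", "ab", "c_prime"):
            s: PathStats = getattr(self, name)
            rows.append({"path": name, "estimate": s.estimate, "se": s.se,
                         "z": s.z, "p": s.p})
        df = pd.DataFrame(rows)
        df.attrs["n_subjects"] = self.n_subjects
        df.attrs["n_boot"] = self.n_boot
        return df


def _zscore_pooled(col: pd.Series) -> pd.Series:
    sd = col.std(ddof=0)
    if sd == 0:
        raise ValueError(f"column {col.name!r} is constant; cannot z-score")
    return (col - col.mean()) / sd


def _ols(y: np.ndarray, X: np.ndarray):
    coef, _, rank, _ = np.linalg.lstsq(X, y, rcond=None)
    if rank < X.shape[1]:
        return None
    return coef


def subject_paths(trials: pd.DataFrame, use_covariate: bool = True):
    """Within-subject OLS paths for one subject's (X, M, Y) trials.

    Expects columns X, M, Y (already z-scored across the pooled sample)
    and optionally covariate. Returns ``(a_j, b_j, c_prime_j)`` or None
    when the design is rank-deficient (the subject is then excluded from
    the group step). Requires >= 5 trials.
    """
    if len(trials) < 5:
        raise ValueError("need >= 5 trials per subject")
    x = trials["X"].to_numpy(float)
    m = trials["M"].to_numpy(float)
    y = trials["Y"].to_numpy(float)
    ones = np.ones_like(x)
    cov = [trials["covariate"].to_numpy(float)] \
        if use_covariate and "covariate" in trials.columns else []
    Xa = np.column_stack([ones, x, *cov])
    ca = _ols(m, Xa)
    Xb = np.column_stack([ones, m, x, *cov])
    cb = _ols(y, Xb)
    if ca is None or cb is None:
        return None
    return float(ca[1]), float(cb[1]), float(cb[2])


def bootstrap_mediation(data: pd.DataFrame, n_boot: int = 10_000,
                        rng: np.random.Generator | None = None,
                        use_covariate: bool = True,
                        standardize: bool = True) -> MediationPaths:
    """Group mediation paths with subject-resampling bootstrap.

    ``data`` is a trial table with columns subject, X, M, Y and optionally
    covariate. X, M, Y are z-scored across all trials (disable with
    ``standardize=False`` if inputs are pre-standardized); per-subject
    paths are estimated by OLS and the group means of a, b, a*b and c'
    are bootstrapped by resampling subjects with replacement.
    """
    if rng is None:
        rng = np.random.default_rng()
    if n_boot < 100:
        warnings.warn("n_boot < 100 gives unstable bootstrap p-values")
    df = data.copy()
    if standardize:
        for col in ("X", "M", "Y"):
            df[col] = _zscore_pooled(df[col].astype(float))
    paths = []
    for _, sub in df.groupby("subject"):
        p = subject_paths(sub, use_covariate=use_covariate)
        if p is not None:
            paths.append(p)
    if len(paths) < 3:
        raise ValueError("need >= 3 subjects with estimable paths")
    arr = np.asarray(paths)                       # (n, 3): a, b, c'
    ab_j = arr[:, 0] * arr[:, 1]
    observed = {
        "a": arr[:, 0].mean(), "b": arr[:, 1].mean(),
        "ab": ab_j.mean(), "c_prime": arr[:, 2].mean(),
    }
    n = len(arr)
    idx = rng.integers(0, n, size=(n_boot, n))
    boot = {
        "a": arr[:, 0][idx].mean(axis=1),
        "b": arr[:, 1][idx].mean(axis=1),
        "ab": ab_j[idx].mean(axis=1),
        "c_prime": arr[:, 2][idx].mean(axis=1),
    }
    stats = {}
    for name, est in observed.items():
        dist = boot[name]
        se = float(dist.std(ddof=1))
        p = float(min(1.0, 2.0 * min((dist <= 0).mean(), (dist >= 0).mean())))
        z = float(est / se) if se > 0 else float("nan")
        stats[name] = PathStats(float(est), se, z, p)
    return MediationPaths(stats["a"], stats["b"], stats["ab"],
                          stats["c_prime"], n, n_boot)
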