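"""Group-level nonparametric tests and screening utilities.

Wilcoxon signed-rank tests against a reference value (is the group's k
different from 1? is b different from 0?), Spearman rank correlations
across subjects (do pain and vision parameters covary?), and a
single-pass SD-based outlier screen. Small samples get exact null
distributions; larger samples use the standard approximations, and the
method actually used is recorded in the result.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from itertools import permutations

import numpy as np
from scipy import stats

__all__ = [
    "TestResult",
    "wilcoxon_vs_reference",
    "spearman_correlation",
    "sd_outlier_exclusion",
]

_EXACT_WILCOXON_MAX_N = 25
_EXACT_SPEARMAN_MAX_N = 9


@dataclass(frozen=True)
class TestResult:
    statistic: float
    p_value: float
    n_effective: int
    method: str

    def __post_init__(self) -> None:
        if not (math.isnan(self.p_value) or 0.0 <= self.p_value <= 1.0):
            raise ValueError("p-value outside [0, 1]")


def wilcoxon_vs_reference(values, reference: float = 0.0, *,
                          zero_method: str = "wilcox") -> TestResult:
    """Two-sided Wilcoxon signed-rank test of ``values`` against a constant.

    Differences of exactly zero are dropped before ranking
    (``zero_method="wilcox"``, the classical convention) or retained in
    the ranking with Pratt's method (``zero_method="pratt"``). The null
    distribution is exact for n_effective <= 25 and a normal approximation
    with continuity correction above.
    """
    d = np.asarray(values, dtype=float) - reference
    if d.size < 1:
        raise ValueError("need at least one value")
    n_eff = int(np.count_nonzero(d))
    if n_eff == 0:
        warnings.warn("all values equal the reference; p = 1")
        return TestResult(float("nan"), 1.0, 0, "degenerate")
    if zero_method == "wilcox":
        d = d[d != 0]
    has_ties = len(np.unique(np.abs(d))) < len(d) or (d == 0).any()
    exact = n_eff <= _EXACT_WILCOXON_MAX_N and not has_ties
    method = "exact" if exact else "approx"
    res = stats.wilcoxon(
        d, zero_method=zero_method, correction=not exact,
        alternative="two-sided", method=method,
    )
    return TestResult(float(res.statistic), float(res.pvalue), n_eff,
                      f"wilcoxon-{method}")


def spearman_correlation(x, y) -> TestResult:
    """Two-sided Spearman rank correlation with average-rank ties.

    The p-value is exact (full permutation enumeration of one margin) for
    n <= 9 and the usual t-approximation above. Constant input has no
    defined correlation: returns NaN statistic/p with a warning.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.size < 3:
        raise ValueError("x and y must have equal length >= 3")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        warnings.warn("constant input; Spearman correlation undefined")
        return TestResult(float("nan"), float("nan"), int(x.size), "degenerate")
    n = int(x.size)
    rho = float(stats.spearmanr(x, y).statistic)
    if n <= _EXACT_SPEARMAN_MAX_N:
        p = _exact_spearman_p(x, y, rho)
        method = "spearman-exact-permutation"
    else:
        # t-approximation with n - 2 df
        t = rho * math.sqrt((n - 2) / max(1.0 - rho**2, 1e-300))
        p = float(min(1.0, 2.0 * stats.t.sf(abs(t), n - 2)))
        method = "spearman-t-approx"
    return TestResult(rho, p, n, method)


def _exact_spearman_p(x: np.ndarray, y: np.ndarray, rho_obs: float) -> float:
    """Two-sided exact p by enumerating all permutations of one margin."""
    rx = stats.rankdata(x)
    ry = stats.rankdata(y)
    perms = np.array(list(permutations(ry)))
    xc = rx - rx.mean()
    pc = perms - perms.mean(axis=1, keepdims=True)
    denom = np.sqrt((xc @ xc) * (pc**2).sum(axis=1))
    rhos = (pc @ xc) / denom
    return float(np.mean(np.abs(rhos) >= abs(rho_obs) - 1e-12))


def sd_outlier_exclusion(scores, threshold_sd: float = 3.5):
    """Single-pass exclusion of scores far from the group mean.

    Removes scores with |score - mean| > threshold_sd * SD, with mean and
    (population) SD computed once on the full input — no re-iteration
    after removal. Zero-SD input excludes nothing.

    Returns ``(kept_values, excluded_indices)``.
    """
    s = np.asarray(scores, dtype=float)
    if s.size < 2:
        raise ValueError("need at least two scores")
    sd = s.std()
    if sd == 0:
        return s.copy(), np.array([], dtype=int)
    z = np.abs(s - s.mean()) / sd
    excluded = np.flatnonzero(z > threshold_sd)
    return np.delete(s, excluded), excluded
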