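"""Per-subject estimation of the cue-weighting parameters (k, b).

The two free parameters are estimated per participant and modality by
minimizing the sum of squared differences between observed expectation
ratings and the model expectation of each trial's cue (ordinary least
squares in the nonlinear-regression sense).

Numerics: the objective is non-convex and k spans three orders of
magnitude, so the search runs on (log k, b) from a multi-start grid
(log k in {-1, 0, 1, 2} x b in {-10, 0, 10}) plus a few random restarts,
each start refined by bounded trust-region least squares. Near the
equal-weighting observer (k = 1, b = 0) the surface is almost flat in k;
among near-equal optima (SSE within 1e-6) the solution with the smallest
|log k| + |b| is reported so output is reproducible.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.optimize import least_squares
from scipy.stats import pearsonr

from .expectation_model import B_BOUNDS, K_BOUNDS, WeightParams, expected_value

__all__ = ["FitResult", "fit_weight_params", "fit_metrics", "fit_cohort"]

_CUE_COLS = [f"cue_v{i}" for i in range(1, 11)]

_LOG_K_LO, _LOG_K_HI = np.log(1e-6), np.log(K_BOUNDS[1])
_GRID_STARTS = [(lk, b) for lk in (-1.0, 0.0, 1.0, 2.0) for b in (-10.0, 0.0, 10.0)]
_N_RANDOM_STARTS = 5
_SSE_TIE_TOL = 1e-6


@dataclass(frozen=True)
class FitResult:
    """Point estimates and fit diagnostics for one subject x modality."""

    k_hat: float
    b_hat: float
    sse: float
    r_overall: float
    rmse: float
    r_by_mean_level: dict
    n_trials: int
    converged: bool
    n_restarts_used: int
    constant_ratings: bool = False

    @property
    def params(self) -> WeightParams:
        return WeightParams(self.k_hat, self.b_hat)


def _extract(trials: pd.DataFrame):
    rated = trials.dropna(subset=["rating"])
    cues = rated[_CUE_COLS].to_numpy(float)
    if np.isnan(cues).any():
        raise ValueError("fit requires trials with complete cue values")
    return cues, rated["rating"].to_numpy(float), rated


def fit_weight_params(trials: pd.DataFrame, *, power_form: str = "absolute",
                      n_random_starts: int = _N_RANDOM_STARTS,
                      seed: int = 0) -> FitResult:
    """Fit (k, b) to one subject's rated trials of one modality.

    ``trials`` is a long-format table with cue_v1..cue_v10 and rating
    columns; requires at least 10 rated trials. ``seed`` only controls the
    random restarts; on well-conditioned data the returned optimum is
    insensitive to it.
    """
    cues, ratings, rated = _extract(trials)
    if len(ratings) < 10:
        raise ValueError(f"need >= 10 rated trials with cues, got {len(ratings)}")
    constant = bool(np.ptp(ratings) == 0)
    if constant:
        warnings.warn("all ratings identical; fit is weakly identified")

    def residuals(theta):
        return expected_value(cues, k=float(np.exp(theta[0])), b=float(theta[1]),
                              power_form=power_form) - ratings

    rng = np.random.default_rng(seed)
    starts = list(_GRID_STARTS) + [
        (rng.uniform(-2.0, 3.0), rng.uniform(-15.0, 15.0))
        for _ in range(n_random_starts)
    ]
    candidates = []
    any_converged = False
    for lk0, b0 in starts:
        res = least_squares(
            residuals, x0=[lk0, b0],
            bounds=([_LOG_K_LO, B_BOUNDS[0]], [_LOG_K_HI, B_BOUNDS[1]]),
            ftol=1e-8, xtol=1e-10, gtol=1e-10,
        )
        any_converged = any_converged or res.success
        candidates.append((2.0 * res.cost, res.x))  # cost = SSE / 2
    best_sse = min(c[0] for c in candidates)
    # among near-ties prefer the simplest observer (reproducible output)
    near = [x for sse, x in candidates if sse <= best_sse + _SSE_TIE_TOL]
    lk, b = min(near, key=lambda x: abs(x[0]) + abs(x[1]))
    k_hat = float(np.clip(np.exp(lk), np.nextafter(0, 1), K_BOUNDS[1]))
    b_hat = float(np.clip(b, *B_BOUNDS))
    params = WeightParams(k_hat, b_hat)
    r, rmse, r_lvl = fit_metrics(rated, params, power_form=power_form)
    sse = float(np.sum(residuals([np.log(k_hat), b_hat]) ** 2))
    return FitResult(k_hat, b_hat, sse, r, rmse, r_lvl, len(ratings),
                     any_converged, len(starts), constant)


def fit_metrics(trials: pd.DataFrame, params: WeightParams, *,
                power_form: str = "absolute"):
    """Predicted-vs-observed fit metrics for given parameters.

    Returns (r_overall, rmse, r_by_mean_level). The within-level
    correlations guard against the cue-mean factor inflating the overall
    correlation: each is a Pearson r restricted to one cue-mean level.
    Levels where predictions or observations are constant have no defined
    correlation and are reported as NaN.
    """
    cues, ratings, rated = _extract(trials)
    pred = np.atleast_1d(expected_value(cues, params, power_form=power_form))
    rmse = float(np.sqrt(np.mean((pred - ratings) ** 2)))
    r_overall = _safe_pearson(pred, ratings)
    r_by_level = {}
    if "cue_mean" in rated.columns and rated["cue_mean"].notna().any():
        for level, idx in rated.groupby("cue_mean").groups.items():
            loc = rated.index.get_indexer(idx)
            r_by_level[float(level)] = _safe_pearson(pred[loc], ratings[loc])
    return r_overall, rmse, r_by_level


def _safe_pearson(x: np.ndarray, y: np.ndarray) -> float:
    if len(x) < 3 or np.ptp(x) == 0 or np.ptp(y) == 0:
        return float("nan")
    return float(pearsonr(x, y).statistic)


def fit_cohort(trials: pd.DataFrame, *, power_form: str = "absolute",
               seed: int = 0) -> pd.DataFrame:
    """Fit every subject x modality in a long-format expectation table.

    Returns one row per (subject_id, modality) with k_hat, b_hat and the
    fit metrics; within-level correlations appear as r_mean_<level> columns.
    """
    rows = []
    for (sid, modality), sub in trials.groupby(["subject_id", "modality"]):
        fit = fit_weight_params(sub, power_form=power_form, seed=seed)
        row = {
            "subject_id": sid, "modality": modality,
            "k_hat": fit.k_hat, "b_hat": fit.b_hat, "sse": fit.sse,
            "r_overall": fit.r_overall, "rmse": fit.rmse,
            "n_trials": fit.n_trials, "converged": fit.converged,
        }
        for level, r in sorted(fit.r_by_mean_level.items()):
            row[f"r_mean_{level:g}"] = r
        rows.append(row)
    return pd.DataFrame(rows)
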