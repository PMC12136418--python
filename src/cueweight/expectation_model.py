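"""Cue-weighting model of expectation generation.

A "distribution cue" is a set of 10 values on a 0-100 visual analogue
scale (VAS), presented as alleged ratings of prior participants. The model
assumes the expectation reported after seeing such a cue is a weighted sum
of the 10 values, where each value's weight depends on its relative
location within the cue:

1. rescale the 10 values to [0, 1] (per-cue min-max) and demean them,
   giving ``X_i`` (negative below the cue mean, positive above);
2. a *power* weight ``Wk_i = |X_i|^(k-1)`` (sum-normalized) captures
   inlier (k < 1) versus outlier (k > 1) over-weighting;
3. a *logistic* weight ``Wb_i = 1 / (1 + exp(-b * X_i))`` captures
   over-weighting of values below (b < 0) or above (b > 0) the mean;
4. the combined, sum-normalized weight ``W_i`` multiplies the original
   (unscaled) cue value: ``Expectation = sum_i V_i * W_i``.

``k = 1`` and ``b = 0`` reduce the model to the arithmetic mean of the cue.

All weight functions accept a single cue (10 values) or a stack of cues
(n, 10) and broadcast over the stack; this vectorization is what makes
per-subject fitting over hundreds of trials cheap.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.special import expit

__all__ = [
    "WeightParams",
    "K_BOUNDS",
    "B_BOUNDS",
    "rescale_demean",
    "power_weights",
    "logistic_weights",
    "combine_weights",
    "cue_weights",
    "expected_value",
    "weight_curve",
]

#: Allowed range for the power parameter k (open at 0).
K_BOUNDS = (0.0, 1000.0)
#: Allowed range for the logistic parameter b (closed).
B_BOUNDS = (-1000.0, 1000.0)

#: Floor on |X_i| before exponentiation, so k < 1 (negative exponent)
#: never hits the singularity at a value exactly on the cue mean.
EPS_ABS_X = 1e-6


@dataclass(frozen=True)
class WeightParams:
    """The model's two free parameters, validated against their bounds."""

    k: float
    b: float

    def __post_init__(self) -> None:
        if not (K_BOUNDS[0] < self.k <= K_BOUNDS[1]):
            raise ValueError(f"k must be in (0, 1000], got {self.k}")
        if not (B_BOUNDS[0] <= self.b <= B_BOUNDS[1]):
            raise ValueError(f"b must be in [-1000, 1000], got {self.b}")


def _check_k(k: float) -> None:
    if not (K_BOUNDS[0] < k <= K_BOUNDS[1]):
        raise ValueError(f"k must be in (0, 1000], got {k}")


def _check_b(b: float) -> None:
    if not (B_BOUNDS[0] <= b <= B_BOUNDS[1]):
        raise ValueError(f"b must be in [-1000, 1000], got {b}")


def rescale_demean(values) -> np.ndarray:
    """Map cue values to their rescaled, demeaned coordinates ``X_i``.

    Per cue: min-max rescale to [0, 1], then subtract the rescaled mean,
    so values below the cue mean are negative and values above positive.
    A zero-range (constant) cue maps to all zeros.

    Parameters
    ----------
    values
        Array of shape (10,) or (n, 10) of VAS values.
    """
    v = np.asarray(values, dtype=float)
    lo = v.min(axis=-1, keepdims=True)
    span = v.max(axis=-1, keepdims=True) - lo
    with np.errstate(invalid="ignore", divide="ignore"):
        x = np.where(span > 0, (v - lo) / np.where(span > 0, span, 1.0), 0.0)
    return x - x.mean(axis=-1, keepdims=True)


def power_weights(x, k: float, *, form: str = "absolute") -> np.ndarray:
    """Power-term weights, sum-normalized over each cue.

    The default ``form="absolute"`` computes ``|X_i|^(k-1)`` (with |X_i|
    floored at :data:`EPS_ABS_X`), which gives equal weights at k = 1 and a
    strictly positive normalizer for every cue. ``form="signed"`` computes
    ``sign(X_i) * |X_i|^k`` instead; it is provided for sensitivity
    analysis only — its normalizer can be arbitrarily close to zero for
    symmetric cues and its weights can be negative.
    """
    _check_k(k)
    x = np.asarray(x, dtype=float)
    ax = np.maximum(np.abs(x), EPS_ABS_X)
    if form == "absolute":
        raw = ax ** (k - 1.0)
    elif form == "signed":
        raw = np.sign(x) * ax**k
    else:
        raise ValueError(f"unknown power form: {form!r}")
    return raw / raw.sum(axis=-1, keepdims=True)


def logistic_weights(x, b: float) -> np.ndarray:
    """Logistic weights ``1 / (1 + exp(-b * X_i))``, overflow-safe."""
    _check_b(b)
    return expit(b * np.asarray(x, dtype=float))


def combine_weights(w_power, w_logistic) -> np.ndarray:
    """Combine the two weight terms and renormalize to sum to 1 per cue."""
    raw = np.asarray(w_power, dtype=float) + np.asarray(w_logistic, dtype=float)
    return raw / raw.sum(axis=-1, keepdims=True)


def cue_weights(values, k: float, b: float, *, power_form: str = "absolute") -> np.ndarray:
    """Final weights ``W_i`` for cue values of shape (10,) or (n, 10)."""
    x = rescale_demean(values)
    return combine_weights(power_weights(x, k, form=power_form), logistic_weights(x, b))


def expected_value(values, params: WeightParams | None = None, *, k: float | None = None,
                   b: float | None = None, power_form: str = "absolute"):
    """Model expectation for one cue or a stack of cues.

    ``Expectation = sum_i V_i * W_i`` with the original VAS-scale values
    ``V_i``; the result is a convex combination, so it always lies within
    [min V, max V] of its cue.

    Accepts either a :class:`WeightParams` or explicit ``k=``/``b=``.
    Returns a scalar for a single cue, an array of length n for a stack.
    """
    if params is not None:
        k, b = params.k, params.b
    if k is None or b is None:
        raise TypeError("provide WeightParams or both k= and b=")
    v = np.asarray(values, dtype=float)
    out = (v * cue_weights(v, k, b, power_form=power_form)).sum(axis=-1)
    return float(out) if out.ndim == 0 else out


def weight_curve(values, params: WeightParams, *, grid: int = 101,
                 power_form: str = "absolute") -> pd.DataFrame:
    """Weight a hypothetical cue value would receive, across the cue range.

    Holds the cue's rescaling frame and normalizers fixed (the probe value
    does not enter the sums), so the curve shows the weight function the
    10 actual values are evaluated under. Columns: ``value``, ``weight``,
    ``equal_weight`` (the 1/10 reference line for equal weighting).
    """
    v = np.asarray(values, dtype=float)
    x = rescale_demean(v)
    ax = np.maximum(np.abs(x), EPS_ABS_X)
    if power_form == "absolute":
        raw_k = ax ** (params.k - 1.0)
    else:
        raw_k = np.sign(x) * ax**params.k
    sum_k = raw_k.sum()
    wb = expit(params.b * x)
    denom = (raw_k / sum_k + wb).sum()

    grid_v = np.linspace(v.min(), v.max(), grid)
    lo, span = v.min(), v.max() - v.min()
    gx = (grid_v - lo) / span if span > 0 else np.zeros_like(grid_v)
    gx = gx - ((v - lo) / span).mean() if span > 0 else gx
    gax = np.maximum(np.abs(gx), EPS_ABS_X)
    if power_form == "absolute":
        g_raw_k = gax ** (params.k - 1.0)
    else:
        g_raw_k = np.sign(gx) * gax**params.k
    g_w = (g_raw_k / sum_k + expit(params.b * gx)) / denom
    return pd.DataFrame(
        {"value": grid_v, "weight": g_w, "equal_weight": np.full(grid, 0.1)}
    )
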