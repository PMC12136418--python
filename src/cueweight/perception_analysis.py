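"""Cued-perception behavioral analyses.

Covers the trial-level analysis chain for the cued-perception task:
response-time exclusions, construction of the model matrix with the
study's coding conventions, linear mixed-effects fitting with a
simplification ladder for the random-effects structure, the persistence
(cue effect x trial) models, subjective stimulus values from the
calibration task, prediction-error boundary variables and their
polynomial mixed model, and the cross-modality correlation of per-subject
cue effects.

Coding conventions: binary factors (stimulus intensity, cue mean, cue
variance in the cued task) are coded -1 / +1; cue skewness is two dummy
regressors against the symmetric reference; numeric predictors and the
rating response are z-scored. Mixed models start from the maximal
random-effects structure; on convergence trouble the random correlations
are dropped first (slopes become independent variance components), then
components with boundary (near-zero) variance, down to a random intercept
only. The mixed-model engine is statsmodels' MixedLM; p-values are Wald
tests on the fixed effects (normal approximation), reported with residual
degrees of freedom — not the Satterthwaite approximation some mixed-model
software prints.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats

__all__ = [
    "ModelMatrix",
    "RT_MIN_S",
    "RT_MAX_S",
    "apply_rt_exclusions",
    "build_model_matrix",
    "fit_lmm",
    "persistence_model",
    "subjective_stimulus_values",
    "boundary_variables",
    "fit_boundary_model",
    "subject_cue_effect_correlation",
]

RT_MIN_S = 0.2   # below: too fast to be a deliberate rating
RT_MAX_S = 4.5   # above: rating not completed within the response window


# ---------------------------------------------------------------------------
# Exclusions


def apply_rt_exclusions(trials: pd.DataFrame):
    """Drop trials with implausible response times (strict inequalities).

    Keeps rt in [0.2, 4.5] s inclusive; trials with missing RT are kept
    and counted separately. Returns ``(kept, report)`` where report is a
    one-row DataFrame with counts by reason.
    """
    rt = trials["rt"]
    too_fast = rt < RT_MIN_S
    too_slow = rt > RT_MAX_S
    missing = rt.isna()
    kept = trials[~(too_fast | too_slow)].copy()
    report = pd.DataFrame([{
        "n_input": len(trials),
        "n_too_fast": int(too_fast.sum()),
        "n_too_slow": int(too_slow.sum()),
        "n_missing_rt": int(missing.sum()),
        "n_kept": len(kept),
    }])
    return kept, report


# ---------------------------------------------------------------------------
# Model matrix


@dataclass
class ModelMatrix:
    """Response, named predictor columns and subject grouping for a LMM."""

    y: pd.Series
    X: pd.DataFrame
    groups: pd.Series
    coding: dict = field(default_factory=dict)


def _zscore(col: pd.Series) -> pd.Series:
    sd = col.std(ddof=0)
    if sd == 0:
        raise ValueError(f"cannot z-score constant column {col.name!r}")
    return (col - col.mean()) / sd


def _pm1(col: pd.Series, name: str) -> pd.Series:
    levels = sorted(col.dropna().unique())
    if len(levels) != 2:
        raise ValueError(f"{name!r} has {len(levels)} levels; +-1 coding needs 2")
    return col.map({levels[0]: -1.0, levels[1]: 1.0})


_SKEW_LEVELS = ("negative", "symmetric", "positive")


def build_model_matrix(trials: pd.DataFrame, predictors: dict,
                       interactions="all", response: str = "rating") -> ModelMatrix:
    """Construct the study's coding for a trial table of one modality.

    ``predictors`` maps column names to a coding: ``"pm1"`` (-1/+1 for a
    two-level factor), ``"zscore"`` (numeric), or ``"skew"`` (two dummies
    vs. the symmetric reference, producing columns ``<name>_neg`` and
    ``<name>_pos``). ``interactions`` is ``"all"`` (all pairwise and
    higher products of the expanded columns of distinct predictors),
    ``None``, or an explicit list of tuples of predictor names. The
    response is z-scored.
    """
    cols: dict[str, pd.Series] = {}
    expanded: dict[str, list[str]] = {}
    for name, coding in predictors.items():
        if name not in trials.columns:
            raise ValueError(f"unknown predictor column {name!r}")
        col = trials[name]
        if coding == "pm1":
            cols[name] = _pm1(col, name)
            expanded[name] = [name]
        elif coding == "zscore":
            cols[name] = _zscore(col.astype(float))
            expanded[name] = [name]
        elif coding == "skew":
            bad = set(col.dropna()) - set(_SKEW_LEVELS)
            if bad:
                raise ValueError(f"unknown skewness level(s): {sorted(bad)}")
            cols[f"{name}_neg"] = (col == "negative").astype(float)
            cols[f"{name}_pos"] = (col == "positive").astype(float)
            expanded[name] = [f"{name}_neg", f"{name}_pos"]
        else:
            raise ValueError(f"unknown coding {coding!r} for {name!r}")
    X = pd.DataFrame(cols, index=trials.index)

    if interactions == "all":
        terms = _all_interactions(list(predictors))
    elif interactions is None:
        terms = []
    else:
        terms = [tuple(t) for t in interactions]
    for term in terms:
        for combo in _expand_term(term, expanded):
            label = ":".join(combo)
            X[label] = np.prod([X[c].to_numpy() for c in combo], axis=0)
    return ModelMatrix(
        y=_zscore(trials[response].astype(float)).rename(response),
        X=X,
        groups=trials["subject_id"].rename("subject_id"),
        coding=dict(predictors),
    )


def _all_interactions(names: list[str]) -> list[tuple]:
    from itertools import combinations

    out = []
    for r in range(2, len(names) + 1):
        out.extend(combinations(names, r))
    return out


def _expand_term(term: tuple, expanded: dict) -> list[tuple]:
    from itertools import product

    return [tuple(c) for c in product(*(expanded[n] for n in term))]


# ---------------------------------------------------------------------------
# Mixed models


def _result_table(result, structure: str) -> pd.DataFrame:
    fe = result.fe_params
    se = result.bse_fe
    tvals = fe / se
    df_resid = int(result.nobs - len(fe))
    pvals = 2.0 * stats.norm.sf(np.abs(tvals))
    table = pd.DataFrame({
        "beta": fe, "se": se, "t": tvals, "df": df_resid, "p": pvals,
    })
    table.attrs["random_structure"] = structure
    table.attrs["p_method"] = "wald-normal"
    return table


_OPTIMIZERS = ("lbfgs", "bfgs", "cg", "powell", "nm")


def _try_fit(endog, exog, groups, exog_re=None, exog_vc=None):
    """Fit a MixedLM, cycling optimizers; never raises.

    Returns ``(result, converged)``; result is None only if every
    optimizer failed outright. A non-converged result is kept as a
    fallback so the last ladder rung can still report best-effort
    estimates.
    """
    best = None
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        for method in _OPTIMIZERS:
            if exog_vc is not None:
                model = sm.MixedLM(endog, exog, groups=groups, exog_vc=exog_vc)
            else:
                model = sm.MixedLM(endog, exog, groups=groups, exog_re=exog_re)
            try:
                result = model.fit(reml=True, method=method)
            except Exception:
                continue
            if result.converged and np.isfinite(result.fe_params).all() \
                    and np.isfinite(result.bse_fe).all():
                return result, True
            if best is None:
                best = result
    return best, False


def _vc_spec(X_re: pd.DataFrame, groups: pd.Series, keep: list[str]):
    from statsmodels.regression.mixed_linear_model import VCSpec

    names = list(keep)
    colnames = [[c] for c in names]
    mats = []
    for c in names:
        mats.append([X_re.loc[groups == g, [c]].to_numpy()
                     for g in pd.unique(groups)])
    return VCSpec(names, colnames, mats)


def fit_lmm(matrix: ModelMatrix, random_spec="maximal") -> pd.DataFrame:
    """Linear mixed model with a random-structure simplification ladder.

    ``random_spec`` is ``"maximal"`` (random intercept plus a random slope
    for every fixed-effect column, correlated), a list of column names for
    the random slopes, or ``[]`` / ``"intercept"`` for a random intercept
    only. Ladder on convergence trouble: (1) correlated slopes; (2) the
    same slopes as independent variance components; (3) drop components
    with near-zero estimated variance; (4) intercept only. The structure
    actually used is recorded in ``table.attrs["random_structure"]``.
    """
    y = np.asarray(matrix.y, float)
    X = sm.add_constant(matrix.X, prepend=True)
    groups = matrix.groups

    if random_spec == "maximal":
        slopes = list(matrix.X.columns)
    elif random_spec in ("intercept", None) or len(random_spec) == 0:
        slopes = []
    else:
        slopes = list(random_spec)

    if slopes:
        exog_re = sm.add_constant(matrix.X[slopes], prepend=True)
        result, ok = _try_fit(y, X, groups, exog_re=exog_re)
        if ok:
            return _result_table(result, f"correlated: intercept+{slopes}")
        # ladder step 1: drop random correlations
        intercept_only = pd.DataFrame(
            {"const": np.ones(len(matrix.X))}, index=matrix.X.index)
        vc = _vc_spec(matrix.X, groups, slopes)
        result, ok = _try_fit_vc(y, X, groups, intercept_only, vc)
        if ok:
            # ladder step 2: drop boundary-variance components
            vcomp = getattr(result, "vcomp", np.array([]))
            drop = [s for s, v in zip(slopes, vcomp) if v < 1e-8]
            keep = [s for s in slopes if s not in drop]
            if drop and keep:
                result2, ok2 = _try_fit_vc(y, X, groups, intercept_only,
                                           _vc_spec(matrix.X, groups, keep))
                if ok2:
                    return _result_table(
                        result2, f"uncorrelated: intercept+{keep}")
            return _result_table(result, f"uncorrelated: intercept+{slopes}")
    # intercept only
    result, ok = _try_fit(y, X, groups, exog_re=None)
    if result is None:
        raise RuntimeError("mixed model unfittable even with intercept-only "
                           "random effects")
    return _result_table(result, "intercept-only")


def _try_fit_vc(endog, exog, groups, exog_re, vcspec):
    best = None
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        for method in _OPTIMIZERS:
            model = sm.MixedLM(endog, exog, groups=groups,
                               exog_re=exog_re, exog_vc=vcspec)
            try:
                result = model.fit(reml=True, method=method)
            except Exception:
                continue
            if result.converged and np.isfinite(result.fe_params).all() \
                    and np.isfinite(result.bse_fe).all():
                return result, True
            if best is None:
                best = result
    return best, False


# ---------------------------------------------------------------------------
# Persistence of the cue effect


def persistence_model(trials: pd.DataFrame) -> dict:
    """Does the cue-mean effect on perception persist across the task?

    For one modality's cued-perception trials, fits (a) rating ~ cue_mean
    x trial, with trial z-scored continuously across the task (not within
    block), and (b) the cue-mean effect restricted to the last block.
    Returns ``{"across_task": table, "last_block": table}``.
    """
    mm = build_model_matrix(
        trials,
        {"cue_mean": "pm1", "trial_overall": "zscore"},
        interactions=[("cue_mean", "trial_overall")],
    )
    across = fit_lmm(mm, random_spec="maximal")
    last = trials[trials["block"] == trials["block"].max()]
    mm_last = build_model_matrix(last, {"cue_mean": "pm1"}, interactions=None)
    last_tab = fit_lmm(mm_last, random_spec="maximal")
    return {"across_task": across, "last_block": last_tab}


# ---------------------------------------------------------------------------
# Boundary effects


def subjective_stimulus_values(sr_trials: pd.DataFrame) -> pd.DataFrame:
    """Mean calibration rating per (subject, modality, intensity) cell.

    The subjective stimulus value is each participant's average rating of
    stimuli with the same physical intensity in the stimulus-response
    task. Empty cells are absent from the output (a warning is raised if
    any rated trial had to be dropped for missing fields).
    """
    rated = sr_trials.dropna(subset=["rating", "stimulus_intensity"])
    if len(rated) < len(sr_trials):
        warnings.warn(f"{len(sr_trials) - len(rated)} calibration trials "
                      "without rating/intensity ignored")
    out = (rated.groupby(["subject_id", "modality", "stimulus_intensity"])
           ["rating"].mean().rename("subjective_value").reset_index())
    return out


def interpolate_subjective_values(subjective_map: pd.DataFrame,
                                  intensities: dict) -> pd.DataFrame:
    """Extend the subjective-value map to uncalibrated intensities.

    The cued task can present intensities between calibration levels
    (e.g. 60% contrast when calibration sampled 50% and 72.5%); each
    subject's map is linearly interpolated over their calibrated levels.
    ``intensities`` maps modality -> iterable of required intensities.
    """
    rows = []
    for (sid, modality), sub in subjective_map.groupby(
            ["subject_id", "modality"]):
        sub = sub.sort_values("stimulus_intensity")
        want = np.asarray(intensities.get(modality, ()), dtype=float)
        have = sub["stimulus_intensity"].to_numpy(float)
        vals = np.interp(want, have, sub["subjective_value"].to_numpy(float))
        for s, v in zip(want, vals):
            rows.append({"subject_id": sid, "modality": modality,
                         "stimulus_intensity": s, "subjective_value": v})
    extra = pd.DataFrame(rows)
    out = pd.concat([subjective_map, extra], ignore_index=True)
    return out.drop_duplicates(
        ["subject_id", "modality", "stimulus_intensity"], keep="first")


def boundary_variables(cued_trials: pd.DataFrame,
                       subjective_map: pd.DataFrame) -> pd.DataFrame:
    """Attach prediction-error variables to cued-perception trials.

    cue_pe = subjective_value - cue_mean (the PE induced by the cue);
    experienced_pe = rating - subjective_value. By construction
    experienced_pe + subjective_value reconstructs the rating exactly.
    Raises if any (subject, modality, intensity) cell present in the
    trials is missing from the map.
    """
    merged = cued_trials.merge(
        subjective_map, on=["subject_id", "modality", "stimulus_intensity"],
        how="left", validate="many_to_one",
    )
    missing = merged[merged["subjective_value"].isna()]
    if len(missing):
        cells = missing[["subject_id", "modality", "stimulus_intensity"]]
        raise ValueError(
            "subjective_map does not cover cells:\n"
            + cells.drop_duplicates().to_string(index=False))
    merged["cue_pe"] = merged["subjective_value"] - merged["cue_mean"]
    merged["experienced_pe"] = merged["rating"] - merged["subjective_value"]
    return merged


def fit_boundary_model(trials: pd.DataFrame, complex_model: bool = False
                       ) -> pd.DataFrame:
    """Polynomial prediction-error model with random intercepts only.

    Simple model: experienced_pe ~ cue_pe + cue_pe^2 + cue_pe^3 (raw,
    non-centered powers). The complex model adds cue_pe^4, the per-modality
    trial number, and every PE-power x trial interaction. A nonzero cubic
    term signals a boundary: assimilation that works near the subjective
    value but breaks down for large cue prediction errors. Powers are
    deliberately left non-centered, so collinearity between them is
    expected and not "fixed" here.
    """
    df = trials.dropna(subset=["cue_pe", "experienced_pe"]).copy()
    X = pd.DataFrame(index=df.index)
    powers = [1, 2, 3, 4] if complex_model else [1, 2, 3]
    for p in powers:
        X[f"cue_pe^{p}" if p > 1 else "cue_pe"] = df["cue_pe"] ** p
    if complex_model:
        trial = df.groupby("modality")["trial_overall"].transform(
            lambda c: (c - c.mean()) / c.std(ddof=0))
        X["trial"] = trial
        for p in powers:
            name = f"cue_pe^{p}" if p > 1 else "cue_pe"
            X[f"{name}:trial"] = X[name] * trial
    # response stays on its natural scale (a difference of VAS quantities)
    # and the powers stay non-centered; columns are only rescaled by a
    # constant for conditioning (cue_pe^4 reaches ~1e6) and the estimates
    # mapped back, which leaves the model itself unchanged
    scales = X.abs().max().replace(0.0, 1.0)
    y = df["experienced_pe"].to_numpy(float)
    Xc = sm.add_constant(X / scales, prepend=True)
    result, ok = _try_fit(y, Xc, df["subject_id"], exog_re=None)
    if result is None:
        raise RuntimeError("boundary model unfittable")
    table = _result_table(result, "intercept-only")
    factor = pd.concat([pd.Series({"const": 1.0}), scales])
    table["beta"] = table["beta"] / factor
    table["se"] = table["se"] / factor
    return table


# ---------------------------------------------------------------------------
# Cross-modality consistency of the cue effect


def subject_cue_effect_correlation(trials_pain: pd.DataFrame,
                                   trials_vision: pd.DataFrame,
                                   method: str = "ols"):
    """Correlate per-subject cue-mean effects across modalities.

    The per-subject effect is the OLS slope of the z-scored rating on the
    -1/+1 cue-mean code within that subject (``method="ols"``, default) or
    the subject's conditional random slope (BLUP) from a mixed model with
    a random cue-mean slope (``method="blup"``). Returns a dict with the
    Pearson r, its 95% CI (Fisher z), p, and n.
    """
    slopes = {}
    for name, sub in (("pain", trials_pain), ("vision", trials_vision)):
        slopes[name] = (_blup_slopes(sub) if method == "blup"
                        else _ols_slopes(sub))
    joined = pd.concat([slopes["pain"].rename("pain"),
                        slopes["vision"].rename("vision")], axis=1).dropna()
    n = len(joined)
    if n < 3:
        raise ValueError("need at least 3 subjects with both modalities")
    r, p = stats.pearsonr(joined["pain"], joined["vision"])
    z = np.arctanh(np.clip(r, -1 + 1e-15, 1 - 1e-15))
    # Fisher-z interval needs n > 3; at n = 3 the CI is undefined
    half = stats.norm.ppf(0.975) / np.sqrt(n - 3) if n > 3 else np.inf
    return {"r": float(r), "p": float(p), "n": n,
            "ci_low": float(np.tanh(z - half)),
            "ci_high": float(np.tanh(z + half)),
            "method": method}


def _ols_slopes(trials: pd.DataFrame) -> pd.Series:
    mm = build_model_matrix(trials, {"cue_mean": "pm1"}, interactions=None)
    df = pd.DataFrame({"y": mm.y, "x": mm.X["cue_mean"],
                       "subject": mm.groups})
    out = {}
    for sid, sub in df.groupby("subject"):
        if sub["x"].nunique() < 2:
            out[sid] = np.nan
            continue
        out[sid] = float(np.polyfit(sub["x"], sub["y"], 1)[0])
    return pd.Series(out)


def _blup_slopes(trials: pd.DataFrame) -> pd.Series:
    mm = build_model_matrix(trials, {"cue_mean": "pm1"}, interactions=None)
    y = np.asarray(mm.y, float)
    X = sm.add_constant(mm.X, prepend=True)
    exog_re = sm.add_constant(mm.X[["cue_mean"]], prepend=True)
    result, ok = _try_fit(y, X, mm.groups, exog_re=exog_re)
    if result is None:
        raise RuntimeError("BLUP extraction failed: model unfittable")
    fixed = float(result.fe_params.iloc[list(X.columns).index("cue_mean")])
    re = result.random_effects
    return pd.Series({sid: fixed + float(eff.get("cue_mean", 0.0))
                      for sid, eff in re.items()})
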