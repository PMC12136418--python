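"""Synthetic participants with the generative structure the analyses assume.

The study's participant data are not deposited, so every downstream stage
(fitting, group statistics, mixed models, mediation) is exercised on
simulated agents. An agent rates expectations with the cue-weighting
model (per-modality k and b) plus Gaussian response noise, and rates
perceived intensity as a convex combination of its cue-based expectation
and its subjective stimulus value, with optional linear drift over blocks
and trials (habituation/sensitization) and the same noise model. Ratings
are clipped to the 0-100 VAS.

Cohort defaults mirror the study conditions: 45 agents, 180 expectation
trials per modality, response noise SD 6 VAS points (the scale of the
study's reported model RMSE), k log-normal around medians 1.66 (pain) /
1.47 (vision), b normal around -1.64 / 0.16.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .expectation_model import WeightParams, expected_value

__all__ = [
    "AgentParams",
    "default_intensity_map",
    "sample_cohort",
    "simulate_expectation_ratings",
    "simulate_perception_ratings",
    "simulate_sr_ratings",
    "simulate_mediation_dataset",
]

#: Population medians/locations used when drawing heterogeneous cohorts.
COHORT_K_MEDIAN = {"pain": 1.66, "vision": 1.47}
COHORT_B_LOC = {"pain": -1.64, "vision": 0.16}
COHORT_K_LOG_SD = 0.4
COHORT_B_SD = 2.0


def default_intensity_map(modality: str, intensity: float) -> float:
    """Map physical intensity to a subjective VAS value.

    Pain: linear in temperature, 45 degC -> 10 VAS up to 49 degC -> 70 VAS
    (15 VAS points per degC). Vision: contrast percentage read out directly
    as VAS (5% -> 5 ... 95% -> 95). Both are simple monotone placeholders
    for a psychometric function; the analyses only require monotonicity.
    """
    if modality == "pain":
        return 10.0 + 15.0 * (intensity - 45.0)
    return float(intensity)


@dataclass(frozen=True)
class AgentParams:
    """Generative parameters of one synthetic participant."""

    weights: dict = field(default_factory=lambda: {
        "pain": WeightParams(1.66, -1.64),
        "vision": WeightParams(1.47, 0.16),
    })
    integration_weight: float = 0.35   # weight on cue-based expectation
    noise_sd: float = 6.0              # VAS units
    block_drift: float = 0.0           # VAS units per z-scored block
    trial_drift: float = 0.0           # VAS units per z-scored trial
    intensity_map: object = default_intensity_map

    def __post_init__(self) -> None:
        if not (0.0 <= self.integration_weight <= 1.0):
            raise ValueError("integration_weight must be in [0, 1]")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")

    def subjective_value(self, modality: str, intensity: float) -> float:
        return float(self.intensity_map(modality, intensity))


def sample_cohort(n_agents: int, rng: np.random.Generator,
                  k_log_sd: float = COHORT_K_LOG_SD,
                  b_sd: float = COHORT_B_SD,
                  noise_sd: float = 6.0,
                  integration_weight_range: tuple = (0.15, 0.55)) -> list[AgentParams]:
    """Draw a heterogeneous cohort of agents.

    k is log-normal around the per-modality population medians, b normal
    around the per-modality locations; the integration weight is uniform
    in ``integration_weight_range``.
    """
    if n_agents < 1:
        raise ValueError("need at least one agent")
    cohort = []
    for _ in range(n_agents):
        weights = {
            m: WeightParams(
                float(np.clip(COHORT_K_MEDIAN[m] * np.exp(rng.normal(0, k_log_sd)),
                              1e-3, 1000.0)),
                float(np.clip(rng.normal(COHORT_B_LOC[m], b_sd), -1000.0, 1000.0)),
            )
            for m in ("pain", "vision")
        }
        cohort.append(AgentParams(
            weights=weights,
            integration_weight=float(rng.uniform(*integration_weight_range)),
            noise_sd=noise_sd,
        ))
    return cohort


_CUE_COLS = [f"cue_v{i}" for i in range(1, 11)]


def _zscore(a: np.ndarray) -> np.ndarray:
    sd = a.std()
    return (a - a.mean()) / sd if sd > 0 else np.zeros_like(a)


def simulate_expectation_ratings(design: pd.DataFrame, agent: AgentParams,
                                 rng: np.random.Generator) -> pd.DataFrame:
    """Fill expectation-task ratings: model expectation + Gaussian noise.

    rating = expected_value(cue; k, b) + N(0, noise_sd), clipped to [0, 100].
    Also fills plausible response times (log-normal around ~1 s).
    """
    out = design.copy()
    for modality, idx in out.groupby("modality").groups.items():
        cues = out.loc[idx, _CUE_COLS].to_numpy(float)
        mu = expected_value(cues, agent.weights[modality])
        noise = rng.normal(0.0, agent.noise_sd, size=len(idx)) if agent.noise_sd > 0 \
            else np.zeros(len(idx))
        out.loc[idx, "rating"] = np.clip(mu + noise, 0.0, 100.0)
    out["rt"] = rng.lognormal(mean=0.0, sigma=0.35, size=len(out))
    return out


def simulate_perception_ratings(design: pd.DataFrame, agent: AgentParams,
                                rng: np.random.Generator) -> pd.DataFrame:
    """Fill cued-perception ratings by expectation/input integration.

    rating = w * E_cue + (1 - w) * S_subj + block_drift * z(block)
    + trial_drift * z(trial) + N(0, noise_sd), clipped to [0, 100], with
    S_subj from the agent's subjective intensity map. Drift covariates are
    z-scored within modality, matching how the analyses model them.
    """
    out = design.copy()
    w = agent.integration_weight
    for modality, idx in out.groupby("modality").groups.items():
        sub = out.loc[idx]
        cues = sub[_CUE_COLS].to_numpy(float)
        e_cue = expected_value(cues, agent.weights[modality])
        s_subj = np.array([
            agent.subjective_value(modality, s) for s in sub["stimulus_intensity"]
        ])
        drift = (agent.block_drift * _zscore(sub["block"].to_numpy(float))
                 + agent.trial_drift * _zscore(sub["trial_overall"].to_numpy(float)))
        noise = rng.normal(0.0, agent.noise_sd, size=len(idx)) if agent.noise_sd > 0 \
            else np.zeros(len(idx))
        out.loc[idx, "rating"] = np.clip(
            w * e_cue + (1.0 - w) * s_subj + drift + noise, 0.0, 100.0)
    out["rt"] = rng.lognormal(mean=0.0, sigma=0.35, size=len(out))
    return out


def simulate_sr_ratings(design: pd.DataFrame, agent: AgentParams,
                        rng: np.random.Generator) -> pd.DataFrame:
    """Fill stimulus-response (calibration) ratings: map + Gaussian noise."""
    out = design.copy()
    s_subj = np.array([
        agent.subjective_value(m, s)
        for m, s in zip(out["modality"], out["stimulus_intensity"])
    ])
    noise = rng.normal(0.0, agent.noise_sd, size=len(out)) if agent.noise_sd > 0 \
        else np.zeros(len(out))
    out["rating"] = np.clip(s_subj + noise, 0.0, 100.0)
    out["rt"] = rng.lognormal(mean=0.0, sigma=0.35, size=len(out))
    return out


def simulate_mediation_dataset(n_subjects: int, n_trials: int,
                               a: float, b_path: float, c_prime: float,
                               between_subject_sd: float,
                               rng: np.random.Generator,
                               noise_sd: float = 1.0) -> pd.DataFrame:
    """Trial-level (X, M, Y) data with a known multilevel mediation structure.

    Per subject j: a_j ~ N(a, between_subject_sd), b_j ~ N(b_path,
    between_subject_sd); per trial X ~ N(0, 1), M = a_j X + e_M,
    Y = b_j M + c' X + e_Y with e ~ N(0, noise_sd). The population
    indirect effect is E[a_j b_j] = a * b_path (paths drawn independently).
    Returns columns subject, X, M, Y, covariate (a pure-noise covariate,
    so the estimation interface matches the real analysis).
    """
    if n_subjects < 2 or n_trials < 2:
        raise ValueError("need at least 2 subjects and 2 trials")
    frames = []
    for j in range(n_subjects):
        a_j = rng.normal(a, between_subject_sd)
        b_j = rng.normal(b_path, between_subject_sd)
        x = rng.normal(0.0, 1.0, n_trials)
        m = a_j * x + (rng.normal(0.0, noise_sd, n_trials) if noise_sd > 0 else 0.0)
        y = b_j * m + c_prime * x + (
            rng.normal(0.0, noise_sd, n_trials) if noise_sd > 0 else 0.0)
        frames.append(pd.DataFrame({
            "subject": j, "X": x, "M": m, "Y": y,
            "covariate": rng.normal(0.0, 1.0, n_trials),
        }))
    return pd.concat(frames, ignore_index=True)
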