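"""Shared fixtures: seeded rngs and expensive session-scoped simulations."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

import cueweight as cw

CUE_COLS = [f"cue_v{i}" for i in range(1, 11)]


@pytest.fixture()
def rng():
    return np.random.default_rng(2024)


def random_cues(rng: np.random.Generator, n: int) -> np.ndarray:
    """Unconstrained random 10-value cues on the VAS, shape (n, 10)."""
    means = rng.uniform(20, 80, size=(n, 1))
    sds = rng.uniform(3, 15, size=(n, 1))
    return np.clip(rng.normal(means, sds, size=(n, 10)), 0, 100)


def _recovery_cohort(seed: int, n_agents: int = 20):
    """Simulate agents over the full expectation task and refit (k, b).

    One (k, b) per agent, k uniform on [0.5, 5], b uniform on [-8, 8],
    rating noise SD 6; each agent rates a fresh 360-trial design and the
    fit pools all of the agent's trials.
    """
    rng = np.random.default_rng(seed)
    k_true = rng.uniform(0.5, 5, n_agents)
    b_true = rng.uniform(-8, 8, n_agents)
    k_hat, b_hat = [], []
    for i in range(n_agents):
        design = cw.make_expectation_design(rng, 6)
        agent = cw.AgentParams(
            weights={m: cw.WeightParams(k_true[i], b_true[i])
                     for m in ("pain", "vision")},
            noise_sd=6.0,
        )
        sim = cw.simulate_expectation_ratings(design, agent, rng)
        fit = cw.fit_weight_params(sim)
        k_hat.append(fit.k_hat)
        b_hat.append(fit.b_hat)
    return pd.DataFrame({"k_true": k_true, "b_true": b_true,
                         "k_hat": k_hat, "b_hat": b_hat})


@pytest.fixture(scope="session")
def recovery_cohort_a():
    return _recovery_cohort(seed=0)


@pytest.fixture(scope="session")
def recovery_cohort_both(recovery_cohort_a):
    return pd.concat([recovery_cohort_a, _recovery_cohort(seed=1)],
                     ignore_index=True)
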