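"""Generation of constrained cue distributions and factorial task designs.

The experiment shows participants "distribution cues": 10 alleged prior
ratings on a 0-100 VAS, constructed to manipulate the cue's mean, spread
and skewness independently. Three tasks use them:

* stimulus-response — 50 trials, 5 intensities x 5 reps per modality
  (heat 45-49 degC, checkerboards at 5/27.5/50/72.5/95 % contrast), used
  to calibrate each subject's subjective stimulus values;
* expectation — 360 trials, full factorial of modality(2) x cue mean
  {30,40,50,60,70} x cue SD {5,12.5} x skew {negative,symmetric,positive},
  6 reps, in six blocks with three consecutive blocks per modality;
* cued-perception — 144 trials, modality(2) x intensity(2) x cue mean
  {30,70} x cue SD {5,12.5} x skew(3), 3 reps, six 24-trial blocks each
  split into two single-modality 12-trial mini-blocks.

Cue construction: symmetric cues are normal draws; skewed cues are nine
log-normal draws (reflected about their mean for negative skew) plus one
injected extreme value 2.0-2.5 SDs from the mean on the skew side, so
every skewed cue contains at least one clear outlier. Draws are affinely
standardized to the exact target mean/SD (affine maps preserve skewness)
and accepted only if all values lie in [0, 100] and the sample skewness
falls in the class band: < -0.3 (negative), > 0.3 (positive), within
[-0.035, 0.035] (symmetric).

Trial tables are pandas DataFrames in a single long format shared by all
tasks (see :mod:`cueweight.io` for the schema); absent fields are NaN.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import brentq
from scipy.stats import skew as sample_skewness

__all__ = [
    "CueSpec",
    "Cue",
    "CueGenerationError",
    "MODALITIES",
    "EXPECTATION_MEANS",
    "CUED_MEANS",
    "CUE_SDS",
    "SKEW_CLASSES",
    "PAIN_SR_INTENSITIES",
    "VISION_SR_INTENSITIES",
    "PAIN_CUED_INTENSITIES",
    "VISION_CUED_INTENSITIES",
    "sample_base_values",
    "standardize_moments",
    "generate_cue",
    "make_stimulus_response_design",
    "make_expectation_design",
    "make_cued_perception_design",
]

MODALITIES = ("pain", "vision")
EXPECTATION_MEANS = (30.0, 40.0, 50.0, 60.0, 70.0)
CUED_MEANS = (30.0, 70.0)
CUE_SDS = (5.0, 12.5)
SKEW_CLASSES = ("negative", "symmetric", "positive")

PAIN_SR_INTENSITIES = (45.0, 46.0, 47.0, 48.0, 49.0)          # degC
VISION_SR_INTENSITIES = (5.0, 27.5, 50.0, 72.5, 95.0)         # % contrast
PAIN_CUED_INTENSITIES = (47.0, 48.0)
VISION_CUED_INTENSITIES = (50.0, 60.0)

#: Skewness acceptance bands per class (lo, hi); open bounds handled below.
_SKEW_BANDS = {
    "negative": (-np.inf, -0.3),
    "symmetric": (-0.035, 0.035),
    "positive": (0.3, np.inf),
}

# Log-normal shape parameter sigma solving for skewness 1 of the base
# draws: skew = (w + 2) sqrt(w - 1) with w = exp(sigma^2). Standardization
# is affine so only the shape matters; the accept loop does the rest.
_LOGNORM_SIGMA = brentq(
    lambda s: (np.exp(s**2) + 2.0) * np.sqrt(np.exp(s**2) - 1.0) - 1.0, 0.05, 1.0
)


class CueGenerationError(RuntimeError):
    """Raised when the accept-resample loop exhausts its attempt budget."""


@dataclass(frozen=True)
class CueSpec:
    """Target moments and skewness class of a cue distribution."""

    target_mean: float
    target_sd: float
    skew_class: str

    def __post_init__(self) -> None:
        if self.skew_class not in SKEW_CLASSES:
            raise ValueError(f"unknown skew class: {self.skew_class!r}")
        if self.target_sd <= 0:
            raise ValueError("target_sd must be positive")
        if not (0.0 <= self.target_mean <= 100.0):
            raise ValueError("target_mean must be on the VAS scale [0, 100]")


@dataclass(frozen=True)
class Cue:
    """Ten VAS values satisfying the moment/skewness constraints of a spec."""

    values: tuple
    spec: CueSpec = field(compare=False)

    def __post_init__(self) -> None:
        if len(self.values) != 10:
            raise ValueError("a cue has exactly 10 values")

    @property
    def array(self) -> np.ndarray:
        return np.asarray(self.values, dtype=float)

    @property
    def skewness(self) -> float:
        return float(sample_skewness(self.array, bias=False))


def sample_base_values(spec: CueSpec, rng: np.random.Generator) -> np.ndarray:
    """Raw draws for one cue, before standardization and acceptance.

    Symmetric class: 10 normal draws at the target moments. Skewed classes:
    9 log-normal draws (reflected about their mean for negative skew) plus
    one extreme value injected uniformly 2.0-2.5 SDs of the nine draws
    above (positive) or below (negative) their mean.
    """
    if spec.skew_class == "symmetric":
        return rng.normal(spec.target_mean, spec.target_sd, size=10)
    base = rng.lognormal(mean=0.0, sigma=_LOGNORM_SIGMA, size=9)
    if spec.skew_class == "negative":
        base = 2.0 * base.mean() - base  # reflect: long tail now points down
    offset = rng.uniform(2.0, 2.5) * base.std()
    extreme = base.mean() + (offset if spec.skew_class == "positive" else -offset)
    return np.append(base, extreme)


def standardize_moments(values, target_mean: float, target_sd: float) -> np.ndarray:
    """Affinely map values to the exact target mean and (population) SD.

    The positive affine transform leaves sample skewness unchanged, so
    skewness constraints can be checked after exact moment matching.
    """
    v = np.asarray(values, dtype=float)
    sd = v.std()
    if sd == 0:
        raise ValueError("cannot standardize a zero-variance draw")
    return target_mean + target_sd * (v - v.mean()) / sd


def _skew_ok(s: float, skew_class: str) -> bool:
    lo, hi = _SKEW_BANDS[skew_class]
    if skew_class == "symmetric":
        return lo <= s <= hi
    if skew_class == "negative":
        return s < hi
    return s > lo


def _sample_base_batch(spec: CueSpec, rng: np.random.Generator,
                       size: int) -> np.ndarray:
    """Vectorized equivalent of :func:`sample_base_values`: (size, 10)."""
    if spec.skew_class == "symmetric":
        return rng.normal(spec.target_mean, spec.target_sd, size=(size, 10))
    base = rng.lognormal(mean=0.0, sigma=_LOGNORM_SIGMA, size=(size, 9))
    if spec.skew_class == "negative":
        base = 2.0 * base.mean(axis=1, keepdims=True) - base
    offset = rng.uniform(2.0, 2.5, size=size) * base.std(axis=1)
    sign = 1.0 if spec.skew_class == "positive" else -1.0
    extreme = base.mean(axis=1) + sign * offset
    return np.column_stack([base, extreme])


def generate_cue(spec: CueSpec, rng: np.random.Generator,
                 max_attempts: int = 10_000) -> Cue:
    """Accept-resample loop producing a cue that satisfies its spec.

    Each attempt: draw base values, standardize to the exact moments,
    reject if any value leaves [0, 100] or the sample skewness falls
    outside the class band. Candidates are drawn in vectorized batches,
    which changes only speed, not the accept-resample semantics. Raises
    :class:`CueGenerationError` if ``max_attempts`` is exhausted
    (infeasible spec/tolerance combination).
    """
    if max_attempts < 1:
        raise ValueError("max_attempts must be >= 1")
    attempts = 0
    batch = 16 if spec.skew_class != "symmetric" else 64
    while attempts < max_attempts:
        n = min(batch, max_attempts - attempts)
        attempts += n
        raw = _sample_base_batch(spec, rng, n)
        sd = raw.std(axis=1)
        ok = sd > 0
        vals = np.empty_like(raw)
        vals[ok] = (spec.target_mean
                    + spec.target_sd * (raw[ok] - raw[ok].mean(axis=1, keepdims=True))
                    / sd[ok, None])
        ok &= (vals.min(axis=1) >= 0.0) & (vals.max(axis=1) <= 100.0)
        if not ok.any():
            continue
        skews = sample_skewness(vals[ok], axis=1, bias=False)
        lo, hi = _SKEW_BANDS[spec.skew_class]
        if spec.skew_class == "symmetric":
            admissible = (skews >= lo) & (skews <= hi)
        elif spec.skew_class == "negative":
            admissible = skews < hi
        else:
            admissible = skews > lo
        if admissible.any():
            winner = vals[ok][admissible][0]
            return Cue(values=tuple(winner), spec=spec)
    raise CueGenerationError(
        f"no admissible cue for {spec} within {max_attempts} attempts"
    )


# ---------------------------------------------------------------------------
# Trial tables


_COLUMNS = [
    "task", "subject_id", "modality", "block", "trial_in_block",
    "trial_overall", "cue_mean", "cue_sd", "cue_skew",
    *[f"cue_v{i}" for i in range(1, 11)],
    "stimulus_intensity", "rating", "rt",
]


def _empty_trials(n: int) -> pd.DataFrame:
    df = pd.DataFrame({c: [np.nan] * n for c in _COLUMNS})
    for c in ("task", "modality", "cue_skew"):
        df[c] = df[c].astype(object)
    return df


def _round_robin_blocks(items: list, n_blocks: int, rng: np.random.Generator) -> list[list]:
    """Deal repeated factorial cells across blocks as evenly as possible."""
    blocks: list[list] = [[] for _ in range(n_blocks)]
    for j, item in enumerate(items):
        blocks[j % n_blocks].append(item)
    for b in blocks:
        rng.shuffle(b)
    return blocks


def make_stimulus_response_design(rng: np.random.Generator,
                                  subject_id: int = 0) -> pd.DataFrame:
    """One pain and one vision calibration block, 25 stimuli each.

    Five intensity levels per modality, five repetitions each, randomized
    within block; block order randomized.
    """
    order = list(MODALITIES)
    rng.shuffle(order)
    rows = []
    overall = 0
    for block, modality in enumerate(order, start=1):
        levels = PAIN_SR_INTENSITIES if modality == "pain" else VISION_SR_INTENSITIES
        stims = [lvl for lvl in levels for _ in range(5)]
        rng.shuffle(stims)
        for i, s in enumerate(stims, start=1):
            overall += 1
            rows.append((modality, block, i, overall, s))
    df = _empty_trials(len(rows))
    df["task"] = "stimulus_response"
    df["subject_id"] = subject_id
    df[["modality", "block", "trial_in_block", "trial_overall",
        "stimulus_intensity"]] = pd.DataFrame(rows, index=df.index)
    return df


def make_expectation_design(rng: np.random.Generator, n_reps: int = 6,
                            subject_id: int = 0,
                            max_attempts: int = 10_000) -> pd.DataFrame:
    """Factorial expectation-task design with freshly generated cues.

    modality(2) x mean(5) x SD(2) x skew(3), each combination ``n_reps``
    times (default 6 -> 360 trials); six blocks, three consecutive blocks
    per modality, repetitions dealt evenly across a modality's blocks and
    shuffled within block.
    """
    if n_reps < 1:
        raise ValueError("n_reps must be >= 1")
    first = MODALITIES[rng.integers(2)]
    order = (first,) + tuple(m for m in MODALITIES if m != first)
    rows = []
    overall = 0
    block_no = 0
    for modality in order:
        cells = [
            (m, sd, sk)
            for m in EXPECTATION_MEANS
            for sd in CUE_SDS
            for sk in SKEW_CLASSES
            for _ in range(n_reps)
        ]
        rng.shuffle(cells)
        for block_cells in _round_robin_blocks(cells, 3, rng):
            block_no += 1
            for i, (m, sd, sk) in enumerate(block_cells, start=1):
                overall += 1
                cue = generate_cue(CueSpec(m, sd, sk), rng, max_attempts)
                rows.append((modality, block_no, i, overall, m, sd, sk, *cue.values))
    df = _empty_trials(len(rows))
    df["task"] = "expectation"
    df["subject_id"] = subject_id
    cols = ["modality", "block", "trial_in_block", "trial_overall",
            "cue_mean", "cue_sd", "cue_skew", *[f"cue_v{i}" for i in range(1, 11)]]
    df[cols] = pd.DataFrame(rows, index=df.index)
    return df


def make_cued_perception_design(rng: np.random.Generator, n_reps: int = 3,
                                subject_id: int = 0,
                                max_attempts: int = 10_000) -> pd.DataFrame:
    """Factorial cued-perception design: cue followed by a real stimulus.

    modality(2) x intensity(2) x cue mean(2) x cue SD(2) x skew(3), each
    ``n_reps`` times (default 3 -> 144 trials). Blocks hold 24 trials as
    two single-modality mini-blocks of 12, mini-block order and
    within-modality trial order randomized.
    """
    if n_reps < 1:
        raise ValueError("n_reps must be >= 1")
    n_mini = 2 * n_reps  # per modality; 12-trial mini-blocks
    mini: dict[str, list[list]] = {}
    for modality in MODALITIES:
        intensities = (PAIN_CUED_INTENSITIES if modality == "pain"
                       else VISION_CUED_INTENSITIES)
        cells = [
            (s, m, sd, sk)
            for s in intensities
            for m in CUED_MEANS
            for sd in CUE_SDS
            for sk in SKEW_CLASSES
            for _ in range(n_reps)
        ]
        rng.shuffle(cells)
        mini[modality] = _round_robin_blocks(cells, n_mini, rng)
    rows = []
    overall = 0
    for block in range(1, n_mini + 1):
        pair = list(MODALITIES)
        rng.shuffle(pair)
        i = 0
        for modality in pair:
            for (s, m, sd, sk) in mini[modality][block - 1]:
                i += 1
                overall += 1
                cue = generate_cue(CueSpec(m, sd, sk), rng, max_attempts)
                rows.append((modality, block, i, overall, m, sd, sk,
                             *cue.values, s))
    df = _empty_trials(len(rows))
    df["task"] = "cued_perception"
    df["subject_id"] = subject_id
    cols = ["modality", "block", "trial_in_block", "trial_overall",
            "cue_mean", "cue_sd", "cue_skew",
            *[f"cue_v{i}" for i in range(1, 11)], "stimulus_intensity"]
    df[cols] = pd.DataFrame(rows, index=df.index)
    return df
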