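"""Trial-table I/O: one long CSV schema shared by all three tasks.

One row per trial; columns absent for a task (e.g. stimulus intensity on
expectation trials) are empty. Cue values occupy cue_v1..cue_v10. Files
are UTF-8 CSV with a header row and '.' decimal separator; metadata
(seed, config hash) is embedded as leading ``# key=value`` comment lines
so a results file is self-describing without a sidecar.
"""

from __future__ import annotations

from pathlib import Path

import pandas as pd

__all__ = ["BASE_COLUMNS", "CUE_COLUMNS", "read_trials", "write_trials",
           "SchemaError"]

CUE_COLUMNS = [f"cue_v{i}" for i in range(1, 11)]
BASE_COLUMNS = [
    "task", "subject_id", "modality", "block", "trial_in_block",
    "trial_overall", "cue_mean", "cue_sd", "cue_skew", *CUE_COLUMNS,
    "stimulus_intensity", "rating", "rt",
]

_NUMERIC = ["subject_id", "block", "trial_in_block", "trial_overall",
            "cue_mean", "cue_sd", *CUE_COLUMNS, "stimulus_intensity",
            "rating", "rt"]

_TASKS_WITH_CUES = {"expectation", "cued_perception"}


class SchemaError(ValueError):
    """A trial CSV does not match the documented schema."""


def write_trials(trials: pd.DataFrame, path, *, seed=None, config_hash=None
                 ) -> None:
    """Write a trial table, embedding seed/config metadata as comments."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w", encoding="utf-8", newline="") as fh:
        meta = {}
        if seed is not None:
            meta["seed"] = seed
        if config_hash is not None:
            meta["config_hash"] = config_hash
        for k, v in meta.items():
            fh.write(f"# {k}={v}\n")
        trials.to_csv(fh, index=False)


def read_trials(path) -> pd.DataFrame:
    """Read and validate a trial CSV.

    Validation: all base columns present; numeric columns parse as
    numbers (offending rows are reported by index); rows of cue-bearing
    tasks must have all 10 cue values. An empty file returns an empty
    table with a warning.
    """
    import warnings

    path = Path(path)
    df = pd.read_csv(path, comment="#")
    if df.empty:
        warnings.warn(f"{path}: no trial rows")
        return pd.DataFrame(columns=BASE_COLUMNS)
    missing = [c for c in BASE_COLUMNS if c not in df.columns]
    if missing:
        raise SchemaError(f"{path}: missing required column(s): {missing}")
    for col in _NUMERIC:
        coerced = pd.to_numeric(df[col], errors="coerce")
        bad = df.index[coerced.isna() & df[col].notna()]
        if len(bad):
            raise SchemaError(
                f"{path}: non-numeric values in {col!r} at rows "
                f"{list(bad[:10])}")
        df[col] = coerced
    cue_rows = df["task"].isin(_TASKS_WITH_CUES)
    incomplete = df.loc[cue_rows, CUE_COLUMNS].isna().any(axis=1)
    if incomplete.any():
        raise SchemaError(
            f"{path}: cue-bearing rows with incomplete cue values at rows "
            f"{list(df.loc[cue_rows].index[incomplete][:10])}")
    return df[BASE_COLUMNS + [c for c in df.columns if c not in BASE_COLUMNS]]
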