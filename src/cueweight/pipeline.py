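"""End-to-end synthetic pipeline driver and run configuration.

Stages, in order: generate per-agent task designs -> simulate ratings ->
response-time exclusions -> per-agent (k, b) fitting -> group statistics
-> perception analyses (persistence, boundary effects, cross-modality
cue-effect correlation) -> multilevel mediation on a synthetic trial-level
mediator. Every intermediate table is written to the output directory,
and because the inputs are synthetic the run ends with a recovery report
comparing generating and recovered parameters.

Configuration is a flat key-value structure (``RunConfig``); a config
file is plain text with one ``key = value`` per line, '#' comments
allowed. Every output artifact embeds the seed and a hash of the
configuration, so results are traceable to their settings; reruns with
the same config are byte-identical.
"""

from __future__ import annotations

import hashlib
import json
import logging
import sys
from dataclasses import asdict, dataclass, field, fields
from pathlib import Path

import numpy as np
import pandas as pd

from . import group_stats, io, mediation, perception_analysis, synthetic_agents
from .fitting import fit_cohort
from .task_design import (
    make_cued_perception_design,
    make_expectation_design,
    make_stimulus_response_design,
)

__all__ = ["RunConfig", "run_pipeline"]

log = logging.getLogger("cueweight")
if not log.handlers:
    _h = logging.StreamHandler(sys.stderr)
    _h.setFormatter(logging.Formatter("%(asctime)s cueweight[%(run_id)s] %(message)s"))
    log.addHandler(_h)
    log.setLevel(logging.INFO)


@dataclass(frozen=True)
class RunConfig:
    """All knobs of a pipeline run, with documented defaults."""

    seed: int = 0
    n_agents: int = 45                  # study cohort size
    expectation_reps: int = 6           # -> 360 expectation trials
    cued_reps: int = 3                  # -> 144 cued-perception trials
    noise_sd: float = 6.0               # agent rating noise, VAS units
    n_boot: int = 10_000                # mediation bootstrap resamples
    mediator_effect: float = 0.5        # synthetic mediator loading on X
    out_dir: str = "cueweight_out"
    power_form: str = "absolute"        # Eq-form switch for the power term
    run_perception: bool = True
    run_mediation: bool = True

    def config_hash(self) -> str:
        payload = json.dumps(asdict(self), sort_keys=True).encode()
        return hashlib.sha256(payload).hexdigest()[:12]

    @classmethod
    def from_file(cls, path) -> "RunConfig":
        """Parse a plain ``key = value`` config file."""
        kinds = {f.name: f.type for f in fields(cls)}
        casts = {"int": int, "float": float, "str": str,
                 "bool": lambda s: s.lower() in ("1", "true", "yes")}
        kwargs = {}
        for lineno, raw in enumerate(Path(path).read_text().splitlines(), 1):
            line = raw.split("#", 1)[0].strip()
            if not line:
                continue
            if "=" not in line:
                raise ValueError(f"{path}:{lineno}: expected 'key = value'")
            key, val = (s.strip() for s in line.split("=", 1))
            if key not in kinds:
                raise ValueError(f"{path}:{lineno}: unknown config key {key!r}")
            kwargs[key] = casts[kinds[key]](val)
        return cls(**kwargs)


def _write(df: pd.DataFrame, path: Path, cfg: RunConfig) -> None:
    io.write_trials(df, path, seed=cfg.seed, config_hash=cfg.config_hash())


def run_pipeline(config: RunConfig) -> dict:
    """Run every stage on a synthetic cohort; returns the summary dict.

    Each stage failure is re-raised annotated with the stage name. All
    tables land under ``config.out_dir``; the summary is also written as
    ``summary.json``.
    """
    if config.n_agents < 1:
        raise ValueError("config.n_agents must be >= 1")
    extra = {"run_id": config.config_hash()[:6]}
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(config.seed)
    summary: dict = {"seed": config.seed, "config_hash": config.config_hash()}

    stage = "simulate"
    try:
        log.info("simulating %d agents", config.n_agents, extra=extra)
        cohort = synthetic_agents.sample_cohort(
            config.n_agents, rng, noise_sd=config.noise_sd)
        sr_tabs, exp_tabs, cued_tabs = [], [], []
        for sid, agent in enumerate(cohort):
            sr = make_stimulus_response_design(rng, subject_id=sid)
            sr_tabs.append(synthetic_agents.simulate_sr_ratings(sr, agent, rng))
            exp = make_expectation_design(rng, config.expectation_reps,
                                          subject_id=sid)
            exp_tabs.append(
                synthetic_agents.simulate_expectation_ratings(exp, agent, rng))
            cued = make_cued_perception_design(rng, config.cued_reps,
                                               subject_id=sid)
            cued_tabs.append(
                synthetic_agents.simulate_perception_ratings(cued, agent, rng))
        sr_trials = pd.concat(sr_tabs, ignore_index=True)
        exp_trials = pd.concat(exp_tabs, ignore_index=True)
        cued_trials = pd.concat(cued_tabs, ignore_index=True)
        _write(sr_trials, out / "stimulus_response_trials.csv", config)
        _write(exp_trials, out / "expectation_trials.csv", config)
        _write(cued_trials, out / "cued_perception_trials.csv", config)

        stage = "exclusions"
        cued_kept, report = perception_analysis.apply_rt_exclusions(cued_trials)
        report.to_csv(out / "exclusions.csv", index=False)
        summary["exclusions"] = report.iloc[0].to_dict()

        stage = "fit"
        log.info("fitting (k, b) per agent x modality", extra=extra)
        fits = fit_cohort(exp_trials, power_form=config.power_form,
                          seed=config.seed)
        truth = pd.DataFrame([
            {"subject_id": sid, "modality": m,
             "k_true": agent.weights[m].k, "b_true": agent.weights[m].b}
            for sid, agent in enumerate(cohort) for m in ("pain", "vision")
        ])
        recovery = truth.merge(fits, on=["subject_id", "modality"])
        recovery = recovery[["subject_id", "modality", "k_true", "k_hat",
                             "b_true", "b_hat", "r_overall", "rmse"]]
        recovery.columns = ["subject_id", "modality", "k_true", "k_hat",
                            "b_true", "b_hat", "r", "rmse"]
        recovery.to_csv(out / "recovery_report.csv", index=False)
        fits.to_csv(out / "weight_fits.csv", index=False)

        stage = "group_stats"
        gs = {}
        for m in ("pain", "vision"):
            sub = fits[fits["modality"] == m]
            wk = group_stats.wilcoxon_vs_reference(sub["k_hat"], 1.0)
            wb = group_stats.wilcoxon_vs_reference(sub["b_hat"], 0.0)
            gs[m] = {"median_k": float(sub["k_hat"].median()),
                     "median_b": float(sub["b_hat"].median()),
                     "wilcoxon_k_vs_1_p": wk.p_value,
                     "wilcoxon_b_vs_0_p": wb.p_value,
                     "mean_r": float(sub["r_overall"].mean()),
                     "mean_rmse": float(sub["rmse"].mean())}
        if config.n_agents >= 3:
            wide = fits.pivot(index="subject_id", columns="modality",
                              values=["k_hat", "b_hat"])
            rho_k = group_stats.spearman_correlation(
                wide[("k_hat", "pain")], wide[("k_hat", "vision")])
            rho_b = group_stats.spearman_correlation(
                wide[("b_hat", "pain")], wide[("b_hat", "vision")])
            gs["cross_modality"] = {"rho_k": rho_k.statistic,
                                    "rho_k_p": rho_k.p_value,
                                    "rho_b": rho_b.statistic,
                                    "rho_b_p": rho_b.p_value}
        summary["group_stats"] = gs

        if config.run_perception:
            stage = "perception"
            log.info("perception analyses", extra=extra)
            subj_map = perception_analysis.subjective_stimulus_values(sr_trials)
            subj_map = perception_analysis.interpolate_subjective_values(
                subj_map, {m: cued_kept.loc[cued_kept["modality"] == m,
                                            "stimulus_intensity"].unique()
                           for m in ("pain", "vision")})
            bvars = perception_analysis.boundary_variables(cued_kept, subj_map)
            for complex_model, name in ((False, "boundary_simple"),
                                        (True, "boundary_complex")):
                tab = perception_analysis.fit_boundary_model(
                    bvars, complex_model=complex_model)
                tab.to_csv(out / f"{name}.csv")
                summary[name] = tab["beta"].to_dict()
            pers = {}
            for m in ("pain", "vision"):
                tabs = perception_analysis.persistence_model(
                    cued_kept[cued_kept["modality"] == m])
                tabs["across_task"].to_csv(out / f"persistence_{m}.csv")
                pers[m] = {
                    "interaction_beta": float(
                        tabs["across_task"]["beta"].get("cue_mean:trial_overall",
                                                        np.nan)),
                    "last_block_cue_beta": float(
                        tabs["last_block"]["beta"].get("cue_mean", np.nan)),
                }
            summary["persistence"] = pers
            if config.n_agents >= 3:
                corr = perception_analysis.subject_cue_effect_correlation(
                    cued_kept[cued_kept["modality"] == "pain"],
                    cued_kept[cued_kept["modality"] == "vision"])
                summary["cue_effect_correlation"] = corr

        if config.run_mediation:
            stage = "mediation"
            log.info("mediation (n_boot=%d)", config.n_boot, extra=extra)
            med_data = _mediation_table(cued_kept, recovery, config, rng)
            paths = mediation.bootstrap_mediation(
                med_data, n_boot=config.n_boot, rng=rng)
            paths.to_frame().to_csv(out / "mediation_paths.csv", index=False)
            summary["mediation"] = {
                name: {"estimate": s.estimate, "se": s.se, "p": s.p}
                for name, s in (("a", paths.a), ("b", paths.b),
                                ("ab", paths.ab), ("c_prime", paths.c_prime))
            }

        stage = "summary"
        summary["recovery"] = {
            "spearman_k": group_stats.spearman_correlation(
                recovery["k_true"], recovery["k_hat"]).statistic,
            "spearman_b": group_stats.spearman_correlation(
                recovery["b_true"], recovery["b_hat"]).statistic,
        } if config.n_agents >= 2 else {}
        (out / "summary.json").write_text(
            json.dumps(summary, indent=2, sort_keys=True, default=float) + "\n")
        return summary
    except Exception as exc:
        raise RuntimeError(f"pipeline stage {stage!r} failed: {exc}") from exc


def _mediation_table(cued_trials: pd.DataFrame, recovery: pd.DataFrame,
                     config: RunConfig, rng: np.random.Generator) -> pd.DataFrame:
    """Trial-level mediation inputs from the pain trials.

    X is the cue-based expectation from each agent's fitted (k, b); the
    mediator is synthetic (the study's mediators are brain signature
    scores, unavailable here): M = effect * z(X) + effect * z(intensity)
    + noise. Y is the observed rating, intensity the covariate.
    """
    from .expectation_model import WeightParams, expected_value

    pain = cued_trials[cued_trials["modality"] == "pain"].copy()
    params = {row.subject_id: WeightParams(row.k_hat, row.b_hat)
              for row in recovery[recovery["modality"] == "pain"].itertuples()}
    cues = pain[io.CUE_COLUMNS].to_numpy(float)
    x = np.empty(len(pain))
    for i, (sid, cue) in enumerate(zip(pain["subject_id"], cues)):
        x[i] = expected_value(cue, params[sid])
    z = lambda a: (a - a.mean()) / a.std()
    zx = z(x)
    zs = z(pain["stimulus_intensity"].to_numpy(float))
    m = config.mediator_effect * (zx + zs) + rng.normal(0, 1, len(pain))
    return pd.DataFrame({
        "subject": pain["subject_id"].to_numpy(),
        "X": x, "M": m, "Y": pain["rating"].to_numpy(float),
        "covariate": zs,
    })
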