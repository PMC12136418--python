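# cueweight

Tools for analyzing **distribution-cue experiments** in pain and visual
psychophysics: paradigms in which participants see ten alleged prior
ratings ("a distribution cue") on a 0–100 visual analogue scale before
rating either their *expected* or their *perceived* intensity of a heat
or visual-contrast stimulus. The package is aimed at researchers who run
or reanalyze such experiments and need the whole chain — constrained cue
generation, the cue-weighting expectation model, per-subject fitting,
group statistics, trial-level mixed models, prediction-error boundary
analyses, and multilevel bootstrap mediation — under one tested roof.
Because no participant data are publicly deposited for this paradigm, a
synthetic-agent module generates cohorts with the exact statistical
structure the analyses assume, so every stage is validated end to end.

## The model

Given cue values V₁…V₁₀, rescale per cue to [0, 1] and demean to get
Xᵢ. Each value's weight combines a **power term** capturing inlier vs.
outlier weighting and a **logistic term** capturing below- vs.
above-mean weighting:

    Wkᵢ = |Xᵢ|^(k−1) / Σⱼ |Xⱼ|^(k−1)          k ∈ (0, 1000]
    Wbᵢ = 1 / (1 + exp(−b·Xᵢ))                 b ∈ [−1000, 1000]
    Wᵢ  = (Wkᵢ + Wbᵢ) / Σⱼ (Wkⱼ + Wbⱼ)
    Expectation = Σᵢ Vᵢ · Wᵢ

k = 1 and b = 0 reduce the expectation to the arithmetic cue mean;
k > 1 over-weights outliers, b < 0 over-weights low values (e.g.
"safety signals" in pain). The two parameters are estimated per subject
and modality by bounded multi-start nonlinear least squares on the
trial-level ratings. See `docs/methods.md` for every numerical
convention and design decision.

## Worked example

```python
import numpy as np
import cueweight as cw

rng = np.random.default_rng(7)

# a positively skewed cue: mean 50, SD 12.5, one injected outlier
cue = cw.generate_cue(cw.CueSpec(50, 12.5, "positive"), rng)
print(np.round(cue.array, 1))
print("skewness:", round(cue.skewness, 3))

# an outlier-over-weighting, low-value-favoring observer
params = cw.WeightParams(k=1.66, b=-1.64)
print("cue mean:", round(cue.array.mean(), 2),
      "model expectation:", round(cw.expected_value(cue.array, params), 2))

# simulate a participant over the 360-trial expectation task and refit
design = cw.make_expectation_design(rng, n_reps=6)
agent = cw.AgentParams(weights={"pain": params, "vision": params},
                       noise_sd=6.0)
trials = cw.simulate_expectation_ratings(design, agent, rng)
fit = cw.fit_weight_params(trials)
print(f"recovered k={fit.k_hat:.2f} b={fit.b_hat:.2f} "
      f"r={fit.r_overall:.3f} rmse={fit.rmse:.2f}")
```

Output:

```
[48.6 53.2 44.8 37.3 42.5 36.2 49.5 72.8 42.  73. ]
skewness: 1.12
cue mean: 50.0 model expectation: 47.87
recovered k=2.44 b=-1.40 r=0.916 rmse=6.20
```

The generated cue has exactly the requested mean and SD, skewness well
past the > 0.3 band, and two clear high outliers. For this observer the
expectation (47.9) falls below the cue mean: b = −1.64 pulls weight
toward low values, and here that outweighs the extra weight k = 1.66
places on the high outliers. Refitting the simulated ratings recovers
the generating parameters to the noise-limited precision documented in
`docs/methods.md` — b tightly, k more loosely (its weight-mass share is
small) — with a predicted-vs-observed correlation of .92 and an RMSE on
the scale of the injected rating noise (6 VAS points).

A full synthetic study — cohort simulation, exclusions, fitting, group
tests, persistence and boundary models, mediation — runs with:

```sh
cueweight run-all --seed 1 --out-dir out/
```

which writes every intermediate table (trial CSVs, weight fits, a
k/b recovery report, mixed-model coefficient tables, mediation paths)
plus `summary.json`. Individual stages are exposed as `design`,
`simulate`, `fit`, `analyze`, `mediate`, and `recover` subcommands.

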