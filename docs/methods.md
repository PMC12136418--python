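# Methods

## The scientific setting

Participants in distribution-cue experiments are shown ten alleged prior
ratings ("a cue") on a 0–100 visual analogue scale (VAS) before rating
either their *expected* intensity of an upcoming stimulus (expectation
task) or the *perceived* intensity of a delivered stimulus (cued-perception
task: heat pain at 47/48 °C or checkerboards at 50/60 % contrast). Cue
mean, spread and skewness are manipulated factorially, which makes it
possible to ask how people aggregate a distribution of social information
into a single expectation, and how that expectation shapes perception.
`cueweight` implements the full analysis chain for such designs, plus a
synthetic-agent generator so every stage can be exercised and validated
without participant data (none are publicly deposited for this paradigm).

## Cue generation

A cue is ten values with exact target mean M ∈ {30, 40, 50, 60, 70} (or
{30, 70} in the cued task), exact target SD ∈ {5, 12.5}, and a skewness
class: sample skewness < −0.3 (negative), > 0.3 (positive) or within
±0.035 (symmetric). Skewness uses the adjusted Fisher–Pearson
(bias-corrected) estimator.

Construction: symmetric cues are 10 normal draws. Skewed cues are 9
log-normal draws — shape parameter chosen so the base distribution's
theoretical skewness is 1, reflected about their mean for negative skew —
plus one injected extreme value placed uniformly 2.0–2.5 SDs of the nine
draws above (positive) or below (negative) their mean, guaranteeing at
least one clear outlier per skewed cue. Draws are then standardized by a
positive affine map to the exact target mean and SD; affine maps preserve
skewness, so only the skewness band and the [0, 100] range need an
accept–resample loop (default budget 10,000 attempts per cue; the loop
draws candidates in vectorized batches, which changes speed only).

Numerical conventions worth noting:

* SDs in the standardization and the extreme-value injection are
  population (ddof = 0) SDs. The convention is fixed by requiring that
  standardizing {0, 1} to mean 50 / SD 5 yields exactly {45, 55}.
* The injected extreme's offset is defined in the 9-draw frame. After the
  tenth value joins, the 10-sample mean moves toward it and the 10-sample
  SD grows, so its distance in final-sample SDs is necessarily smaller
  (≈ 1.7–2.1). The leave-one-out z-score, which is what the construction
  controls, is affine-invariant and survives standardization exactly.
* Cue values are continuous (no rounding to whole VAS points) and are
  kept in range by resampling, never by clipping, which would distort
  moments.
* A spec whose extreme value cannot fit in [0, 100] (e.g. mean 2, SD
  12.5, negative skew) is infeasible; the generator reports it rather
  than looping forever.

## Task designs

* Stimulus–response (calibration): one pain and one vision block, 25
  trials each — 5 intensities (45–49 °C; 5/27.5/50/72.5/95 % contrast)
  × 5 repetitions, shuffled within block.
* Expectation: modality × M(5) × SD(2) × skew(3), 6 repetitions → 360
  trials in six blocks, three consecutive blocks per modality (order
  randomized per design; counterbalancing across participants arises from
  per-subject seeding). Repetitions are dealt evenly across a modality's
  three blocks, then shuffled within block. Every trial carries a freshly
  generated cue.
* Cued perception: modality × intensity(2) × M(2) × SD(2) × skew(3), 3
  repetitions → 144 trials in six 24-trial blocks, each block two
  single-modality mini-blocks of 12 with randomized mini-block order.

All designs are balanced factorials, so factor codes are exactly
orthogonal, and byte-reproducible from a seeded generator.

## The expectation model

For cue values V_1..V_10, rescale to [0, 1] per cue (min–max), demean to
get X_i, then

* power weight: Wk_i = |X_i|^(k−1), sum-normalized; k ∈ (0, 1000].
  k = 1 weights all values equally, k > 1 over-weights outliers, k < 1
  over-weights inliers.
* logistic weight: Wb_i = 1 / (1 + exp(−b·X_i)); b ∈ [−1000, 1000].
  b < 0 favors values below the cue mean, b > 0 above.
* combined: W_i = (Wk_i + Wb_i) / Σ_j (Wk_j + Wb_j).
* expectation: Σ_i V_i·W_i — a convex combination of the cue values.

Choices where the printed formulation is ambiguous:

* The power-term exponent is read as |X|^(k−1). This is the only reading
  under which k = 1 gives equal weights and the sum normalization is
  well-defined for every cue (a signed |X|^k variant has a normalizer
  that can vanish for symmetric cues). The signed variant remains
  available as `power_form="signed"` for sensitivity analysis.
* "Rescaled to [0, 1]" is implemented per cue (min–max), making the
  weight profile scale-free across cues; dividing by 100 instead is a
  one-line change callers can apply before the weight functions.
* |X_i| is floored at ε = 1e−6 before exponentiation so k < 1 never hits
  the singularity at a value exactly on the cue mean.

A structural property worth knowing: the logistic weights sum to ≈ 5
while the normalized power weights sum to 1, so the power term carries
about 1/6 of the combined weight mass. Between extreme k values the model
expectation moves by only ~1.5 VAS RMS over typical factorial cues —
k is therefore intrinsically harder to estimate than b at realistic
noise levels (see Fitting).

## Synthetic agents

An agent holds per-modality (k, b), an integration weight w ∈ [0, 1], a
rating-noise SD, optional block/trial drift (VAS per z-unit), and a
subjective intensity map. Defaults mirror the study conditions: 45
agents, 360 expectation trials (180 per modality), 144 cued trials,
noise SD 6 VAS points (the scale of the empirically reported model
RMSE, ≈ 5.9 pain / 6.4 vision); cohorts draw k log-normally around the
reported medians (1.66 pain, 1.47 vision; log-SD 0.4) and b normally
around −1.64 / 0.16 (SD 2).

Generative equations: expectation ratings are the model expectation plus
Gaussian noise; perception ratings are w·E_cue + (1−w)·S_subj + drift +
noise; all ratings clip to [0, 100]. The subjective map defaults to
simple monotone placeholders (pain: 10 + 15·(T − 45) VAS; vision:
contrast read out as VAS). The perception model is a single configurable
integration observer — a declared stand-in, not a reimplementation of
any particular multi-model comparison — and includes no learning, so
simulated cue effects do not decay unless drift is configured.

What passing tests on these agents do show: the estimator, the coding,
the mixed-model machinery and the mediation procedure recover the
generating structure they assume. What they cannot show: that real
raters follow the weighting model, or realistic violations (lapses,
scale-use habits, sequential dependencies) beyond Gaussian noise and
linear drift.

The cued task presents 60 % contrast, which the calibration task does not
sample; subjective values there are linearly interpolated per subject
over the calibrated levels.

## Fitting

(k, b) are estimated per subject (and modality) by nonlinear least
squares on the trial-level ratings. The search runs on (log k, b) — k
spans three orders of magnitude — with a multi-start grid log k ∈
{−1, 0, 1, 2} × b ∈ {−10, 0, 10} plus 5 seeded random restarts, each
refined by bounded trust-region least squares (ftol 1e−8). Near the
equal-weighting observer the objective is nearly flat in k; among optima
within 1e−6 SSE of the best, the solution minimizing |log k| + |b| is
reported, so output is reproducible. Fit quality is summarized by
Pearson r and RMSE of predicted vs. observed ratings, plus r within each
cue-mean level (the between-level spread otherwise inflates the overall
correlation).

Recovery at the default study scale (noise SD 6, 360 trials pooled per
agent): rank recovery is strong for b (Spearman ≈ 0.98) and good for k
(Spearman ≈ 0.8–0.85); the median |log(k̂/k)| is ≈ 0.24 with
cohort-to-cohort SD ≈ 0.08. The k limit is structural (see the weight-
mass note above), not an optimizer artifact: the returned optimum's SSE
never exceeds the SSE at the generating parameters, and noiseless data
are recovered to < 1e−3.

## Perception analyses

* RT exclusions: trials with rt < 0.2 s or > 4.5 s are dropped (strict
  inequalities); missing RTs are kept and counted.
* Coding: two-level factors ±1; skewness as two dummies vs. the
  symmetric reference; numeric predictors and the rating response
  z-scored.
* Mixed models: statsmodels MixedLM. Starting from the maximal
  random-effects structure, the ladder on convergence trouble is (1)
  correlated random slopes, (2) the same slopes as independent variance
  components (correlations dropped), (3) components with near-zero
  variance removed, (4) random intercept only; the structure used is
  recorded on the result. p-values are Wald-normal with residual df
  reported — not Satterthwaite; on balanced synthetic data fixed effects
  match OLS, which the tests verify.
* Persistence: rating ~ cue-mean × z(trial across task, per modality),
  plus the cue-mean effect in the last block alone.
* Boundary effects: subjective stimulus value = per-cell mean
  calibration rating; cue PE = subjective value − cue mean; experienced
  PE = rating − subjective value (the identity experienced PE +
  subjective value = rating holds by construction). The polynomial model
  regresses experienced PE on non-centered cue-PE powers (cubic; the
  complex variant adds the quartic, per-modality trial, and power ×
  trial interactions) with random intercepts only. Collinearity among
  raw powers is expected and deliberately not "fixed"; internally
  columns are rescaled by constants for conditioning and estimates
  mapped back, which leaves the model unchanged.
* Cross-modality consistency: per-subject cue-mean slopes (per-subject
  OLS by default; mixed-model BLUPs optionally) correlated across
  modalities with a Fisher-z 95% CI.

## Group statistics

Two-sided Wilcoxon signed-rank vs. a reference (exact null for ≤ 25
effective values and no ties, normal approximation with continuity
correction otherwise; zero differences dropped by default, Pratt's
method optional) and two-sided Spearman correlation (exact permutation
enumeration for n ≤ 9, t-approximation above; average ranks for ties).
The method actually used is recorded in each result. Outlier screening
removes scores > 3.5 SDs from the mean in a single pass — mean and SD
are computed once, before any removal.

## Mediation

Trial-level X (cue-based expectation or intensity), M (mediator score),
Y (rating) are z-scored across the pooled sample; within each subject,
OLS gives a_j (M ~ X + covariate) and b_j, c′_j (Y ~ M + X + covariate);
rank-deficient subjects are excluded. The group step resamples subjects
with replacement (default 10,000 draws) and recomputes mean a, mean b,
mean a_j·b_j and mean c′; the two-sided p is the symmetric bootstrap
tail proportion min(P(θ* ≤ 0), P(θ* ≥ 0))·2 capped at 1, the SE is the
bootstrap SD, and point estimates come from the observed sample. The
subject-level (rather than hierarchically weighted) bootstrap is a
declared design choice. For OLS with shared covariates the decomposition
c = c′ + a·b holds exactly per subject, which the tests exploit.

## Pipeline and reproducibility

`run_pipeline` chains design → simulate → exclude → fit → group stats →
perception analyses → mediation, writing every intermediate table (CSV
with `# seed=…`/`# config_hash=…` header lines) plus a recovery report
(k_true, k_hat, b_true, b_hat, r, rmse) and `summary.json`. All
randomness flows from the single config seed; reruns are byte-identical
apart from the embedded config hash. The mediation stage uses a
synthetic trial-level mediator (M = 0.5·z(X) + 0.5·z(intensity) +
noise), since the study's mediators are brain-signature scores that
require imaging data.

Problem sizes in the shipped tests keep the suite quick while staying at
the study's per-subject scale: recovery uses 20-agent cohorts at the full
360-trial design; calibration checks use 2,000 Wilcoxon null draws at
n = 45 and 200 null mediation datasets at 1,000 bootstrap draws each;
the pipeline smoke test runs 3 agents at one repetition per cell.

## Known limitations

* The perception observer is linear-integration only; no learning or
  attention dynamics, so model-comparison questions about cue
  down-weighting over time are out of scope.
* Mixed-model p-values are asymptotic (Wald-normal); small-sample df
  corrections are not implemented.
* k's estimation precision is bounded by the model's own weight-mass
  structure at realistic noise; studies needing tight k estimates would
  require more trials or lower-noise ratings.
* The generator's constraints are per-cue; it does not impose joint
  constraints across a block (e.g. exact orthogonality of realized cue
  moments with other factors beyond the factorial structure).
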