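# Methods

## Task protocol

A session is 480 trials in six 80-trial blocks, each with 20 stop, 40
go-shape and 20 go-image trials (25% stop trials, preserving response
prepotency). Blocks 1–3 run under one stop-valence instruction
("stop for pleasant images" or "stop for unpleasant images"), blocks
4–6 under the other; the order alternates across participants
(counterbalancing). Stop trials show an image of the instructed
valence after the stop-signal delay (SSD); go-image trials show an
image of the opposite valence after a delay yoked to the SSD of the
most recent stop trial in the current half (before any stop trial has
run, the staircase starting value is used). Go-image outcomes never
feed back into the staircase.

Each stop-valence condition has its own SSD staircase: one-up/one-down
in 50 ms steps, starting at 250 ms, clamped to [50, 950] ms. Successful
inhibition lengthens the next delay, a failed stop shortens it, so the
long-run inhibition rate converges to 50%. The staircase starts fresh
exactly once per condition — when the instruction changes between
blocks three and four — and is otherwise continuous across block
boundaries. Because each step is ±50 ms and the delay returns near its
equilibrium, the inhibited-trial count over a long run is almost
invariant to the noise seed (each inhibition must eventually be paired
with a failed stop for the delay to return), which is why the
equilibrium check is so stable.

Trial-type order within a block is a seeded constrained shuffle: the
first two trials are go-shape and runs of non-go-shape trials are
capped at two. These constraints are not dictated by the task design
beyond "pseudo-randomized"; they encode the prepotency intent and are
configurable (`TaskSpec.n_leading_go_shape`,
`max_consecutive_non_shape`). Non-shape slots are allocated into the
gaps between go-shape trials by capacity-limited random placement,
avoiding the rejection sampling that the raw constraint would make
astronomically slow. Each scene image (120 pleasant + 120 unpleasant
synthetic identifiers by default) occurs exactly once per session.

Timing semantics: responses are accepted until the end of the 3,000 ms
trial window on every trial type; go responses slower than the 1,000 ms
maximum go RT are retained as (slow) correct responses rather than
omissions, and an ex-Gaussian draw beyond the trial window counts as an
omission. Whether a late response should instead score as an omission
is unknowable from the protocol description alone; retaining it is the
default and the scoring is localized in `run_session`.

## Generative participant model

Participants are parameter sets for the independent race model:

| parameter | meaning | younger / older template |
|---|---|---|
| `go_mu`, `go_sigma`, `go_tau` (ms) | ex-Gaussian go finishing time on shape discrimination | 580/80/150 vs 650/70/147 |
| `image_appraisal_shift` (ms, per valence) | extra time to appraise a go-image before completing the response | 108–161 vs 160–222 |
| `ssrt_mean`, `ssrt_sd` (ms) | stop-process finishing time, normal truncated at 0 | 215/40 vs 253/45 |
| `p_go_omission` | go response never emitted | 0.019 vs 0.028 |
| `p_choice_error` | wrong key on a shape response | 0.010 vs 0.013 |
| `p_trigger_failure` | stop process fails to launch | 0 (both) |
| `p_image_wrong_action` (per valence) | withhold or mis-key on a go-image | 0.025–0.035 vs 0.035–0.075 |
| `p_rating_agreement` (per valence) | post-task rating matches the normative label | 0.98–0.99 vs 0.96–0.99 |

Between-subject dispersion is normal around the template (probabilities
clipped to [0, 1], scales floored at small positive values);
`dispersion_scale=0` recovers the template exactly. The presets are
calibrated so that simulated default cohorts land within ±10% of the
target descriptive regime (go-shape RT ≈ 733/797 ms, SSRT ≈ 215/253 ms,
go-image RTs ≈ 840–1020 ms, omissions ≈ 2–3%), with the asymmetric
valence effect on go-image accuracy concentrated in the older group;
the calibration check is a test
(`tests/test_io_cli.py::TestCohortCalibration`) and the `reproduce` CLI
command prints the resulting descriptives table.

On a stop trial the racing go process is the **plain
shape-discrimination ex-Gaussian, without the image-appraisal shift**.
This is the package's deliberate reading of the race: the image at SSD
is the stop cue, and the time to recognise and appraise it is part of
the stop latency, not of the go process already underway. It is also
the only reading consistent with the two properties the model must
exhibit jointly — context independence (signal-respond RTs are a
censored sample of the go-shape RT distribution, hence faster than
go-shape means) and recoverability of the generating stop latency by a
go-shape-based integration estimator. With the appraisal shift inside
the race, the estimator would be biased downward by roughly the shift
(150–220 ms), which no block-averaging could repair.

Not emulated (hence not demonstrated by passing tests): sequential
dependencies (post-stop slowing), within-block fatigue or strategic
slowing trends, RT–accuracy trade-offs, and any genuine effect of image
valence on stopping speed — the generator encodes a null valence effect
on SSRT by construction, which is what makes the type-I-rate check
meaningful. Proactive slowing is representable only through the block
structure, not generated.

## SSRT estimation

Integration method per block: replace each go-shape omission by the
maximum allowable go RT (1,000 ms), keep choice-error RTs in the
distribution (configurable `include_choice_errors`), sort, take the
value at 1-based rank `ceil(p_respond × N_go)`, and subtract the mean
SSD over all of the block's stop trials regardless of outcome. The
per-condition SSRT is the unweighted mean of block SSRTs over retained
blocks (minimum two per instruction). Only go-shape trials enter the
go distribution — go-image trials have different perceptual demands
and their own accuracy analysis.

Conventions that the protocol description leaves open are surfaced as
flags rather than silently fixed: the rank rule (`ceiling`, the
conservative consensus choice, vs `interpolate`, the linearly
interpolated empirical quantile) and choice-error inclusion. Blocks
with p(respond) of exactly 0 or 1 leave the quantile unidentified and
raise; the QC stopping-accuracy band excludes them upstream.

Validation: exact agreement with an independently coded
sort-and-count oracle on 200 random small blocks; cohort-level
parameter recovery through the full protocol (30 participants per
preset) with |bias| ≤ 15 ms and group ordering preserved. The ceiling
rank and the omission replacement both push estimates slightly upward;
at these trial counts (40 go / 20 stop per block) the net cohort bias
measured in the recovery test is ≈ +10 ms for the younger preset and
≈ 0 ms for the older.

## Data-validity rules

* participant level: excluded when the go-image miss rate (any
  non-correct outcome: omission, incorrect withhold, wrong key) exceeds
  33% for either valence; the 33% boundary itself is retained.
* block level: dropped when go-image accuracy < 66% (all go-image
  trials in the denominator) or stopping accuracy falls strictly
  outside the inclusive 25–75% band. The go-image rule is evaluated
  first and gives the primary label when both fire. The two rules are
  order-independent and idempotent.
* estimability: a participant-condition needs ≥ 2 retained blocks.
* race-model check: per participant and condition, mean signal-respond
  RT must be below the mean RT of each go trial type (go-shape,
  pleasant go-image, unpleasant go-image), with cohort-level paired
  t-tests; participants without signal-respond trials are skipped with
  a flag. Go-shape RTs under 150 ms are counted as an anticipation
  diagnostic, not an exclusion.

On clean default cohorts, exclusions are rare (< 5% of blocks; the
seed-2024 cohort used in the tests drops 3 of 474 blocks and no
participants).

## Inference layer

* t-tests are computable from summary statistics (mean, SD, n) or raw
  samples; pooled df = n₁+n₂−2, Welch uses the Welch–Satterthwaite df.
  Cohen's *d* uses the pooled SD in both variants, so the effect size
  printed alongside a Welch test matches the pooled-SD convention of
  the common reporting style. All p-values are two-tailed.
* the Levene gate uses mean-centred Levene at α = 0.05 to choose
  pooled vs Welch.
* the 2×2 mixed ANOVA uses the classical split-plot decomposition:
  group is tested against subjects-within-groups; condition and the
  interaction against the condition × subject-within-groups residual.
  Group sizes may differ (weighted-mean sums of squares; exact
  agreement with `pingouin.mixed_anova` including unbalanced cases,
  and with a design-matrix least-squares oracle to 1e-8 on balanced
  toys). Partial eta squared is SS_effect / (SS_effect + SS_error) per
  stratum. Degenerate strata (zero effect SS) report F = 0, p = 1.
* the mixed ANCOVA enters the subject-level covariate (e.g. the
  affective bias score) in the between-subjects stratum only — subject
  means modelled as intercept + covariate + group, group tested by
  Type-III SS with N−3 error df. Covariate × factor interactions are
  excluded by design, so within-subject effects are unchanged; the
  alternative (covariate interacting with the repeated factor) would
  additionally adjust the within stratum and is intentionally not
  implemented. A constant covariate falls back to the plain ANOVA with
  a warning; a covariate collinear with group absorbs the group effect
  (F → 0) rather than erroring, via minimum-norm least squares.
* power for the within-between interaction uses the noncentral F with
  df₁ = (g−1)(m−1)ε, df₂ = (N−g)(m−1)ε and noncentrality
  λ = f²·N·(m·ε)/(1−ρ) — the repeated-measures convention of the
  standard power tools, in which the measurement correlation ρ boosts
  the effective effect. ρ = 0.5 and ε = 1 are the conventional defaults
  and are explicit `PowerSpec` fields, not hidden constants. The
  minimum N search steps by one from the smallest N with df₂ ≥ 1.

## Affective bias

Per participant: agreement with the normative valence label is the
fraction of images rated identically to the label, split by normative
valence; bias = agree(pleasant) − agree(unpleasant) ∈ [−1, 1], positive
when unpleasant images are pulled toward pleasant ratings. Rating
non-responses are dropped from numerator and denominator with a logged
count. Bias is antisymmetric under a global valence-label swap.

## Randomness and reproducibility

One root seed per cohort; per-participant child streams for schedule,
parameter sampling, session noise and ratings are spawned via
`numpy.random.SeedSequence` with fixed spawn keys, so the trial
schedule is invariant to participant parameters and every artifact is
byte-identical across reruns of the same seed. Negative draws from the
truncated distributions are resampled, not clipped, so finishing-time
distributions have no atom at zero.

## Problem sizes used in validation

The staircase-equilibrium check uses 1,500–2,000 staircase-tracked
stop trials with a 20-trial burn-in (50% ± 3 percentage points).
Parameter recovery uses 30 participants per preset through the full
480-trial protocol. The cohort-level inference pattern uses 500
replicate cohorts of N = 79 (39 younger / 40 older): the age main
effect on SSRT must reject in > 80% of replicates and the (truly null)
valence effect near the nominal 5% rate. These sizes give Monte-Carlo
standard errors comfortably inside the asserted bands (binomial SE
≈ 1.5 percentage points at 500 replicates).

## Known limitations

* The generator's ex-Gaussian + truncated-normal forms are a
  field-standard emulation, not a fitted model of any particular data
  set; absolute descriptives should be read as regime-level, not
  subject-level, realism.
* No likelihood-based race-model fitting (no BEESTS-style estimation,
  no trigger-failure-corrected SSRT); `p_trigger_failure` exists for
  robustness experiments but the estimator does not correct for it.
* The mixed ANCOVA's covariate adjustment is between-subjects only, by
  design (see above).
* QC reproduces decision rules, not clinical screening; recruitment-
  stage exclusions are out of scope.
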