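# Methods

## The task being emulated

One session of the oculomotor Simon task is 5 blocks × 60 trials. Each
trial shows a central fixation point for 875–1250 ms (uniform over 125-ms
steps), then a blue or yellow target at ±12° of visual angle for 1000 ms.
The color→direction mapping (e.g. blue = saccade left) is fixed per
participant and alternates across participants; the four color × side
combinations are balanced within every block, so half the trials are
congruent (instructed direction = target side) and half incongruent. Gaze
is sampled at 300 Hz; only the horizontal channel is analyzed.

## The decision model

The simulator is a conflict diffusion model: a single evidence variable
X(t) integrates a controlled route and a direct (automatic) route,

    X ← X + μ_c·Δt + s·g·[a(t+Δt) − a(t)] + σ·√Δt·ε,     Δt = 1 ms,

with a response emitted at the first t where |X| ≥ b. Positive crossings
are the instructed (correct) response; s = +1 on congruent and −1 on
incongruent trials, so the automatic pulse a(t) initially drives the
response toward the target's physical location. The base pulse is

    a(t) = A·(t/τ)·exp(1 − t/τ) − r·A·(t/cτ)·exp(1 − t/cτ),

a gamma-like surge peaking near t = τ (value ≈ A), minus a slow, small
rebound (fraction r, time scale c·τ) representing selective inhibition
overshooting: late in the trial the *net* automatic contribution is
slightly negative, which is what lets the congruence effect keep shrinking
— and cross zero — for the slowest responses, as empirical Simon delta
plots often do.

Trial-to-trial variability is essential to the distributional signatures
and enters in four places:

- **pulse gain** g ~ max(0, N(1, a_cv²)): high-gain trials are genuine
  response-capture events — very fast correct responses when congruent,
  fast errors when incongruent. This is what puts the delta-plot maximum in
  the first septile; without it, fast correct incongruent trials are the
  noise-lucky ones and the delta plot peaks in bins 2–3 instead;
- **pulse time scale** τ ~ lognormal(median τ, tau_log_sd): spreads the
  pulse decay over the whole RT range so the delta plot declines smoothly
  through the late bins rather than flattening at zero;
- **starting point** X(0) ~ N(0, start_sd²), truncated at ±0.9·b;
- **non-decision time** t0 ~ N(t0_mean, t0_sd²) per trial. RT = bound
  crossing time + t0, and the ground-truth saccade onset is placed at RT
  (non-decision time ends at saccade onset, so RT is saccade latency).

A stimulus-independent **lapse** flips the response side on a small
fraction of trials at unchanged latency. It represents attention slips and
keeps congruent accuracy realistically below ceiling (~95–96% instead of
~99.9%), which matters both for realism and for keeping the logistic
mixed models away from quasi-separation.

Participant-level random effects are drawn once per participant: drift
μ_c,p ~ N(μ_c, sd_mu_participant²) (floored at 0.02 evidence/ms) and
t0_mean,p ~ N(t0_mean, sd_t0_participant²) (floored at 60 ms).

Trials not reaching the bound by 1500 ms are no-response trials; they are
rendered without a saccade and excluded downstream as missing.

### Default parameters

| parameter | default | unit | role |
|---|---|---|---|
| μ_c | 0.50 | evidence/ms | controlled drift |
| b | 75 | evidence | symmetric decision bound |
| σ | 3.2 | evidence/√ms | diffusion noise |
| A | 31 | evidence | peak automatic activation |
| a_cv | 0.85 | — | trial CV of pulse gain |
| τ | 20 | ms | median pulse time-to-peak |
| tau_log_sd | 0.55 | — | lognormal SD of τ |
| rebound r | 0.06 | — | suppression-overshoot fraction |
| rebound scale c | 20 | ×τ | overshoot time scale |
| start_sd | 8 | evidence | starting-point SD |
| lapse_rate | 0.04 | — | side-flip probability |
| t0_mean, t0_sd | 150, 10 | ms | non-decision time |
| sd_mu_participant | 0.025 | evidence/ms | between-participant drift SD |
| sd_t0_participant | 20 | ms | between-participant t0 SD |

The defaults were chosen by coarse grid search so that a 43-participant
session reproduces the canonical Simon-task summary statistics: mean
correct-trial RT ≈ 290 ms; a congruence effect of ~23–30 ms (literature
range 20–30 ms); an overall accuracy difference of ~5 points; first-septile
incongruent accuracy depressed by ≥ 30 points while septiles 3–7 differ by
< 5 points; and an aggregate delta plot strictly decreasing from bin 1 to
bin 7. These targets act as calibration bands, not fitted data: no real
recordings enter the package. Setting a_cv, tau_log_sd, rebound, start_sd,
and lapse_rate to 0 recovers the bare pulse-plus-drift accumulator.

The Euler step is 1 ms — well below the 3.33-ms sample period and adequate
for RT-scale dynamics; the noise-free closed form (RT = ⌈b/μ_c⌉ + t0 with
A = 0, σ = 0) is exact under this discretization and asserted in the tests.

## Trace rendering

Fixation samples sit at 0° plus Gaussian positional noise
(trace_noise_deg, default 0.05°). At the ground-truth onset the eye moves
to ±12° along a minimum-jerk position profile with main-sequence duration
2.2 ms/deg · amplitude + 21 ms (≈ 47 ms for 12°, analytic peak velocity
1.875·amplitude/duration ≈ 475°/s). Right is positive; target onset is
t = 0. The y channel is pure noise (no vertical saccades are simulated).

## Saccade detection

Velocity is the Savitzky–Golay first derivative (window 7 samples ≈ 23 ms,
order 2) scaled to deg/s; edges use the filter's polynomial extrapolation
and are excluded from event candidacy (half-window margin) because their
noise is inflated. The peak threshold PT iterates mean + 6·SD over samples
with |v| ≤ PT from a 100 deg/s start until the change is < 1 deg/s; the
statistics are taken over signed velocities, whose fixation distribution is
zero-mean, so the fixed point sits near 6× the noise SD. Onset/offset are
found by walking outward from each suprathreshold run to the first sample
below a locally estimated noise threshold (pre-target fixation mean +
3·SD, floored at 10 deg/s — below that, drift and tremor dominate). Runs
closer than 20 ms merge; events shorter than 10 ms are dropped. On
synthetic traces with 0.1° noise this recovers > 99% of true onsets within
2 samples with no false positives on response-free traces.

## Trial analysis and exclusions

The response is the first saccade with onset ≥ 0 and amplitude ≥ 2°;
smaller movements are fixational micro-saccades and are skipped rather than
voiding the trial. A trial is correct when the response direction matches
the side instructed by the target's color. Exclusions: no response;
latency strictly < 100 ms (anticipations) or strictly > 1000 ms (beyond
target presentation) — boundary values are kept; then one non-iterated
3-SD pass on each participant's surviving RTs, pooled across congruence
conditions (per-participant is the field convention and matches the
per-participant binning downstream; the alternative interpretations are
exposed as parameters). On default synthetic sessions ~1% of trials are
excluded.

## Distributional statistics

Septile binning is vincentized: each participant × condition's RTs are
rank-ordered (stable sort; ties keep input order) and split into 7 bins
whose sizes follow the largest-remainder rule (earlier bins take the extra
trials). The CAF keeps error trials and reports accuracy per bin; the
delta plot uses correct trials only, bins each condition separately, pairs
bins by rank, and reports Δ_k = mean RT_incongruent,k − mean RT_congruent,k
with the midpoint of the two means as the x-coordinate. Aggregation across
participants is an unweighted mean of per-participant bin values, with
across-participant SEs.

## Inference

- RT ~ congruence: Gaussian LMM, participant random intercept, REML
  (statsmodels MixedLM), correct included trials. The test is a Wald F with
  residual-df denominator (matching the very large denominators this
  analysis tradition reports); exact denominator-df methods
  (Satterthwaite/Kenward–Roger) are out of scope.
- accuracy ~ congruence, and ~ congruence × bin (both categorical):
  logistic mixed model with participant random intercept, maximum
  likelihood with a Laplace approximation of the marginal likelihood. The
  solver is implemented in-package (inner damped Newton per participant;
  outer L-BFGS-B over fixed effects and log σ_u; covariance from a
  high-accuracy numerical Hessian) because the Python stack offers no
  frequentist GLMM; the test suite cross-checks estimates and SEs against
  R lme4 (lmer/glmer) on fixture data. Complete separation raises a
  diagnostic error.
- Post hoc congruence-within-bin contrasts come from the fitted 2 × 7
  model's coefficients and covariance, as z-tests with single-step max-|z|
  adjustment: p_adj,k = P(max_j |Z_j| ≥ |z_k|) under the joint normal of
  the contrast estimates (the same family-wise logic as multcomp's glht
  Tukey adjustment); Holm–Bonferroni is the deterministic fallback and the
  choice is recorded in the output. Adjusted p-values are clipped to never
  fall below raw ones.
- delta ~ bin (categorical): Gaussian LMM with participant random
  intercept; the omnibus bin test is a Wald F (chi²/q) with residual-df
  denominator.

## What the generator does and does not emulate

It emulates: balanced pseudo-random designs, jittered fixation periods,
conflict-dependent RT and accuracy with realistic distributional structure
(fast errors, shrinking deltas), participant heterogeneity, positional
trace noise, micro-movement-free fixation, and no-response trials. It does
not emulate: vertical or oblique saccades, pupil dynamics, blinks,
glissades, drift or calibration error, binocular disparity, sequential
effects (post-error slowing, congruence-sequence effects), or
practice/fatigue trends. Passing tests therefore demonstrate that the
analysis stack is correct on data whose generative structure is known —
not that the detector or the models are robust to every artifact of real
recordings.

## Numerical choices and degenerate inputs

- Determinism: all randomness descends from one master seed through
  numpy SeedSequence spawn keys (design stream and per-participant
  simulation streams are independent substreams); identical seeds give
  byte-identical outputs at every level, including the full report bundle.
- Septile ties break by stable input order; with fewer trials than bins
  the empty bins are dropped with a warning.
- The adaptive threshold raises on traces whose every sample exceeds the
  initial PT (degenerate input); an all-zero velocity trace converges to
  PT = 0 in one step.
- Zero between-participant variance is reported with a `singular` flag
  rather than an error; two-participant runs complete with an explicit
  instability warning in the report.
- GLMM optimization uses tight L-BFGS-B tolerances so Wald statistics are
  invariant (to ~1e-4 relative) under categorical relabeling.

## Problem sizes in the test suite

The acceptance tests run the study-scale configuration (43 participants ×
300 trials) where the property under test concerns the default simulation:
100 replicates for the activation-suppression signature, 50 per model for
parameter recovery, and 60 null replicates for error-rate control; the
detection-recovery check uses 1200 rendered trials plus 300 response-free
traces. These sizes give the binomial assertions comfortable margins while
keeping a full `pytest` run to a few minutes.

## Known limitations

- The accumulator is one defensible instantiation of the dual-route
  account, not a fitted model of any participant; its parameters are
  calibration choices.
- The Laplace approximation can understate random-intercept variance when
  clusters are small; here clusters are 300 trials, where Laplace and
  adaptive quadrature agree closely (and lme4 cross-checks confirm).
- Residual-df Wald tests are anti-conservative relative to
  Satterthwaite-corrected tests at small participant counts; with 43
  participants and ≥ 12k trials the difference is negligible for the
  effects of interest.
- The max-|z| adjustment assumes joint normality of the contrast
  estimates, the standard large-sample approximation.
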