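# ocusimon

Simulation and distributional analysis of an **oculomotor Simon task** —
a two-choice conflict paradigm in which participants saccade left or right
according to a target's *color* while ignoring its *location*. When the
location-driven (automatic) response and the color-instructed (controlled)
response disagree, reaction times lengthen and fast errors appear. The
package provides, end to end:

- a **dual-route accumulator simulator** in the activation–suppression
  tradition: constant controlled drift toward the instructed response plus a
  transient automatic activation pulse toward the target's location,
  rendered as 300-Hz horizontal gaze traces with ground truth attached;
- **saccade detection** with Savitzky–Golay velocity estimation and an
  iterative, data-driven peak-velocity threshold (mean + 6·SD of
  sub-threshold samples, iterated to convergence);
- **trial analysis**: the first post-target saccade of ≥ 2° is the response
  (RT = its onset latency); exclusions for no-response trials, latencies
  < 100 ms or > 1000 ms, and per-participant 3-SD outliers;
- **distributional statistics**: vincentized septile bins, conditional
  accuracy functions (CAF) and delta plots
  (Δ<sub>k</sub> = RT<sub>IC,k</sub> − RT<sub>C,k</sub> on correct trials);
- **mixed-effects inference**: RT ~ congruence (Gaussian LMM, REML),
  accuracy ~ congruence and accuracy ~ congruence × bin (logistic GLMM,
  Laplace ML, participant random intercepts), delta ~ bin, with
  single-step max-|z| adjusted post hoc congruence-by-bin contrasts.

It is aimed at researchers who analyze conflict-task eye-movement data and
want a fully synthetic, ground-truth-verifiable test bed for every stage of
that analysis.

## The model in brief

Evidence X(t) evolves in 1-ms Euler steps

```
X ← X + μ_c·Δt + s·[a(t+Δt) − a(t)] + σ·√Δt·ε,   a(t) = A·(t/τ)·e^(1−t/τ)
```

with `s = +1` on congruent and `−1` on incongruent trials; a response is
emitted when |X| ≥ b, and saccade latency is the crossing time plus
non-decision time. The pulse a(t) rises to its peak A at t = τ and decays —
"activation, then suppression". Trial-to-trial variability in pulse
amplitude and time scale, a trial-varying starting point, and a small slow
suppression-overshoot term produce the two distributional signatures of
conflict tasks: depressed first-septile accuracy under incongruence
(response capture) and a delta plot that decreases — eventually below
zero — as responses slow. See `docs/methods.md` for parameter meanings,
units, and defaults.

## Worked example

```bash
ocusimon run --seed 7 --out results/demo
```

runs the default study-scale configuration (43 participants × 5 blocks ×
60 trials, targets at ±12°, 300 Hz) through simulation, detection,
exclusion, distributional statistics, and inference, and prints

```json
{
  "congruence_effect_ms": 28.508650058106355,
  "accuracy_difference": 0.060591038303136835,
  "fraction_excluded": 0.011937984496124031
}
```

i.e. correct incongruent saccades start ~29 ms later than congruent ones,
accuracy is ~6 points lower under conflict, and ~1.2% of trials were
removed by the exclusion rules. `results/demo/` contains the trial table,
CAF and delta tables (per participant and aggregated), the fitted-model
JSON, figures (PNG + SVG with CSV sidecars), the exclusion summary, and a
JSON-lines run log; a second run with the same seed reproduces every number
byte-for-byte.

The same stages are available as library calls (`simulate_session`,
`detect_saccades`, `extract_response`, `apply_exclusions`, `compute_caf`,
`compute_delta`, `fit_rt_lmm`, …) and as individual CLI verbs
(`simulate`, `detect`, `trials`, `dist`, `infer`, `io validate`).

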