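"""Session design generation and dual-route trial simulation.

The simulator implements an activation–suppression style accumulator for a
two-choice oculomotor Simon task: a controlled route contributes constant
drift toward the instructed (correct) side, while a direct route contributes
a transient, pulse-shaped automatic activation toward the target's physical
location.  On congruent trials the pulse helps; on incongruent trials it
pushes toward the wrong response early in the trial, producing fast errors
and a congruence effect that shrinks as responses slow — the two signatures
the distributional analysis downstream is designed to expose.

Decisions are rendered as 300-Hz horizontal gaze traces with a minimum-jerk
saccade waveform so that the saccade-detection stage can be validated against
known ground truth.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace
from typing import Literal

import numpy as np
import pandas as pd

Color = Literal["blue", "yellow"]
Side = Literal["left", "right"]
Congruence = Literal["congruent", "incongruent"]

FIXATION_CHOICES_MS = (875.0, 1000.0, 1125.0, 1250.0)

__all__ = [
    "TrialDesign",
    "SimParams",
    "TrialRecording",
    "generate_design",
    "simulate_decision",
    "simulate_decisions",
    "render_trial_recording",
    "simulate_session",
    "saccade_duration_ms",
    "min_jerk_position",
]


@dataclass(frozen=True)
class TrialDesign:
    """One planned trial of the oculomotor Simon task.

    ``left_color`` encodes the color→direction mapping: a target of that
    color instructs a leftward saccade.  Congruence is fully determined by
    the mapping and the target's physical side.
    """

    participant_id: str
    block: int
    trial: int
    target_color: Color
    target_side: Side
    left_color: Color
    fixation_duration_ms: float
    target_duration_ms: float = 1000.0
    iti_ms: float = 1250.0

    def __post_init__(self) -> None:
        if self.target_color not in ("blue", "yellow"):
            raise ValueError(f"invalid target_color {self.target_color!r}")
        if self.target_side not in ("left", "right"):
            raise ValueError(f"invalid target_side {self.target_side!r}")
        if self.left_color not in ("blue", "yellow"):
            raise ValueError(f"invalid left_color {self.left_color!r}")
        if self.fixation_duration_ms not in FIXATION_CHOICES_MS:
            raise ValueError(
                f"fixation_duration_ms must be one of {FIXATION_CHOICES_MS}, "
                f"got {self.fixation_duration_ms}"
            )

    @property
    def correct_side(self) -> Side:
        """Side instructed by the target's color under this mapping."""
        return "left" if self.target_color == self.left_color else "right"

    @property
    def congruence(self) -> Congruence:
        return "congruent" if self.correct_side == self.target_side else "incongruent"


@dataclass
class SimParams:
    """Parameters of the conflict accumulator and the trace renderer.

    The accumulator evolves in 1-ms Euler steps::

        X <- X + mu_c * dt + s * [a(t + dt) - a(t)] + sigma * sqrt(dt) * eps

    with automatic activation ``a(t) = A * (t / tau) * exp(1 - t / tau)``
    (peaking at ``t = tau`` with value ``A``, minus an optional slow
    suppression-overshoot term controlled by ``rebound``) and ``s = +1`` on
    congruent, ``-1`` on incongruent trials.  A response is emitted when
    ``|X| >= b``; a positive crossing is the instructed (correct) response.
    Saccade latency is the crossing time plus non-decision time.

    Trial-to-trial variability in pulse gain (``a_cv``), pulse time scale
    (``tau_log_sd``), starting point (``start_sd``), and non-decision time,
    plus a stimulus-independent lapse rate, shape the RT distributions;
    setting them to 0 recovers the bare pulse-plus-drift accumulator.
    Defaults are calibrated so a simulated session shows a mean congruence
    effect of roughly 25 ms, an overall accuracy difference of ~5 points,
    strongly depressed first-septile incongruent accuracy, and a delta plot
    that decreases across septiles.  See ``docs/methods.md``.
    """

    mu_c: float = 0.50          # controlled drift, evidence/ms
    A: float = 31.0             # peak automatic activation, evidence units
    a_cv: float = 0.85          # trial-to-trial CV of the pulse amplitude
    tau: float = 20.0           # median time-to-peak of automatic activation, ms
    tau_log_sd: float = 0.55    # trial-to-trial lognormal SD of tau
    rebound: float = 0.06       # suppression overshoot fraction (0 = none)
    rebound_scale: float = 20.0  # time scale of the overshoot, multiples of tau
    b: float = 75.0             # symmetric decision bound, evidence units
    sigma: float = 3.2          # diffusion noise SD per sqrt(ms)
    start_sd: float = 8.0       # SD of trial-varying starting point (evidence units)
    lapse_rate: float = 0.04    # stimulus-independent response-side lapses
    t0_mean: float = 150.0      # non-decision time mean, ms
    t0_sd: float = 10.0         # within-participant non-decision SD, ms
    sd_mu_participant: float = 0.025
    sd_t0_participant: float = 20.0
    eccentricity_deg: float = 12.0
    sample_rate_hz: float = 300.0
    trace_noise_deg: float = 0.05
    cap_ms: float = 1500.0      # trials not terminating by here are no-response
    seed: int | None = None

    def __post_init__(self) -> None:
        for name in ("mu_c", "A", "a_cv", "tau", "b", "sigma", "start_sd",
                     "t0_mean", "t0_sd",
                     "sd_mu_participant", "sd_t0_participant",
                     "eccentricity_deg", "sample_rate_hz", "trace_noise_deg",
                     "cap_ms"):
            v = getattr(self, name)
            if not math.isfinite(v):
                raise ValueError(f"SimParams.{name} must be finite, got {v}")
        if self.b <= 0:
            raise ValueError("decision bound b must be > 0")
        if self.sigma < 0:
            raise ValueError("sigma must be >= 0")
        if self.tau <= 0:
            raise ValueError("tau must be > 0")
        if self.sample_rate_hz <= 0:
            raise ValueError("sample_rate_hz must be > 0")
        if not 0.0 <= self.rebound < 1.0:
            raise ValueError("rebound must be in [0, 1)")
        if not 0.0 <= self.lapse_rate < 0.5:
            raise ValueError("lapse_rate must be in [0, 0.5)")
        if self.rebound_scale <= 1.0:
            raise ValueError("rebound_scale must be > 1")
        for name in ("a_cv", "tau_log_sd", "start_sd", "t0_sd",
                     "sd_mu_participant",
                     "sd_t0_participant", "trace_noise_deg"):
            if getattr(self, name) < 0:
                raise ValueError(f"SimParams.{name} must be >= 0")


@dataclass
class TrialRecording:
    """Gaze-sample trace for one trial, time-locked to target onset (t=0)."""

    design: TrialDesign
    t_ms: np.ndarray
    x_deg: np.ndarray
    y_deg: np.ndarray
    events: dict[str, float]  # fixation_onset, target_onset, target_offset
    # ground truth, synthetic recordings only
    true_rt_ms: float | None = None
    true_side: str | None = None          # 'left' / 'right' / 'none'
    true_onset_index: int | None = None   # first sample at/after saccade onset

    def __post_init__(self) -> None:
        if len(self.t_ms) != len(self.x_deg) or len(self.t_ms) != len(self.y_deg):
            raise ValueError("t_ms, x_deg, y_deg must have equal length")
        for ev in ("fixation_onset", "target_onset", "target_offset"):
            if ev not in self.events:
                raise ValueError(f"missing event {ev!r}")


def generate_design(
    n_participants: int,
    n_blocks: int = 5,
    trials_per_block: int = 60,
    mapping_assignment: str = "alternate",
    seed: int = 0,
) -> list[TrialDesign]:
    """Generate a balanced, pseudo-random session design per participant.

    Each session contains equally many of the 4 (color x side) combinations;
    the color→direction mapping alternates across participants so half
    perform with blue→left and half with yellow→left.  Fixation durations are
    drawn uniformly from 875–1250 ms in 125-ms steps.
    """
    if n_blocks < 1:
        raise ValueError("n_blocks must be >= 1")
    if trials_per_block % 4 != 0:
        raise ValueError(
            f"trials_per_block must be divisible by 4 to balance the "
            f"color x location combinations, got {trials_per_block}"
        )
    if mapping_assignment not in ("alternate", "blue_left", "yellow_left"):
        raise ValueError(f"unknown mapping_assignment {mapping_assignment!r}")

    designs: list[TrialDesign] = []
    combos = [(c, s) for c in ("blue", "yellow") for s in ("left", "right")]
    for p in range(n_participants):
        rng = np.random.default_rng(np.random.SeedSequence(seed, spawn_key=(0, p)))
        if mapping_assignment == "alternate":
            left_color: Color = "blue" if p % 2 == 0 else "yellow"
        else:
            left_color = "blue" if mapping_assignment == "blue_left" else "yellow"
        pid = f"P{p + 1:02d}"
        for blk in range(1, n_blocks + 1):
            order = np.repeat(np.arange(4), trials_per_block // 4)
            rng.shuffle(order)
            fix = rng.choice(FIXATION_CHOICES_MS, size=trials_per_block)
            for i, (combo_idx, f) in enumerate(zip(order, fix), start=1):
                color, side = combos[combo_idx]
                designs.append(
                    TrialDesign(
                        participant_id=pid,
                        block=blk,
                        trial=i,
                        target_color=color,
                        target_side=side,
                        left_color=left_color,
                        fixation_duration_ms=float(f),
                    )
                )
    return designs


def _automatic_pulse(
    t: np.ndarray, A: float, tau: float,
    rebound: float = 0.0, rebound_scale: float = 3.0,
) -> np.ndarray:
    """Automatic-route activation, a gamma-shaped pulse with optional rebound.

    The base shape is ``A * (t/tau) * exp(1 - t/tau)``, which rises to ``A``
    at ``t = tau`` and decays.  With ``rebound > 0`` a slower pulse of the
    same form (time scale ``rebound_scale * tau``) is subtracted, so the net
    automatic contribution overshoots below zero late in the trial — the
    selective-inhibition overshoot that keeps the congruence effect shrinking
    (and eventually reversing) for the slowest responses.
    """
    base = A * (t / tau) * np.exp(1.0 - t / tau)
    if rebound > 0:
        ts = rebound_scale * tau
        base = base - rebound * A * (t / ts) * np.exp(1.0 - t / ts)
    return base


def simulate_decisions(
    n: int,
    params: SimParams,
    congruent: bool,
    rng: np.random.Generator,
    mu_c: float | None = None,
    t0_mean: float | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Vectorized accumulator run for ``n`` i.i.d. trials of one condition.

    Returns ``(rt_ms, correct)``; ``rt_ms`` is NaN (and ``correct`` False)
    for trials that fail to reach the bound by ``params.cap_ms``.
    ``mu_c`` / ``t0_mean`` override the population values (participant-level
    random effects are applied by the caller).
    """
    mu = params.mu_c if mu_c is None else mu_c
    t0m = params.t0_mean if t0_mean is None else t0_mean
    s = 1.0 if congruent else -1.0
    dt = 1.0
    n_steps = int(params.cap_ms)

    t_grid = np.arange(n_steps + 1, dtype=float)
    if params.tau_log_sd > 0:
        # trial-varying pulse time-constant, lognormal around the median,
        # quantized to equal-probability levels so the per-step pulse
        # increments can be precomputed once per level
        from scipy.stats import norm
        n_levels = 12
        q = (np.arange(n_levels) + 0.5) / n_levels
        taus = params.tau * np.exp(params.tau_log_sd * norm.ppf(q))
        level = rng.integers(0, n_levels, size=n)
    else:
        taus = np.array([params.tau])
        level = np.zeros(n, dtype=int)
    pulse_inc = np.stack(
        [np.diff(_automatic_pulse(t_grid, params.A, tv,
                                  params.rebound, params.rebound_scale))
         for tv in taus]
    )
    if params.a_cv > 0:
        # trial-varying automatic-activation strength (response capture
        # on high-gain trials); gain is non-negative
        gain = np.maximum(1.0 + params.a_cv * rng.standard_normal(n), 0.0)
    else:
        gain = np.ones(n)
    coef = s * gain

    if params.start_sd > 0:
        # trial-varying starting point, truncated inside the bounds
        x = np.clip(params.start_sd * rng.standard_normal(n),
                    -0.9 * params.b, 0.9 * params.b)
    else:
        x = np.zeros(n)
    decision = np.full(n, np.nan)
    correct = np.zeros(n, dtype=bool)
    active = np.ones(n, dtype=bool)
    sig = params.sigma * math.sqrt(dt)
    for k in range(n_steps):
        idx = np.flatnonzero(active)
        if idx.size == 0:
            break
        step = mu * dt + coef[idx] * pulse_inc[level[idx], k]
        if sig > 0:
            x[idx] += step + sig * rng.standard_normal(idx.size)
        else:
            x[idx] += step
        crossed = idx[np.abs(x[idx]) >= params.b]
        if crossed.size:
            decision[crossed] = (k + 1) * dt
            correct[crossed] = x[crossed] >= params.b
            active[crossed] = False

    responded = ~np.isnan(decision)
    t0 = t0m + params.t0_sd * rng.standard_normal(n)
    rt = np.where(responded, decision + t0, np.nan)
    correct = correct & responded
    if params.lapse_rate > 0:
        # occasional stimulus-independent wrong-side responses at normal
        # latencies (attention lapses); symmetric across conditions
        lapse = rng.random(n) < params.lapse_rate
        correct = np.where(lapse & responded, ~correct, correct)
    return rt, correct


def simulate_decision(
    params: SimParams,
    congruence: Congruence,
    rng: np.random.Generator,
    participant_effects: tuple[float, float] | None = None,
) -> tuple[float, Side | Literal["none"], bool]:
    """Run one trial; returns (rt_ms, accumulator outcome sign, correct).

    The second element is ``'correct'``-side semantics resolved by the
    caller; here it is reported as ``'right'`` for a positive crossing when
    interpreted on a rightward-correct trial.  Use :func:`simulate_session`
    for design-aware response sides.
    """
    if congruence not in ("congruent", "incongruent"):
        raise ValueError(f"invalid congruence {congruence!r}")
    mu_c, t0_mean = participant_effects if participant_effects else (None, None)
    rt, correct = simulate_decisions(
        1, params, congruence == "congruent", rng, mu_c=mu_c, t0_mean=t0_mean
    )
    if np.isnan(rt[0]):
        return math.nan, "none", False
    return float(rt[0]), ("right" if correct[0] else "left"), bool(correct[0])


def saccade_duration_ms(amplitude_deg: float) -> float:
    """Main-sequence duration rule: 2.2 ms/deg * amplitude + 21 ms."""
    return 2.2 * amplitude_deg + 21.0


def min_jerk_position(frac: np.ndarray) -> np.ndarray:
    """Minimum-jerk normalized displacement profile on [0, 1]."""
    f = np.clip(frac, 0.0, 1.0)
    return 10.0 * f**3 - 15.0 * f**4 + 6.0 * f**5


def render_trial_recording(
    decision: tuple[float, str, bool],
    design: TrialDesign,
    params: SimParams,
    rng: np.random.Generator,
) -> TrialRecording:
    """Render a simulated decision as a horizontal gaze trace.

    ``decision`` is ``(rt_ms, response_side, correct)`` where
    ``response_side`` is 'left', 'right', or 'none'.  The ground-truth
    saccade onset is placed at the decision RT: non-decision time is taken
    to end at saccade onset, so RT is saccade latency.  Responses whose
    onset falls beyond the recording window are rendered without a saccade
    and flagged with ``true_side='none'``.
    """
    rt_ms, side, _correct = decision
    dt = 1000.0 / params.sample_rate_hz
    t0 = -design.fixation_duration_ms
    n_samples = int(math.floor((design.target_duration_ms - t0) / dt)) + 1
    t = t0 + dt * np.arange(n_samples)

    x = np.zeros(n_samples)
    true_rt: float | None = None
    true_side: str = "none"
    onset_index: int | None = None

    has_response = side in ("left", "right") and math.isfinite(rt_ms)
    if has_response and rt_ms <= design.target_duration_ms:
        sign = 1.0 if side == "right" else -1.0
        amp = sign * params.eccentricity_deg
        dur = saccade_duration_ms(params.eccentricity_deg)
        frac = (t - rt_ms) / dur
        x = amp * min_jerk_position(frac)
        true_rt = float(rt_ms)
        true_side = side
        onset_index = int(np.searchsorted(t, rt_ms))
    if params.trace_noise_deg > 0:
        x = x + params.trace_noise_deg * rng.standard_normal(n_samples)
    y = (params.trace_noise_deg * rng.standard_normal(n_samples)
         if params.trace_noise_deg > 0 else np.zeros(n_samples))

    return TrialRecording(
        design=design,
        t_ms=t,
        x_deg=x,
        y_deg=y,
        events={
            "fixation_onset": float(t0),
            "target_onset": 0.0,
            "target_offset": float(design.target_duration_ms),
        },
        true_rt_ms=true_rt,
        true_side=true_side,
        true_onset_index=onset_index,
    )


def simulate_session(
    n_participants: int,
    params: SimParams | None = None,
    n_blocks: int = 5,
    trials_per_block: int = 60,
    seed: int = 0,
    render: bool = True,
) -> tuple[list[TrialRecording], pd.DataFrame]:
    """Simulate full sessions for ``n_participants``.

    Participant-level random effects on drift and non-decision time are
    drawn once per participant from the between-participant SDs in
    ``params``.  Returns the rendered recordings (empty list when
    ``render=False``) and a tidy ground-truth table with one row per trial.
    All randomness descends deterministically from ``seed``.
    """
    params = params if params is not None else SimParams()
    designs = generate_design(n_participants, n_blocks, trials_per_block, seed=seed)
    per_session = n_blocks * trials_per_block

    recordings: list[TrialRecording] = []
    rows: list[dict] = []
    for p in range(n_participants):
        prng = np.random.default_rng(np.random.SeedSequence(seed, spawn_key=(1, p)))
        mu_p = params.mu_c + params.sd_mu_participant * prng.standard_normal()
        mu_p = max(mu_p, 0.02)  # keep drift positive: participants follow task
        t0_p = params.t0_mean + params.sd_t0_participant * prng.standard_normal()
        t0_p = max(t0_p, 60.0)
        p_designs = designs[p * per_session:(p + 1) * per_session]

        cong_mask = np.array([d.congruence == "congruent" for d in p_designs])
        rt = np.full(per_session, np.nan)
        ok = np.zeros(per_session, dtype=bool)
        for is_c in (True, False):
            sel = np.flatnonzero(cong_mask == is_c)
            r, c = simulate_decisions(sel.size, params, is_c, prng,
                                      mu_c=mu_p, t0_mean=t0_p)
            rt[sel], ok[sel] = r, c

        for i, d in enumerate(p_designs):
            if np.isnan(rt[i]):
                side = "none"
            else:
                correct_side = d.correct_side
                wrong_side = "left" if correct_side == "right" else "right"
                side = correct_side if ok[i] else wrong_side
            rows.append({
                "participant_id": d.participant_id,
                "block": d.block,
                "trial": d.trial,
                "congruence": d.congruence,
                "true_rt_ms": rt[i],
                "true_side": side,
                "true_correct": bool(ok[i]) if side != "none" else None,
            })
            if render:
                recordings.append(
                    render_trial_recording((rt[i], side, ok[i]), d, params, prng)
                )
    return recordings, pd.DataFrame(rows)


def perturbed(params: SimParams, **changes) -> SimParams:
    """Copy of ``params`` with fields replaced (validation re-runs)."""
    return replace(params, **changes)
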