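"""Adaptive velocity-threshold saccade detection.

Horizontal gaze velocity is estimated with a Savitzky–Golay derivative
filter and saccades are found with a data-driven peak-velocity threshold:
starting from an initial guess, the threshold is iterated as
``mean + k * SD`` over the sub-threshold samples until it converges, so it
adapts to each trial's noise level.  Onsets and offsets are then refined by
walking outward from each suprathreshold run to a lower, noise-derived
threshold estimated from the pre-target fixation window.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Literal

import numpy as np
from scipy.signal import savgol_filter

from .design_sim import TrialRecording

__all__ = ["Saccade", "DetectorParams", "compute_velocity",
           "adaptive_peak_threshold", "detect_saccades"]


@dataclass(frozen=True)
class Saccade:
    """One detected horizontal eye-movement event."""

    onset_ms: float
    offset_ms: float
    amplitude_deg: float
    peak_velocity_deg_s: float
    direction: Literal["left", "right"]

    def __post_init__(self) -> None:
        if self.offset_ms <= self.onset_ms:
            raise ValueError("offset must follow onset")
        if self.amplitude_deg < 0:
            raise ValueError("amplitude must be >= 0")


@dataclass
class DetectorParams:
    """Detection constants; defaults suit 300-Hz recordings."""

    sg_window: int = 7          # samples (~23 ms at 300 Hz), odd
    sg_order: int = 2
    pt_init_deg_s: float = 100.0
    pt_multiplier: float = 6.0   # threshold = mean + k*SD of subthreshold samples
    onset_multiplier: float = 3.0
    pt_tol_deg_s: float = 1.0
    min_duration_ms: float = 10.0
    merge_gap_ms: float = 20.0
    onset_floor_deg_s: float = 10.0  # lower bound on the onset/offset threshold

    def __post_init__(self) -> None:
        if self.sg_window % 2 != 1 or self.sg_window <= self.sg_order:
            raise ValueError("sg_window must be odd and > sg_order")
        if self.pt_multiplier <= 0 or self.onset_multiplier <= 0:
            raise ValueError("multipliers must be > 0")
        if self.pt_tol_deg_s <= 0:
            raise ValueError("pt_tol_deg_s must be > 0")


def compute_velocity(
    t_ms: np.ndarray, x_deg: np.ndarray, params: DetectorParams | None = None
) -> np.ndarray:
    """Horizontal velocity in deg/s via a Savitzky–Golay derivative filter.

    Assumes uniform sampling; edge samples use the filter's polynomial
    extrapolation fit (exact for signals polynomial up to ``sg_order``).
    """
    params = params or DetectorParams()
    t_ms = np.asarray(t_ms, dtype=float)
    x_deg = np.asarray(x_deg, dtype=float)
    if t_ms.size < params.sg_window:
        raise ValueError(
            f"need at least sg_window={params.sg_window} samples, got {t_ms.size}"
        )
    dt_s = float(np.median(np.diff(t_ms))) / 1000.0
    return savgol_filter(
        x_deg, params.sg_window, params.sg_order, deriv=1,
        delta=dt_s, mode="interp",
    )


def adaptive_peak_threshold(
    velocity_deg_s: np.ndarray, params: DetectorParams | None = None
) -> float:
    """Converged data-driven peak-velocity threshold.

    Iterates ``PT <- mean + pt_multiplier * SD`` over samples with
    ``|velocity| < PT`` until the change falls below ``pt_tol_deg_s``
    (cap 100 iterations).  Raises on degenerate input where no sample lies
    below the initial threshold.
    """
    params = params or DetectorParams()
    v = np.asarray(velocity_deg_s, dtype=float)
    if v.size == 0:
        raise ValueError("velocity series is empty")
    pt = float(params.pt_init_deg_s)
    for _ in range(100):
        below = v[np.abs(v) <= pt]
        if below.size == 0:
            raise ValueError(
                f"no samples below initial peak threshold {params.pt_init_deg_s}"
            )
        # signed velocity statistics: fixation noise is zero-mean, so the
        # fixed point sits near pt_multiplier * noise SD
        new_pt = float(below.mean() + params.pt_multiplier * below.std())
        if abs(new_pt - pt) < params.pt_tol_deg_s:
            return new_pt
        pt = new_pt
    return pt


def _noise_stats(
    t_ms: np.ndarray, v_abs: np.ndarray, pt: float
) -> tuple[float, float]:
    """Velocity noise mean/SD from the pre-target fixation window.

    Falls back to all sub-threshold samples when no pre-target samples
    exist (e.g. cropped recordings).
    """
    pre = v_abs[t_ms < 0.0]
    pre = pre[pre < pt]
    if pre.size < 5:
        pre = v_abs[v_abs < pt]
    if pre.size == 0:
        return 0.0, 0.0
    return float(pre.mean()), float(pre.std())


def detect_saccades(
    recording: TrialRecording, params: DetectorParams | None = None
) -> list[Saccade]:
    """Detect horizontal saccades in one recording, in time order.

    Candidate events are maximal runs of ``|velocity| >= PT`` (the adaptive
    peak threshold); runs closer than ``merge_gap_ms`` are merged; each
    event's onset/offset is the nearest sample where velocity drops below
    the fixation-noise threshold; events shorter than ``min_duration_ms``
    are discarded.  Only the horizontal channel is used.
    """
    params = params or DetectorParams()
    t = np.asarray(recording.t_ms, dtype=float)
    x = np.asarray(recording.x_deg, dtype=float)
    v = compute_velocity(t, x, params)
    v_abs = np.abs(v)
    pt = adaptive_peak_threshold(v, params)

    noise_mean, noise_sd = _noise_stats(t, v_abs, max(pt, 1e-9))
    onset_thr = max(
        noise_mean + params.onset_multiplier * noise_sd,
        params.onset_floor_deg_s,
    )

    above = v_abs >= max(pt, onset_thr)
    # the SG derivative extrapolates at the array edges, inflating noise
    # there; candidate runs are restricted to the interior
    margin = params.sg_window // 2
    above[:margin] = False
    if margin:
        above[-margin:] = False
    if not above.any():
        return []

    # maximal suprathreshold runs
    idx = np.flatnonzero(above)
    splits = np.flatnonzero(np.diff(idx) > 1)
    runs = [(r[0], r[-1]) for r in np.split(idx, splits + 1)]

    # merge runs separated by less than merge_gap_ms
    merged: list[list[int]] = [list(runs[0])]
    for s, e in runs[1:]:
        if t[s] - t[merged[-1][1]] < params.merge_gap_ms:
            merged[-1][1] = e
        else:
            merged.append([s, e])

    n = t.size
    saccades: list[Saccade] = []
    for s, e in merged:
        onset = s
        while onset > 0 and v_abs[onset - 1] >= onset_thr:
            onset -= 1
        offset = e
        while offset < n - 1 and v_abs[offset + 1] >= onset_thr:
            offset += 1
        if t[offset] - t[onset] < params.min_duration_ms:
            continue
        disp = x[offset] - x[onset]
        peak = float(v_abs[s:e + 1].max())
        saccades.append(Saccade(
            onset_ms=float(t[onset]),
            offset_ms=float(t[offset]),
            amplitude_deg=float(abs(disp)),
            peak_velocity_deg_s=peak,
            direction="right" if disp >= 0 else "left",
        ))
    return saccades
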