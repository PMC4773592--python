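"""Per-trial response extraction and exclusion filtering.

The response on each trial is the very first saccade after target onset
with an amplitude of at least 2 degrees — whether it goes toward or away
from the target — and its onset latency is the trial's RT.  Smaller
movements are treated as fixational micro-saccades and skipped.  Trials
are then excluded for missing responses, anticipatory latencies (<100 ms),
latencies beyond the target presentation (>1000 ms), and per-participant
3-SD latency outliers.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from enum import Enum
from typing import Sequence

import numpy as np
import pandas as pd

from .design_sim import TrialRecording
from .saccade_detection import Saccade

__all__ = ["ExclusionReason", "TrialResult", "ExclusionSummary",
           "extract_response", "apply_exclusions", "results_to_frame"]


class ExclusionReason(str, Enum):
    NONE = "none"
    NO_RESPONSE = "no_response"
    LATENCY_LT_100 = "latency_lt_100"
    LATENCY_GT_1000 = "latency_gt_1000"
    OUTLIER_3SD = "outlier_3sd"


@dataclass
class TrialResult:
    """One analyzed trial: response, latency, correctness, exclusion state."""

    participant_id: str
    block: int
    trial: int
    congruence: str
    rt_ms: float            # NaN when no response
    response_side: str      # 'left' / 'right' / 'none'
    correct: bool | None    # None when no response
    excluded: bool = False
    exclusion_reason: ExclusionReason = ExclusionReason.NONE


@dataclass
class ExclusionSummary:
    n_total: int
    n_excluded_by_reason: dict[str, int] = field(default_factory=dict)

    @property
    def n_excluded(self) -> int:
        return sum(self.n_excluded_by_reason.values())

    @property
    def fraction_excluded(self) -> float:
        return self.n_excluded / self.n_total if self.n_total else 0.0

    def to_dict(self) -> dict:
        return {
            "n_total": self.n_total,
            "n_excluded": self.n_excluded,
            "fraction_excluded": self.fraction_excluded,
            "by_reason": dict(self.n_excluded_by_reason),
        }


def extract_response(
    recording: TrialRecording,
    saccades: Sequence[Saccade],
    amplitude_threshold_deg: float = 2.0,
) -> TrialResult:
    """First post-target saccade of >=2 degrees becomes the response.

    Saccades below the amplitude threshold (micro-movements) and saccades
    starting before target onset are ignored.  With no qualifying saccade
    the trial is marked no-response (exclusion applied later by
    :func:`apply_exclusions`).
    """
    d = recording.design
    response = next(
        (s for s in sorted(saccades, key=lambda s: s.onset_ms)
         if s.onset_ms >= 0.0 and s.amplitude_deg >= amplitude_threshold_deg),
        None,
    )
    if response is None:
        return TrialResult(
            participant_id=d.participant_id, block=d.block, trial=d.trial,
            congruence=d.congruence, rt_ms=float("nan"),
            response_side="none", correct=None,
        )
    return TrialResult(
        participant_id=d.participant_id, block=d.block, trial=d.trial,
        congruence=d.congruence, rt_ms=float(response.onset_ms),
        response_side=response.direction,
        correct=(response.direction == d.correct_side),
    )


def results_to_frame(results: Sequence[TrialResult]) -> pd.DataFrame:
    return pd.DataFrame([{
        "participant_id": r.participant_id,
        "block": r.block,
        "trial": r.trial,
        "congruence": r.congruence,
        "rt_ms": r.rt_ms,
        "response_side": r.response_side,
        "correct": r.correct,
        "excluded": r.excluded,
        "exclusion_reason": (
            r.exclusion_reason.value
            if isinstance(r.exclusion_reason, ExclusionReason)
            else r.exclusion_reason
        ),
    } for r in results])


def apply_exclusions(
    results: pd.DataFrame | Sequence[TrialResult],
    lo_ms: float = 100.0,
    hi_ms: float = 1000.0,
    sd_mult: float = 3.0,
) -> tuple[pd.DataFrame, ExclusionSummary]:
    """Two-pass exclusion filter; returns annotated results and a summary.

    Pass 1 removes no-response trials and latencies strictly below
    ``lo_ms`` or strictly above ``hi_ms`` (boundary values are kept).
    Pass 2 computes each participant's mean and SD of RT over surviving
    trials — pooled across congruence conditions — and removes RTs outside
    mean ± ``sd_mult``·SD in a single pass.  Trial order never affects
    which trials are excluded.
    """
    df = (results.copy() if isinstance(results, pd.DataFrame)
          else results_to_frame(results))
    if df.empty:
        return df, ExclusionSummary(n_total=0)

    reason = np.full(len(df), ExclusionReason.NONE.value, dtype=object)
    rt = df["rt_ms"].to_numpy(dtype=float)
    no_resp = (df["response_side"] == "none").to_numpy() | np.isnan(rt)
    reason[no_resp] = ExclusionReason.NO_RESPONSE.value
    fast = ~no_resp & (rt < lo_ms)
    reason[fast] = ExclusionReason.LATENCY_LT_100.value
    slow = ~no_resp & (rt > hi_ms)
    reason[slow] = ExclusionReason.LATENCY_GT_1000.value

    surviving = reason == ExclusionReason.NONE.value
    df = df.assign(_reason=reason)
    for pid, g in df[surviving].groupby("participant_id", sort=False):
        m, sd = g["rt_ms"].mean(), g["rt_ms"].std(ddof=1)
        if not np.isfinite(sd) or sd == 0:
            continue
        out = g.index[(g["rt_ms"] - m).abs() > sd_mult * sd]
        df.loc[out, "_reason"] = ExclusionReason.OUTLIER_3SD.value

    df["exclusion_reason"] = df.pop("_reason")
    df["excluded"] = df["exclusion_reason"] != ExclusionReason.NONE.value

    counts = (
        df.loc[df["excluded"], "exclusion_reason"].value_counts().to_dict()
    )
    summary = ExclusionSummary(
        n_total=len(df),
        n_excluded_by_reason={str(k): int(v) for k, v in counts.items()},
    )
    return df, summary
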