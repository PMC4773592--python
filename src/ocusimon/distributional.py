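"""Distributional statistics: septile bins, CAFs, and delta plots.

Conditional accuracy functions (CAF) and delta plots are the standard
distributional tools of the activation–suppression framework: the CAF
exposes fast response-capture errors under conflict, and the delta plot
tracks how the congruence effect on correct-trial RT shrinks as responses
slow.  Binning is vincentized: each participant's RTs are rank-ordered and
split into equal-count bins, then bin statistics are averaged across
participants with equal weight.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd

__all__ = ["bin_septiles", "compute_caf", "compute_delta"]


def bin_septiles(rts, n_bins: int = 7) -> np.ndarray:
    """Assign each RT to a quantile bin 1..n_bins by stable rank order.

    Bin sizes follow the largest-remainder rule: when ``len(rts)`` is not
    divisible by ``n_bins``, the earliest bins take the extra elements.
    Ties keep input order (stable sort).  Returns an int array aligned with
    the input.  With fewer elements than bins, later bins are left empty
    (downstream aggregation drops empty bins with a warning).
    """
    rts = np.asarray(rts, dtype=float)
    if rts.size == 0:
        raise ValueError("rts must be non-empty")
    if n_bins < 1:
        raise ValueError("n_bins must be >= 1")
    n = rts.size
    order = np.argsort(rts, kind="stable")
    base, extra = divmod(n, n_bins)
    sizes = [base + 1 if i < extra else base for i in range(n_bins)]
    bins = np.empty(n, dtype=np.int64)
    start = 0
    for b, size in enumerate(sizes, start=1):
        bins[order[start:start + size]] = b
        start += size
    return bins


def _included(results: pd.DataFrame) -> pd.DataFrame:
    if "excluded" in results.columns:
        return results[~results["excluded"].astype(bool)]
    return results


def compute_caf(
    results: pd.DataFrame, n_bins: int = 7
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Conditional accuracy function per participant x congruence.

    ``results`` needs columns ``participant_id``, ``congruence``, ``rt_ms``,
    ``correct`` (and optionally ``excluded``, honored if present).  Error
    trials are retained: accuracy is the proportion correct within each RT
    bin.  Returns ``(rows, aggregate)`` where ``rows`` has one row per
    participant x congruence x bin and ``aggregate`` is the unweighted mean
    over participants per congruence x bin, with across-participant SE.
    """
    df = _included(results)
    rows = []
    for (pid, cong), g in df.groupby(["participant_id", "congruence"], sort=True):
        if len(g) == 0:
            continue
        if len(g) < n_bins:
            warnings.warn(
                f"participant {pid} {cong}: only {len(g)} trials for "
                f"{n_bins} bins; empty bins dropped"
            )
        bins = bin_septiles(g["rt_ms"].to_numpy(), n_bins)
        for b in range(1, n_bins + 1):
            m = bins == b
            if not m.any():
                continue
            rows.append({
                "participant_id": pid,
                "congruence": cong,
                "bin": b,
                "mean_rt_ms": float(g["rt_ms"].to_numpy()[m].mean()),
                "accuracy": float(g["correct"].to_numpy()[m].mean()),
                "n_trials": int(m.sum()),
            })
    caf = pd.DataFrame(rows)
    if caf.empty:
        return caf, caf
    agg = (
        caf.groupby(["congruence", "bin"], sort=True)
        .agg(
            mean_rt_ms=("mean_rt_ms", "mean"),
            accuracy=("accuracy", "mean"),
            se_accuracy=("accuracy", "sem"),
            n_participants=("participant_id", "nunique"),
        )
        .reset_index()
    )
    return caf, agg


def compute_delta(
    results: pd.DataFrame, n_bins: int = 7
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Delta plot rows per participant: incongruent minus congruent bin means.

    Only correct, included trials enter.  Bins are computed separately
    within each congruence condition and paired by rank, so ``delta_ms`` of
    bin k is the k-th incongruent bin mean minus the k-th congruent bin
    mean; ``bin_rt_ms`` is the midpoint of the two means.  Participants
    missing a bin in either condition are omitted from the aggregate with a
    warning.
    """
    df = _included(results)
    df = df[df["correct"].astype(bool)]
    rows = []
    for pid, g in df.groupby("participant_id", sort=True):
        per_cond: dict[str, pd.DataFrame] = {}
        for cong in ("congruent", "incongruent"):
            gc = g[g["congruence"] == cong]
            if len(gc) == 0:
                continue
            bins = bin_septiles(gc["rt_ms"].to_numpy(), n_bins)
            means = {
                b: gc["rt_ms"].to_numpy()[bins == b].mean()
                for b in range(1, n_bins + 1)
                if (bins == b).any()
            }
            per_cond[cong] = means
        if set(per_cond) != {"congruent", "incongruent"}:
            warnings.warn(f"participant {pid}: missing a congruence condition; omitted")
            continue
        missing = [
            b for b in range(1, n_bins + 1)
            if b not in per_cond["congruent"] or b not in per_cond["incongruent"]
        ]
        if missing:
            warnings.warn(
                f"participant {pid}: no correct trials in bins {missing}; omitted"
            )
            continue
        for b in range(1, n_bins + 1):
            mc = per_cond["congruent"][b]
            mi = per_cond["incongruent"][b]
            rows.append({
                "participant_id": pid,
                "bin": b,
                "mean_rt_congruent_ms": float(mc),
                "mean_rt_incongruent_ms": float(mi),
                "delta_ms": float(mi - mc),
                "bin_rt_ms": float((mi + mc) / 2.0),
            })
    delta = pd.DataFrame(rows)
    if delta.empty:
        return delta, delta
    agg = (
        delta.groupby("bin", sort=True)
        .agg(
            delta_ms=("delta_ms", "mean"),
            se_delta_ms=("delta_ms", "sem"),
            bin_rt_ms=("bin_rt_ms", "mean"),
            n_participants=("participant_id", "nunique"),
        )
        .reset_index()
    )
    return delta, agg
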