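"""Pipeline orchestration and report generation.

``run_pipeline`` executes simulate → detect → extract/exclude →
distributional → inference from a single :class:`~ocusimon.config.RunConfig`
and writes tables (CSV), figures (PNG + SVG, each with a CSV data sidecar),
an inference JSON, the exclusion summary, and a JSON-lines log.  A second
run with the same config reproduces all numeric outputs exactly.
"""

from __future__ import annotations

import json
import time
from pathlib import Path

import matplotlib
matplotlib.use("Agg")
import matplotlib.pyplot as plt
import numpy as np
import pandas as pd

from .config import RunConfig
from .design_sim import simulate_session
from .distributional import bin_septiles, compute_caf, compute_delta
from .inference import (fit_acc_glmm, fit_caf_glmm, fit_delta_lmm, fit_rt_lmm,
                        posthoc_congruence_by_bin)
from .saccade_detection import detect_saccades
from .trial_pipeline import apply_exclusions, extract_response, results_to_frame

__all__ = ["summarize_congruence", "attach_bins", "run_pipeline"]


def summarize_congruence(trials: pd.DataFrame) -> pd.DataFrame:
    """Mean RT (correct trials) and accuracy per congruence condition.

    Per-participant means are computed first; the table reports their
    across-participant mean and standard error, i.e. the error-bar
    convention of a participants-as-unit summary figure.
    """
    df = trials
    if "excluded" in df.columns:
        df = df[~df["excluded"].astype(bool)]
    responded = df[df["response_side"] != "none"]
    rt_pm = (responded[responded["correct"].astype(bool)]
             .groupby(["participant_id", "congruence"], observed=True)["rt_ms"]
             .mean().rename("rt"))
    acc_pm = (responded.assign(acc=responded["correct"].astype(float))
              .groupby(["participant_id", "congruence"], observed=True)["acc"]
              .mean())
    out = []
    for cong in sorted(responded["congruence"].unique()):
        rt = rt_pm.xs(cong, level="congruence")
        acc = acc_pm.xs(cong, level="congruence")
        out.append({
            "congruence": cong,
            "mean_rt_ms": float(rt.mean()),
            "se_rt_ms": float(rt.sem()) if len(rt) > 1 else 0.0,
            "accuracy": float(acc.mean()),
            "se_accuracy": float(acc.sem()) if len(acc) > 1 else 0.0,
            "n_participants": int(rt.index.nunique()),
        })
    return pd.DataFrame(out)


def attach_bins(trials: pd.DataFrame, n_bins: int = 7) -> pd.DataFrame:
    """Septile bin assignment per participant x congruence (included trials)."""
    df = trials.copy()
    included = ~df["excluded"].astype(bool) if "excluded" in df else np.ones(len(df), bool)
    df["bin"] = pd.NA
    sub = df[included]
    for (_, _), g in sub.groupby(["participant_id", "congruence"], observed=True):
        df.loc[g.index, "bin"] = bin_septiles(g["rt_ms"].to_numpy(), n_bins)
    df["bin"] = df["bin"].astype("Int64")
    return df


def _save_fig(fig, stem: Path) -> None:
    fig.savefig(stem.with_suffix(".png"), dpi=150)
    fig.savefig(stem.with_suffix(".svg"))
    plt.close(fig)


def _figure_congruence(summary: pd.DataFrame, stem: Path) -> None:
    fig, axes = plt.subplots(1, 2, figsize=(7, 3.2))
    x = np.arange(len(summary))
    axes[0].bar(x, summary["mean_rt_ms"], yerr=summary["se_rt_ms"],
                color=["#4477aa", "#cc6677"], capsize=4)
    axes[0].set_xticks(x, summary["congruence"])
    axes[0].set_ylabel("mean RT (ms), correct trials")
    axes[0].set_ylim(bottom=max(0.0, summary["mean_rt_ms"].min() - 50))
    axes[1].bar(x, 100 * summary["accuracy"], yerr=100 * summary["se_accuracy"],
                color=["#4477aa", "#cc6677"], capsize=4)
    axes[1].set_xticks(x, summary["congruence"])
    axes[1].set_ylabel("accuracy (%)")
    axes[1].set_ylim(50, 100)
    fig.tight_layout()
    _save_fig(fig, stem)


def _figure_caf(agg: pd.DataFrame, stem: Path) -> None:
    fig, ax = plt.subplots(figsize=(4.6, 3.4))
    for cong, color in (("congruent", "#4477aa"), ("incongruent", "#cc6677")):
        g = agg[agg["congruence"] == cong]
        ax.errorbar(g["mean_rt_ms"], 100 * g["accuracy"],
                    yerr=100 * g["se_accuracy"], marker="o", color=color,
                    label=cong)
    ax.set_xlabel("bin mean RT (ms)")
    ax.set_ylabel("accuracy (%)")
    ax.set_ylim(0, 100)
    ax.legend()
    fig.tight_layout()
    _save_fig(fig, stem)


def _figure_delta(agg: pd.DataFrame, stem: Path) -> None:
    fig, ax = plt.subplots(figsize=(4.6, 3.4))
    ax.errorbar(agg["bin_rt_ms"], agg["delta_ms"], yerr=agg["se_delta_ms"],
                marker="o", color="#333333")
    ax.axhline(0.0, color="grey", lw=0.8, ls="--")
    ax.set_xlabel("bin RT (ms)")
    ax.set_ylabel("delta (incongruent − congruent, ms)")
    fig.tight_layout()
    _save_fig(fig, stem)


def run_pipeline(config: RunConfig, out_dir: str | Path) -> dict:
    """Run every stage and write the report bundle; returns the summary dict."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    log_path = out / "run_log.jsonl"
    log_fh = open(log_path, "w", encoding="utf-8")
    t_start = time.time()

    def log(stage: str, **kv) -> None:
        rec = {"stage": stage, "elapsed_s": round(time.time() - t_start, 3), **kv}
        log_fh.write(json.dumps(rec, sort_keys=True) + "\n")
        log_fh.flush()

    try:
        config.to_yaml(out / "config.yaml")

        recordings, ground_truth = simulate_session(
            config.n_participants, config.sim,
            n_blocks=config.n_blocks,
            trials_per_block=config.trials_per_block,
            seed=config.seed,
        )
        ground_truth.to_csv(out / "ground_truth.csv", index=False)
        log("simulate", n_trials=len(recordings))

        results = []
        for rec in recordings:
            saccades = detect_saccades(rec, config.detector)
            results.append(extract_response(rec, saccades))
        trials = results_to_frame(results)
        log("detect+extract", n_trials=len(trials))

        trials, excl = apply_exclusions(
            trials, lo_ms=config.exclusions.lo_ms,
            hi_ms=config.exclusions.hi_ms,
            sd_mult=config.exclusions.sd_mult,
        )
        trials = attach_bins(trials, config.n_bins)
        trials.to_csv(out / "trials.csv", index=False)
        with open(out / "exclusions.json", "w", encoding="utf-8") as fh:
            json.dump(excl.to_dict(), fh, indent=2, sort_keys=True)
        log("exclusions", **excl.to_dict())

        congruence_summary = summarize_congruence(trials)
        congruence_summary.to_csv(out / "congruence_summary.csv", index=False)
        _figure_congruence(congruence_summary, out / "fig_congruence")

        caf_rows, caf_agg = compute_caf(trials, config.n_bins)
        caf_rows.to_csv(out / "caf.csv", index=False)
        caf_agg.to_csv(out / "caf_aggregate.csv", index=False)
        _figure_caf(caf_agg, out / "fig_caf")

        delta_rows, delta_agg = compute_delta(trials, config.n_bins)
        delta_rows.to_csv(out / "delta.csv", index=False)
        delta_agg.to_csv(out / "delta_aggregate.csv", index=False)
        _figure_delta(delta_agg, out / "fig_delta")
        log("distributional", n_caf_rows=len(caf_rows),
            n_delta_rows=len(delta_rows))

        inference: dict = {}
        warnings_list: list[str] = []
        if config.n_participants < 3:
            warnings_list.append(
                "fewer than 3 participants: mixed-model estimates are unstable"
            )
        try:
            rt_fit = fit_rt_lmm(trials)
            inference["rt_lmm"] = rt_fit.to_dict()
            acc_fit = fit_acc_glmm(trials)
            inference["accuracy_glmm"] = acc_fit.to_dict()
            caf_fit = fit_caf_glmm(trials, config.n_bins)
            inference["caf_glmm"] = caf_fit.to_dict()
            inference["posthoc_congruence_by_bin"] = [
                c.to_dict() for c in posthoc_congruence_by_bin(
                    caf_fit, config.n_bins, method=config.posthoc_method)
            ]
            inference["posthoc_adjustment"] = config.posthoc_method
            delta_fit = fit_delta_lmm(delta_rows)
            inference["delta_lmm"] = delta_fit.to_dict()
        except Exception as exc:  # degraded mode for tiny sessions
            warnings_list.append(f"inference incomplete: {exc}")
        with open(out / "inference.json", "w", encoding="utf-8") as fh:
            json.dump(inference, fh, indent=2, sort_keys=True)
        log("inference", warnings=warnings_list)

        cs = congruence_summary.set_index("congruence")
        summary = {
            "seed": config.seed,
            "n_participants": config.n_participants,
            "n_trials": int(len(trials)),
            "fraction_excluded": excl.fraction_excluded,
            "congruence_effect_ms": float(
                cs.loc["incongruent", "mean_rt_ms"]
                - cs.loc["congruent", "mean_rt_ms"]),
            "accuracy_difference": float(
                cs.loc["congruent", "accuracy"]
                - cs.loc["incongruent", "accuracy"]),
            "caf_aggregate": caf_agg.to_dict(orient="records"),
            "delta_aggregate": delta_agg.to_dict(orient="records"),
            "warnings": warnings_list,
        }
        with open(out / "summary.json", "w", encoding="utf-8") as fh:
            json.dump(summary, fh, indent=2, sort_keys=True)
        log("done")
        return summary
    except Exception as exc:
        log("error", error=str(exc))
        raise
    finally:
        log_fh.close()
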