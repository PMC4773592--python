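"""Mixed-model specification, recovery, and cross-validation against lme4."""

import json
import subprocess

import numpy as np
import pandas as pd
import pytest

from ocusimon.design_sim import SimParams, simulate_session
from ocusimon.inference import (SeparationError, fit_acc_glmm, fit_caf_glmm,
                                fit_delta_lmm, fit_rt_lmm,
                                posthoc_congruence_by_bin)


def _rt_frame(per_participant, shift=25.0, seed=0, sd_between=20.0):
    """Balanced two-condition RT data with participant intercepts."""
    rng = np.random.default_rng(seed)
    rows = []
    for p in range(per_participant[0]):
        u = rng.normal(0, sd_between)
        for cong, off in (("congruent", 0.0), ("incongruent", shift)):
            for rt in rng.normal(300 + u + off, 40, per_participant[1]):
                rows.append({"participant_id": f"P{p:02d}", "congruence": cong,
                             "rt_ms": rt, "correct": True,
                             "response_side": "right"})
    return pd.DataFrame(rows)


def _acc_frame(n_p=20, n_t=150, logodds_diff=1.0, base=1.5, sd_u=0.5, seed=0):
    rng = np.random.default_rng(seed)
    rows = []
    for p in range(n_p):
        u = rng.normal(0, sd_u)
        for cong, eta in (("congruent", base + u),
                          ("incongruent", base + u - logodds_diff)):
            y = rng.random(n_t) < 1 / (1 + np.exp(-eta))
            for ok in y:
                rows.append({"participant_id": f"P{p:02d}", "congruence": cong,
                             "correct": bool(ok), "rt_ms": 300.0,
                             "response_side": "right"})
    return pd.DataFrame(rows)


class TestRtLmm:
    def test_zero_between_variance_collapses_to_mean_difference(self):
        df = _rt_frame((6, 40), shift=25.0, sd_between=0.0, seed=1)
        fit = fit_rt_lmm(df)
        raw = (df[df.congruence == "incongruent"].rt_ms.mean()
               - df[df.congruence == "congruent"].rt_ms.mean())
        _, est, _ = fit.fixed_effect("incongruent")
        assert est == pytest.approx(raw, abs=1e-6)

    def test_recovers_injected_shift(self):
        df = _rt_frame((20, 100), shift=25.0, seed=2)
        fit = fit_rt_lmm(df)
        _, est, se = fit.fixed_effect("incongruent")
        assert abs(est - 25.0) < 3 * se
        assert fit.random_intercept_sd > 5.0

    def test_single_condition_rejected(self):
        df = _rt_frame((4, 20), seed=3)
        with pytest.raises(ValueError, match="congruence"):
            fit_rt_lmm(df[df.congruence == "congruent"])

    def test_single_participant_rejected(self):
        df = _rt_frame((1, 20), seed=3)
        with pytest.raises(ValueError, match="participants"):
            fit_rt_lmm(df)

    def test_estimate_invariant_to_row_permutation(self):
        df = _rt_frame((8, 30), seed=4)
        a = fit_rt_lmm(df)
        b = fit_rt_lmm(df.sample(frac=1.0, random_state=9))
        assert a.fixed_effect("incongruent")[1] == pytest.approx(
            b.fixed_effect("incongruent")[1], abs=1e-8)


class TestAccGlmm:
    def test_null_data_gives_null_estimate(self):
        df = _acc_frame(n_p=15, n_t=100, logodds_diff=0.0, base=0.0, seed=5)
        fit = fit_acc_glmm(df)
        _, est, se = fit.fixed_effect("incongruent")
        assert abs(est) < 2 * se

    def test_recovers_injected_log_odds_difference(self):
        df = _acc_frame(n_p=25, n_t=150, logodds_diff=1.0, seed=6)
        fit = fit_acc_glmm(df)
        _, est, se = fit.fixed_effect("incongruent")
        assert abs(est - (-1.0)) < 3 * se
        assert 0.1 < fit.random_intercept_sd < 1.5

    def test_all_correct_raises_separation_error(self):
        df = _acc_frame(seed=7)
        df["correct"] = True
        with pytest.raises(SeparationError):
            fit_acc_glmm(df)


def _binned_acc_frame(n_p=15, n_t=14 * 10, seed=0, bin1_penalty=0.0):
    """Accuracy data with explicit bins; optional conflict effect in bin 1."""
    rng = np.random.default_rng(seed)
    rows = []
    for p in range(n_p):
        u = rng.normal(0, 0.4)
        for cong in ("congruent", "incongruent"):
            for b in range(1, 8):
                eta = 2.2 + u
                if cong == "incongruent" and b == 1:
                    eta -= bin1_penalty
                for ok in rng.random(n_t // 14) < 1 / (1 + np.exp(-eta)):
                    rows.append({"participant_id": f"P{p:02d}",
                                 "congruence": cong, "bin": b,
                                 "correct": bool(ok), "rt_ms": 300.0,
                                 "response_side": "right"})
    return pd.DataFrame(rows)


class TestCafGlmm:
    def test_interaction_detected_when_bin1_depressed(self):
        df = _binned_acc_frame(n_p=20, n_t=14 * 15, seed=8, bin1_penalty=2.0)
        fit = fit_caf_glmm(df)
        assert fit.extra_tests["congruence:bin"][3] < 0.01

    def test_omnibus_invariant_to_bin_relabeling(self):
        df = _binned_acc_frame(n_p=10, seed=9, bin1_penalty=1.5)
        fit_a = fit_caf_glmm(df)
        perm = {1: 4, 2: 7, 3: 1, 4: 6, 5: 2, 6: 3, 7: 5}
        df2 = df.assign(bin=df["bin"].map(perm))
        fit_b = fit_caf_glmm(df2)
        assert fit_a.extra_tests["congruence:bin"][0] == pytest.approx(
            fit_b.extra_tests["congruence:bin"][0], rel=1e-4)

    def test_empty_cells_rejected_with_listing(self):
        df = _binned_acc_frame(n_p=6, seed=10)
        df = df[~((df.congruence == "incongruent") & (df.bin == 3))]
        with pytest.raises(ValueError, match=r"incongruent.*3"):
            fit_caf_glmm(df)

    def test_missing_bin_column_rejected(self):
        df = _binned_acc_frame(n_p=4, seed=11).drop(columns=["bin"])
        with pytest.raises(ValueError, match="bin"):
            fit_caf_glmm(df)


class TestPosthoc:
    @pytest.fixture(scope="class")
    def fit(self):
        df = _binned_acc_frame(n_p=20, n_t=14 * 15, seed=12, bin1_penalty=2.0)
        return fit_caf_glmm(df)

    def test_adjusted_p_never_below_raw(self, fit):
        for method in ("max-z", "holm"):
            for c in posthoc_congruence_by_bin(fit, method=method):
                assert c.p_adjusted >= c.p_value
                assert 0.0 <= c.p_adjusted <= 1.0

    def test_bin1_contrast_is_the_congruence_coefficient(self, fit):
        contrasts = posthoc_congruence_by_bin(fit)
        _, est, se = fit.fixed_effect("congruence[T.incongruent]")
        assert contrasts[0].estimate == pytest.approx(est, abs=1e-12)
        assert contrasts[0].se == pytest.approx(se, abs=1e-12)

    def test_only_bin1_significant_under_bin1_effect(self, fit):
        contrasts = posthoc_congruence_by_bin(fit)
        assert contrasts[0].p_adjusted < 0.05
        assert sum(c.p_adjusted < 0.05 for c in contrasts[2:]) <= 1


class TestDeltaLmm:
    def _delta_frame(self, n_p=12, seed=0, slope=-5.0):
        rng = np.random.default_rng(seed)
        rows = []
        for p in range(n_p):
            u = rng.normal(0, 5)
            for b in range(1, 8):
                rows.append({"participant_id": f"P{p:02d}", "bin": b,
                             "delta_ms": 40 + slope * b + u + rng.normal(0, 4)})
        return pd.DataFrame(rows)

    def test_saturated_fit_reproduces_cell_means_when_balanced(self):
        df = self._delta_frame(seed=13)
        fit = fit_delta_lmm(df)
        cell = df.groupby("bin")["delta_ms"].mean()
        names = dict((n, (e, s)) for n, e, s in fit.fixed_effects)
        intercept = names["Intercept"][0]
        assert intercept == pytest.approx(cell[1], abs=1e-6)
        for b in range(2, 8):
            est = names[f"bin[T.{b}]"][0]
            assert intercept + est == pytest.approx(cell[b], abs=1e-6)

    def test_bin_effect_detected_for_sloped_deltas(self):
        fit = fit_delta_lmm(self._delta_frame(seed=14, slope=-5.0))
        assert fit.test[4] < 0.001

    def test_single_bin_rejected(self):
        df = self._delta_frame(seed=15)
        with pytest.raises(ValueError, match="bins"):
            fit_delta_lmm(df[df["bin"] == 1])


class TestAgainstLme4:
    """Cross-check estimates against R lme4 on one small dataset."""

    def test_estimates_match_lmer_and_glmer(self, tmp_path):
        rt = _rt_frame((10, 60), shift=25.0, seed=16)
        acc = _acc_frame(n_p=12, n_t=120, logodds_diff=1.0, seed=17)
        rt.to_csv(tmp_path / "rt.csv", index=False)
        acc.assign(acc=acc["correct"].astype(int)).to_csv(
            tmp_path / "acc.csv", index=False)
        script = tmp_path / "fit.R"
        script.write_text("""
suppressMessages(library(lme4))
args <- commandArgs(trailingOnly=TRUE)
rt <- read.csv(file.path(args[1], "rt.csv"))
m1 <- lmer(rt_ms ~ congruence + (1|participant_id), data=rt, REML=TRUE)
acc <- read.csv(file.path(args[1], "acc.csv"))
m2 <- glmer(acc ~ congruence + (1|participant_id), data=acc, family=binomial)
cat(jsonlite::toJSON(list(
  rt_est=unname(fixef(m1)["congruenceincongruent"]),
  rt_se=unname(sqrt(diag(vcov(m1)))[2]),
  acc_est=unname(fixef(m2)["congruenceincongruent"]),
  acc_se=unname(sqrt(diag(vcov(m2)))[2]),
  acc_sd_u=unname(attr(VarCorr(m2)$participant_id, "stddev"))
), auto_unbox=TRUE))
""")
        out = subprocess.run(
            ["Rscript", str(script), str(tmp_path)],
            capture_output=True, text=True, timeout=300)
        assert out.returncode == 0, out.stderr
        ref = json.loads(out.stdout)

        fit_rt = fit_rt_lmm(rt)
        _, est, se = fit_rt.fixed_effect("incongruent")
        assert est == pytest.approx(ref["rt_est"], abs=0.05)
        assert se == pytest.approx(ref["rt_se"], rel=0.02)

        fit_acc = fit_acc_glmm(acc)
        _, est, se = fit_acc.fixed_effect("incongruent")
        assert est == pytest.approx(ref["acc_est"], rel=0.03, abs=0.02)
        assert se == pytest.approx(ref["acc_se"], rel=0.10)
        assert fit_acc.random_intercept_sd == pytest.approx(
            ref["acc_sd_u"], rel=0.15, abs=0.05)


class TestOnCalibratedSimulation:
    """Inference pattern on default-calibrated synthetic sessions mirrors the
    canonical Simon-task findings: a strong congruence x bin interaction, a
    significant delta bin effect, and post hoc contrasts that isolate the
    congruence effect in the earliest bin."""

    def test_full_inference_pattern(self):
        from ocusimon.design_sim import SimParams, simulate_session
        from ocusimon.distributional import compute_delta
        from ocusimon.report import attach_bins
        from ocusimon.trial_pipeline import apply_exclusions
        from conftest import ground_truth_to_results

        for seed in (501, 502, 503):
            _, gt = simulate_session(43, SimParams(), seed=seed, render=False)
            df, _ = apply_exclusions(ground_truth_to_results(gt))
            df = attach_bins(df)
            fit = fit_caf_glmm(df)
            assert fit.extra_tests["congruence:bin"][3] < 0.05
            contrasts = posthoc_congruence_by_bin(fit)
            assert contrasts[0].p_adjusted < 0.05
            assert sum(c.p_adjusted < 0.05 for c in contrasts[2:]) <= 1
            delta_rows, _ = compute_delta(df[~df["excluded"]])
            assert fit_delta_lmm(delta_rows).test[4] < 0.05
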