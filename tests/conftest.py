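import numpy as np
import pandas as pd
import pytest

from ocusimon.design_sim import SimParams, simulate_session
from ocusimon.report import attach_bins
from ocusimon.trial_pipeline import apply_exclusions


@pytest.fixture(scope="session")
def default_params() -> SimParams:
    return SimParams()


@pytest.fixture(scope="session")
def small_ground_truth() -> pd.DataFrame:
    """Ground-truth table for 6 simulated participants (no rendering)."""
    _, gt = simulate_session(6, SimParams(), seed=11, render=False)
    return gt


def ground_truth_to_results(gt: pd.DataFrame) -> pd.DataFrame:
    """Recast a simulator ground-truth table as a trial-results table."""
    df = gt.rename(columns={
        "true_rt_ms": "rt_ms", "true_side": "response_side",
        "true_correct": "correct",
    }).copy()
    df["correct"] = df["correct"].map(lambda v: bool(v) if v is not None else False)
    return df


@pytest.fixture(scope="session")
def small_results(small_ground_truth) -> pd.DataFrame:
    """Excluded-annotated, bin-annotated results for 6 participants."""
    df, _ = apply_exclusions(ground_truth_to_results(small_ground_truth))
    return attach_bins(df)


@pytest.fixture(scope="session")
def rendered_session():
    """A tiny rendered session (2 participants) with ground truth."""
    recordings, gt = simulate_session(2, SimParams(), seed=21)
    return recordings, gt
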