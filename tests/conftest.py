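"""Shared fixtures: small synthetic recordings and the cached benchmark runs."""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
import pytest

import cyclecast as cc


@pytest.fixture()
def tiny_series() -> cc.EventRateSeries:
    return cc.EventRateSeries(
        start_time=pd.Timestamp("2021-01-01 00:00"),
        counts=np.array([1, 2, 3]),
        missing=np.array([False, False, False]),
    )


@pytest.fixture(scope="session")
def small_recording() -> tuple[cc.EventRateSeries, cc.SeizureTimes]:
    """A 60-day recording with one strongly seizure-locked circadian cycle.

    Small enough for the full pseudo-prospective loop to run in seconds
    while still exercising cycle detection, locking and retraining.
    """
    cfg = cc.SyntheticConfig(
        duration_days=60,
        baseline_rate=10.0,
        cycles=[
            cc.CycleSpec(
                period_hours=24.0, amplitude=8.0,
                seizure_locked=True, preferred_phase=0.0, kappa=5.0,
            )
        ],
        n_seizures=60,
        gap_start_day=None,
        gap_length_days=None,
        seed=42,
    )
    return cc.simulate_recording(cfg)


@pytest.fixture(scope="session")
def benchmark_runs() -> list[tuple[cc.PipelineResult, cc.EvaluationReport]]:
    """Ten participant-1 benchmark pipeline runs, computed once per session.

    This is the expensive fixture behind the headline operating-point
    checks (AUC, seizure sensitivity, low-risk time fraction).
    """
    runs = []
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        for seed in range(10):
            runs.append(cc.run_benchmark(seed))
    return runs
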