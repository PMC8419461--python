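"""The participant-1 synthetic benchmark: one call from seed to report.

The benchmark recording is 183 days of hourly counts (baseline 12
events/h) carrying a circadian cycle plus 18-day and 29-day cycles, 134
seizures locked to the two multiday cycles (von Mises kappa = 5), and a
12-day device-removal gap from day 100; the forecaster runs with a 14-day
warm start and retrains after every test seizure.
"""

from __future__ import annotations

from .evaluation import EvaluationReport, evaluate_forecast
from .forecaster import PipelineResult, pseudo_prospective_run
from .series import RunConfig
from .synthetic import participant1_benchmark, simulate_recording


def run_benchmark(
    seed: int, config: RunConfig | None = None
) -> tuple[PipelineResult, EvaluationReport]:
    """Simulate one benchmark recording and run the full pipeline on it."""
    syn = participant1_benchmark(seed=seed)
    series, seizures = simulate_recording(syn)
    if config is None:
        config = RunConfig(random_seed=seed)
    result = pseudo_prospective_run(series, seizures, config)
    report = evaluate_forecast(result.forecast, series, seizures)
    return result, report
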