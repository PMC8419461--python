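"""Scoring a forecast against observed seizures.

Metrics follow the forecasting literature's operating-point summary: the
rank-based AUC over test hours (probability a random seizure hour
outranks a random non-seizure hour, ties counting one half), the fraction
of time spent in each risk state, the fraction of seizure events falling
in each state, and the median time already spent in the high-risk state
when a high-risk seizure arrives.
"""

from __future__ import annotations

from dataclasses import dataclass, asdict

import numpy as np
from scipy.stats import rankdata

from .forecaster import ForecastSeries
from .risk import RISK_STATES
from .series import EventRateSeries, SeizureTimes, hour_index_of


class EvaluationError(ValueError):
    pass


@dataclass
class EvaluationReport:
    """Operating-point summary of a forecast over its test window."""

    auc: float
    time_fraction: dict[str, float]
    seizure_fraction: dict[str, float]
    seizure_counts: dict[str, int]
    median_lead_hours: float | None
    n_test_seizures: int
    n_test_hours: int

    def __post_init__(self) -> None:
        for frac in (self.time_fraction, self.seizure_fraction):
            total = sum(frac.values())
            if abs(total - 1.0) > 1e-9:
                raise EvaluationError(f"state fractions sum to {total}, not 1")
        if sum(self.seizure_counts.values()) != self.n_test_seizures:
            raise EvaluationError("seizure counts do not sum to the total")

    def to_dict(self) -> dict:
        return asdict(self)


def auc_score(likelihoods, labels) -> float:
    """Rank-based AUC with the ties-count-half convention."""
    lik = np.asarray(likelihoods, dtype=float)
    y = np.asarray(labels, dtype=bool)
    n_pos = int(y.sum())
    n_neg = int(y.size - n_pos)
    if n_pos == 0 or n_neg == 0:
        raise EvaluationError("AUC requires both classes in the test window")
    ranks = rankdata(lik)  # average ranks handle ties as half-wins
    return float((ranks[y].sum() - n_pos * (n_pos + 1) / 2.0) / (n_pos * n_neg))


def state_distributions(
    risk: np.ndarray, seizure_states: np.ndarray
) -> tuple[dict[str, float], dict[str, float], dict[str, int]]:
    """Hour-count fraction per state and seizure events per state."""
    risk = np.asarray(risk, dtype=str)
    n = risk.size
    if n == 0:
        raise EvaluationError("empty forecast")
    time_fraction = {s: float((risk == s).sum() / n) for s in RISK_STATES}
    counts = {s: int((np.asarray(seizure_states) == s).sum()) for s in RISK_STATES}
    total = sum(counts.values())
    if total:
        seizure_fraction = {s: counts[s] / total for s in RISK_STATES}
    else:
        seizure_fraction = {s: (1.0 if s == "low" else 0.0) for s in RISK_STATES}
    return time_fraction, seizure_fraction, counts


def median_lead_time(risk: np.ndarray, seizure_hours) -> float | None:
    """Median hours already spent in high risk when a seizure arrives.

    For each seizure whose hour is high risk, the lead is the number of
    hours since the current uninterrupted high-risk run began (0 for a
    seizure in the run's first hour). None when no seizure falls in a
    high-risk hour.
    """
    risk = np.asarray(risk, dtype=str)
    high = risk == "high"
    # run_start[i] = index where the high run containing i began
    run_start = np.arange(risk.size)
    for i in range(1, risk.size):
        if high[i] and high[i - 1]:
            run_start[i] = run_start[i - 1]
    leads = [
        float(h - run_start[h])
        for h in np.asarray(seizure_hours, dtype=int)
        if 0 <= h < risk.size and high[h]
    ]
    if not leads:
        return None
    return float(np.median(leads))


def evaluate_forecast(
    forecast: ForecastSeries,
    series: EventRateSeries,
    seizures: SeizureTimes,
) -> EvaluationReport:
    """Score a pseudo-prospective forecast over its test window.

    Masked (device-gap) hours are excluded from the AUC, which needs
    defined likelihoods, but their carried-forward risk labels count
    toward time-in-state; seizure events are attributed to the state of
    their containing hour.
    """
    cutoff = forecast.first_hour
    test_hours = np.array(
        [h for h in seizures.hour_indices(series) if h >= cutoff], dtype=int
    )
    rel_hours = test_hours - cutoff
    labels = np.zeros(forecast.n_hours, dtype=bool)
    labels[rel_hours] = True

    usable = ~forecast.carried
    if labels[usable].any() and (~labels[usable]).any():
        auc = auc_score(forecast.likelihood[usable], labels[usable])
    else:
        raise EvaluationError("test window lacks one of the two classes")

    seizure_states = forecast.risk[rel_hours]
    time_fraction, seizure_fraction, counts = state_distributions(
        forecast.risk, seizure_states
    )
    lead = median_lead_time(forecast.risk, rel_hours)
    return EvaluationReport(
        auc=auc,
        time_fraction=time_fraction,
        seizure_fraction=seizure_fraction,
        seizure_counts=counts,
        median_lead_hours=lead,
        n_test_seizures=int(len(test_hours)),
        n_test_hours=int(forecast.n_hours),
    )


def summary_table(report: EvaluationReport) -> str:
    """Human-readable operating-point table."""
    lines = [
        "            High risk   Medium risk   Low risk",
        "Seizures    {h} ({hp:.0%})     {m} ({mp:.0%})       {l} ({lp:.0%})".format(
            h=report.seizure_counts["high"],
            hp=report.seizure_fraction["high"],
            m=report.seizure_counts["medium"],
            mp=report.seizure_fraction["medium"],
            l=report.seizure_counts["low"],
            lp=report.seizure_fraction["low"],
        ),
        "Time        {h:.0%}          {m:.0%}           {l:.0%}".format(
            h=report.time_fraction["high"],
            m=report.time_fraction["medium"],
            l=report.time_fraction["low"],
        ),
        f"AUC: {report.auc:.2f}",
    ]
    if report.median_lead_hours is not None:
        lines.append(
            f"Median time in high risk before a seizure: "
            f"{report.median_lead_hours:.0f} h"
        )
    return "\n".join(lines)
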