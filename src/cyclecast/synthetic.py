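"""Synthetic recordings with the statistical structure of a chronic
sub-scalp EEG monitoring study.

Real sub-scalp event-rate recordings are commercially sensitive and
unavailable, so every downstream stage is exercised on simulated data:
hourly Poisson event counts modulated by circadian and multiday cycles,
seizure onsets phase-locked to a subset of those cycles through a von
Mises phase preference, and an extended missing-data window emulating a
period of device removal.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from typing import Optional

import numpy as np
import pandas as pd

from .series import EventRateSeries, SeizureTimes, SeriesError, HOUR

DEFAULT_START = pd.Timestamp("2021-01-01 00:00")


@dataclass
class CycleSpec:
    """One periodic component of the simulated event rate.

    ``amplitude`` modulates the Poisson rate (events/hour); if
    ``seizure_locked`` the seizure process prefers phase
    ``preferred_phase`` of this cycle with von Mises concentration
    ``kappa`` (kappa=0 gives no preference; large kappa pins every
    seizure to the preferred phase).
    """

    period_hours: float
    amplitude: float = 0.0
    rate_phase_offset: float = 0.0
    seizure_locked: bool = False
    preferred_phase: float = 0.0
    kappa: float = 0.0

    def __post_init__(self) -> None:
        if self.period_hours <= 0:
            raise ValueError("period_hours must be > 0")
        if self.amplitude < 0:
            raise ValueError("amplitude must be >= 0")
        if self.kappa < 0:
            raise ValueError("kappa must be >= 0")

    def phase_at(self, hours: np.ndarray) -> np.ndarray:
        """Ideal (noise-free) cycle phase at integer hour offsets."""
        return np.mod(
            2.0 * np.pi * np.asarray(hours, dtype=float) / self.period_hours
            - self.rate_phase_offset,
            2.0 * np.pi,
        )


def _benchmark_cycles() -> list[CycleSpec]:
    return [
        CycleSpec(period_hours=24.0, amplitude=4.0),
        CycleSpec(
            period_hours=432.0, amplitude=4.0,
            seizure_locked=True, preferred_phase=0.0, kappa=5.0,
        ),
        CycleSpec(
            period_hours=696.0, amplitude=4.0,
            seizure_locked=True, preferred_phase=0.0, kappa=5.0,
        ),
    ]


@dataclass
class SyntheticConfig:
    """Configuration of a simulated recording.

    The defaults are the "participant-1 benchmark": ~6 months of hourly
    counts at baseline 12 events/h carrying a circadian cycle plus an
    18-day (432 h) and a 29-day (696 h) cycle, 134 seizures locked to the
    two multiday cycles (kappa = 5), and a 12-day device-removal gap
    starting on day 100.
    """

    duration_days: float = 183.0
    baseline_rate: float = 12.0
    cycles: list[CycleSpec] = field(default_factory=_benchmark_cycles)
    n_seizures: int = 134
    gap_start_day: Optional[float] = 100.0
    gap_length_days: Optional[float] = 12.0
    seed: int = 0
    start_time: pd.Timestamp = DEFAULT_START

    def __post_init__(self) -> None:
        if self.duration_days <= 0:
            raise ValueError("duration_days must be > 0")
        if self.baseline_rate < 0:
            raise ValueError("baseline_rate must be >= 0")
        if self.n_seizures < 0:
            raise ValueError("n_seizures must be >= 0")

    @property
    def n_hours(self) -> int:
        return int(round(self.duration_days * 24))

    def to_dict(self) -> dict:
        d = asdict(self)
        d["start_time"] = str(self.start_time)
        return d


def rate_profile(config: SyntheticConfig) -> np.ndarray:
    """Deterministic hourly Poisson intensity lambda(t), clipped at 0."""
    t = np.arange(config.n_hours, dtype=float)
    lam = np.full(config.n_hours, config.baseline_rate, dtype=float)
    for c in config.cycles:
        lam += c.amplitude * np.cos(
            2.0 * np.pi * t / c.period_hours - c.rate_phase_offset
        )
    return np.clip(lam, 0.0, None)


def generate_event_rates(config: SyntheticConfig) -> EventRateSeries:
    """Draw counts[t] ~ Poisson(lambda(t)); deterministic given the seed."""
    lam = rate_profile(config)
    if not (lam > 0).any():
        raise ValueError(
            "rate profile is zero everywhere: baseline and amplitudes "
            "cancel; increase baseline_rate"
        )
    rng = np.random.default_rng(config.seed)
    counts = rng.poisson(lam)
    return EventRateSeries(
        start_time=config.start_time,
        counts=counts,
        missing=np.zeros(config.n_hours, dtype=bool),
    )


def generate_seizures(
    config: SyntheticConfig, series: EventRateSeries
) -> SeizureTimes:
    """Draw phase-locked seizure onset hours.

    Each hour t receives weight prod over locked cycles of
    exp(kappa * cos(theta_cycle(t) - preferred_phase)); ``n_seizures``
    distinct hours are drawn with probability proportional to that weight
    (at most one seizure per hour), onsets placed at the hour start.
    With no locked cycle the weights are uniform.
    """
    n = series.n_hours
    if config.n_seizures > n:
        raise ValueError(
            f"n_seizures={config.n_seizures} exceeds available hours ({n})"
        )
    t = np.arange(n, dtype=float)
    log_w = np.zeros(n, dtype=float)
    for c in config.cycles:
        if c.seizure_locked:
            theta = 2.0 * np.pi * t / c.period_hours
            log_w += c.kappa * np.cos(theta - c.preferred_phase)
    log_w -= log_w.max()  # overflow-safe for huge kappa
    w = np.exp(log_w)
    p = w / w.sum()
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 7]))
    hours = rng.choice(n, size=config.n_seizures, replace=False, p=p)
    hours.sort()
    onsets = series.start_time + pd.to_timedelta(hours, unit="h")
    return SeizureTimes(onsets=pd.DatetimeIndex(onsets))


def insert_gap(
    series: EventRateSeries, gap_start_day: float, gap_length_days: float
) -> EventRateSeries:
    """Mark a device-removal window as missing; counts elsewhere unchanged."""
    start_h = int(round(gap_start_day * 24))
    length_h = int(round(gap_length_days * 24))
    if length_h < 0 or start_h < 0 or start_h + length_h > series.n_hours:
        raise SeriesError(
            f"gap [{gap_start_day}, {gap_start_day + gap_length_days}) days "
            f"outside the {series.n_hours / 24:.1f}-day series span"
        )
    missing = series.missing.copy()
    missing[start_h : start_h + length_h] = True
    return EventRateSeries(
        start_time=series.start_time, counts=series.counts.copy(), missing=missing
    )


def simulate_recording(
    config: SyntheticConfig,
) -> tuple[EventRateSeries, SeizureTimes]:
    """Full simulated study: rates, phase-locked seizures, then the gap."""
    series = generate_event_rates(config)
    seizures = generate_seizures(config, series)
    if config.gap_start_day is not None and config.gap_length_days:
        series = insert_gap(series, config.gap_start_day, config.gap_length_days)
    return series, seizures


def participant1_benchmark(seed: int = 0) -> SyntheticConfig:
    """The default benchmark configuration with a caller-chosen seed."""
    return SyntheticConfig(seed=seed)
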