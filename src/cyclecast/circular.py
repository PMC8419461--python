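"""Circular statistics for seizure phase locking.

Two statistics drive feature selection: the synchronization index (SI),
the modulus of the mean unit phasor of a phase sample (0 = uniform,
1 = perfect alignment), and the Hodges-Ajne omnibus test of circular
uniformity, whose statistic m is the minimum number of sample points in
any closed half-circle.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.special import gammaln

from .cycles import CyclePhaseSeries
from .series import EventRateSeries, SeizureTimes, hour_index_of

TWO_PI = 2.0 * np.pi

#: below this sample size the omnibus test has essentially no power and
#: returns p = 1 with a warning.
MIN_OMNIBUS_N = 5


class CircularStatsError(ValueError):
    pass


@dataclass
class SeizureCycle:
    """A cycle detected in seizure times: a fixed sinusoid of given period.

    Phase is measured from ``anchor`` (phase 0), so
    phase(t) = 2*pi*((t - anchor)/period mod 1); only relative phase
    enters the sin/cos features, so the anchor convention is free.
    """

    period: float
    anchor: pd.Timestamp
    si: float
    p_value: float
    source: str = "seizure_time"

    def __post_init__(self) -> None:
        if self.period <= 0:
            raise CircularStatsError("period must be > 0")
        if not 0.0 <= self.si <= 1.0 + 1e-12:
            raise CircularStatsError(f"SI {self.si} outside [0, 1]")

    def phase_at(self, times) -> np.ndarray:
        """Wrapped phase of the fixed sinusoid at arbitrary timestamps."""
        times = pd.DatetimeIndex(times)
        frac = (times - self.anchor) / pd.Timedelta(hours=self.period)
        return np.mod(np.asarray(frac, dtype=float), 1.0) * TWO_PI


def sync_index(angles) -> float:
    """Synchronization index: modulus of the mean unit phasor."""
    a = np.asarray(angles, dtype=float)
    if a.size == 0:
        raise CircularStatsError("empty phase sample")
    return float(np.abs(np.exp(1j * a).mean()))


def _min_halfcircle_count(a: np.ndarray) -> int:
    """Minimum number of points in any closed half-circle (exact scan).

    The count as a half-circle rotates changes only when its boundary
    crosses a data point or an antipode, so scanning boundaries at the
    midpoints between consecutive such critical angles is exact. Angles
    are snapped to a 1e-12 grid so that antipodes coincide exactly with
    data points when they mathematically should (e.g. evenly spaced
    samples), keeping every scan boundary safely between critical angles.
    """
    a = np.sort(np.round(np.mod(a, TWO_PI), 12))
    n = a.size
    crit = np.unique(np.round(np.mod(np.concatenate([a, a + np.pi]), TWO_PI), 12))
    # midpoints between consecutive critical angles, cyclically
    nxt = np.roll(crit, -1).astype(float)
    nxt[-1] += TWO_PI
    bounds = np.mod((crit + nxt) / 2.0, TWO_PI)
    doubled = np.concatenate([a, a + TWO_PI])
    m = n
    for theta in bounds:
        inside = np.searchsorted(doubled, theta + np.pi) - np.searchsorted(
            doubled, theta
        )
        m = min(m, int(inside), n - int(inside))
    return int(m)


def omnibus_test(angles) -> float:
    """Hodges-Ajne omnibus test for circular uniformity (p-value).

    Exact small-sample form p = 2^(1-n) * (n - 2m) * C(n, m) for n <= 50,
    the standard large-sample approximation beyond; p is capped at 1, and
    a maximally spread sample (m = n/2) yields p = 1.
    """
    a = np.asarray(angles, dtype=float)
    n = a.size
    if n == 0:
        raise CircularStatsError("empty phase sample")
    if n < MIN_OMNIBUS_N:
        warnings.warn(
            f"omnibus test on n={n} < {MIN_OMNIBUS_N} angles has no power; "
            "returning p = 1",
            stacklevel=2,
        )
        return 1.0
    m = _min_halfcircle_count(a)
    if n - 2 * m <= 0:
        return 1.0
    if n <= 50:
        log_p = (
            (1 - n) * np.log(2.0)
            + np.log(n - 2.0 * m)
            + gammaln(n + 1)
            - gammaln(m + 1)
            - gammaln(n - m + 1)
        )
        p = float(np.exp(log_p))
    else:
        A = np.pi * np.sqrt(n) / (2.0 * (n - 2.0 * m))
        p = float(np.sqrt(2.0 * np.pi) / A * np.exp(-np.pi**2 / (8.0 * A**2)))
    return min(1.0, p)


def phases_at_events(
    cycle: CyclePhaseSeries | SeizureCycle,
    event_times,
    series: EventRateSeries | None = None,
) -> np.ndarray:
    """Cycle phase at each event time.

    For a seizure-time cycle (fixed sinusoid) the phase is defined at any
    timestamp. For an event-rate cycle the phase is the Hilbert phase of
    the event's clock hour; events falling in missing-data hours are
    excluded with a warning.
    """
    times = pd.DatetimeIndex(
        event_times.onsets if isinstance(event_times, SeizureTimes) else event_times
    )
    if isinstance(cycle, SeizureCycle):
        return cycle.phase_at(times)
    if cycle.start_time is None:
        raise CircularStatsError("event-rate cycle lacks a start_time")
    ref = EventRateSeries(
        start_time=cycle.start_time,
        counts=np.zeros(cycle.phase.size, dtype=int),
        missing=np.zeros(cycle.phase.size, dtype=bool),
    ) if series is None else series
    idx = np.array([hour_index_of(ref, t) for t in times], dtype=np.int64)
    dropped = cycle.missing[idx]
    if dropped.any():
        warnings.warn(
            f"excluded {int(dropped.sum())} event(s) in missing-data hours "
            "from the phase sample",
            stacklevel=2,
        )
    return cycle.phase[idx[~dropped]]


def scan_seizure_cycles(
    seizures: SeizureTimes,
    candidate_periods,
    anchor,
    si_threshold: float = 0.4,
    alpha: float = 0.05,
) -> list[SeizureCycle]:
    """Scan fixed-period sinusoids for seizure-time cycles.

    A candidate period is retained when seizure phases on it are both
    non-uniform (omnibus p < alpha) and concentrated (SI >= si_threshold);
    retained periods are then greedily pruned by descending SI so that no
    kept period lies within the +/-33% frequency band of a stronger one.
    """
    n = len(seizures)
    if n < MIN_OMNIBUS_N:
        warnings.warn(
            f"only {n} seizures: too few for the seizure-cycle scan",
            stacklevel=2,
        )
        return []
    anchor = pd.Timestamp(anchor)
    candidates = []
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")  # per-candidate low-n warnings
        for period in np.asarray(candidate_periods, dtype=float):
            cyc = SeizureCycle(period=period, anchor=anchor, si=0.0, p_value=1.0)
            phases = cyc.phase_at(seizures.onsets)
            si = sync_index(phases)
            p = omnibus_test(phases)
            if si >= si_threshold and p < alpha:
                candidates.append(
                    SeizureCycle(period=period, anchor=anchor, si=si, p_value=p)
                )
    candidates.sort(key=lambda c: (-c.si, c.period))
    kept: list[SeizureCycle] = []
    for cand in candidates:
        freq = 1.0 / cand.period
        if all(
            not ((1.0 - 0.33) / k.period <= freq <= (1.0 + 0.33) / k.period)
            for k in kept
        ):
            kept.append(cand)
    kept.sort(key=lambda c: c.period)
    return kept


def filter_event_cycles(
    cycles: list[CyclePhaseSeries],
    seizures: SeizureTimes,
    alpha: float = 0.05,
    series: EventRateSeries | None = None,
) -> list[CyclePhaseSeries]:
    """Keep an event-rate cycle iff seizures are phase-locked to it.

    Locking is assessed with the omnibus test on the Hilbert phases of the
    cycle at seizure hours (p < alpha).
    """
    kept = []
    for cyc in cycles:
        phases = phases_at_events(cyc, seizures, series=series)
        if phases.size and omnibus_test(phases) < alpha:
            kept.append(cyc)
    return kept
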