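"""Cycle detection in hourly event rates.

A Morlet continuous wavelet transform of the z-standardized hourly rates
yields a global (time-averaged) wavelet spectrum over a fixed grid of
candidate periods. Peaks exceeding the time-averaged chi-square
significance level against an AR(1) red-noise background are significant
cycles; overlapping peaks are pruned so only the strongest peak within any
cycle's band-pass pass band survives. Each surviving cycle's instantaneous
phase is the analytic-signal angle of the zero-phase Butterworth
band-passed series.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.signal import butter, hilbert, sosfiltfilt
from scipy.stats import chi2

from .series import EventRateSeries

#: Morlet central (non-dimensional) frequency.
OMEGA0 = 6.0
#: Fourier wavelength of a Morlet wavelet at unit scale.
FOURIER_FACTOR = 4.0 * np.pi / (OMEGA0 + np.sqrt(2.0 + OMEGA0**2))
#: Decorrelation factor gamma for the time-averaged significance test.
GAMMA_AVG = 2.32

GRID_MIN_PERIOD = 2.4


class CycleDetectionError(ValueError):
    pass


@dataclass
class WaveletSpectrum:
    """Global wavelet power and its significance level per candidate period."""

    periods: np.ndarray
    global_power: np.ndarray
    significance_level: np.ndarray

    def __post_init__(self) -> None:
        self.periods = np.asarray(self.periods, dtype=float)
        self.global_power = np.asarray(self.global_power, dtype=float)
        self.significance_level = np.asarray(self.significance_level, dtype=float)
        if not (
            self.periods.shape
            == self.global_power.shape
            == self.significance_level.shape
        ):
            raise CycleDetectionError("spectrum arrays must share one length")
        if (self.global_power < 0).any():
            raise CycleDetectionError("wavelet power must be non-negative")

    def power_at(self, period: float) -> float:
        i = int(np.argmin(np.abs(self.periods - period)))
        return float(self.global_power[i])


@dataclass
class CyclePhaseSeries:
    """Per-hour instantaneous phase and envelope of one detected cycle."""

    period: float
    phase: np.ndarray  # radians, wrapped to [0, 2pi)
    amplitude: np.ndarray  # analytic-signal modulus, >= 0
    source: str  # "event_rate" | "seizure_time"
    start_time: pd.Timestamp
    missing: np.ndarray  # hours where the underlying data was missing

    def __post_init__(self) -> None:
        self.phase = np.asarray(self.phase, dtype=float)
        self.amplitude = np.asarray(self.amplitude, dtype=float)
        self.missing = np.asarray(self.missing, dtype=bool)
        if not (self.phase.shape == self.amplitude.shape == self.missing.shape):
            raise CycleDetectionError("phase/amplitude/missing lengths differ")


def standardize(series: EventRateSeries) -> np.ndarray:
    """Z-standardize hourly counts over non-missing hours (population SD).

    Missing hours are imputed with 0, the post-standardization mean, so
    spectral stages see a regular grid while gaps contribute no power.
    """
    valid = ~series.missing
    if valid.sum() < 2:
        raise CycleDetectionError("need >= 2 non-missing hours to standardize")
    x = series.counts.astype(float)
    mu = x[valid].mean()
    sd = x[valid].std()  # population SD (ddof=0)
    if sd == 0:
        raise CycleDetectionError("constant series: zero variance")
    z = np.zeros_like(x)
    z[valid] = (x[valid] - mu) / sd
    return z


def build_period_grid(duration_hours: float) -> np.ndarray:
    """Candidate cycle periods in hours.

    Four arithmetic segments — every 1.2 h from 2.4 to 31.2 h, every
    2.4 h from 33.6 to 48 h, every 4.8 h from 52.8 h to 4 days, and every
    12 h from 5 days up — truncated at a quarter of the recording
    duration so at least four repetitions of every candidate fit.
    """
    max_period = duration_hours / 4.0
    if max_period < GRID_MIN_PERIOD:
        raise CycleDetectionError(
            f"duration {duration_hours} h too short: no candidate period "
            f">= {GRID_MIN_PERIOD} h fits four times"
        )
    segments = [
        1.2 * np.arange(2, 27),  # 2.4 .. 31.2 h
        2.4 * np.arange(14, 21),  # 33.6 .. 48 h
        4.8 * np.arange(11, 21),  # 52.8 .. 96 h
        12.0 * np.arange(10, int(np.floor(max_period / 12.0 + 1e-9)) + 1),
    ]
    grid = np.concatenate(segments)
    return grid[grid <= max_period + 1e-9]


def _morlet_cwt(x: np.ndarray, scales: np.ndarray) -> np.ndarray:
    """FFT-based Morlet CWT; rows are scales, columns time."""
    n = x.size
    npad = int(2 ** np.ceil(np.log2(n)))
    xhat = np.fft.fft(x, npad)
    omega = 2.0 * np.pi * np.fft.fftfreq(npad)
    pos = omega > 0
    W = np.empty((scales.size, n), dtype=complex)
    norm_const = np.pi**-0.25
    for i, s in enumerate(scales):
        psi_hat = np.zeros(npad)
        arg = s * omega[pos] - OMEGA0
        psi_hat[pos] = norm_const * np.sqrt(2.0 * np.pi * s) * np.exp(-0.5 * arg**2)
        W[i] = np.fft.ifft(xhat * psi_hat)[:n]
    return W


def _lag1_autocorrelation(x: np.ndarray) -> float:
    if x.size < 3 or np.allclose(x, x[0]):
        return 0.0
    x0 = x - x.mean()
    denom = float(np.dot(x0, x0))
    if denom == 0.0:
        return 0.0
    alpha = float(np.dot(x0[:-1], x0[1:]) / denom)
    return float(np.clip(alpha, 0.0, 0.999))


def global_wavelet_spectrum(
    standardized: np.ndarray,
    grid: np.ndarray,
    confidence: float = 0.99,
    background: str = "red",
) -> WaveletSpectrum:
    """Time-averaged Morlet wavelet power with chi-square significance.

    Power at each scale is averaged over hours outside the cone of
    influence (edge distance >= sqrt(2)*scale). The significance level is
    the theoretical AR(1) red-noise (or white-noise) background spectrum
    scaled by the chi-square quantile at ``confidence`` with the
    time-averaged degrees of freedom.
    """
    x = np.asarray(standardized, dtype=float)
    n = x.size
    grid = np.asarray(grid, dtype=float)
    scales = grid / FOURIER_FACTOR
    W = _morlet_cwt(x, scales)
    power = np.abs(W) ** 2

    # distance of every hour to the nearer series edge
    edge = np.minimum(np.arange(n), np.arange(n)[::-1]).astype(float)
    gws = np.empty(grid.size)
    n_avg = np.empty(grid.size)
    for i, s in enumerate(scales):
        inside = edge >= np.sqrt(2.0) * s
        if not inside.any():  # period too long for any COI-free hour
            inside = np.ones(n, dtype=bool)
        gws[i] = power[i, inside].mean()
        n_avg[i] = inside.sum()

    if background == "white":
        alpha = 0.0
    else:
        alpha = _lag1_autocorrelation(x)
    freq = 1.0 / grid  # cycles per hour, dt = 1 h
    bg = (1.0 - alpha**2) / (1.0 + alpha**2 - 2.0 * alpha * np.cos(2.0 * np.pi * freq))
    # variance of the standardized series is 1 by construction
    dof = 2.0 * np.sqrt(1.0 + (n_avg / (GAMMA_AVG * scales)) ** 2)
    sig = bg * chi2.ppf(confidence, dof) / dof
    return WaveletSpectrum(periods=grid, global_power=gws, significance_level=sig)


def find_significant_periods(
    spectrum: WaveletSpectrum, duration_hours: float
) -> np.ndarray:
    """Strict local maxima above the significance level, capped at duration/4.

    A peak must be strictly greater than both grid neighbours (plateaus
    yield no peak; endpoints have a single neighbour and are excluded),
    and at least four repetitions of the period must fit the recording.
    """
    p = spectrum.global_power
    keep = []
    for i in range(1, p.size - 1):
        if (
            p[i] > p[i - 1]
            and p[i] > p[i + 1]
            and p[i] > spectrum.significance_level[i]
            and spectrum.periods[i] <= duration_hours / 4.0 + 1e-9
        ):
            keep.append(spectrum.periods[i])
    return np.array(keep)


def apply_sparsity(
    significant_periods: np.ndarray,
    spectrum: WaveletSpectrum,
    bandpass_fraction: float = 0.33,
) -> np.ndarray:
    """Keep only the strongest peak within any kept cycle's pass band.

    Greedy by descending wavelet power: a candidate survives iff its
    frequency lies outside [(1-f), (1+f)] times the frequency of every
    already-kept cycle. The result is independent of input ordering.
    """
    periods = np.asarray(significant_periods, dtype=float)
    if periods.size == 0:
        return periods
    powers = np.array([spectrum.power_at(p) for p in periods])
    order = np.lexsort((periods, -powers))  # power desc, shorter period first
    kept: list[float] = []
    f = bandpass_fraction
    for i in order:
        freq = 1.0 / periods[i]
        if all(
            not ((1.0 - f) / pk <= freq <= (1.0 + f) / pk) for pk in kept
        ):
            kept.append(periods[i])
    return np.sort(np.array(kept))


def extract_cycle_phase(
    standardized: np.ndarray,
    period: float,
    bandpass_fraction: float = 0.33,
    *,
    start_time=None,
    missing: np.ndarray | None = None,
) -> CyclePhaseSeries:
    """Instantaneous phase of one cycle via band-pass + Hilbert transform.

    The series is filtered with a zero-phase (forward-backward) 2nd-order
    Butterworth band-pass with cut-offs at +/-``bandpass_fraction`` of the
    cycle frequency; the phase is the wrapped analytic-signal angle and the
    amplitude its modulus.
    """
    x = np.asarray(standardized, dtype=float)
    f = bandpass_fraction
    low, high = (1.0 - f) / period, (1.0 + f) / period
    if high >= 0.5:
        raise CycleDetectionError(
            f"pass band upper edge {high:.3f} cycles/h reaches the Nyquist "
            f"frequency (0.5) for period {period} h"
        )
    if x.size <= 4 * period:
        warnings.warn(
            f"fewer than four repetitions of period {period} h in the series",
            stacklevel=2,
        )
    sos = butter(2, [low, high], btype="bandpass", fs=1.0, output="sos")
    # even reflection with a few cycle periods of padding keeps the
    # boundary phase faithful for oscillatory input; the default pad is
    # far too short for multiday pass bands
    padlen = int(min(x.size - 1, max(24, 3 * period)))
    filtered = sosfiltfilt(sos, x, padtype="even", padlen=padlen)
    analytic = hilbert(filtered)
    phase = np.mod(np.angle(analytic), 2.0 * np.pi)
    if missing is None:
        missing = np.zeros(x.size, dtype=bool)
    return CyclePhaseSeries(
        period=float(period),
        phase=phase,
        amplitude=np.abs(analytic),
        source="event_rate",
        start_time=pd.Timestamp(start_time) if start_time is not None else None,
        missing=np.asarray(missing, dtype=bool),
    )


def detect_event_cycles(
    series: EventRateSeries,
    confidence: float = 0.99,
    bandpass_fraction: float = 0.33,
    background: str = "red",
) -> tuple[WaveletSpectrum, list[CyclePhaseSeries]]:
    """Full event-rate cycle scan: spectrum, significance, sparsity, phases.

    Periods whose pass band would reach Nyquist (shorter than ~2.7 h at
    hourly sampling) are skipped with a warning.
    """
    z = standardize(series)
    grid = build_period_grid(series.n_hours)
    spectrum = global_wavelet_spectrum(z, grid, confidence, background)
    sig = find_significant_periods(spectrum, series.n_hours)
    kept = apply_sparsity(sig, spectrum, bandpass_fraction)
    phases = []
    for p in kept:
        try:
            cps = extract_cycle_phase(
                z, p, bandpass_fraction,
                start_time=series.start_time, missing=series.missing,
            )
        except CycleDetectionError as exc:
            warnings.warn(f"skipping {p} h cycle: {exc}", stacklevel=2)
            continue
        phases.append(cps)
    return spectrum, phases
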