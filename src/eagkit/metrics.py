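"""Response parameters extracted from median traces.

Four parameters are computed: response strength (mean voltage in a
+/-25 ms window around the in-window maximum), response onset and offset
times (10%-of-maximum crossings before/after the peak), and -- for 10-Hz
train responses -- a multitaper power spectral density with sine tapers,
summarized into a pulse-tracking score.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .preprocess import Trace
from .qc import RESPONSE_WINDOW_S

__all__ = [
    "ResponseMetrics",
    "PsdResult",
    "response_strength",
    "response_onset",
    "response_offset",
    "compute_metrics",
    "sine_tapers",
    "multitaper_psd",
    "psd_train_window",
    "tracking_score",
]

#: half-width of the strength averaging window (s)
STRENGTH_HALF_WINDOW_S = 0.025

#: fraction of the maximum defining onset/offset crossings
CROSSING_FRACTION = 0.1

#: PSD window: starts this long after the first train valve opening (s)
PSD_WINDOW_START_S = 0.4
#: PSD window length (s)
PSD_WINDOW_LENGTH_S = 3.0


@dataclass
class ResponseMetrics:
    """Strength and timing of one antenna x odorant x pulse-duration."""

    strength_mV: float
    onset_s: float
    offset_s: float
    peak_time_s: float
    onset_valid: bool
    offset_valid: bool


def _peak(trace: Trace) -> tuple[int, float, float]:
    """Index, time and value of the in-window maximum (first occurrence)."""
    t = trace.times()
    lo, hi = RESPONSE_WINDOW_S
    mask = (t >= lo - 1e-12) & (t <= hi + 1e-12)
    idx_window = np.flatnonzero(mask)
    v = trace.voltage[idx_window]
    i = idx_window[int(np.argmax(v))]
    return int(i), float(t[i]), float(trace.voltage[i])


def response_strength(median_trace: Trace) -> float:
    """Mean voltage within 25 ms before/after the maximum between 50 ms
    and 1 s after valve opening (window clipped at trace edges).

    May be negative for inhibitory traces (the maximum of an all-negative
    trace is its least-negative point).
    """
    i_max, _, _ = _peak(median_trace)
    half = int(round(STRENGTH_HALF_WINDOW_S * median_trace.sampling_rate))
    lo = max(i_max - half, 0)
    hi = min(i_max + half + 1, len(median_trace.voltage))
    return float(np.mean(median_trace.voltage[lo:hi]))


def response_onset(median_trace: Trace, crossing: str = "last") -> tuple[float, bool]:
    """Time from valve opening to 10% of the signal maximum, before the peak.

    With ``crossing="last"`` (default) the onset is the first sample of
    the last contiguous run of samples >= 10% of the maximum ending at the
    peak -- i.e. the final upward crossing, robust to early noise blips.
    ``crossing="first"`` uses the first sample at/after valve opening that
    reaches the 10% level. Returns ``(onset_s, valid)``; invalid (and
    excluded from timing models) when the in-window maximum is <= 0.
    """
    if crossing not in ("last", "first"):
        raise ValueError(f"crossing must be 'last' or 'first', got {crossing!r}")
    i_max, _, m = _peak(median_trace)
    if m <= 0:
        return np.nan, False
    level = CROSSING_FRACTION * m
    t = median_trace.times()
    i_zero = int(np.searchsorted(t, -1e-12))  # first sample with t >= 0
    v = median_trace.voltage
    if crossing == "last":
        i = i_max
        while i > i_zero and v[i - 1] >= level:
            i -= 1
    else:
        reached = np.flatnonzero(v[i_zero : i_max + 1] >= level)
        if reached.size == 0:
            return np.nan, False
        i = i_zero + int(reached[0])
    return float(t[max(i, i_zero)]), True


def response_offset(median_trace: Trace) -> tuple[float, bool]:
    """Time from valve opening to 10% of the signal maximum, after the peak.

    The first sample after the peak with value <= 10% of the maximum,
    searched to the end of the trace. Invalid when the level is never
    reached (or the maximum is <= 0).
    """
    i_max, _, m = _peak(median_trace)
    if m <= 0:
        return np.nan, False
    level = CROSSING_FRACTION * m
    v = median_trace.voltage
    below = np.flatnonzero(v[i_max + 1 :] <= level)
    if below.size == 0:
        return np.nan, False
    i = i_max + 1 + int(below[0])
    return float(median_trace.times()[i]), True


def compute_metrics(median_trace: Trace, crossing: str = "last") -> ResponseMetrics:
    """All scalar response parameters of one median trace."""
    _, t_max, _ = _peak(median_trace)
    onset, onset_ok = response_onset(median_trace, crossing=crossing)
    offset, offset_ok = response_offset(median_trace)
    return ResponseMetrics(
        strength_mV=response_strength(median_trace),
        onset_s=onset,
        offset_s=offset,
        peak_time_s=t_max,
        onset_valid=onset_ok,
        offset_valid=offset_ok,
    )


def sine_tapers(n_samples: int, k_tapers: int) -> np.ndarray:
    """Orthonormal sine tapers, shape ``(k_tapers, n_samples)``.

    Taper k (1-based) at sample t (0-based) is
    ``sqrt(2 / (N + 1)) * sin(pi * k * (t + 1) / (N + 1))``.
    """
    if not 1 <= k_tapers < n_samples:
        raise ValueError(
            f"need 1 <= k_tapers < n_samples, got {k_tapers} and {n_samples}"
        )
    k = np.arange(1, k_tapers + 1)[:, None]
    t = np.arange(1, n_samples + 1)[None, :]
    return np.sqrt(2.0 / (n_samples + 1)) * np.sin(np.pi * k * t / (n_samples + 1))


@dataclass
class PsdResult:
    """One-sided multitaper spectral density estimate."""

    frequencies: np.ndarray  # Hz, [0, fs/2]
    density: np.ndarray  # power per Hz
    n_tapers: int


def psd_train_window(train_trace: Trace) -> np.ndarray:
    """Extract the 3 s analysis window starting 0.4 s after the first
    valve opening from a train-locked trace (relative time [0.4, 3.4) s)."""
    return train_trace.window(
        PSD_WINDOW_START_S, PSD_WINDOW_START_S + PSD_WINDOW_LENGTH_S
    )


def multitaper_psd(
    window: np.ndarray,
    sampling_rate: float,
    k_tapers: int = 5,
    expected_length_s: float = PSD_WINDOW_LENGTH_S,
) -> PsdResult:
    """Sine-taper multitaper PSD of a fixed-length window.

    The window mean is removed, each taper is applied, and the one-sided
    periodograms are averaged and scaled to density units (power per Hz),
    so the integral of the PSD matches the variance of the windowed
    signal. A 3 s window gives a 1/3 Hz frequency resolution.
    """
    x = np.asarray(window, dtype=float)
    n_expected = int(round(expected_length_s * sampling_rate))
    if len(x) != n_expected:
        raise ValueError(
            f"window has {len(x)} samples, expected {n_expected} "
            f"({expected_length_s} s at {sampling_rate} Hz)"
        )
    n = len(x)
    x = x - x.mean()
    tapers = sine_tapers(n, k_tapers)
    spec = np.fft.rfft(tapers * x[None, :], axis=1)
    power = (np.abs(spec) ** 2).mean(axis=0) / sampling_rate
    # one-sided: double all bins except DC (and Nyquist when n is even)
    power[1:] *= 2.0
    if n % 2 == 0:
        power[-1] /= 2.0
    freqs = np.fft.rfftfreq(n, 1.0 / sampling_rate)
    return PsdResult(frequencies=freqs, density=power, n_tapers=k_tapers)


def tracking_score(
    psd: PsdResult, f0: float = 10.0, half_band_hz: float = 3.0
) -> float:
    """Pulse-tracking score: density at ``f0`` over the median density in
    the surrounding +/- ``half_band_hz`` band (excluding the ``f0`` bin).

    A score much greater than 1 indicates the response tracks the pulse
    train; white noise scores about 1.
    """
    df = psd.frequencies[1] - psd.frequencies[0]
    i0 = int(round(f0 / df))
    if abs(psd.frequencies[i0] - f0) > 1e-6:
        raise ValueError(f"f0 = {f0} Hz is not on the frequency grid")
    band = (np.abs(psd.frequencies - f0) <= half_band_hz + 1e-9) & (
        np.arange(len(psd.frequencies)) != i0
    )
    ref = float(np.median(psd.density[band]))
    peak = float(psd.density[i0])
    if ref == 0.0:
        return np.inf if peak > 0 else np.nan
    return peak / ref
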