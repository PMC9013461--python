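"""Stimulus-locked trace extraction and denoising.

The fixed pipeline order is: segment -> baseline_correct ->
median_over_repeats -> running_median. Each trace lives on the relative
time grid [-0.2 s, 4.8 s) at the recording's sampling rate; the sample at
relative time 0 is the first sample at/after valve opening.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
import pandas as pd

from .signal_io import Recording

__all__ = [
    "Trace",
    "SegmentationError",
    "PRE_S",
    "POST_S",
    "segment",
    "segment_events",
    "baseline_correct",
    "median_over_repeats",
    "running_median",
    "preprocess_recording",
]

#: pre-stimulus window length (s); the baseline window is [-PRE_S, 0)
PRE_S = 0.2
#: post-stimulus window length (s); traces end at +POST_S (exclusive)
POST_S = 4.8

MEDIAN_REPEAT = "median"


class SegmentationError(ValueError):
    """Raised when an event window does not fit the recording."""


@dataclass
class Trace:
    """A stimulus-locked voltage segment on the standard relative grid."""

    voltage: np.ndarray
    sampling_rate: float
    antenna_id: str = ""
    odorant: str = ""
    pulse_duration_ms: float = np.nan
    block: str = "main"
    repeat: object = 1  # repeat index, or "median" after averaging

    def times(self) -> np.ndarray:
        """Relative sample times (s), starting at -0.2 s."""
        return -PRE_S + np.arange(len(self.voltage)) / self.sampling_rate

    @property
    def stimulus_key(self) -> tuple:
        return (self.antenna_id, self.odorant, self.pulse_duration_ms, self.block)

    def window(self, start_s: float, stop_s: float, *, closed: str = "left") -> np.ndarray:
        """Samples with relative time in [start_s, stop_s) (or [..] if
        ``closed='both'``)."""
        t = self.times()
        if closed == "both":
            mask = (t >= start_s - 1e-12) & (t <= stop_s + 1e-12)
        else:
            mask = (t >= start_s - 1e-12) & (t < stop_s - 1e-12)
        return self.voltage[mask]


def _grid_counts(fs: float) -> tuple[int, int]:
    pre_n = PRE_S * fs
    total_n = (PRE_S + POST_S) * fs
    if abs(pre_n - round(pre_n)) > 1e-9 or abs(total_n - round(total_n)) > 1e-9:
        raise SegmentationError(
            f"sampling rate {fs} Hz does not place the [-0.2, 4.8) s window "
            "on an integer sample grid"
        )
    return int(round(pre_n)), int(round(total_n))


def segment(recording: Recording, event: pd.Series) -> Trace:
    """Cut the 5 s window [onset - 0.2 s, onset + 4.8 s) around one event.

    Voltage values are copied verbatim from the recording (no
    interpolation). Raises :class:`SegmentationError`, identifying the
    event, if the window exceeds the recording bounds.
    """
    fs = recording.sampling_rate
    pre_n, total_n = _grid_counts(fs)
    onset = float(event["onset_s"])
    idx_onset = int(np.ceil((onset - recording.t0) * fs - 1e-9))
    start = idx_onset - pre_n
    stop = start + total_n
    if start < 0 or stop > len(recording.voltage):
        raise SegmentationError(
            f"event at {onset} s ({event['odorant']}, "
            f"{float(event['valve_open_s']) * 1000:g} ms, repeat "
            f"{event['repeat_index']}) needs samples [{start}, {stop}) but "
            f"recording has {len(recording.voltage)}"
        )
    return Trace(
        voltage=recording.voltage[start:stop].copy(),
        sampling_rate=fs,
        antenna_id=recording.antenna_id,
        odorant=str(event["odorant"]),
        pulse_duration_ms=float(event["valve_open_s"]) * 1000.0,
        block=str(event["block"]),
        repeat=int(event["repeat_index"]),
    )


def segment_events(recording: Recording, block: str | None = None) -> list[Trace]:
    """Segment every event (optionally restricted to one block label)."""
    events = recording.events
    if block is not None:
        events = events[events["block"] == block]
    return [segment(recording, row) for _, row in events.iterrows()]


def baseline_correct(trace: Trace) -> Trace:
    """Subtract the median voltage of the pre-stimulus window [-0.2, 0) s
    from the entire trace. Idempotent."""
    pre_n, _ = _grid_counts(trace.sampling_rate)
    baseline = float(np.median(trace.voltage[:pre_n]))
    return replace(trace, voltage=trace.voltage - baseline)


def median_over_repeats(traces: list[Trace]) -> Trace:
    """Pointwise median over same-stimulus repeats.

    For even counts the midpoint of the two central order statistics is
    used. All traces must share the grid and the stimulus identity; the
    result's repeat field is ``"median"``.
    """
    if not traces:
        raise ValueError("need at least one trace")
    key = traces[0].stimulus_key
    n = len(traces[0].voltage)
    for tr in traces[1:]:
        if tr.stimulus_key != key:
            raise ValueError(
                f"mixed stimulus identities: {tr.stimulus_key} != {key}"
            )
        if len(tr.voltage) != n or tr.sampling_rate != traces[0].sampling_rate:
            raise ValueError("traces do not share the sample grid")
    stack = np.vstack([tr.voltage for tr in traces])
    return replace(traces[0], voltage=np.median(stack, axis=0), repeat=MEDIAN_REPEAT)


def _window_samples(window_ms: float, fs: float) -> int:
    w = window_ms * fs / 1000.0
    if abs(w - round(w)) > 1e-9:
        raise ValueError(
            f"window of {window_ms} ms is not an integer number of samples "
            f"at {fs} Hz"
        )
    w = int(round(w))
    if w % 2 == 0:
        raise ValueError(f"running median window must be odd, got {w} samples")
    return w


def running_median(trace: Trace, window_ms: float = 11.0) -> Trace:
    """Centered running median filter (default 11 ms window).

    Edge samples use a shrinking window (the median over the available
    samples), so the output length equals the input length. The window
    must map to an odd integer sample count at the trace's rate.
    """
    w = _window_samples(window_ms, trace.sampling_rate)
    return replace(trace, voltage=_running_median_array(trace.voltage, w))


def _running_median_array(x: np.ndarray, w: int) -> np.ndarray:
    h = w // 2
    n = len(x)
    out = np.empty(n, dtype=float)
    if n >= w:
        view = np.lib.stride_tricks.sliding_window_view(x, w)
        out[h : n - h] = np.median(view, axis=1)
    for i in range(min(h, n)):
        out[i] = np.median(x[: i + h + 1])
    for i in range(max(n - h, 0), n):
        out[i] = np.median(x[max(i - h, 0) :])
    return out


def preprocess_recording(
    recording: Recording, window_ms: float = 11.0, filter_after_median: bool = True
) -> list[Trace]:
    """Full preprocessing of one recording.

    Groups events by (odorant, pulse duration, block), segments and
    baseline-corrects each repeat, takes the median over repeats, and
    applies the running median filter. By default the filter runs after
    the median-of-repeats (the reference order); set
    ``filter_after_median=False`` to filter each repeat first instead
    (sensitivity checks).
    """
    out: list[Trace] = []
    groups = recording.events.groupby(
        ["odorant", "valve_open_s", "block"], sort=False
    )
    for (_, _, block), ev in groups:
        if block == "train":
            # a 10-Hz train is one stimulus: lock to its first opening
            ev = ev.iloc[:1]
        traces = [baseline_correct(segment(recording, row)) for _, row in ev.iterrows()]
        if not filter_after_median:
            traces = [running_median(tr, window_ms) for tr in traces]
        med = median_over_repeats(traces)
        if filter_after_median:
            med = running_median(med, window_ms)
        out.append(med)
    return out
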