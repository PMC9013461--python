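"""Antenna quality control.

Two screens decide whether an antenna's recordings enter the analysis:

1. Responsiveness -- the filtered median trace of the final control block
   must exceed a 2-SD response threshold for at least 50 consecutive ms
   between 50 and 1000 ms after valve opening.
2. Baseline stability -- the continuous recording must not contain a
   sudden step-like baseline shift (criterion fully specified here; the
   defaults are tuned so that generator artifacts of the documented
   magnitude are always caught while artifact-free recordings are not).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .preprocess import Trace
from .signal_io import Recording

__all__ = [
    "QCResult",
    "RESPONSE_WINDOW_S",
    "MIN_RUN_MS",
    "response_threshold",
    "detect_response",
    "detect_baseline_shift",
    "qc_antenna",
]

#: response search window, inclusive endpoints (s after valve opening)
RESPONSE_WINDOW_S = (0.05, 1.0)

#: minimum supra-threshold run length (ms)
MIN_RUN_MS = 50.0

#: tail window used for the threshold SD (s, relative time, half-open)
THRESHOLD_TAIL_S = (1.8, 4.8)


@dataclass
class QCResult:
    """Per-antenna QC outcome; ``decision`` is "include" or "exclude"."""

    antenna_id: str
    responsive: bool
    threshold_mV: float
    longest_exceedance_ms: float
    baseline_shift_detected: bool
    decision: str
    reason: str


def response_threshold(median_trace: Trace) -> float:
    """2 x population SD of the last 3 s of the trace ([1.8, 4.8) s).

    Invariant to adding a constant to the whole trace.
    """
    tail = median_trace.window(*THRESHOLD_TAIL_S)
    return 2.0 * float(np.std(tail))


def _longest_run(above: np.ndarray) -> int:
    if not above.any():
        return 0
    padded = np.concatenate(([0], above.astype(np.int8), [0]))
    edges = np.flatnonzero(np.diff(padded))
    return int((edges[1::2] - edges[::2]).max())


def detect_response(median_trace: Trace, threshold: float) -> tuple[bool, float]:
    """Check for >= 50 consecutive ms strictly above ``threshold`` within
    [50, 1000] ms (inclusive) after valve opening.

    A run is counted in whole samples fully inside the window and
    converted to ms (one sample period per sample). Returns
    ``(responsive, longest_exceedance_ms)``.
    """
    if threshold < 0:
        raise ValueError("threshold must be >= 0")
    t = median_trace.times()
    lo, hi = RESPONSE_WINDOW_S
    mask = (t >= lo - 1e-12) & (t <= hi + 1e-12)
    above = median_trace.voltage[mask] > threshold
    run = _longest_run(above)
    run_ms = run * 1000.0 / median_trace.sampling_rate
    return run_ms >= MIN_RUN_MS, run_ms


def qc_antenna(
    final_control_median_trace: Trace,
    baseline_shift_detected: bool = False,
) -> QCResult:
    """Include/exclude decision from the final-control median trace.

    The responsiveness decision is a pure function of this trace;
    exclusion applies to all of the antenna's recordings. A pre-computed
    baseline-shift flag (see :func:`detect_baseline_shift`) may be folded
    into the decision.
    """
    if final_control_median_trace.block != "control":
        raise ValueError(
            "qc_antenna expects the median trace of the final control block, "
            f"got block {final_control_median_trace.block!r}"
        )
    thr = response_threshold(final_control_median_trace)
    responsive, run_ms = detect_response(final_control_median_trace, thr)
    if not responsive:
        decision, reason = "exclude", "unresponsive"
    elif baseline_shift_detected:
        decision, reason = "exclude", "baseline shift"
    else:
        decision, reason = "include", ""
    return QCResult(
        antenna_id=final_control_median_trace.antenna_id,
        responsive=responsive,
        threshold_mV=thr,
        longest_exceedance_ms=run_ms,
        baseline_shift_detected=baseline_shift_detected,
        decision=decision,
        reason=reason,
    )


def detect_baseline_shift(
    recording: Recording,
    k: float = 6.0,
    window_s: float = 0.5,
    step_s: float = 0.05,
    stimulus_exclusion_s: tuple[float, float] = (-0.1, 1.5),
    train_exclusion_s: float = 4.0,
) -> bool:
    """Screen a continuous recording for a sudden baseline step.

    At candidate positions (every ``step_s``), the medians of the
    adjacent ``window_s`` windows before and after the position are
    compared; a shift is flagged when their absolute difference exceeds
    ``k`` times a robust noise scale (1.4826 x MAD of the first-difference
    signal). Positions whose comparison windows would overlap
    ``stimulus_exclusion_s`` (relative seconds) around any stimulus onset
    are skipped -- the zone is dilated by ``window_s`` on both sides -- so
    genuine responses are never mistaken for artifacts (steps landing
    inside a response window are a documented blind spot). A 10-Hz train
    accumulates a response that outlasts a single pulse, so train events
    use the longer ``train_exclusion_s`` tail. Invariant to adding a
    constant to the whole recording.
    """
    v = recording.voltage
    fs = recording.sampling_rate
    w = int(round(window_s * fs))
    if len(v) <= 2 * w:
        raise ValueError("recording shorter than two analysis windows")
    diff = np.diff(v)
    noise = 1.4826 * float(np.median(np.abs(diff - np.median(diff))))
    if noise == 0.0:
        noise = np.finfo(float).tiny

    step = max(int(round(step_s * fs)), 1)
    positions = np.arange(w, len(v) - w, step)
    pos_t = recording.t0 + positions / fs
    onsets = recording.events["onset_s"].to_numpy(dtype=float)
    if len(onsets):
        is_train = (recording.events["block"] == "train").to_numpy()
        lo = stimulus_exclusion_s[0] - window_s
        hi = np.where(is_train, train_exclusion_s, stimulus_exclusion_s[1]) + window_s
        rel = pos_t[:, None] - onsets[None, :]
        excluded = np.any((rel >= lo) & (rel <= hi[None, :]), axis=1)
        positions = positions[~excluded]
    for p in positions:
        before = np.median(v[p - w : p])
        after = np.median(v[p : p + w])
        if abs(after - before) > k * noise:
            return True
    return False
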