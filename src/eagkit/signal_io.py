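"""On-disk representation of EAG recordings.

A recording is stored as three plain-text files sharing a common stem:

- ``<antenna_id>.trace.csv``  -- columns ``time_s, voltage_mV``
- ``<antenna_id>.events.csv`` -- the stimulus event table
- ``<antenna_id>.meta.json``  -- antenna metadata and the sampling grid

The time column is redundant with ``(t0, sampling_rate)`` but is kept for
human inspection; the reader trusts the metadata and cross-checks the
column against it.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = [
    "Recording",
    "FormatError",
    "ECOTYPES",
    "EVENT_COLUMNS",
    "make_event_table",
    "write_recording",
    "read_recording",
    "validate_recording",
]

ECOTYPES = ("full-winged", "wing-reduced", "reference")

#: canonical event-table columns, in file order
EVENT_COLUMNS = ("onset_s", "valve_open_s", "odorant", "block", "repeat_index")

#: allowed block labels
BLOCKS = ("main", "train", "control")

#: absolute tolerance (s) for gaps in the stored time column
TIME_GRID_TOL_S = 1e-6


class FormatError(ValueError):
    """Raised when on-disk data violate the recording format."""


def make_event_table(rows) -> pd.DataFrame:
    """Build an event table from an iterable of (onset_s, valve_open_s,
    odorant, block, repeat_index) tuples."""
    df = pd.DataFrame(list(rows), columns=list(EVENT_COLUMNS))
    df["onset_s"] = df["onset_s"].astype(float)
    df["valve_open_s"] = df["valve_open_s"].astype(float)
    df["repeat_index"] = df["repeat_index"].astype(int)
    return df


@dataclass
class Recording:
    """A continuous single-channel voltage recording with its event table.

    Attributes
    ----------
    antenna_id : str
        Unique identifier of the antenna.
    ecotype : str
        One of ``full-winged``, ``wing-reduced`` or ``reference``.
    population : str
        Collection-site label.
    sampling_rate : float
        Samples per second (Hz).
    voltage : numpy.ndarray
        Voltage in millivolts, uniformly sampled.
    t0 : float
        Absolute time (s) of the first sample.
    events : pandas.DataFrame
        Stimulus event table with columns :data:`EVENT_COLUMNS`.
    """

    antenna_id: str
    ecotype: str
    population: str
    sampling_rate: float
    voltage: np.ndarray
    t0: float = 0.0
    events: pd.DataFrame = field(default_factory=lambda: make_event_table([]))

    @property
    def duration_s(self) -> float:
        return len(self.voltage) / self.sampling_rate

    def times(self) -> np.ndarray:
        """Absolute sample times (s)."""
        return self.t0 + np.arange(len(self.voltage)) / self.sampling_rate

    def copy(self) -> "Recording":
        return replace(
            self, voltage=self.voltage.copy(), events=self.events.copy()
        )


def _paths(directory: Path, antenna_id: str) -> tuple[Path, Path, Path]:
    d = Path(directory)
    return (
        d / f"{antenna_id}.trace.csv",
        d / f"{antenna_id}.events.csv",
        d / f"{antenna_id}.meta.json",
    )


def write_recording(recording: Recording, directory) -> list[Path]:
    """Write a recording to ``directory``; returns the created file paths.

    Floats are serialized with Python's shortest round-trip repr so that
    ``read_recording(write_recording(r)) == r`` holds bit-exactly.
    """
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    trace_path, events_path, meta_path = _paths(directory, recording.antenna_id)

    trace = pd.DataFrame(
        {
            "time_s": recording.times(),
            "voltage_mV": np.asarray(recording.voltage, dtype=float),
        }
    )
    trace.to_csv(trace_path, index=False)
    recording.events.loc[:, list(EVENT_COLUMNS)].to_csv(events_path, index=False)
    meta = {
        "antenna_id": recording.antenna_id,
        "ecotype": recording.ecotype,
        "population": recording.population,
        "sampling_rate": recording.sampling_rate,
        "t0": recording.t0,
        "n_samples": int(len(recording.voltage)),
    }
    meta_path.write_text(json.dumps(meta, indent=2) + "\n")
    return [trace_path, events_path, meta_path]


def _check_time_column(times: np.ndarray, t0: float, fs: float) -> None:
    dt = 1.0 / fs
    expected = t0 + np.arange(len(times)) * dt
    err = np.abs(times - expected)
    bad = np.nonzero(err > TIME_GRID_TOL_S)[0]
    if bad.size:
        row = int(bad[0])
        raise FormatError(
            f"non-uniform time grid: row {row} has time {times[row]!r}, "
            f"expected {expected[row]!r} (tolerance {TIME_GRID_TOL_S} s)"
        )


def _check_events_sorted(events: pd.DataFrame) -> None:
    onsets = events["onset_s"].to_numpy()
    if len(onsets) > 1:
        bad = np.nonzero(np.diff(onsets) < 0)[0]
        if bad.size:
            row = int(bad[0]) + 1
            raise FormatError(
                f"event table not sorted by onset: row {row} "
                f"(onset {onsets[row]!r} after {onsets[row - 1]!r})"
            )


def read_recording(directory, antenna_id: str) -> Recording:
    """Read a recording previously written by :func:`write_recording`.

    Raises :class:`FormatError` on missing files, a non-uniform time grid
    (tolerance ``1e-6`` s against the sidecar's ``t0``/``sampling_rate``),
    or an unsorted event table, naming the offending row.
    """
    trace_path, events_path, meta_path = _paths(Path(directory), antenna_id)
    for p in (trace_path, events_path, meta_path):
        if not p.exists():
            raise FormatError(f"missing file: {p}")

    meta = json.loads(meta_path.read_text())
    fs = float(meta["sampling_rate"])
    t0 = float(meta["t0"])

    trace = pd.read_csv(trace_path, float_precision="round_trip")
    if list(trace.columns) != ["time_s", "voltage_mV"]:
        raise FormatError(f"unexpected trace columns in {trace_path}: {list(trace.columns)}")
    times = trace["time_s"].to_numpy(dtype=float)
    _check_time_column(times, t0, fs)

    events = pd.read_csv(events_path, float_precision="round_trip")
    missing = [c for c in EVENT_COLUMNS if c not in events.columns]
    if missing:
        raise FormatError(f"event table missing columns {missing} in {events_path}")
    if len(events) == 0:
        events = make_event_table([])
    else:
        events = events.loc[:, list(EVENT_COLUMNS)]
        events["repeat_index"] = events["repeat_index"].astype(int)
    _check_events_sorted(events)

    return Recording(
        antenna_id=str(meta["antenna_id"]),
        ecotype=str(meta["ecotype"]),
        population=str(meta["population"]),
        sampling_rate=fs,
        voltage=trace["voltage_mV"].to_numpy(dtype=float),
        t0=t0,
        events=events,
    )


def validate_recording(recording: Recording) -> list[str]:
    """Check Recording invariants; returns a list of human-readable issues.

    Never raises on bad data -- an empty list means the recording is valid.
    """
    issues: list[str] = []
    if len(recording.voltage) < 1:
        issues.append("voltage series is empty")
    if not recording.sampling_rate > 0:
        issues.append(f"sampling_rate must be > 0, got {recording.sampling_rate}")
    if recording.ecotype not in ECOTYPES:
        issues.append(f"unknown ecotype {recording.ecotype!r}")
    if not np.all(np.isfinite(recording.voltage)):
        issues.append("voltage contains non-finite values")

    ev = recording.events
    onsets = ev["onset_s"].to_numpy(dtype=float) if len(ev) else np.array([])
    if len(onsets) > 1 and np.any(np.diff(onsets) < 0):
        row = int(np.nonzero(np.diff(onsets) < 0)[0][0]) + 1
        issues.append(f"event onsets not sorted ascending (row {row})")
    if len(ev) and recording.sampling_rate > 0 and len(recording.voltage):
        end = recording.t0 + recording.duration_s
        for row, onset in enumerate(onsets):
            if onset < recording.t0 or onset > end:
                issues.append(
                    f"event row {row}: onset {onset} outside recording "
                    f"[{recording.t0}, {end}]"
                )
    if len(ev):
        for row, (block, rep) in enumerate(
            zip(ev["block"], ev["repeat_index"].astype(int))
        ):
            if block not in BLOCKS:
                issues.append(f"event row {row}: unknown block {block!r}")
            if block in ("main", "control") and not 1 <= rep <= 10:
                issues.append(
                    f"event row {row}: repeat_index {rep} outside 1..10"
                )
    return issues
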