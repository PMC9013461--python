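import numpy as np
import pytest

from eagkit.preprocess import PRE_S, Trace

FS = 1000.0
N_GRID = 5000  # 5 s at 1 kHz


def make_trace(voltage, fs=FS, **kwargs) -> Trace:
    defaults = dict(
        antenna_id="a1",
        odorant="2-heptanone",
        pulse_duration_ms=300.0,
        block="main",
        repeat=1,
    )
    defaults.update(kwargs)
    return Trace(voltage=np.asarray(voltage, dtype=float), sampling_rate=fs, **defaults)


def grid_trace(fill=0.0, **kwargs) -> Trace:
    """A standard-grid trace ([-0.2, 4.8) s at 1 kHz) filled with a constant."""
    return make_trace(np.full(N_GRID, float(fill)), **kwargs)


def rel_index(t_rel: float, fs=FS) -> int:
    """Index on the standard grid of the sample at relative time t_rel."""
    return int(round((t_rel + PRE_S) * fs))


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
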