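"""Synthetic EAG recordings with known ground truth.

The generator emulates the stimulation protocol and the statistical
structure the downstream analysis assumes: odorant concentration dynamics
with slow (>150 ms) rise times, a linear first-order transduction cascade
per antenna, ecotype-dependent amplitude and kinetics, additive Gaussian
noise, slow drift, and rare step-like baseline-shift artifacts. Every
quantity the pipeline later estimates is recorded in a ground-truth table.

Model summary (per antenna):

    valve state --first-order (odorant rise/decay tau)--> concentration
    concentration --delay--> --low-pass (rise tau)--> --high-pass-like
    adaptation (decay tau)--> x gain --> voltage (+ noise + drift
    + optional baseline step)

Positive deflections are excitatory. All randomness flows from
``GeneratorConfig.rng_seed``; identical config and seed give bit-identical
output.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy.signal import lfilter

from .signal_io import Recording, make_event_table

__all__ = [
    "OdorantKinetics",
    "AntennaKinetics",
    "EcotypeEffects",
    "GeneratorConfig",
    "StimulusProtocol",
    "AntennaSpec",
    "build_protocol",
    "concentration_trace",
    "generate_recording",
    "generate_cohort",
    "fast_antenna_config",
    "slow_antenna_config",
]

#: valve-open durations of the main stimulus series (s)
PULSE_DURATIONS_S = (0.015, 0.030, 0.150, 0.300)

#: inter-stimulus interval of the main and control series (s)
ISI_S = 5.0

#: gap between the last 300-ms stimulus and the 10-Hz train (s)
TRAIN_DELAY_S = 10.0

#: 10-Hz train: valve open time, period, number of openings
TRAIN_OPEN_S = 0.050
TRAIN_PERIOD_S = 0.100
TRAIN_N_OPENINGS = 30

#: gap between the end of the train and the next block (s)
POST_TRAIN_GAP_S = 5.0

#: lead-in before the first stimulus (s); must exceed the 0.2 s
#: pre-stimulus segmentation window
PROTOCOL_START_S = 1.0


class ConfigurationError(ValueError):
    """Raised when generator parameters violate their invariants."""


@dataclass(frozen=True)
class OdorantKinetics:
    """First-order concentration dynamics of one odorant channel."""

    rise_s: float
    decay_s: float

    def __post_init__(self):
        if self.rise_s <= 0 or self.decay_s <= 0:
            raise ConfigurationError("odorant time constants must be > 0")


@dataclass(frozen=True)
class AntennaKinetics:
    """Linear transduction cascade parameters of one antenna."""

    latency_s: float = 0.03
    rise_s: float = 0.06
    decay_s: float = 1.2
    gain_mv: float = 5.0

    def __post_init__(self):
        if self.rise_s <= 0 or self.decay_s <= 0:
            raise ConfigurationError("antenna time constants must be > 0")
        if self.latency_s < 0:
            raise ConfigurationError("latency must be >= 0")


@dataclass(frozen=True)
class EcotypeEffects:
    """Ground-truth ecotype contrasts (wing-reduced relative to full-winged).

    ``amplitude_ratio`` scales the wing-reduced gain multiplicatively;
    ``onset_delay_s`` adds to the wing-reduced transduction latency
    (shifting both onset and offset); ``offset_delay_s`` adds to the
    wing-reduced adaptation time constant, lengthening measured offsets
    monotonically (the mapping to the 10%-crossing shift is approximate).
    """

    amplitude_ratio: float = 1.0
    onset_delay_s: float = 0.0
    offset_delay_s: float = 0.0

    def __post_init__(self):
        if self.amplitude_ratio <= 0:
            raise ConfigurationError("amplitude_ratio must be > 0")


def _default_odorant_kinetics() -> dict:
    # rise times > 150 ms, odorant-specific
    return {
        "2-heptanone": OdorantKinetics(rise_s=0.25, decay_s=0.35),
        "1-octanol": OdorantKinetics(rise_s=0.30, decay_s=0.50),
        "2-butanone": OdorantKinetics(rise_s=0.18, decay_s=0.25),
    }


@dataclass(frozen=True)
class GeneratorConfig:
    """All knobs of the synthetic cohort generator.

    Noise, drift and between-antenna variance defaults are assumptions of
    this generator (chosen to stress the analysis), not measured values.
    """

    sampling_rate: float = 1000.0
    odorants: tuple = ("2-heptanone",)
    odorant_kinetics: dict = field(default_factory=_default_odorant_kinetics)
    antenna_kinetics: AntennaKinetics = field(default_factory=AntennaKinetics)
    ecotype_effects: EcotypeEffects = field(default_factory=EcotypeEffects)
    noise_sd_mv: float = 0.05
    drift_amplitude_mv: float = 0.15
    drift_timescale_s: float = 60.0
    drift_random_walk_sd: float = 0.0
    artifact_probability: float = 0.0
    artifact_magnitude_mv: float = 2.0
    n_antennae: int = 10
    antenna_gain_sd_log2: float = 0.4
    n_repeats: int = 10
    rng_seed: int = 0

    def __post_init__(self):
        if self.sampling_rate <= 0:
            raise ConfigurationError("sampling_rate must be > 0")
        if self.noise_sd_mv < 0:
            raise ConfigurationError("noise_sd_mv must be >= 0")
        if not 0.0 <= self.artifact_probability <= 1.0:
            raise ConfigurationError("artifact_probability must be in [0, 1]")
        if self.drift_timescale_s <= 0:
            raise ConfigurationError("drift_timescale_s must be > 0")
        if not 1 <= self.n_repeats <= 10:
            raise ConfigurationError("n_repeats must be in 1..10")
        for name in self.odorants:
            if name not in self.odorant_kinetics:
                raise ConfigurationError(f"no kinetics for odorant {name!r}")


@dataclass(frozen=True)
class StimulusProtocol:
    """Ordered stimulus events (main series, 10-Hz trains, final control)."""

    events: pd.DataFrame

    def __post_init__(self):
        onsets = self.events["onset_s"].to_numpy()
        if len(onsets) > 1 and not np.all(np.diff(onsets) > 0):
            raise ConfigurationError("event onsets must be strictly increasing")

    @property
    def duration_s(self) -> float:
        """Protocol span: last onset plus one trailing ISI."""
        return float(self.events["onset_s"].iloc[-1]) + ISI_S

    def odorants(self) -> list[str]:
        return list(dict.fromkeys(self.events["odorant"]))


def build_protocol(config: GeneratorConfig, odorants=None) -> StimulusProtocol:
    """Build the full stimulation protocol.

    Per odorant: ``n_repeats`` presentations of each valve-open duration
    (15/30/150/300 ms) at 5 s ISI, then -- 10 s after the last 300 ms
    stimulus -- a 10-Hz train (50 ms openings, 100 ms period, 30 openings
    spanning 3 s). 5 s after the train the next odorant begins; a final
    control block of ``n_repeats`` x 300 ms presentations of the first
    odorant ends the protocol.
    """
    odorants = list(odorants if odorants is not None else config.odorants)
    if not odorants:
        raise ConfigurationError("odorant list must be non-empty")

    rows = []
    t = PROTOCOL_START_S
    for odorant in odorants:
        for dur in PULSE_DURATIONS_S:
            for rep in range(1, config.n_repeats + 1):
                rows.append((t, dur, odorant, "main", rep))
                t += ISI_S
        # t is now last main onset + ISI; train starts TRAIN_DELAY_S after
        # the last 300 ms stimulus onset
        train_start = t - ISI_S + TRAIN_DELAY_S
        for k in range(TRAIN_N_OPENINGS):
            rows.append(
                (train_start + k * TRAIN_PERIOD_S, TRAIN_OPEN_S, odorant, "train", k + 1)
            )
        t = train_start + TRAIN_N_OPENINGS * TRAIN_PERIOD_S + POST_TRAIN_GAP_S
    for rep in range(1, config.n_repeats + 1):
        rows.append((t, 0.300, odorants[0], "control", rep))
        t += ISI_S
    return StimulusProtocol(events=make_event_table(rows))


def concentration_trace(
    events: pd.DataFrame,
    kinetics: OdorantKinetics,
    sampling_rate: float,
    n_samples: int,
    t0: float = 0.0,
) -> np.ndarray:
    """Odorant concentration (in [0, 1]) from a valve event table.

    The 0/1 valve state drives an exact first-order low-pass whose time
    constant is ``rise_s`` while the valve is open and ``decay_s`` after it
    closes, so a valve opening of length T from rest peaks at
    ``1 - exp(-T / rise_s)``.
    """
    dt = 1.0 / sampling_rate
    valve = np.zeros(n_samples, dtype=bool)
    for onset, dur in zip(events["onset_s"], events["valve_open_s"]):
        i0 = int(np.ceil((onset - t0) * sampling_rate - 1e-9))
        i1 = int(np.ceil((onset + dur - t0) * sampling_rate - 1e-9))
        valve[max(i0, 0) : max(i1, 0)] = True

    conc = np.empty(n_samples, dtype=float)
    bounds = np.flatnonzero(np.diff(valve.astype(np.int8))) + 1
    starts = np.concatenate(([0], bounds))
    ends = np.concatenate((bounds, [n_samples]))
    c_prev = 0.0
    for s, e in zip(starts, ends):
        target = 1.0 if valve[s] else 0.0
        tau = kinetics.rise_s if valve[s] else kinetics.decay_s
        decay = np.exp(-np.arange(1, e - s + 1) * dt / tau)
        conc[s:e] = target + (c_prev - target) * decay
        c_prev = conc[e - 1]
    return conc


@dataclass(frozen=True)
class AntennaSpec:
    """Per-antenna identity plus its realized transduction parameters."""

    antenna_id: str
    ecotype: str
    population: str
    kinetics: AntennaKinetics


def _transduce(conc: np.ndarray, kinetics: AntennaKinetics, fs: float) -> np.ndarray:
    """Linear cascade: latency delay, low-pass (rise), adaptation high-pass
    (decay), gain."""
    n_lat = int(round(kinetics.latency_s * fs))
    x = np.zeros_like(conc)
    if n_lat < len(conc):
        x[n_lat:] = conc[: len(conc) - n_lat] if n_lat else conc
    dt = 1.0 / fs
    a_r = np.exp(-dt / kinetics.rise_s)
    y = lfilter([1.0 - a_r], [1.0, -a_r], x)
    a_d = np.exp(-dt / kinetics.decay_s)
    z = lfilter([1.0 - a_d], [1.0, -a_d], y)
    return kinetics.gain_mv * (y - z)


def generate_recording(
    config: GeneratorConfig,
    protocol: StimulusProtocol,
    antenna: AntennaSpec,
    rng: np.random.Generator | None = None,
) -> Recording:
    """Render one antenna's voltage trace for a protocol.

    The deterministic response is the summed transduction of each
    odorant's concentration trace; noise, drift and the optional baseline
    step are drawn from ``rng`` (a fresh generator seeded from the config
    if omitted). ``noise_sd_mv = 0`` is allowed for deterministic tests.
    """
    if rng is None:
        rng = np.random.default_rng(config.rng_seed)
    fs = config.sampling_rate
    n = int(np.ceil(protocol.duration_s * fs))
    voltage = np.zeros(n, dtype=float)

    for odorant in protocol.odorants():
        ev = protocol.events[protocol.events["odorant"] == odorant]
        conc = concentration_trace(
            ev, config.odorant_kinetics[odorant], fs, n, t0=0.0
        )
        voltage += _transduce(conc, antenna.kinetics, fs)

    t = np.arange(n) / fs
    if config.drift_amplitude_mv > 0:
        phase = rng.uniform(0.0, 2.0 * np.pi)
        voltage += config.drift_amplitude_mv * np.sin(
            2.0 * np.pi * t / config.drift_timescale_s + phase
        )
    if config.drift_random_walk_sd > 0:
        steps = rng.normal(0.0, config.drift_random_walk_sd / np.sqrt(fs), n)
        voltage += np.cumsum(steps)
    if config.artifact_probability > 0:
        u = rng.random()
        loc = rng.uniform(0.05, 0.95)
        sign = 1.0 if rng.random() < 0.5 else -1.0
        if u < config.artifact_probability:
            voltage[int(loc * n) :] += sign * config.artifact_magnitude_mv
    if config.noise_sd_mv > 0:
        voltage += rng.normal(0.0, config.noise_sd_mv, n)

    return Recording(
        antenna_id=antenna.antenna_id,
        ecotype=antenna.ecotype,
        population=antenna.population,
        sampling_rate=fs,
        voltage=voltage,
        t0=0.0,
        events=protocol.events.copy(),
    )


def _antenna_kinetics_for(config: GeneratorConfig, ecotype: str, gain_factor: float) -> AntennaKinetics:
    base = config.antenna_kinetics
    eff = config.ecotype_effects
    if ecotype == "wing-reduced":
        return AntennaKinetics(
            latency_s=base.latency_s + eff.onset_delay_s,
            rise_s=base.rise_s,
            decay_s=base.decay_s + eff.offset_delay_s,
            gain_mv=base.gain_mv * eff.amplitude_ratio * gain_factor,
        )
    return replace(base, gain_mv=base.gain_mv * gain_factor)


def generate_cohort(
    config: GeneratorConfig,
    protocol: StimulusProtocol | None = None,
    population: str = "pop1",
) -> tuple[list[Recording], pd.DataFrame]:
    """Generate a paired cohort of full-winged and wing-reduced antennae.

    Returns the recordings plus a ground-truth table holding each
    antenna's realized gain and latency together with the cohort-level
    true log2 amplitude ratio and onset/offset deltas -- the quantities
    the statistical models must recover. Per-antenna gains are drawn
    multiplicatively around the ecotype mean with SD
    ``antenna_gain_sd_log2`` on the log2 scale (the variance the random
    intercept absorbs).
    """
    if config.n_antennae < 1:
        raise ConfigurationError("n_antennae must be >= 1 per ecotype")
    if protocol is None:
        protocol = build_protocol(config)

    master = np.random.SeedSequence(config.rng_seed)
    recordings: list[Recording] = []
    truth_rows = []
    true_log2_ratio = float(np.log2(config.ecotype_effects.amplitude_ratio))
    for ecotype, prefix in (("full-winged", "fw"), ("wing-reduced", "wr")):
        for i in range(config.n_antennae):
            rng = np.random.default_rng(master.spawn(1)[0])
            gain_factor = float(2.0 ** rng.normal(0.0, config.antenna_gain_sd_log2))
            kin = _antenna_kinetics_for(config, ecotype, gain_factor)
            spec = AntennaSpec(
                antenna_id=f"{prefix}{i + 1:02d}",
                ecotype=ecotype,
                population=population,
                kinetics=kin,
            )
            recordings.append(generate_recording(config, protocol, spec, rng=rng))
            truth_rows.append(
                {
                    "antenna_id": spec.antenna_id,
                    "ecotype": ecotype,
                    "population": population,
                    "true_gain_mv": kin.gain_mv,
                    "true_latency_s": kin.latency_s,
                    "true_decay_s": kin.decay_s,
                    "true_log2_ratio": true_log2_ratio,
                    "true_onset_delay_s": config.ecotype_effects.onset_delay_s,
                    "true_offset_delay_s": config.ecotype_effects.offset_delay_s,
                }
            )
    return recordings, pd.DataFrame(truth_rows)


def fast_antenna_config(**overrides) -> GeneratorConfig:
    """Honey-bee-like preset: kinetics fast enough to track 10-Hz pulses."""
    defaults = dict(
        odorants=("2-butanone",),
        odorant_kinetics={"2-butanone": OdorantKinetics(rise_s=0.010, decay_s=0.012)},
        antenna_kinetics=AntennaKinetics(
            latency_s=0.005, rise_s=0.004, decay_s=0.250, gain_mv=5.0
        ),
        noise_sd_mv=0.05,
        drift_amplitude_mv=0.0,
    )
    defaults.update(overrides)
    return GeneratorConfig(**defaults)


def slow_antenna_config(**overrides) -> GeneratorConfig:
    """Stonefly-like preset: slow kinetics that cannot track 10-Hz pulses."""
    defaults = dict(
        odorants=("2-heptanone",),
        odorant_kinetics={"2-heptanone": OdorantKinetics(rise_s=0.30, decay_s=0.40)},
        antenna_kinetics=AntennaKinetics(
            latency_s=0.03, rise_s=0.80, decay_s=2.0, gain_mv=5.0
        ),
        noise_sd_mv=0.10,
        drift_amplitude_mv=0.0,
    )
    defaults.update(overrides)
    return GeneratorConfig(**defaults)
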