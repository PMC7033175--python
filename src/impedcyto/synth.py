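"""Seeded generator of multi-frequency lock-in traces with ground truth.

Emulates the demodulated amplitude channels a lock-in amplifier delivers
while particles transit the sensing pore: every event is a smooth Gaussian
voltage bump appearing simultaneously on all frequency channels, riding on
slow baseline drift and additive white noise.  Event amplitudes are
parameterised directly in µV at the 500 kHz reference frequency (the
drive-to-voltage conversion of the instrument chain is not modelled); the
equivalent-circuit model supplies only the *relative* amplitude across
frequencies, so bead events are flat across channels while cell and
aggregate events decline at high frequency.

Three presets mirror the assay's experimental samples:

``pure_beads``
    300 events, 90 % single beads (2 µV) + 10 % non-specific doublets (10 µV).
``pure_cells``
    300 events, all cells (15 µV).
``mixture``
    200 events from an immuno-magnetic separation: 75 % bare beads plus 25 %
    bead-cell aggregates (25 µV mean, broad spread, essentially all > 10 µV).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from pathlib import Path

import h5py
import numpy as np
import pandas as pd

from .circuit import (
    ElectrodeCircuit,
    FrequencyGrid,
    InvalidParameterError,
    ParticleKind,
    ParticleModel,
    default_particles,
    delta_impedance_magnitude,
)

REFERENCE_FREQUENCY_HZ = 500e3

PRESET_NAMES = ("pure_beads", "pure_cells", "mixture")


class GenerationError(RuntimeError):
    """Raised when a trace cannot be generated under the given constraints."""


def freq_label(f_hz: float) -> str:
    """Column/dataset label for a frequency channel (integer hertz)."""
    return str(int(round(float(f_hz))))


def amp_column(f_hz: float) -> str:
    return f"amp_uv_{freq_label(f_hz)}"


def snr_column(f_hz: float) -> str:
    return f"snr_{freq_label(f_hz)}"


@dataclass(frozen=True)
class PopulationSpec:
    """One particle population within a sample.

    ``amp_mean_uv`` / ``amp_cv`` describe the peak-amplitude distribution at
    the reference frequency; ``particle`` supplies the circuit branch used to
    scale that amplitude to the other channels.
    """

    kind: ParticleKind
    weight: float
    amp_mean_uv: float
    amp_cv: float
    particle: ParticleModel

    def __post_init__(self) -> None:
        if not (0.0 <= self.weight <= 1.0):
            raise InvalidParameterError(f"weight must be in [0, 1], got {self.weight}")
        if not self.amp_mean_uv > 0:
            raise InvalidParameterError(f"amp_mean_uv must be > 0, got {self.amp_mean_uv}")
        if not (0.0 <= self.amp_cv < 1.0):
            raise InvalidParameterError(f"amp_cv must be in [0, 1), got {self.amp_cv}")


@dataclass(frozen=True)
class TraceConfig:
    """Acquisition and nuisance-signal settings for one simulated trace."""

    grid: FrequencyGrid = field(default_factory=FrequencyGrid)
    sampling_rate_hz: float = 100e3
    duration_s: float = 20.0
    n_events: int = 300
    pulse_width_s: float = 1e-3
    noise_sigma_uv: float = 0.3
    drift_amplitude_uv: float = 5.0
    drift_period_s: float = 30.0
    drift_slope_uv_per_s: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_events < 0:
            raise InvalidParameterError("n_events must be >= 0")
        if not self.pulse_width_s > 0 or not self.duration_s > 0:
            raise InvalidParameterError("pulse_width_s and duration_s must be > 0")
        if self.pulse_width_s * self.n_events >= self.duration_s:
            raise InvalidParameterError(
                f"{self.n_events} events of {self.pulse_width_s} s cannot fit "
                f"in {self.duration_s} s"
            )
        if not self.sampling_rate_hz > 2.0 / self.pulse_width_s:
            raise InvalidParameterError(
                "sampling_rate_hz must exceed 2 / pulse_width_s to resolve pulses"
            )
        if self.noise_sigma_uv < 0 or self.drift_amplitude_uv < 0:
            raise InvalidParameterError("noise and drift amplitudes must be >= 0")

    @property
    def n_samples(self) -> int:
        return int(round(self.duration_s * self.sampling_rate_hz))


@dataclass
class MultiFrequencyTrace:
    """Time-aligned demodulated amplitude channels, one per frequency, µV."""

    times_s: np.ndarray
    channels: dict[float, np.ndarray]
    grid: FrequencyGrid
    sampling_rate_hz: float

    def __post_init__(self) -> None:
        if len(self.channels) != len(self.grid):
            raise InvalidParameterError("channel count must equal grid length")
        n = len(self.times_s)
        for f, ch in self.channels.items():
            if len(ch) != n:
                raise InvalidParameterError(
                    f"channel {f} Hz length {len(ch)} != time base length {n}"
                )

    def channel(self, f_hz: float) -> np.ndarray:
        f = self.grid.frequencies_hz[self.grid.index_of(f_hz)]
        return self.channels[f]


def sample_population(
    spec: PopulationSpec, n: int, seed: int | np.random.Generator
) -> np.ndarray:
    """Draw ``n`` reference-frequency amplitudes, normal truncated at > 0."""
    if n < 0:
        raise InvalidParameterError("n must be >= 0")
    rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed
    mean = spec.amp_mean_uv
    sd = spec.amp_cv * mean
    if sd == 0.0:
        return np.full(n, mean)
    out = rng.normal(mean, sd, size=n)
    # resample the (rare) non-positive draws rather than clipping
    for _ in range(1000):
        bad = out <= 0
        if not bad.any():
            break
        out[bad] = rng.normal(mean, sd, size=int(bad.sum()))
    else:  # pragma: no cover - requires pathological cv
        raise GenerationError("could not draw positive amplitudes; amp_cv too large")
    return out


def scale_across_frequencies(
    ref_amp_uv: float,
    particle: ParticleModel,
    circuit: ElectrodeCircuit,
    grid: FrequencyGrid,
    ref_freq_hz: float = REFERENCE_FREQUENCY_HZ,
) -> np.ndarray:
    """Per-frequency amplitudes: ref_amp × ΔZ(f) / ΔZ(f_ref)."""
    if not ref_amp_uv > 0:
        raise InvalidParameterError(f"ref_amp_uv must be > 0, got {ref_amp_uv}")
    grid.index_of(ref_freq_hz)  # raises if absent
    dz_ref = delta_impedance_magnitude(circuit, particle, ref_freq_hz)
    return np.array(
        [ref_amp_uv * delta_impedance_magnitude(circuit, particle, f) / dz_ref for f in grid]
    )


def _place_event_indices(
    rng: np.random.Generator, config: TraceConfig
) -> np.ndarray:
    """Uniform-random event sample indices with a 3-pulse-width minimum gap."""
    n = config.n_events
    if n == 0:
        return np.array([], dtype=int)
    fs = config.sampling_rate_hz
    margin = int(math.ceil(3 * config.pulse_width_s * fs))
    min_gap = 3 * config.pulse_width_s
    lo, hi = margin, config.n_samples - margin
    if hi <= lo:
        raise GenerationError("trace too short for even one event with edge margins")
    if n * min_gap + 2 * 3 * config.pulse_width_s > config.duration_s:
        raise GenerationError(
            f"cannot place {n} events with minimum separation {min_gap} s "
            f"(no overlap within 3 pulse widths) in a {config.duration_s} s trace"
        )
    placed: list[int] = []
    max_attempts = 1000 * n
    attempts = 0
    while len(placed) < n:
        attempts += 1
        if attempts > max_attempts:
            raise GenerationError(
                f"could not place {n} events of width {config.pulse_width_s} s "
                f"in {config.duration_s} s without overlap "
                f"(minimum separation {min_gap} s)"
            )
        cand = int(rng.integers(lo, hi))
        if all(abs(cand - p) >= min_gap * fs for p in placed):
            placed.append(cand)
    return np.array(sorted(placed), dtype=int)


def generate_trace(
    config: TraceConfig,
    populations: list[PopulationSpec],
    circuit: ElectrodeCircuit | None = None,
) -> tuple[MultiFrequencyTrace, pd.DataFrame]:
    """Simulate one multi-frequency trace plus its ground-truth event log.

    The event log is a DataFrame with columns ``time_s``, ``kind`` and one
    ``amp_uv_<freq>`` column per grid frequency, sorted by time.  Output is
    bit-identical for identical ``(config, populations)``.
    """
    if not populations:
        raise InvalidParameterError("at least one population is required")
    wsum = sum(p.weight for p in populations)
    if abs(wsum - 1.0) > 1e-9:
        raise InvalidParameterError(f"population weights must sum to 1, got {wsum}")
    circuit = circuit or ElectrodeCircuit()
    rng = np.random.default_rng(config.seed)

    n = config.n_samples
    fs = config.sampling_rate_hz
    times = np.arange(n) / fs
    freqs = list(config.grid)

    # nuisance components + noise
    channels: dict[float, np.ndarray] = {}
    drift = np.zeros(n)
    if config.drift_amplitude_uv > 0:
        drift = config.drift_amplitude_uv * np.sin(2 * np.pi * times / config.drift_period_s)
    if config.drift_slope_uv_per_s != 0.0:
        drift = drift + config.drift_slope_uv_per_s * times
    for f in freqs:
        ch = drift.copy()
        if config.noise_sigma_uv > 0:
            ch = ch + rng.normal(0.0, config.noise_sigma_uv, size=n)
        channels[f] = ch

    # events
    event_idx = _place_event_indices(rng, config)
    pop_choice = rng.choice(len(populations), size=len(event_idx), p=[p.weight for p in populations])
    ratios = {
        id(p): scale_across_frequencies(1.0, p.particle, circuit, config.grid)
        for p in populations
    }
    sigma_t = config.pulse_width_s / 4.0
    half = int(math.ceil(5 * sigma_t * fs))
    rows = []
    for idx, pi in zip(event_idx, pop_choice):
        pop = populations[pi]
        ref_amp = float(sample_population(pop, 1, rng)[0])
        amps = ref_amp * ratios[id(pop)]
        window = np.arange(max(0, idx - half), min(n, idx + half + 1))
        bump = np.exp(-0.5 * ((window - idx) / (sigma_t * fs)) ** 2)
        for f, a in zip(freqs, amps):
            channels[f][window] += a * bump
        row = {"time_s": idx / fs, "kind": pop.kind.value}
        row.update({amp_column(f): a for f, a in zip(freqs, amps)})
        rows.append(row)

    columns = ["time_s", "kind"] + [amp_column(f) for f in freqs]
    log = pd.DataFrame(rows, columns=columns)
    trace = MultiFrequencyTrace(
        times_s=times, channels=channels, grid=config.grid, sampling_rate_hz=fs
    )
    return trace, log


# -- presets ----------------------------------------------------------------

def preset_populations(name: str) -> list[PopulationSpec]:
    parts = default_particles()
    if name == "pure_beads":
        return [
            PopulationSpec(ParticleKind.BEAD, 0.9, 2.0, 0.05, parts[ParticleKind.BEAD]),
            PopulationSpec(
                ParticleKind.BEAD_DOUBLET, 0.1, 10.0, 0.1, parts[ParticleKind.BEAD_DOUBLET]
            ),
        ]
    if name == "pure_cells":
        return [PopulationSpec(ParticleKind.CELL, 1.0, 15.0, 0.2, parts[ParticleKind.CELL])]
    if name == "mixture":
        return [
            PopulationSpec(ParticleKind.BEAD, 0.75, 2.0, 0.05, parts[ParticleKind.BEAD]),
            PopulationSpec(
                ParticleKind.AGGREGATE, 0.25, 25.0, 0.3, parts[ParticleKind.AGGREGATE]
            ),
        ]
    raise InvalidParameterError(f"unknown preset {name!r}; choose from {PRESET_NAMES}")


def preset_config(name: str, seed: int) -> TraceConfig:
    n_events = {"pure_beads": 300, "pure_cells": 300, "mixture": 200}
    if name not in n_events:
        raise InvalidParameterError(f"unknown preset {name!r}; choose from {PRESET_NAMES}")
    return TraceConfig(n_events=n_events[name], seed=seed)


def preset_sample(
    name: str, seed: int, config: TraceConfig | None = None
) -> tuple[MultiFrequencyTrace, pd.DataFrame]:
    """Simulate one of the three experimental samples."""
    cfg = config if config is not None else preset_config(name, seed)
    if config is not None and config.seed != seed:
        cfg = replace(config, seed=seed)
    return generate_trace(cfg, preset_populations(name))


# -- I/O --------------------------------------------------------------------

def write_trace_hdf5(trace: MultiFrequencyTrace, path: str | Path) -> None:
    """HDF5 layout: /times_s plus /channels/<freq_hz> datasets."""
    with h5py.File(path, "w") as h5:
        h5.create_dataset("times_s", data=trace.times_s)
        h5.attrs["sampling_rate_hz"] = trace.sampling_rate_hz
        h5.attrs["frequencies_hz"] = list(trace.grid)
        grp = h5.create_group("channels")
        for f in trace.grid:
            grp.create_dataset(freq_label(f), data=trace.channels[f])


def read_trace_hdf5(path: str | Path) -> MultiFrequencyTrace:
    with h5py.File(path, "r") as h5:
        freqs = tuple(float(f) for f in h5.attrs["frequencies_hz"])
        grid = FrequencyGrid(freqs)
        times = h5["times_s"][:]
        channels = {f: h5["channels"][freq_label(f)][:] for f in freqs}
        fs = float(h5.attrs["sampling_rate_hz"])
    return MultiFrequencyTrace(times_s=times, channels=channels, grid=grid, sampling_rate_hz=fs)


def write_trace_csv(trace: MultiFrequencyTrace, path: str | Path) -> None:
    """Wide CSV: time_s plus one amp_uv_<freq> column per channel."""
    df = pd.DataFrame({"time_s": trace.times_s})
    for f in trace.grid:
        df[amp_column(f)] = trace.channels[f]
    df.to_csv(path, index=False, float_format="%.8g")


def read_trace_csv(path: str | Path) -> MultiFrequencyTrace:
    df = pd.read_csv(path)
    freqs = tuple(
        sorted(float(c.removeprefix("amp_uv_")) for c in df.columns if c.startswith("amp_uv_"))
    )
    if not freqs:
        raise InvalidParameterError(f"no amp_uv_<freq> columns found in {path}")
    times = df["time_s"].to_numpy()
    if len(times) < 2:
        raise InvalidParameterError("trace CSV must contain at least two samples")
    fs = 1.0 / float(np.median(np.diff(times)))
    grid = FrequencyGrid(freqs)
    channels = {f: df[amp_column(f)].to_numpy() for f in freqs}
    return MultiFrequencyTrace(times_s=times, channels=channels, grid=grid, sampling_rate_hz=fs)


def write_event_log(log: pd.DataFrame, path: str | Path) -> None:
    log.to_csv(path, index=False, float_format="%.8g")


def read_event_log(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path)
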