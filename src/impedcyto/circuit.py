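"""Equivalent-circuit forward model of a two-electrode impedance cytometry sensor.

A particle transiting the sensing pore is modelled as a lumped network in
series with the electrode double layers and the solution resistance:

    Z(f) = 2 / (j 2πf C_dl) + R_s + ΔR ∥ (2 / (j 2πf C_m) + R_c)

where ``C_dl`` is the per-electrode double-layer capacitance (the factor 2
accounts for the two interfaces in series), ``R_s`` the solution resistance,
``ΔR`` the occlusion resistance caused by the particle displacing conductive
buffer, ``C_m`` the membrane capacitance and ``R_c`` the cytoplasm
resistance.  For a rigid bead the membrane branch is treated as open, so the
particle reduces to the purely resistive ``ΔR`` and its impedance change is
flat in frequency.  For a cell the membrane shorts progressively above
~1 MHz, lowering the apparent impedance change — the physical basis for
bead/cell discrimination at high frequency.

The occlusion resistance scales with particle *volume*: a particle of twice
the radius produces an 8-fold larger low-frequency impedance change.
"""

from __future__ import annotations

import enum
import json
import math
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import yaml


class ParticleKind(str, enum.Enum):
    """Particle categories resolved by the assay."""

    BEAD = "bead"
    BEAD_DOUBLET = "bead_doublet"
    CELL = "cell"
    AGGREGATE = "aggregate"

    @property
    def has_membrane(self) -> bool:
        """Whether the membrane (C_m, R_c) branch conducts for this kind."""
        return self in (ParticleKind.CELL, ParticleKind.AGGREGATE)


class InvalidParameterError(ValueError):
    """Raised for non-physical circuit, particle or grid parameters."""


@dataclass(frozen=True)
class ElectrodeCircuit:
    """Shared interface/solution parameters of the sensor.

    Parameters
    ----------
    C_dl_farads:
        Per-electrode double-layer capacitance, farads.
    R_s_ohms:
        Solution (buffer) resistance between the electrodes, ohms.
    """

    C_dl_farads: float = 1e-9
    R_s_ohms: float = 1e4

    def __post_init__(self) -> None:
        if not (self.C_dl_farads > 0 and math.isfinite(self.C_dl_farads)):
            raise InvalidParameterError(f"C_dl must be > 0, got {self.C_dl_farads}")
        if not (self.R_s_ohms > 0 and math.isfinite(self.R_s_ohms)):
            raise InvalidParameterError(f"R_s must be > 0, got {self.R_s_ohms}")


@dataclass(frozen=True)
class ParticleModel:
    """Lumped-element description of one particle plus its geometric radius.

    ``C_m_farads`` may be ``None`` for membrane-less particles (beads); the
    membrane branch is then open regardless of ``R_c_ohms``.
    """

    delta_R_ohms: float
    R_c_ohms: float
    radius_um: float
    kind: ParticleKind
    C_m_farads: float | None = None

    def __post_init__(self) -> None:
        if self.delta_R_ohms < 0:
            raise InvalidParameterError(f"delta_R must be >= 0, got {self.delta_R_ohms}")
        if not self.R_c_ohms > 0:
            raise InvalidParameterError(f"R_c must be > 0, got {self.R_c_ohms}")
        if not self.radius_um > 0:
            raise InvalidParameterError(f"radius must be > 0, got {self.radius_um}")
        if self.C_m_farads is not None and not self.C_m_farads > 0:
            raise InvalidParameterError(f"C_m must be > 0 or None, got {self.C_m_farads}")

    @property
    def membrane_open(self) -> bool:
        return self.C_m_farads is None or not self.kind.has_membrane


@dataclass(frozen=True)
class FrequencyGrid:
    """Ordered set of excitation frequencies, hertz."""

    frequencies_hz: tuple[float, ...] = (300e3, 500e3, 1e6, 5e6, 20e6)

    def __post_init__(self) -> None:
        f = tuple(float(x) for x in self.frequencies_hz)
        object.__setattr__(self, "frequencies_hz", f)
        if len(f) == 0:
            raise InvalidParameterError("frequency grid must not be empty")
        if any(x <= 0 for x in f):
            raise InvalidParameterError("frequencies must be positive")
        if any(b <= a for a, b in zip(f, f[1:])):
            raise InvalidParameterError("frequencies must be strictly increasing")

    def __len__(self) -> int:
        return len(self.frequencies_hz)

    def __iter__(self):
        return iter(self.frequencies_hz)

    def index_of(self, f_hz: float, rtol: float = 1e-9) -> int:
        for i, f in enumerate(self.frequencies_hz):
            if math.isclose(f, f_hz, rel_tol=rtol):
                return i
        raise InvalidParameterError(f"frequency {f_hz} Hz not in grid {self.frequencies_hz}")


# Default particle parameters.  The occlusion resistances follow the volume
# law from the bead reference (100 ohm at radius 1.4 um): the cell is twice
# the bead radius hence 8x the bead volume, a doublet is two bead volumes,
# and an aggregate is one cell plus n bead volumes.
BEAD_RADIUS_UM = 1.4  # 2.8 um diameter superparamagnetic bead
BEAD_DELTA_R_OHMS = 100.0
CELL_RADIUS_RATIO = 2.0
CELL_C_M_FARADS = 1e-11
CELL_R_C_OHMS = 2e3


def _validate_frequency(f_hz: float) -> float:
    f = float(f_hz)
    if not (f > 0 and math.isfinite(f)):
        raise InvalidParameterError(f"frequency must be positive and finite, got {f_hz}")
    return f


def bead_particle(n_beads: int = 1) -> ParticleModel:
    """A bare bead (``n_beads=1``) or a non-specific bead multiplet."""
    if n_beads < 1:
        raise InvalidParameterError("n_beads must be >= 1")
    kind = ParticleKind.BEAD if n_beads == 1 else ParticleKind.BEAD_DOUBLET
    return ParticleModel(
        delta_R_ohms=BEAD_DELTA_R_OHMS * n_beads,
        R_c_ohms=1e9,  # membrane branch open anyway; beads are insulating
        radius_um=BEAD_RADIUS_UM * n_beads ** (1.0 / 3.0),
        kind=kind,
        C_m_farads=None,
    )


def cell_particle() -> ParticleModel:
    """A cancer cell: 2x the bead radius, membrane branch present."""
    return ParticleModel(
        delta_R_ohms=occlusion_resistance(BEAD_DELTA_R_OHMS, CELL_RADIUS_RATIO),
        R_c_ohms=CELL_R_C_OHMS,
        radius_um=BEAD_RADIUS_UM * CELL_RADIUS_RATIO,
        kind=ParticleKind.CELL,
        C_m_farads=CELL_C_M_FARADS,
    )


def aggregate_particle(n_beads: int = 2) -> ParticleModel:
    """A bead-cell aggregate: cell volume plus ``n_beads`` bead volumes.

    The membrane parameters are the cell's; only the occlusion resistance
    grows with the added bead volume.
    """
    if n_beads < 1:
        raise InvalidParameterError("n_beads must be >= 1")
    cell = cell_particle()
    cell_volumes = CELL_RADIUS_RATIO ** 3  # in bead-volume units
    volume_ratio = (cell_volumes + n_beads) / cell_volumes
    return ParticleModel(
        delta_R_ohms=cell.delta_R_ohms * volume_ratio,
        R_c_ohms=cell.R_c_ohms,
        radius_um=cell.radius_um * volume_ratio ** (1.0 / 3.0),
        kind=ParticleKind.AGGREGATE,
        C_m_farads=cell.C_m_farads,
    )


def default_particles() -> dict[ParticleKind, ParticleModel]:
    return {
        ParticleKind.BEAD: bead_particle(1),
        ParticleKind.BEAD_DOUBLET: bead_particle(2),
        ParticleKind.CELL: cell_particle(),
        ParticleKind.AGGREGATE: aggregate_particle(2),
    }


def baseline_impedance(circuit: ElectrodeCircuit, f_hz: float) -> complex:
    """Impedance across the electrodes with no particle present, ohms."""
    f = _validate_frequency(f_hz)
    omega = 2.0 * math.pi * f
    return 2.0 / (1j * omega * circuit.C_dl_farads) + circuit.R_s_ohms


def particle_branch_impedance(particle: ParticleModel, f_hz: float) -> complex:
    """Impedance of the particle network ΔR ∥ (2/(jωC_m) + R_c), ohms."""
    f = _validate_frequency(f_hz)
    if particle.membrane_open:
        return complex(particle.delta_R_ohms)
    if particle.delta_R_ohms == 0:
        return 0j
    omega = 2.0 * math.pi * f
    z_membrane = 2.0 / (1j * omega * particle.C_m_farads) + particle.R_c_ohms
    return (particle.delta_R_ohms * z_membrane) / (particle.delta_R_ohms + z_membrane)


def total_impedance(circuit: ElectrodeCircuit, particle: ParticleModel, f_hz: float) -> complex:
    """Impedance across the electrodes with the particle in the pore, ohms."""
    return baseline_impedance(circuit, f_hz) + particle_branch_impedance(particle, f_hz)


def delta_impedance_magnitude(
    circuit: ElectrodeCircuit, particle: ParticleModel, f_hz: float
) -> float:
    """|Z_with_particle − Z_baseline| at one frequency, ohms.

    This is the quantity a transit event modulates and the lock-in
    demodulates into a voltage pulse.
    """
    return abs(total_impedance(circuit, particle, f_hz) - baseline_impedance(circuit, f_hz))


def occlusion_resistance(reference_delta_R_ohms: float, radius_ratio: float) -> float:
    """Scale an occlusion resistance by the cube of a radius ratio.

    ΔR is proportional to the displaced volume, so a particle ``k`` times the
    reference radius has ``k**3`` times the reference ΔR.
    """
    if not reference_delta_R_ohms > 0:
        raise InvalidParameterError(
            f"reference delta_R must be > 0, got {reference_delta_R_ohms}"
        )
    if not radius_ratio > 0:
        raise InvalidParameterError(f"radius_ratio must be > 0, got {radius_ratio}")
    return reference_delta_R_ohms * radius_ratio ** 3


def frequency_response_curve(
    circuit: ElectrodeCircuit, particle: ParticleModel, grid: FrequencyGrid
) -> list[tuple[float, float]]:
    """(frequency, |ΔZ|) pairs over the grid, order preserved."""
    if len(grid) == 0:  # FrequencyGrid forbids this, but guard plain sequences
        raise InvalidParameterError("empty frequency grid")
    return [(f, delta_impedance_magnitude(circuit, particle, f)) for f in grid]


def write_response_csv(
    path: str | Path, curve: Sequence[tuple[float, float]]
) -> None:
    """Write a response curve as two-column CSV (frequency_hz, delta_z_ohms)."""
    lines = ["frequency_hz,delta_z_ohms"]
    lines += [f"{f:.10g},{dz:.10g}" for f, dz in curve]
    Path(path).write_text("\n".join(lines) + "\n")


# -- configuration ----------------------------------------------------------

def default_config() -> dict:
    """Circuit/particle/grid defaults as a plain dict (YAML/JSON-ready)."""
    parts = default_particles()
    return {
        "circuit": {"C_dl_farads": 1e-9, "R_s_ohms": 1e4},
        "frequency_grid_hz": list(FrequencyGrid().frequencies_hz),
        "particles": {
            kind.value: {
                "delta_R_ohms": p.delta_R_ohms,
                "C_m_farads": p.C_m_farads,
                "R_c_ohms": p.R_c_ohms,
                "radius_um": p.radius_um,
            }
            for kind, p in parts.items()
        },
    }


def load_config(path: str | Path) -> dict:
    """Read a YAML or JSON config file into a dict."""
    path = Path(path)
    text = path.read_text()
    if path.suffix.lower() == ".json":
        return json.loads(text)
    return yaml.safe_load(text)


def circuit_from_config(cfg: dict) -> ElectrodeCircuit:
    c = cfg.get("circuit", {})
    return ElectrodeCircuit(
        C_dl_farads=float(c.get("C_dl_farads", 1e-9)),
        R_s_ohms=float(c.get("R_s_ohms", 1e4)),
    )


def grid_from_config(cfg: dict) -> FrequencyGrid:
    freqs = cfg.get("frequency_grid_hz")
    if freqs is None:
        return FrequencyGrid()
    return FrequencyGrid(tuple(float(f) for f in freqs))


def particles_from_config(cfg: dict) -> dict[ParticleKind, ParticleModel]:
    out = default_particles()
    for name, p in cfg.get("particles", {}).items():
        kind = ParticleKind(name)
        base = out[kind]
        c_m = p.get("C_m_farads", base.C_m_farads)
        out[kind] = ParticleModel(
            delta_R_ohms=float(p.get("delta_R_ohms", base.delta_R_ohms)),
            C_m_farads=None if c_m is None else float(c_m),
            R_c_ohms=float(p.get("R_c_ohms", base.R_c_ohms)),
            radius_um=float(p.get("radius_um", base.radius_um)),
            kind=kind,
        )
    return out
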