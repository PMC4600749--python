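"""Proton-accumulation-rate inference from particle counts and clamp times.

Two independent routes to the per-organelle proton influx:

1. *Clamp bookkeeping*: the number of internalized micelles per cell (from
   a fluorescence standard curve) times the amines per micelle gives the
   proton-absorbing capacity; dividing the consumed capacity by the number
   of organelles and the observed clamp duration yields protons per second
   per organelle.
2. *Stoichiometric extrapolation*: protons/ATP x ATP/rotation x
   rotations/s x pumps/organelle, a cross-check built from published
   v-ATPase mechanochemistry.
"""

from __future__ import annotations

from dataclasses import dataclass

from .constants import AMINES_PER_MICELLE, ORGANELLES_PER_CELL
from .errors import InputError

__all__ = [
    "UptakeMeasurement",
    "RateEstimate",
    "micelles_per_cell",
    "proton_rate_from_clamp",
    "stoichiometric_rate",
]


@dataclass(frozen=True)
class UptakeMeasurement:
    """Bulk fluorescence reading of internalized particles for a well.

    The standard curve is affine: micelles = (F - intercept) * slope.
    """

    total_fluorescence: float  # arbitrary units
    cell_count: int
    standard_curve_slope: float  # micelles per fluorescence unit
    standard_curve_intercept: float = 0.0  # fluorescence units

    def __post_init__(self) -> None:
        if self.cell_count <= 0:
            raise InputError("cell_count must be positive")
        if self.standard_curve_slope <= 0:
            raise InputError("standard_curve_slope must be positive")


@dataclass(frozen=True)
class RateEstimate:
    """Per-organelle proton influx with the inputs that produced it."""

    protons_per_second_per_organelle: float
    micelles_per_cell: float
    amines_per_micelle: float
    organelles_per_cell: float
    clamp_duration_s: float
    consumed_fraction: float

    def __post_init__(self) -> None:
        if self.protons_per_second_per_organelle < 0:
            raise InputError("rate must be >= 0")


def micelles_per_cell(m: UptakeMeasurement) -> float:
    """Internalized micelles per cell from a bulk fluorescence measurement."""
    if m.total_fluorescence < m.standard_curve_intercept:
        raise InputError(
            "total fluorescence below the standard-curve intercept implies a "
            "negative particle count"
        )
    return (
        (m.total_fluorescence - m.standard_curve_intercept)
        * m.standard_curve_slope
        / m.cell_count
    )


def proton_rate_from_clamp(
    micelles_per_cell: float,
    clamp_duration: float,
    amines_per_micelle: float = AMINES_PER_MICELLE,
    organelles_per_cell: float = ORGANELLES_PER_CELL,
    consumed_fraction: float = 1.0,
) -> RateEstimate:
    """Proton influx per organelle from the pH-clamp proton budget.

    rate = micelles_per_cell * amines_per_micelle * consumed_fraction
           / (organelles_per_cell * clamp_duration)

    ``consumed_fraction`` is the portion of the amines titrated during the
    clamp: 1.0 assumes full titration; 0.8 corresponds to the 10-90%
    protonation window and is the right choice when ``clamp_duration``
    comes from a plateau bounded by those thresholds.
    """
    if clamp_duration <= 0:
        raise InputError("clamp_duration must be positive")
    if micelles_per_cell < 0:
        raise InputError("micelles_per_cell must be >= 0")
    if amines_per_micelle <= 0 or organelles_per_cell <= 0:
        raise InputError("amines_per_micelle and organelles_per_cell must be > 0")
    if not (0.0 < consumed_fraction <= 1.0):
        raise InputError("consumed_fraction must lie in (0, 1]")
    rate = (
        micelles_per_cell
        * amines_per_micelle
        * consumed_fraction
        / (organelles_per_cell * clamp_duration)
    )
    return RateEstimate(
        protons_per_second_per_organelle=rate,
        micelles_per_cell=micelles_per_cell,
        amines_per_micelle=amines_per_micelle,
        organelles_per_cell=organelles_per_cell,
        clamp_duration_s=clamp_duration,
        consumed_fraction=consumed_fraction,
    )


def stoichiometric_rate(
    protons_per_ATP: float = 2.0,
    ATP_per_rotation: float = 3.0,
    revolutions_per_s: float = 2.4,
    pumps_per_organelle: float = 20.0,
) -> float:
    """Stoichiometric v-ATPase extrapolation of the proton influx, H+/s.

    The default constants (2 H+/ATP, 3 ATP/rotation, 2.4 rev/s, 20 pumps
    per organelle) multiply to 288 H+/s.
    """
    for v in (protons_per_ATP, ATP_per_rotation, revolutions_per_s, pumps_per_organelle):
        if v < 0:
            raise InputError("stoichiometric factors must be >= 0")
    return protons_per_ATP * ATP_per_rotation * revolutions_per_s * pumps_per_organelle
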