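"""Forward simulation of endo/lysosomal luminal pH under proton pumping.

The lumen is treated as a well-mixed compartment acidified by a constant-
rate v-ATPase pump (with a hard stall floor) and drained by an optional
linear leak toward cytosolic pH.  Protonation of water, an intrinsic
(non-specific) buffer and an internalized nanobuffer load is assumed to
equilibrate instantaneously relative to pumping ("quasi-static"), so each
time step amounts to solving a scalar proton-balance equation

    delivered(t) = free(pH) + intrinsic(pH) + bound_by_load(pH)

for the new pH.  This formulation makes proton conservation exactly
checkable at every sample and reproduces the clamped-plateau phenomenology:
while the load's cooperative protonation window is being titrated, pumped
protons are absorbed by the load and the pH dwells near the load's apparent
pKa.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy.optimize import brentq

from .constants import (
    AMINES_PER_MICELLE,
    AVOGADRO,
    DEFAULT_HILL_N,
    KW,
    ORGANELLES_PER_CELL,
    UPS_SITE_DENSITY_MOL_PER_G,
)
from .errors import InputError, SolverError, StepSizeError

__all__ = [
    "OrganelleModel",
    "NanobufferLoad",
    "PHTrajectory",
    "PlateauReport",
    "simulate_lumen",
    "plateau_stats",
    "activation_signal",
    "dose_to_load",
    "micelle_mass_g",
]


@dataclass(frozen=True)
class OrganelleModel:
    """Lumen parameters of one endocytic organelle.

    Defaults are literature-typical for an endo/lysosome: a 0.5-um-diameter
    sphere (~6.5e-17 L), intrinsic buffering 40 mmol/L per pH unit, pump
    running at the stoichiometric v-ATPase extrapolation (288 H+/s), no
    leak, cytosolic starting pH 7.4 and a pump stall floor at pH 4.0.
    """

    volume: float = 6.5e-17  # litres
    pump_rate: float = 288.0  # protons / s
    leak_rate: float = 0.0  # protons / s / pH-unit gradient
    intrinsic_buffer: float = 0.040  # mol / L / pH
    initial_pH: float = 7.4
    cytosol_pH: float = 7.4
    floor_pH: float = 4.0  # pump stalls at/below this

    def __post_init__(self) -> None:
        if self.volume <= 0:
            raise InputError("volume must be positive")
        if self.pump_rate < 0 or self.intrinsic_buffer < 0:
            raise InputError("pump_rate and intrinsic_buffer must be >= 0")
        if not self.floor_pH < self.initial_pH:
            raise InputError("floor_pH must lie below initial_pH")


@dataclass(frozen=True)
class NanobufferLoad:
    """Internalized nanobuffer content of one organelle."""

    micelles_per_organelle: float
    pKa: float = 6.2
    hill_n: float = DEFAULT_HILL_N
    amines_per_micelle: float = AMINES_PER_MICELLE

    def __post_init__(self) -> None:
        if self.micelles_per_organelle < 0:
            raise InputError("micelles_per_organelle must be >= 0")
        if self.micelles_per_organelle > 0 and self.amines_per_micelle <= 0:
            raise InputError("amines_per_micelle must be > 0 when loaded")

    @property
    def total_amines(self) -> float:
        return self.micelles_per_organelle * self.amines_per_micelle

    def fraction_protonated(self, pH):
        expo = np.clip(self.hill_n * (np.asarray(pH, float) - self.pKa), -300, 300)
        out = 1.0 / (1.0 + 10.0**expo)
        return float(out) if out.ndim == 0 else out

    @property
    def half_width(self) -> float:
        """Half the 10-90% protonation span, pH units (log10(9)/n)."""
        return math.log10(9.0) / self.hill_n


@dataclass
class PHTrajectory:
    """A simulated luminal pH time course on a fixed-step grid."""

    time: np.ndarray  # s, strictly increasing
    pH: np.ndarray
    fraction_protonated: np.ndarray  # of the load's Hill sites, in [0, 1]
    protons_pumped_cumulative: np.ndarray
    protons_net_cumulative: np.ndarray  # pumped minus leaked

    def __post_init__(self) -> None:
        lens = {
            len(self.time),
            len(self.pH),
            len(self.fraction_protonated),
            len(self.protons_pumped_cumulative),
            len(self.protons_net_cumulative),
        }
        if len(lens) != 1:
            raise InputError("trajectory sequences must share length")
        if np.any(np.diff(self.time) <= 0):
            raise InputError("time must be strictly increasing")
        if np.any(np.diff(self.protons_pumped_cumulative) < 0):
            raise InputError("protons_pumped_cumulative must be non-decreasing")

    @property
    def dt(self) -> float:
        return float(self.time[1] - self.time[0])

    def __len__(self) -> int:
        return len(self.time)


@dataclass
class PlateauReport:
    """Detected pH clamp of a trajectory relative to a load-free control."""

    detected: bool
    plateau_mean_pH: float | None = None
    plateau_duration: float | None = None  # s
    activation_delay: float | None = None  # s


def _protons_absorbed(pH: float, model: OrganelleModel, load: NanobufferLoad) -> float:
    """Protons absorbed by the lumen contents between initial_pH and ``pH``."""
    h, h0 = 10.0**-pH, 10.0**-model.initial_pH
    per_molar = model.volume * AVOGADRO  # protons per mol/L
    free = (h - h0 - KW / h + KW / h0) * per_molar
    intrinsic = model.intrinsic_buffer * (model.initial_pH - pH) * per_molar
    bound = load.total_amines * (
        load.fraction_protonated(pH) - load.fraction_protonated(model.initial_pH)
    )
    return free + intrinsic + bound


def simulate_lumen(
    model: OrganelleModel,
    load: NanobufferLoad,
    duration: float,
    dt: float = 1.0,
) -> PHTrajectory:
    """Simulate the luminal pH for ``duration`` seconds at step ``dt``.

    Each step delivers ``pump_rate*dt`` protons (zero once pH <= floor_pH)
    minus ``leak_rate*(cytosol_pH - pH)*dt``, then re-solves the
    fast-equilibrium proton balance for the new pH.  Raises
    :class:`StepSizeError` if any step moves the pH by more than 0.5.
    """
    if dt <= 0:
        raise InputError("dt must be positive")
    if duration < dt:
        raise InputError("duration must be at least one step")
    n_steps = int(round(duration / dt))
    time = np.arange(n_steps + 1) * dt
    pH = np.empty(n_steps + 1)
    pumped = np.zeros(n_steps + 1)
    net = np.zeros(n_steps + 1)
    pH[0] = model.initial_pH
    delivered = 0.0
    for k in range(1, n_steps + 1):
        pump = model.pump_rate if pH[k - 1] > model.floor_pH else 0.0
        leak = model.leak_rate * (model.cytosol_pH - pH[k - 1])
        delivered += (pump - leak) * dt
        pumped[k] = pumped[k - 1] + pump * dt
        net[k] = delivered

        def g(p: float) -> float:
            return _protons_absorbed(p, model, load) - delivered

        lo, hi = 0.5, 13.9
        if g(lo) * g(hi) > 0:
            raise SolverError(f"lumen proton balance has no root at step {k}")
        pH[k] = brentq(g, lo, hi, xtol=1e-11)
        if abs(pH[k] - pH[k - 1]) > 0.5:
            raise StepSizeError(
                f"pH stepped {abs(pH[k] - pH[k - 1]):.2f} (> 0.5) at t={time[k]:g} s;"
                " reduce dt"
            )
    return PHTrajectory(
        time=time,
        pH=pH,
        fraction_protonated=load.fraction_protonated(pH),
        protons_pumped_cumulative=pumped,
        protons_net_cumulative=net,
    )


def _band_run(frac: np.ndarray) -> tuple[int, int] | None:
    """Longest maximal run with fraction in the open (0.1, 0.9) band.

    Returns (start, stop) inclusive sample indices, or None.  Ties between
    equally long runs resolve to the earliest.
    """
    inside = (frac > 0.1) & (frac < 0.9)
    best: tuple[int, int] | None = None
    i = 0
    n = len(inside)
    while i < n:
        if inside[i]:
            j = i
            while j + 1 < n and inside[j + 1]:
                j += 1
            if best is None or (j - i) > (best[1] - best[0]):
                best = (i, j)
            i = j + 1
        else:
            i += 1
    return best


def plateau_stats(
    traj: PHTrajectory, load: NanobufferLoad, control: PHTrajectory
) -> PlateauReport:
    """Clamped-plateau summary of ``traj`` against a load-free ``control``.

    The plateau is the longest interval with the load's protonation fraction
    strictly inside (0.1, 0.9).  A plateau counts as detected only for a
    non-zero load whose interval lasts at least 10 samples and longer than
    the control spends crossing the same band (an unloaded organelle also
    dwells there briefly because intrinsic buffering is finite).

    ``activation_delay`` is the difference in first-crossing times below
    pKa - half-width between trajectory and control (NaN if either never
    crosses).
    """
    if len(traj) != len(control) or not np.allclose(traj.time, control.time):
        raise InputError("trajectory and control must share the time grid")
    run = _band_run(traj.fraction_protonated)
    dt = traj.dt
    ctrl_run = _band_run(load.fraction_protonated(control.pH))
    ctrl_duration = 0.0 if ctrl_run is None else (ctrl_run[1] - ctrl_run[0]) * dt

    thr = load.pKa - load.half_width
    t_traj = traj.time[traj.pH < thr]
    t_ctrl = control.time[control.pH < thr]
    delay = (
        float(t_traj[0] - t_ctrl[0]) if len(t_traj) and len(t_ctrl) else float("nan")
    )

    if load.micelles_per_organelle <= 0 or run is None:
        return PlateauReport(detected=False)
    duration = (run[1] - run[0]) * dt
    if duration < 10 * dt or duration <= ctrl_duration:
        return PlateauReport(detected=False)
    mean_pH = float(np.mean(traj.pH[run[0] : run[1] + 1]))
    return PlateauReport(
        detected=True,
        plateau_mean_pH=mean_pH,
        plateau_duration=float(duration),
        activation_delay=delay,
    )


def activation_signal(traj: PHTrajectory) -> tuple[np.ndarray, float]:
    """Normalized OFF-ON fluorescence surrogate and its half-rise time.

    Micelle dissociation (protonation) switches the reporter ON, so the
    signal is the protonated fraction normalized to its end-time-point
    value; by construction the terminal sample equals 1.  ``t50`` is the
    first time the signal reaches 0.5.
    """
    if len(traj) <= 2:
        raise InputError("trajectory too short for an activation signal")
    terminal = traj.fraction_protonated[-1]
    if terminal <= 1e-12:  # numerically zero: reporter never switches on
        raise InputError("terminal protonated fraction is zero; signal undefined")
    signal = traj.fraction_protonated / terminal
    above = np.nonzero(signal >= 0.5)[0]
    if len(above) == 0:
        raise InputError("signal never reaches half maximum")
    return signal, float(traj.time[above[0]])


def micelle_mass_g(
    amines_per_micelle: float = AMINES_PER_MICELLE,
    site_density: float = UPS_SITE_DENSITY_MOL_PER_G,
) -> float:
    """Mass of one micelle, g, from its amine count and amine density."""
    if amines_per_micelle <= 0 or site_density <= 0:
        raise InputError("amines_per_micelle and site_density must be positive")
    return amines_per_micelle / (site_density * AVOGADRO)


def dose_to_load(
    dose: float,
    uptake_fraction: float,
    cell_volume_medium: float,
    organelles_per_cell: float = ORGANELLES_PER_CELL,
    *,
    pKa: float = 6.2,
    hill_n: float = DEFAULT_HILL_N,
    amines_per_micelle: float = AMINES_PER_MICELLE,
    site_density: float = UPS_SITE_DENSITY_MOL_PER_G,
) -> NanobufferLoad:
    """Convert an incubation dose into a per-organelle micelle load.

    Parameters
    ----------
    dose : float
        Medium concentration, ug/ml.
    uptake_fraction : float
        Fraction of the medium's particle mass endocytosed per cell's share.
    cell_volume_medium : float
        Medium volume per cell, ml.
    organelles_per_cell : float
        Endosomes/lysosomes sharing the internalized load.
    """
    if dose < 0 or uptake_fraction < 0:
        raise InputError("dose and uptake_fraction must be >= 0")
    if cell_volume_medium <= 0 or organelles_per_cell <= 0:
        raise InputError("cell_volume_medium and organelles_per_cell must be > 0")
    mass = micelle_mass_g(amines_per_micelle, site_density)
    micelles = dose * 1e-6 * cell_volume_medium * uptake_fraction / (
        mass * organelles_per_cell
    )
    return NanobufferLoad(
        micelles_per_organelle=micelles,
        pKa=pKa,
        hill_n=hill_n,
        amines_per_micelle=amines_per_micelle,
    )
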