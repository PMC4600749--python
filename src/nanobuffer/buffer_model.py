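"""Cooperative protonation, acid titration and buffer capacity.

The central object is a solute made of Hill-protonatable site groups.  A
micelle-forming ultra-pH-sensitive (UPS) copolymer is modelled as a single
sharp group (the hydrophobic phase transition cooperatively protonates the
tertiary amines, giving a 10-90% span of ~0.25 pH units); small-molecule
comparators such as chloroquine are one classical (Hill n = 1) group per
ionizable nitrogen.

Titrations are simulated by exact charge balance: at every increment of
strong acid the unique pH satisfying

    [H+] - [OH-] + sum_g f_g(pH) C_g = [Cl-]

is found by bracketed root finding, with all concentrations corrected for
titrant dilution.  Buffer capacity beta = -dnH+/dpH is then estimated by
finite differences on the recorded curve, either in "total" mode (as
measured) or "solute-only" mode, where the free-proton (water) content is
removed exactly before differencing.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Literal, Sequence

import numpy as np
from scipy.optimize import brentq

from .constants import (
    CQ_MOLAR_MASS_G_PER_MOL,
    CQ_PKAS,
    KW,
    UPS_SITE_DENSITY_MOL_PER_G,
    hill_n_for_width,
)
from .errors import (
    DataQualityError,
    DegenerateStepError,
    EstimationError,
    InputError,
    SolverError,
)

__all__ = [
    "ProtonationSiteGroup",
    "ProtonatableSpecies",
    "TitrationMixture",
    "TitrationCurve",
    "BufferCapacityProfile",
    "protonation_fraction",
    "solve_pH",
    "acid_to_reach",
    "simulate_titration",
    "titration_from_pH_grid",
    "buffer_capacity",
    "estimate_pKa",
    "fold_buffer_ratio",
    "ups_species",
    "chloroquine",
    "pei",
]

_EXP_CLIP = 300.0  # exponent clip keeps 10**x finite for extreme pH


@dataclass(frozen=True)
class ProtonationSiteGroup:
    """One family of protonatable sites with a shared apparent pKa.

    Parameters
    ----------
    pKa : float
        Apparent pKa, pH units; midpoint of the protonation transition.
    hill_n : float
        Cooperativity exponent (dimensionless, > 0).  n = 1 is a classical
        monoprotic weak base; the UPS default ~7.63 gives a 0.25 pH-unit
        10-90% span.
    site_density : float
        Mol protonatable sites per gram of solute.
    """

    pKa: float
    hill_n: float = 1.0
    site_density: float = UPS_SITE_DENSITY_MOL_PER_G

    def __post_init__(self) -> None:
        if not (0.0 < self.pKa < 14.0):
            raise InputError(f"pKa must lie in (0, 14), got {self.pKa}")
        if not self.hill_n > 0:
            raise InputError(f"hill_n must be > 0, got {self.hill_n}")
        if not self.site_density > 0:
            raise InputError(f"site_density must be > 0, got {self.site_density}")


@dataclass(frozen=True)
class ProtonatableSpecies:
    """A named buffering solute: an ordered collection of site groups."""

    name: str
    site_groups: tuple[ProtonationSiteGroup, ...]
    molar_mass: float | None = None  # g/mol, optional per-molecule bookkeeping

    def __post_init__(self) -> None:
        if len(self.site_groups) == 0:
            raise InputError("species needs at least one site group")
        object.__setattr__(self, "site_groups", tuple(self.site_groups))

    @property
    def total_site_density(self) -> float:
        """Mol sites per gram summed over groups."""
        return sum(g.site_density for g in self.site_groups)


@dataclass(frozen=True)
class TitrationMixture:
    """Vessel contents and titrant protocol for an acid titration.

    The bench protocol this mirrors: solute dissolved in ``initial_volume``
    ml of non-buffering saline, titrated with ``increment_volume`` ul shots
    of ``titrant_concentration`` M strong acid (HCl).
    """

    species_loads: tuple[tuple[ProtonatableSpecies, float], ...]  # (species, mg)
    initial_volume: float = 20.0  # ml
    salt: float = 150.0  # mM NaCl, treated as non-buffering
    titrant_concentration: float = 0.4  # mol/L HCl
    increment_volume: float = 25.0  # ul per shot

    def __post_init__(self) -> None:
        object.__setattr__(self, "species_loads", tuple(self.species_loads))
        names = [s.name for s, _ in self.species_loads]
        if len(set(names)) != len(names):
            raise InputError("species names must be unique within a mixture")
        if any(m <= 0 for _, m in self.species_loads):
            raise InputError("species masses must be positive")
        if self.initial_volume <= 0:
            raise InputError("initial_volume must be positive")
        if self.titrant_concentration <= 0:
            raise InputError("titrant_concentration must be positive")
        if self.increment_volume <= 0:
            raise InputError("increment_volume must be positive")

    @property
    def total_mass_mg(self) -> float:
        return sum(m for _, m in self.species_loads)

    def site_amounts_mmol(self) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        """(pKa, hill_n, mmol sites) arrays over all groups of all species."""
        pka, n, mmol = [], [], []
        for sp, mass_mg in self.species_loads:
            for g in sp.site_groups:
                pka.append(g.pKa)
                n.append(g.hill_n)
                mmol.append(mass_mg * g.site_density)  # mg * mol/g = mmol
        return np.asarray(pka), np.asarray(n), np.asarray(mmol)


@dataclass
class TitrationCurve:
    """Added acid versus pH, with vessel metadata.

    ``added_acid`` is cumulative strong acid in mmol (non-decreasing), ``pH``
    the matching readings, ``volumes`` the dilution-corrected vessel volume
    in ml at each point and ``reference_mass`` the solute mass (mg) to which
    buffer capacities derived from this curve are referred.
    """

    added_acid: np.ndarray  # mmol
    pH: np.ndarray
    volumes: np.ndarray  # ml
    reference_mass: float  # mg

    def __post_init__(self) -> None:
        self.added_acid = np.asarray(self.added_acid, dtype=float)
        self.pH = np.asarray(self.pH, dtype=float)
        self.volumes = np.asarray(self.volumes, dtype=float)
        if not (len(self.added_acid) == len(self.pH) == len(self.volumes)):
            raise InputError("curve sequences must share length")
        if len(self.pH) < 2:
            raise InputError("curve needs at least 2 points")
        if np.any(np.diff(self.added_acid) < 0):
            raise InputError("added_acid must be non-decreasing")

    def __len__(self) -> int:
        return len(self.pH)


@dataclass
class BufferCapacityProfile:
    """Buffer capacity beta(pH) on an ascending pH grid.

    ``beta`` is mmol H+ per pH unit, referred to ``reference_mass`` mg of
    solute.  ``mode`` records whether the water autoionization contribution
    is included ("total") or removed ("solute-only").
    """

    pH_grid: np.ndarray  # ascending
    beta: np.ndarray  # mmol/pH, >= 0
    mode: Literal["total", "solute-only"]
    reference_mass: float  # mg

    def __post_init__(self) -> None:
        self.pH_grid = np.asarray(self.pH_grid, dtype=float)
        self.beta = np.asarray(self.beta, dtype=float)
        if np.any(np.diff(self.pH_grid) <= 0):
            raise InputError("pH_grid must be strictly increasing")
        if np.any(self.beta < 0):
            raise InputError("beta must be non-negative")

    def at(self, pH: float) -> float:
        """Linear interpolation of beta at ``pH`` (must lie inside the grid)."""
        if not (self.pH_grid[0] <= pH <= self.pH_grid[-1]):
            raise InputError(
                f"pH {pH} outside profile grid "
                f"[{self.pH_grid[0]:.3f}, {self.pH_grid[-1]:.3f}]"
            )
        return float(np.interp(pH, self.pH_grid, self.beta))


# ---------------------------------------------------------------------------
# species factories


def ups_species(
    pKa: float,
    *,
    width: float = 0.25,
    site_density: float = UPS_SITE_DENSITY_MOL_PER_G,
    name: str | None = None,
) -> ProtonatableSpecies:
    """A UPS copolymer model: one sharp Hill group.

    ``width`` is the 10-90% protonation span in pH units (0.25 by default,
    the micelle-to-unimer transition sharpness).
    """
    return ProtonatableSpecies(
        name=name or f"UPS{pKa:g}",
        site_groups=(
            ProtonationSiteGroup(
                pKa=pKa, hill_n=hill_n_for_width(width), site_density=site_density
            ),
        ),
    )


def chloroquine() -> ProtonatableSpecies:
    """Chloroquine comparator: diprotic classical base, pKa 8.3 and 10.4."""
    per_site = 1.0 / CQ_MOLAR_MASS_G_PER_MOL  # mol sites per g, per nitrogen
    return ProtonatableSpecies(
        name="CQ",
        site_groups=tuple(
            ProtonationSiteGroup(pKa=p, hill_n=1.0, site_density=per_site)
            for p in CQ_PKAS
        ),
        molar_mass=CQ_MOLAR_MASS_G_PER_MOL,
    )


def pei(
    n_groups: int = 5,
    *,
    pKa_range: tuple[float, float] = (4.0, 10.0),
    total_site_density: float = 0.023,
) -> ProtonatableSpecies:
    """Branched-polyethyleneimine comparator: a broad, featureless buffer.

    Modelled qualitatively as ``n_groups`` classical groups with pKa spread
    uniformly over ``pKa_range`` and the amine content split evenly.
    """
    if n_groups < 5:
        raise InputError("PEI model uses at least 5 site groups")
    pkas = np.linspace(*pKa_range, n_groups)
    return ProtonatableSpecies(
        name="PEI",
        site_groups=tuple(
            ProtonationSiteGroup(
                pKa=float(p), hill_n=1.0, site_density=total_site_density / n_groups
            )
            for p in pkas
        ),
    )


# ---------------------------------------------------------------------------
# operations


def protonation_fraction(group: ProtonationSiteGroup, pH: float | np.ndarray):
    """Fraction of the group's sites protonated at ``pH``.

    Hill closure f = 1 / (1 + 10^(n (pH - pKa))): strictly decreasing in pH,
    f = 1/2 at pH = pKa, and reducing to Henderson-Hasselbalch at n = 1.
    """
    pH = np.asarray(pH, dtype=float)
    if not np.all(np.isfinite(pH)):
        raise InputError("pH must be finite")
    expo = np.clip(group.hill_n * (pH - group.pKa), -_EXP_CLIP, _EXP_CLIP)
    out = 1.0 / (1.0 + 10.0**expo)
    return float(out) if out.ndim == 0 else out


def _bound_mmol(pka: np.ndarray, n: np.ndarray, mmol: np.ndarray, pH: float) -> float:
    """mmol of protons bound by all site groups at ``pH``."""
    expo = np.clip(n * (pH - pka), -_EXP_CLIP, _EXP_CLIP)
    return float(np.sum(mmol / (1.0 + 10.0**expo)))


def _charge_imbalance(
    pH: float,
    pka: np.ndarray,
    n: np.ndarray,
    mmol: np.ndarray,
    volume_ml: float,
    cl_mol_per_l: float,
) -> float:
    """Residual of the charge balance, mol/L (positive = too acidic a guess)."""
    h = 10.0**-pH
    oh = KW / h
    bound = _bound_mmol(pka, n, mmol, pH) / volume_ml  # mmol/ml = mol/L
    return h - oh + bound - cl_mol_per_l


def solve_pH(
    mixture: TitrationMixture,
    added_acid: float,
    *,
    residual_tol: float = 1e-12,
) -> float:
    """pH of ``mixture`` after ``added_acid`` mmol of strong acid.

    Solves the proton/charge balance
    [H+] - [OH-] + sum f_g(pH) C_g = [Cl-] by bracketed root finding over
    (0, 14); all concentrations are dilution-corrected for titrant volume.
    The returned root's charge imbalance is below ``residual_tol`` mol/L.
    """
    if not np.isfinite(added_acid) or added_acid < 0:
        raise InputError(f"added_acid must be finite and >= 0, got {added_acid}")
    pka, n, mmol = mixture.site_amounts_mmol()
    volume_ml = mixture.initial_volume + added_acid / mixture.titrant_concentration
    cl = added_acid / volume_ml  # mmol/ml = mol/L
    args = (pka, n, mmol, volume_ml, cl)
    lo, hi = 1e-9, 14.0 - 1e-9
    f_lo = _charge_imbalance(lo, *args)
    f_hi = _charge_imbalance(hi, *args)
    if f_lo * f_hi > 0:
        raise SolverError("charge balance has no root in (0, 14)")
    pH = brentq(_charge_imbalance, lo, hi, args=args, xtol=1e-14, rtol=8.9e-16)
    residual = _charge_imbalance(pH, *args)
    if abs(residual) > residual_tol:
        raise SolverError(
            f"charge-balance residual {residual:.2e} mol/L exceeds {residual_tol:.0e}"
        )
    return float(pH)


def acid_to_reach(mixture: TitrationMixture, pH: float) -> float:
    """Closed-form inverse of :func:`solve_pH`: mmol of acid that yields ``pH``.

    From the charge balance, with n the added acid (mmol), V = V0 + n/c_t:
    n (1 - ([H+]-[OH-])/c_t) = ([H+]-[OH-]) V0 + bound(pH).  Exact; useful
    as an independent oracle and for building curves on chosen pH grids.
    """
    pka, n_arr, mmol = mixture.site_amounts_mmol()
    h = 10.0**-pH
    net = h - KW / h  # mol/L of free protons over hydroxide
    bound = _bound_mmol(pka, n_arr, mmol, pH)
    denom = 1.0 - net / mixture.titrant_concentration
    if denom <= 0:
        raise SolverError("target pH unreachable with this titrant concentration")
    return (net * mixture.initial_volume + bound) / denom


def simulate_titration(
    mixture: TitrationMixture,
    stop_pH: float = 3.0,
    *,
    max_steps: int = 100_000,
) -> TitrationCurve:
    """Titrate ``mixture`` with successive titrant increments down to ``stop_pH``.

    Iterates :func:`solve_pH` over fixed increments until the pH falls to or
    below ``stop_pH`` (the crossing point is recorded).  The resulting pH
    sequence is strictly decreasing; volumes are dilution-corrected.
    """
    start_pH = solve_pH(mixture, 0.0)
    if stop_pH >= start_pH:
        raise InputError(
            f"stop_pH {stop_pH} must be below the starting pH {start_pH:.3f}"
        )
    inc_mmol = mixture.increment_volume * mixture.titrant_concentration / 1000.0
    acid = [0.0]
    pH = [start_pH]
    vol = [mixture.initial_volume]
    for step in range(1, max_steps + 1):
        a = step * inc_mmol
        try:
            p = solve_pH(mixture, a)
        except SolverError as err:
            raise SolverError(f"titration step {step}: {err}") from err
        acid.append(a)
        pH.append(p)
        vol.append(mixture.initial_volume + a / mixture.titrant_concentration)
        if p <= stop_pH:
            break
    else:
        raise SolverError(f"stop_pH {stop_pH} not reached within {max_steps} steps")
    return TitrationCurve(
        added_acid=np.array(acid),
        pH=np.array(pH),
        volumes=np.array(vol),
        reference_mass=mixture.total_mass_mg,
    )


def titration_from_pH_grid(
    mixture: TitrationMixture, pH_values: Sequence[float]
) -> TitrationCurve:
    """Build a curve at prescribed pH points via the closed-form inverse.

    ``pH_values`` must be strictly decreasing and all lie below the
    zero-acid pH of the mixture.
    """
    pH_values = np.asarray(pH_values, dtype=float)
    if np.any(np.diff(pH_values) >= 0):
        raise InputError("pH_values must be strictly decreasing")
    acid = np.array([acid_to_reach(mixture, p) for p in pH_values])
    if np.any(acid < 0):
        raise InputError("some pH_values lie above the zero-acid pH")
    vol = mixture.initial_volume + acid / mixture.titrant_concentration
    return TitrationCurve(
        added_acid=acid,
        pH=pH_values,
        volumes=vol,
        reference_mass=mixture.total_mass_mg,
    )


def buffer_capacity(
    curve: TitrationCurve, mode: Literal["total", "solute-only"] = "solute-only"
) -> BufferCapacityProfile:
    """Buffer capacity beta = -dnH+/dpH from a titration curve.

    beta is estimated on interval midpoints by first differences of the
    cumulative-acid coordinate (centred differences on the staggered grid).
    In "solute-only" mode the free-proton content V([H+]-[OH-]) is removed
    from the acid coordinate before differencing, which subtracts the water
    autoionization term ln(10)([H+]+[OH-])V exactly, even on coarse grids.
    Negative finite-difference values (noise) are clamped to zero.
    """
    if mode not in ("total", "solute-only"):
        raise InputError(f"unknown beta mode {mode!r}")
    if len(curve) < 3:
        raise InputError("buffer capacity needs at least 3 curve points")
    pH = curve.pH
    dpH = np.diff(pH)
    if np.any(dpH == 0):
        raise DegenerateStepError("repeated pH values span a titrant increment")
    if np.any(dpH > 0):
        raise DataQualityError("curve pH is not strictly decreasing")
    n = curve.added_acid.copy()
    if mode == "solute-only":
        h = 10.0**-pH
        free = (h - KW / h) * curve.volumes  # mol/L * ml = mmol
        n = n - (free - free[0])
    beta = -np.diff(n) / dpH
    beta = np.maximum(beta, 0.0)
    mid = 0.5 * (pH[1:] + pH[:-1])  # decreasing
    return BufferCapacityProfile(
        pH_grid=mid[::-1],
        beta=beta[::-1],
        mode=mode,
        reference_mass=curve.reference_mass,
    )


def _interval_slopes(curve: TitrationCurve) -> tuple[np.ndarray, np.ndarray]:
    """(|dpH/dn|, midpoint added-acid) per interval, 3-point median smoothed."""
    dn = np.diff(curve.added_acid)
    if np.any(dn == 0):
        raise DegenerateStepError("repeated added-acid values")
    slopes = np.abs(np.diff(curve.pH) / dn)
    if len(slopes) >= 3:
        padded = np.pad(slopes, 1, mode="edge")
        slopes = np.array(
            [np.median(padded[i : i + 3]) for i in range(len(slopes))]
        )
    mid_n = 0.5 * (curve.added_acid[1:] + curve.added_acid[:-1])
    return slopes, mid_n


def _local_maxima(values: np.ndarray) -> list[int]:
    """Indices of local maxima; ties within a flat run resolve to the last
    index (larger added-acid coordinate).  Boundary points qualify."""
    idx = []
    m = len(values)
    for i in range(m):
        left = values[i - 1] if i > 0 else -np.inf
        right = values[i + 1] if i < m - 1 else -np.inf
        if values[i] > left and values[i] >= right:
            # walk to the end of a flat run, keep only its last index
            j = i
            while j + 1 < m and values[j + 1] == values[i]:
                j += 1
            nxt = values[j + 1] if j + 1 < m else -np.inf
            if values[i] > nxt or j == m - 1:
                idx.append(j)
    return sorted(set(idx))


def estimate_pKa(curve: TitrationCurve) -> float:
    """Apparent pKa: pH midway (in added acid) between the two equivalence points.

    Equivalence points are the two dominant local maxima of |dpH/dn| after
    3-point median smoothing; they must bracket a buffering plateau (a
    region of much lower slope).  Raises :class:`EstimationError` when no
    such pair exists (e.g. strong acid into plain water).
    """
    if len(curve) < 4:
        raise InputError("pKa estimation needs at least 4 curve points")
    slopes, mid_n = _interval_slopes(curve)
    maxima = _local_maxima(slopes)
    if len(maxima) < 2:
        raise EstimationError("no buffering plateau: fewer than two equivalence points")
    # two most prominent maxima, restored to added-acid order
    top2 = sorted(sorted(maxima, key=lambda i: slopes[i], reverse=True)[:2])
    i1, i2 = top2
    plateau_min = np.min(slopes[i1 : i2 + 1])
    if plateau_min >= 0.5 * min(slopes[i1], slopes[i2]):
        raise EstimationError("no buffering plateau between equivalence points")
    n_mid = 0.5 * (mid_n[i1] + mid_n[i2])
    return float(np.interp(n_mid, curve.added_acid, curve.pH))


def fold_buffer_ratio(
    a: BufferCapacityProfile,
    b: BufferCapacityProfile,
    pH: float,
    a_stat: Literal["max", "at_pH"] = "max",
) -> float:
    """Buffer-strength fold ratio of profile ``a`` over profile ``b`` at ``pH``.

    The numerator is either the maximum of ``a.beta`` or ``a`` interpolated
    at ``pH`` (per ``a_stat``); the denominator is ``b`` interpolated at
    ``pH``.  Profiles must share mode and reference-mass basis.
    """
    if a.mode != b.mode:
        raise InputError(f"profiles mix modes {a.mode!r} and {b.mode!r}")
    if not math.isclose(a.reference_mass, b.reference_mass, rel_tol=1e-9):
        raise InputError("profiles refer to different solute masses")
    if a_stat == "max":
        num = float(np.max(a.beta))
    elif a_stat == "at_pH":
        num = a.at(pH)
    else:
        raise InputError(f"unknown a_stat {a_stat!r}")
    den = b.at(pH)
    if den < 1e-15:
        raise DataQualityError(
            f"denominator beta at pH {pH} is below the numerical floor"
        )
    return num / den
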