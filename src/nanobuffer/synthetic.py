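"""Synthetic datasets with ground truth for every pipeline stage.

Each generator emulates one bench experiment -- acid titration, dose-series
pH-clamp time courses with per-cell uptake, two-channel ratiometric punctae
fields, and three-channel colocalization stacks -- and returns, beside the
dataset, a ground-truth table sufficient to score every downstream
estimator (true pKa, true pump rate, true per-punta pH, true overlap
fraction).

Randomness: a single integer seed fans out to independent per-scenario
substreams via ``numpy.random.SeedSequence([seed, stream_id])`` with fixed
stream ids (titration 0, uptake 1, trajectories 2, ratiometric 3, coloc 4),
so adding a generator never perturbs the others and identical seeds give
identical outputs.

Default noise levels model bench-scale acquisition: titration pH sd 0.02,
Poisson shot noise plus Gaussian read noise at 2% of dynamic range for
images, lognormal per-cell uptake with CV 20% and 5% fluorescence
measurement noise.  All are overridable.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .buffer_model import (
    ProtonatableSpecies,
    TitrationCurve,
    TitrationMixture,
    simulate_titration,
)
from .errors import InputError
from .imaging import CalibrationModel, ChannelImage
from .lumen_sim import (
    NanobufferLoad,
    OrganelleModel,
    PHTrajectory,
    dose_to_load,
    simulate_lumen,
)

__all__ = [
    "STREAM_IDS",
    "scenario_rng",
    "gen_titration",
    "gen_trajectories",
    "TrajectoryDataset",
    "gen_ratiometric_images",
    "gen_coloc_stacks",
    "lysosensor_like_calibration",
]

STREAM_IDS = {
    "titration": 0,
    "uptake": 1,
    "trajectories": 2,
    "ratiometric_images": 3,
    "coloc_stacks": 4,
}


def scenario_rng(seed: int, scenario: str) -> np.random.Generator:
    """Independent substream for one scenario of one master seed."""
    if scenario not in STREAM_IDS:
        raise InputError(
            f"unknown scenario {scenario!r}; known: {sorted(STREAM_IDS)}"
        )
    return np.random.default_rng(np.random.SeedSequence([seed, STREAM_IDS[scenario]]))


# ---------------------------------------------------------------------------
# titration


def gen_titration(
    true_species: ProtonatableSpecies,
    protocol: TitrationMixture | None = None,
    pH_noise_sd: float = 0.02,
    seed: int = 0,
    *,
    stop_pH: float = 3.0,
) -> tuple[TitrationCurve, pd.DataFrame]:
    """Simulated titration of ``true_species`` with additive pH read noise.

    If ``protocol`` is None, the species is titrated at 2 mg/ml in 20 ml of
    150 mM NaCl with 25-ul shots of 0.4 M HCl (the bench protocol).  Warns
    if the noise leaves the curve non-monotone even after 3-point median
    smoothing.  Identical seeds give identical curves.
    """
    if pH_noise_sd < 0:
        raise InputError("pH_noise_sd must be >= 0")
    if protocol is None:
        protocol = TitrationMixture(species_loads=((true_species, 40.0),))
    elif not any(sp is true_species for sp, _ in protocol.species_loads):
        raise InputError("protocol must include the true species")
    clean = simulate_titration(protocol, stop_pH=stop_pH)
    rng = scenario_rng(seed, "titration")
    noisy_pH = clean.pH + rng.normal(0.0, pH_noise_sd, size=len(clean))
    if pH_noise_sd > 0 and len(noisy_pH) >= 3:
        padded = np.pad(noisy_pH, 1, mode="edge")
        smoothed = np.array(
            [np.median(padded[i : i + 3]) for i in range(len(noisy_pH))]
        )
        if np.any(np.diff(smoothed) > 0):
            warnings.warn(
                "pH noise leaves the curve non-monotone after smoothing; "
                "consider regenerating with a smaller pH_noise_sd",
                stacklevel=2,
            )
    curve = TitrationCurve(
        added_acid=clean.added_acid.copy(),
        pH=noisy_pH,
        volumes=clean.volumes.copy(),
        reference_mass=clean.reference_mass,
    )
    truth = pd.DataFrame(
        {
            "species": [true_species.name],
            "true_pKa": [true_species.site_groups[0].pKa],
            "true_hill_n": [true_species.site_groups[0].hill_n],
            "true_site_density_mol_per_g": [true_species.total_site_density],
            "pH_noise_sd": [pH_noise_sd],
            "seed": [seed],
        }
    )
    return curve, truth


# ---------------------------------------------------------------------------
# trajectories + uptake


@dataclass
class TrajectoryDataset:
    """Per-cell pH-clamp simulations plus the matching uptake table."""

    trajectories: dict[tuple[float, int], PHTrajectory]  # (dose, cell) -> traj
    control: PHTrajectory
    loads: dict[tuple[float, int], NanobufferLoad]
    uptake: pd.DataFrame
    ground_truth: pd.DataFrame
    standard_curve_slope: float
    standard_curve_intercept: float


def gen_trajectories(
    model: OrganelleModel,
    doses: list[float],
    n_cells: int = 20,
    uptake_cv: float = 0.20,
    seed: int = 0,
    *,
    load_pKa: float = 6.2,
    uptake_fraction: float = 1e-4,
    cell_volume_medium: float = 2e-5,  # ml per cell
    organelles_per_cell: float = 200.0,
    duration: float = 20_000.0,
    dt: float = 10.0,
    cell_count_per_well: int = 100,
    standard_curve_slope: float = 50.0,  # micelles per fluorescence unit
    standard_curve_intercept: float = 100.0,
    measurement_noise: float = 0.05,
) -> TrajectoryDataset:
    """Dose series of luminal pH time courses with heterogeneous uptake.

    Per-cell uptake multipliers are lognormal with mean 1 and coefficient
    of variation ``uptake_cv``; each cell's per-organelle load follows from
    :func:`dose_to_load` and is simulated with :func:`simulate_lumen`.  The
    uptake table reports one well per (dose, cell) with an affine standard
    curve and multiplicative fluorescence measurement noise; the ground
    truth records the exact per-cell micelle counts and the pump rate.
    """
    if any(d <= 0 for d in doses):
        raise InputError("doses must be positive")
    if uptake_cv < 0 or measurement_noise < 0:
        raise InputError("noise parameters must be >= 0")
    rng = scenario_rng(seed, "trajectories")
    rng_uptake = scenario_rng(seed, "uptake")
    if uptake_cv > 0:
        sigma = np.sqrt(np.log1p(uptake_cv**2))
        factors = rng.lognormal(-0.5 * sigma**2, sigma, size=(len(doses), n_cells))
    else:
        factors = np.ones((len(doses), n_cells))

    control = simulate_lumen(
        model,
        NanobufferLoad(0.0, pKa=load_pKa),
        duration=duration,
        dt=dt,
    )
    trajectories: dict[tuple[float, int], PHTrajectory] = {}
    loads: dict[tuple[float, int], NanobufferLoad] = {}
    uptake_rows, truth_rows = [], []
    for i, dose in enumerate(doses):
        for c in range(n_cells):
            eff_dose = dose * factors[i, c]
            load = dose_to_load(
                eff_dose,
                uptake_fraction,
                cell_volume_medium,
                organelles_per_cell,
                pKa=load_pKa,
            )
            key = (dose, c)
            loads[key] = load
            trajectories[key] = simulate_lumen(model, load, duration, dt)
            micelles_cell = load.micelles_per_organelle * organelles_per_cell
            fl_clean = (
                standard_curve_intercept
                + micelles_cell * cell_count_per_well / standard_curve_slope
            )
            noise = rng_uptake.normal(0.0, measurement_noise) if measurement_noise else 0.0
            fl = standard_curve_intercept + (fl_clean - standard_curve_intercept) * (
                1.0 + noise
            )
            uptake_rows.append(
                {
                    "well_id": f"d{dose:g}_c{c}",
                    "dose_ug_ml": dose,
                    "total_fluorescence": fl,
                    "cell_count": cell_count_per_well,
                }
            )
            truth_rows.append(
                {
                    "well_id": f"d{dose:g}_c{c}",
                    "dose_ug_ml": dose,
                    "cell": c,
                    "true_micelles_per_cell": micelles_cell,
                    "true_micelles_per_organelle": load.micelles_per_organelle,
                    "true_pump_rate": model.pump_rate,
                    "true_pKa": load_pKa,
                    "seed": seed,
                }
            )
    return TrajectoryDataset(
        trajectories=trajectories,
        control=control,
        loads=loads,
        uptake=pd.DataFrame(uptake_rows),
        ground_truth=pd.DataFrame(truth_rows),
        standard_curve_slope=standard_curve_slope,
        standard_curve_intercept=standard_curve_intercept,
    )


# ---------------------------------------------------------------------------
# ratiometric punctae images


def lysosensor_like_calibration() -> CalibrationModel:
    """A realistic default R(pH) calibration for synthetic punctae fields.

    Bi-sigmoid with transitions at pH 4.8 and 6.4 (slopes 1.2, equal mix),
    ratio spanning 0.3-2.6 over pH 4.0-7.4.  Two staggered transitions keep
    the curve informative across the whole endo/lysosomal range, the reason
    ratiometric probes are calibrated with a bi-dose-response in practice.
    """
    return CalibrationModel(
        kind="bi-sigmoid",
        bottom=0.3,
        top=2.6,
        midpoints=(4.8, 6.4),
        slopes=(1.2, 1.2),
        fraction=0.5,
        valid_range=(4.0, 7.4),
    )


def _place_spots(
    rng: np.random.Generator,
    n: int,
    shape: tuple[int, ...],
    margin: int,
    min_sep_px: float,
) -> np.ndarray:
    """Rejection-sample ``n`` positions with pairwise separation >= min_sep_px."""
    usable = [s - 2 * margin for s in shape]
    if any(u <= 0 for u in usable):
        raise InputError("field too small for the requested margin")
    # hexagonal-type packings fit ~1.15 points per sep^2; stay well below
    if n * min_sep_px ** len(shape) > 0.9 * np.prod(usable):
        raise InputError("infeasible packing: separation x count exceeds the field")
    pts: list[np.ndarray] = []
    attempts = 0
    while len(pts) < n:
        attempts += 1
        if attempts > 20_000 * n:
            raise InputError("infeasible packing: could not place all punctae")
        cand = np.array([margin + rng.uniform(0, u) for u in usable])
        if all(np.linalg.norm(cand - p) >= min_sep_px for p in pts):
            pts.append(cand)
    return np.array(pts)


def _render_gaussians(
    shape: tuple[int, ...],
    positions: np.ndarray,
    amplitudes: np.ndarray,
    sigma_px: np.ndarray,
) -> np.ndarray:
    img = np.zeros(shape, dtype=float)
    half = np.ceil(4 * sigma_px).astype(int)
    grids = [np.arange(s) for s in shape]
    for pos, amp in zip(positions, amplitudes):
        slices, axes = [], []
        for d in range(len(shape)):
            lo = max(0, int(np.floor(pos[d])) - half[d])
            hi = min(shape[d], int(np.ceil(pos[d])) + half[d] + 1)
            slices.append(slice(lo, hi))
            axes.append(grids[d][lo:hi])
        mesh = np.meshgrid(*axes, indexing="ij")
        d2 = sum(((m - p) / s) ** 2 for m, p, s in zip(mesh, pos, sigma_px))
        img[tuple(slices)] += amp * np.exp(-0.5 * d2)
    return img


def gen_ratiometric_images(
    n_punctae: int,
    pH_distribution: tuple[float, float],
    calib: CalibrationModel,
    psf_sigma: float = 0.2,  # um
    background: float = 150.0,
    background_gradient: float = 0.2,  # fractional tilt across the field
    noise: bool = True,
    read_noise_fraction: float = 0.02,  # of dynamic range
    seed: int = 0,
    *,
    shape: tuple[int, int] = (192, 192),
    voxel_size: tuple[float, float] = (0.1, 0.1),
    amplitude_ch2: float = 3000.0,
    min_separation: float = 1.5,  # um
) -> tuple[ChannelImage, ChannelImage, pd.DataFrame]:
    """Two-channel punctae field with a known pH per punta.

    Channel 2 (denominator, pH-insensitive) has fixed spot amplitude;
    channel 1's amplitude is set so the true background-corrected ratio of
    each punta equals ``calib.forward(true_pH)``.  Spots are Gaussian with
    the stated PSF sigma on a tilted background; noise is Poisson shot
    noise plus Gaussian read noise.  Ground truth lists position, true pH
    and true ratio per punta.
    """
    if n_punctae <= 0:
        raise InputError("n_punctae must be positive")
    rng = scenario_rng(seed, "ratiometric_images")
    mean_pH, sd_pH = pH_distribution
    lo, hi = calib.valid_range
    true_pH = np.clip(rng.normal(mean_pH, sd_pH, size=n_punctae), lo, hi)
    true_R = np.asarray(calib.forward(true_pH), dtype=float)

    sigma_px = np.array([psf_sigma / v for v in voxel_size])
    min_sep_px = min_separation / min(voxel_size)
    margin = int(np.ceil(4 * sigma_px.max())) + 10  # spot support + bg annulus
    positions = _place_spots(rng, n_punctae, shape, margin, min_sep_px)

    amp2 = np.full(n_punctae, amplitude_ch2)
    amp1 = true_R * amp2
    spots1 = _render_gaussians(shape, positions, amp1, sigma_px)
    spots2 = _render_gaussians(shape, positions, amp2, sigma_px)
    yy = np.linspace(-0.5, 0.5, shape[0])[:, None]
    bg = background * (1.0 + background_gradient * yy) * np.ones(shape)
    img1, img2 = spots1 + bg, spots2 + bg
    if noise:
        dyn = max(img1.max(), img2.max())
        read_sd = read_noise_fraction * dyn
        img1 = rng.poisson(img1).astype(float) + rng.normal(0, read_sd, shape)
        img2 = rng.poisson(img2).astype(float) + rng.normal(0, read_sd, shape)
    img1 = np.clip(np.round(img1), 0, 65535)
    img2 = np.clip(np.round(img2), 0, 65535)
    truth = pd.DataFrame(
        {
            "punta_id": np.arange(n_punctae),
            "y": positions[:, 0],
            "x": positions[:, 1],
            "true_pH": true_pH,
            "true_R": true_R,
            "seed": seed,
        }
    )
    ch1 = ChannelImage(img1, channel_id="ch1_pH_sensitive", voxel_size=voxel_size)
    ch2 = ChannelImage(img2, channel_id="ch2_reference", voxel_size=voxel_size)
    return ch1, ch2, truth


# ---------------------------------------------------------------------------
# colocalization stacks


def gen_coloc_stacks(
    n_vesicles: int,
    overlap_fraction: float,
    seed: int = 0,
    *,
    shape: tuple[int, int, int] = (8, 128, 128),
    voxel_size: tuple[float, float, float] = (0.3, 0.1, 0.1),
    psf_sigma: tuple[float, float, float] = (0.3, 0.15, 0.15),  # um
    amplitude: float = 2000.0,
    min_separation: float = 1.0,  # um (lateral)
    noise: bool = True,
    read_noise_fraction: float = 0.02,
) -> tuple[dict[str, ChannelImage], pd.DataFrame]:
    """Three-channel 3D stack with a known cargo/marker overlap fraction.

    Cargo vesicles are assigned to the early-endosome-like marker channel
    so that exactly ``round(overlap_fraction * n_vesicles)`` of them (a
    seeded random subset) colocalize; the remainder carry the
    lysosome-like marker.  With equal vesicle intensities, the expected
    intensity-weighted Mander's M1 of cargo against the first marker
    equals the realized overlap fraction recorded in the ground truth.
    """
    if not (0.0 <= overlap_fraction <= 1.0):
        raise InputError("overlap_fraction must lie in [0, 1]")
    if n_vesicles <= 0:
        raise InputError("n_vesicles must be positive")
    rng = scenario_rng(seed, "coloc_stacks")
    sigma_px = np.array([s / v for s, v in zip(psf_sigma, voxel_size)])
    min_sep_px = min_separation / min(voxel_size[1:])
    margin = int(np.ceil(4 * sigma_px[1:].max()))
    lateral = _place_spots(rng, n_vesicles, shape[1:], margin, min_sep_px)
    z = rng.uniform(sigma_px[0], shape[0] - 1 - sigma_px[0], size=n_vesicles)
    positions = np.column_stack([z, lateral])

    n_over = int(round(overlap_fraction * n_vesicles))
    order = rng.permutation(n_vesicles)
    marker_a = np.zeros(n_vesicles, dtype=bool)
    marker_a[order[:n_over]] = True
    realized = marker_a.mean()

    amps = np.full(n_vesicles, amplitude)
    cargo = _render_gaussians(shape, positions, amps, sigma_px)
    rab = _render_gaussians(shape, positions[marker_a], amps[marker_a], sigma_px)
    lamp = _render_gaussians(shape, positions[~marker_a], amps[~marker_a], sigma_px)
    channels = {}
    for name, img in (("cargo", cargo), ("rab5_like", rab), ("lamp2_like", lamp)):
        if noise:
            read_sd = read_noise_fraction * amplitude
            img = rng.poisson(img).astype(float) + rng.normal(0, read_sd, shape)
        img = np.clip(np.round(img), 0, 65535)
        channels[name] = ChannelImage(img, channel_id=name, voxel_size=voxel_size)
    truth = pd.DataFrame(
        {
            "vesicle_id": np.arange(n_vesicles),
            "z": positions[:, 0],
            "y": positions[:, 1],
            "x": positions[:, 2],
            "marker_a_positive": marker_a,
            "requested_overlap": overlap_fraction,
            "realized_overlap": realized,
            "seed": seed,
        }
    )
    return channels, truth
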