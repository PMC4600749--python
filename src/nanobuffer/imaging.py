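"""Ratiometric fluorescence quantification and colocalization.

Implements the image-analysis chain used for per-organelle pH readout:
punctae (spot) detection, background-corrected two-channel intensity
ratios R = (F1 - B1)/(F2 - B2), a sigmoid / bi-sigmoid ratio-to-pH
calibration, thresholded Mander's colocalization coefficients, and 3D
vesicle morphometrics (voxel volume and shortest distance to the nucleus
surface via Euclidean distance transform).

Coordinates are 0-based; connectivity is 8 in 2D and 26 in 3D.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Literal, Sequence

import numpy as np
import pandas as pd
from scipy import ndimage
from scipy.optimize import brentq, curve_fit
from skimage.filters import gaussian
from skimage.measure import label, regionprops

from .errors import (
    DataQualityError,
    EstimationError,
    ExtrapolationError,
    InputError,
    UndefinedRatioError,
)

__all__ = [
    "ChannelImage",
    "Punta",
    "CalibrationModel",
    "ColocResult",
    "detect_punctae",
    "measure_ratio",
    "measure_ratios",
    "fit_calibration",
    "pH_from_ratio",
    "manders",
    "morphometrics",
]


@dataclass
class ChannelImage:
    """One fluorescence channel: a 2D or 3D non-negative intensity grid."""

    intensities: np.ndarray
    channel_id: str
    voxel_size: tuple[float, ...]  # um per axis, same order as array axes

    def __post_init__(self) -> None:
        self.intensities = np.asarray(self.intensities, dtype=float)
        if self.intensities.ndim not in (2, 3):
            raise InputError("image must be 2D or 3D")
        if not np.all(np.isfinite(self.intensities)):
            raise InputError("intensities must be finite")
        if np.any(self.intensities < 0):
            raise InputError("intensities must be non-negative")
        self.voxel_size = tuple(float(v) for v in self.voxel_size)
        if len(self.voxel_size) != self.intensities.ndim:
            raise InputError("voxel_size must give one spacing per axis")
        if any(v <= 0 for v in self.voxel_size):
            raise InputError("voxel sizes must be positive")

    @property
    def shape(self) -> tuple[int, ...]:
        return self.intensities.shape


@dataclass
class Punta:
    """A segmented fluorescent spot (one endocytic organelle).

    ``F`` and ``B`` hold per-channel mean foreground and local background
    intensities once measured; they start empty.
    """

    id: int
    voxels: np.ndarray  # (n, ndim) 0-based coordinates
    centroid: tuple[float, ...]
    total_intensity: float
    F: dict = field(default_factory=dict)
    B: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.voxels = np.asarray(self.voxels, dtype=int)
        if self.voxels.size == 0:
            raise InputError("punta has no voxels")

    def mask(self, shape: tuple[int, ...]) -> np.ndarray:
        m = np.zeros(shape, dtype=bool)
        m[tuple(self.voxels.T)] = True
        return m


@dataclass
class ColocResult:
    """Thresholded Mander's coefficients between two channels."""

    M1: float
    M2: float
    threshold_A: float
    threshold_B: float

    def __post_init__(self) -> None:
        for m in (self.M1, self.M2):
            if not (0.0 <= m <= 1.0):
                raise InputError("Mander's coefficients must lie in [0, 1]")


# ---------------------------------------------------------------------------
# punctae detection and ratio measurement


def detect_punctae(
    img: ChannelImage,
    smooth_sigma: float = 0.1,
    threshold_quantile: float = 0.99,
    min_voxels: int = 3,
    max_voxels: int = 10_000,
) -> list[Punta]:
    """Segment punctae by smoothing, quantile thresholding and labelling.

    ``smooth_sigma`` is in um and is converted per axis through the voxel
    size.  Connected components (full connectivity) outside the
    [min_voxels, max_voxels] size window are dropped.  Punctae are sorted
    by descending total (raw) intensity, ties broken by lexicographic
    centroid.  A blank field returns an empty list.
    """
    if not (0.0 < threshold_quantile < 1.0):
        raise InputError("threshold_quantile must lie in (0, 1)")
    if min_voxels > max_voxels:
        raise InputError("min_voxels must not exceed max_voxels")
    data = img.intensities
    sigma_px = [smooth_sigma / v for v in img.voxel_size]
    smoothed = gaussian(data, sigma=sigma_px, preserve_range=True)
    thr = np.quantile(smoothed, threshold_quantile)
    mask = smoothed > thr
    if not mask.any():
        return []
    labels = label(mask, connectivity=data.ndim)
    punctae: list[Punta] = []
    for rp in regionprops(labels, intensity_image=data):
        if not (min_voxels <= rp.num_pixels <= max_voxels):
            continue
        punctae.append(
            Punta(
                id=-1,
                voxels=rp.coords,
                centroid=tuple(rp.centroid_weighted),
                total_intensity=float(rp.image_intensity.sum()),
            )
        )
    punctae.sort(key=lambda p: (-p.total_intensity, p.centroid))
    for i, p in enumerate(punctae):
        p.id = i
    return punctae


def _annulus_mask(
    p: Punta,
    shape: tuple[int, ...],
    voxel_size: tuple[float, ...],
    bg_annulus: float,
    exclude: np.ndarray | None,
) -> np.ndarray:
    """Background annulus: voxels between ``bg_annulus`` and ``2*bg_annulus``
    um from the punta surface, minus any excluded (other-punctae) voxels."""
    dist = ndimage.distance_transform_edt(~p.mask(shape), sampling=voxel_size)
    ring = (dist >= bg_annulus) & (dist <= 2.0 * bg_annulus)
    if exclude is not None:
        ring &= ~exclude
    return ring


def measure_ratio(
    p: Punta,
    ch1: ChannelImage,
    ch2: ChannelImage,
    bg_annulus: float = 0.4,
    exclude_mask: np.ndarray | None = None,
) -> float:
    """Background-corrected intensity ratio R = (F1 - B1)/(F2 - B2).

    F is the mean intensity over the punta voxels; B the median over an
    annulus ``bg_annulus`` to ``2*bg_annulus`` um outside it (voxels under
    ``exclude_mask`` - typically all other punctae - are dropped from the
    background).  Raises :class:`UndefinedRatioError` if F2 - B2 <= 0; such
    punctae are flagged and excluded downstream.  Measured F/B values are
    stored on the punta per channel id.
    """
    if ch1.shape != ch2.shape:
        raise InputError("channels must share shape")
    if np.any(p.voxels >= np.array(ch1.shape)) or np.any(p.voxels < 0):
        raise InputError("punta voxels fall outside the image")
    ring = _annulus_mask(p, ch1.shape, ch1.voxel_size, bg_annulus, exclude_mask)
    if not ring.any():
        raise InputError("background annulus is empty")
    idx = tuple(p.voxels.T)
    f1 = float(ch1.intensities[idx].mean())
    f2 = float(ch2.intensities[idx].mean())
    b1 = float(np.median(ch1.intensities[ring]))
    b2 = float(np.median(ch2.intensities[ring]))
    p.F[ch1.channel_id], p.B[ch1.channel_id] = f1, b1
    p.F[ch2.channel_id], p.B[ch2.channel_id] = f2, b2
    if f2 - b2 <= 0:
        raise UndefinedRatioError(
            f"punta {p.id}: denominator F2 - B2 = {f2 - b2:.3g} <= 0"
        )
    return (f1 - b1) / (f2 - b2)


def measure_ratios(
    punctae: Sequence[Punta],
    ch1: ChannelImage,
    ch2: ChannelImage,
    bg_annulus: float = 0.4,
    calibration: "CalibrationModel | None" = None,
) -> pd.DataFrame:
    """Ratio (and optionally pH) table for many punctae.

    Other punctae are excluded from each background annulus.  Punctae with
    an undefined ratio get R = NaN and ``flag = "undefined_ratio"``; ratios
    outside the calibration range get ``flag = "out_of_range"``.
    """
    all_mask = np.zeros(ch1.shape, dtype=bool)
    for p in punctae:
        all_mask[tuple(p.voxels.T)] = True
    rows = []
    for p in punctae:
        exclude = all_mask & ~p.mask(ch1.shape)
        row: dict = {"punta_id": p.id}
        for axis_name, c in zip("zyx"[-ch1.intensities.ndim :], p.centroid):
            row[axis_name] = c
        try:
            r = measure_ratio(p, ch1, ch2, bg_annulus, exclude)
            row["R"], row["flag"] = r, ""
        except UndefinedRatioError:
            row["R"], row["flag"] = np.nan, "undefined_ratio"
        row["F1"] = p.F.get(ch1.channel_id, np.nan)
        row["B1"] = p.B.get(ch1.channel_id, np.nan)
        row["F2"] = p.F.get(ch2.channel_id, np.nan)
        row["B2"] = p.B.get(ch2.channel_id, np.nan)
        if calibration is not None:
            if row["flag"]:
                row["pH"] = np.nan
            else:
                try:
                    row["pH"] = pH_from_ratio(calibration, row["R"])
                except ExtrapolationError:
                    row["pH"], row["flag"] = np.nan, "out_of_range"
        rows.append(row)
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# calibration


def _logistic(pH, mid, slope):
    # decreasing in pH for slope > 0 (acidic ratios are high)
    expo = np.clip(slope * (np.asarray(pH, float) - mid), -300, 300)
    return 1.0 / (1.0 + 10.0**expo)


@dataclass
class CalibrationModel:
    """Monotone R(pH) calibration: sigmoid or bi-sigmoid dose-response.

    sigmoid:     R = bottom + (top - bottom) * L(pH; mid, slope)
    bi-sigmoid:  R = bottom + (top - bottom) *
                     [w * L(pH; mid1, slope1) + (1 - w) * L(pH; mid2, slope2)]

    with L the descending logistic 1/(1 + 10^(slope (pH - mid))).  The two
    logistic terms share bottom/top; ``fraction`` is the convex mixing
    weight w.  ``valid_range`` bounds the pH over which inversion is
    trusted; ``r_range`` echoes the fitted data's ratio span.
    """

    kind: Literal["sigmoid", "bi-sigmoid"]
    bottom: float
    top: float
    midpoints: tuple[float, ...]
    slopes: tuple[float, ...]
    fraction: float | None = None  # bi-sigmoid mixing weight in (0, 1)
    valid_range: tuple[float, float] = (4.0, 7.4)
    r_range: tuple[float, float] | None = None
    rmse: float | None = None

    def __post_init__(self) -> None:
        if self.top <= self.bottom:
            raise InputError("top must exceed bottom")
        lo, hi = self.valid_range
        if not all(lo <= m <= hi for m in self.midpoints):
            raise InputError("midpoints must lie inside valid_range")
        if self.kind == "bi-sigmoid":
            if self.fraction is None or not (0.0 < self.fraction < 1.0):
                raise InputError("bi-sigmoid fraction must lie in (0, 1)")
            if len(self.midpoints) != 2 or len(self.slopes) != 2:
                raise InputError("bi-sigmoid needs two midpoints and slopes")
        elif self.kind == "sigmoid":
            if len(self.midpoints) != 1 or len(self.slopes) != 1:
                raise InputError("sigmoid needs one midpoint and slope")
        else:
            raise InputError(f"unknown calibration kind {self.kind!r}")

    def forward(self, pH):
        """Predicted ratio at ``pH``."""
        if self.kind == "sigmoid":
            core = _logistic(pH, self.midpoints[0], self.slopes[0])
        else:
            w = self.fraction
            core = w * _logistic(pH, self.midpoints[0], self.slopes[0]) + (
                1.0 - w
            ) * _logistic(pH, self.midpoints[1], self.slopes[1])
        return self.bottom + (self.top - self.bottom) * core


def fit_calibration(
    R_values: Sequence[float],
    pH_values: Sequence[float],
    kind: Literal["sigmoid", "bi-sigmoid"] = "sigmoid",
    valid_range: tuple[float, float] | None = None,
) -> CalibrationModel:
    """Least-squares fit of the ratio-to-pH calibration.

    Requires >= 5 distinct pH points for a sigmoid and >= 7 for a
    bi-sigmoid, all within pH [3.5, 8.0].  Initialization is deterministic
    (data quantiles); no random restarts.  Warns if the data are
    non-monotone beyond ~5x the fit residual.
    """
    R = np.asarray(R_values, dtype=float)
    pH = np.asarray(pH_values, dtype=float)
    if R.shape != pH.shape:
        raise InputError("R_values and pH_values must match in length")
    n_distinct = len(np.unique(pH))
    need = 5 if kind == "sigmoid" else 7
    if n_distinct < need:
        raise InputError(f"{kind} calibration needs >= {need} distinct pH points")
    if np.any(pH < 3.5) or np.any(pH > 8.0):
        raise InputError("calibration pH values must lie within [3.5, 8.0]")
    span = R.max() - R.min()
    if span <= 1e-12 * max(1.0, abs(R.max())):
        raise EstimationError("degenerate fit: ratio is constant over all pH")
    order = np.argsort(pH)
    pH_s, R_s = pH[order], R[order]
    if valid_range is None:
        valid_range = (float(pH_s[0]), float(pH_s[-1]))

    bottom0, top0 = float(R.min()), float(R.max())
    # pH at half-maximal ratio, from the sorted data
    half = bottom0 + 0.5 * span
    mid0 = float(np.interp(-half, -R_s, pH_s))  # R decreasing in pH
    lo, hi = 3.0, 8.5
    if kind == "sigmoid":

        def f(x, bottom, top, mid, slope):
            return bottom + (top - bottom) * _logistic(x, mid, slope)

        p0 = [bottom0, top0, mid0, 1.5]
        bounds = ([-np.inf, -np.inf, lo, 0.05], [np.inf, np.inf, hi, 30.0])
    else:

        def f(x, bottom, top, m1, m2, s1, s2, w):
            core = w * _logistic(x, m1, s1) + (1 - w) * _logistic(x, m2, s2)
            return bottom + (top - bottom) * core

        p0 = [bottom0, top0, mid0 - 0.5, mid0 + 0.5, 2.0, 2.0, 0.5]
        bounds = (
            [-np.inf, -np.inf, lo, lo, 0.05, 0.05, 0.01],
            [np.inf, np.inf, hi, hi, 30.0, 30.0, 0.99],
        )
    try:
        popt, _ = curve_fit(f, pH, R, p0=p0, bounds=bounds, maxfev=20_000)
    except RuntimeError as err:
        raise EstimationError(f"calibration fit failed to converge: {err}") from err
    resid = R - f(pH, *popt)
    rmse = float(np.sqrt(np.mean(resid**2)))
    # non-monotonicity of the data beyond noise tolerance
    increases = np.diff(R_s)
    if np.any(increases > max(5.0 * rmse, 1e-9) ):
        warnings.warn(
            "calibration data are non-monotone beyond the fit residual",
            stacklevel=2,
        )
    if kind == "sigmoid":
        bottom, top, mid, slope = popt
        model = CalibrationModel(
            kind="sigmoid",
            bottom=float(min(bottom, top)),
            top=float(max(bottom, top)),
            midpoints=(float(np.clip(mid, *valid_range)),),
            slopes=(float(slope),),
            valid_range=valid_range,
            r_range=(float(R.min()), float(R.max())),
            rmse=rmse,
        )
    else:
        bottom, top, m1, m2, s1, s2, w = popt
        if m1 > m2:  # canonical ordering of the two transitions
            m1, m2, s1, s2, w = m2, m1, s2, s1, 1.0 - w
        model = CalibrationModel(
            kind="bi-sigmoid",
            bottom=float(min(bottom, top)),
            top=float(max(bottom, top)),
            midpoints=(
                float(np.clip(m1, *valid_range)),
                float(np.clip(m2, *valid_range)),
            ),
            slopes=(float(s1), float(s2)),
            fraction=float(w),
            valid_range=valid_range,
            r_range=(float(R.min()), float(R.max())),
            rmse=rmse,
        )
    return model


def pH_from_ratio(model: CalibrationModel, R: float) -> float:
    """Invert the monotone calibration curve: pH such that forward(pH) = R.

    ``R`` must lie within the curve's range over ``valid_range`` (with 5%
    of the span as tolerance, clipped to the boundary); outside that an
    :class:`ExtrapolationError` reports the nearest valid pH.
    """
    lo, hi = model.valid_range
    r_lo, r_hi = model.forward(hi), model.forward(lo)  # R decreasing in pH
    span = r_hi - r_lo
    tol = 0.05 * span
    if R < r_lo - tol or R > r_hi + tol:
        clipped = hi if R < r_lo else lo
        raise ExtrapolationError(
            f"ratio {R:.4g} outside calibrated range [{r_lo:.4g}, {r_hi:.4g}]; "
            f"nearest valid pH is {clipped:g}"
        )
    if R <= r_lo:
        return float(hi)
    if R >= r_hi:
        return float(lo)
    return float(brentq(lambda p: model.forward(p) - R, lo, hi, xtol=1e-9))


# ---------------------------------------------------------------------------
# colocalization and morphometrics


def manders(
    chA: ChannelImage | np.ndarray,
    chB: ChannelImage | np.ndarray,
    tA: float,
    tB: float,
) -> ColocResult:
    """Thresholded Mander's colocalization coefficients.

    M1 is the fraction of channel-A intensity (over voxels with A > tA)
    residing in voxels where B > tB; M2 is the symmetric quantity for B.
    """
    A = chA.intensities if isinstance(chA, ChannelImage) else np.asarray(chA, float)
    B = chB.intensities if isinstance(chB, ChannelImage) else np.asarray(chB, float)
    if A.shape != B.shape:
        raise InputError("channels must share shape")
    if tA < 0 or tB < 0:
        raise InputError("thresholds must be >= 0")
    maskA, maskB = A > tA, B > tB
    sumA = A[maskA].sum()
    sumB = B[maskB].sum()
    if sumA <= 0:
        raise DataQualityError("no signal above threshold in channel A")
    if sumB <= 0:
        raise DataQualityError("no signal above threshold in channel B")
    m1 = A[maskA & maskB].sum() / sumA
    m2 = B[maskA & maskB].sum() / sumB
    return ColocResult(M1=float(m1), M2=float(m2), threshold_A=tA, threshold_B=tB)


def morphometrics(
    vesicle_mask: np.ndarray,
    nucleus_mask: np.ndarray,
    voxel_size: tuple[float, ...],
) -> pd.DataFrame:
    """Per-vesicle volume and shortest distance to the nucleus surface.

    ``vesicle_mask`` is a labelled integer grid (0 = background);
    ``nucleus_mask`` a boolean grid of the same shape.  Volume is voxel
    count times voxel volume (um^3); distance is the minimum, over the
    vesicle's voxels, of the Euclidean distance transform of the nucleus
    complement (um) - zero for vesicles touching the nucleus.
    """
    vesicle_mask = np.asarray(vesicle_mask)
    nucleus_mask = np.asarray(nucleus_mask).astype(bool)
    if vesicle_mask.shape != nucleus_mask.shape:
        raise InputError("masks must share shape")
    if len(voxel_size) != vesicle_mask.ndim:
        raise InputError("voxel_size must give one spacing per axis")
    if not nucleus_mask.any():
        raise InputError("nucleus mask is empty")
    dist = ndimage.distance_transform_edt(~nucleus_mask, sampling=voxel_size)
    voxel_volume = float(np.prod(voxel_size))
    rows = []
    for lab in np.unique(vesicle_mask):
        if lab == 0:
            continue
        sel = vesicle_mask == lab
        rows.append(
            {
                "label": int(lab),
                "volume_um3": float(sel.sum()) * voxel_volume,
                "distance_to_nucleus_um": float(dist[sel].min()),
            }
        )
    return pd.DataFrame(rows, columns=["label", "volume_um3", "distance_to_nucleus_um"])
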