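"""Punctae detection, ratiometric calibration, Mander's and morphometrics."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from nanobuffer import (
    CalibrationModel,
    ChannelImage,
    detect_punctae,
    fit_calibration,
    manders,
    measure_ratio,
    morphometrics,
    pH_from_ratio,
)
from nanobuffer.errors import (
    DataQualityError,
    EstimationError,
    ExtrapolationError,
    InputError,
    UndefinedRatioError,
)
from nanobuffer.imaging import Punta


def spot_image(centers, amp=1000.0, sigma=2.0, shape=(128, 128), bg=10.0):
    yy, xx = np.mgrid[: shape[0], : shape[1]]
    img = np.full(shape, bg)
    for (cy, cx) in centers:
        img += amp * np.exp(-(((yy - cy) ** 2 + (xx - cx) ** 2) / (2 * sigma**2)))
    return ChannelImage(img, "test", (1.0, 1.0))


class TestDetectPunctae:
    def test_blank_image_yields_nothing(self):
        img = ChannelImage(np.zeros((64, 64)), "blank", (1.0, 1.0))
        assert detect_punctae(img) == []

    def test_well_separated_spots_all_found(self):
        grid = [(20 + 22 * i, 20 + 22 * j) for i in range(5) for j in range(5)]
        img = spot_image(grid)
        punctae = detect_punctae(img, smooth_sigma=1.0, threshold_quantile=0.95)
        assert len(punctae) == 25
        found = np.array([p.centroid for p in punctae])
        for c in grid:
            assert np.min(np.linalg.norm(found - np.array(c), axis=1)) < 1.0

    def test_unresolved_pair_merges_into_one(self):
        img = spot_image([(40.0, 40.0), (40.0, 42.5)], sigma=2.0)
        punctae = detect_punctae(img, smooth_sigma=1.0, threshold_quantile=0.99)
        assert len(punctae) == 1


class TestMeasureRatio:
    def _punta_and_channels(self, f1, f2, bg1, bg2):
        shape = (41, 41)
        vox = np.array([[20 + dy, 20 + dx] for dy in (-1, 0, 1) for dx in (-1, 0, 1)])
        p = Punta(id=0, voxels=vox, centroid=(20.0, 20.0), total_intensity=f1 * 9)
        img1 = np.full(shape, bg1)
        img2 = np.full(shape, bg2)
        img1[tuple(vox.T)] = f1
        img2[tuple(vox.T)] = f2
        return (
            p,
            ChannelImage(img1, "c1", (1.0, 1.0)),
            ChannelImage(img2, "c2", (1.0, 1.0)),
        )

    def test_background_corrected_arithmetic(self):
        p, c1, c2 = self._punta_and_channels(100.0, 50.0, 10.0, 5.0)
        assert measure_ratio(p, c1, c2, bg_annulus=2.0) == pytest.approx(2.0)
        assert p.F["c1"] == 100.0 and p.B["c2"] == 5.0

    def test_offset_invariance_per_channel(self):
        p, c1, c2 = self._punta_and_channels(100.0, 50.0, 10.0, 5.0)
        r = measure_ratio(p, c1, c2, bg_annulus=2.0)
        shifted = ChannelImage(c1.intensities + 37.0, "c1", (1.0, 1.0))
        assert measure_ratio(p, shifted, c2, bg_annulus=2.0) == pytest.approx(r)

    def test_background_only_punta_flagged(self):
        p, c1, c2 = self._punta_and_channels(5.0, 5.0, 5.0, 5.0)
        with pytest.raises(UndefinedRatioError):
            measure_ratio(p, c1, c2, bg_annulus=2.0)


class TestCalibration:
    TRUE = CalibrationModel(
        kind="sigmoid", bottom=0.5, top=2.5, midpoints=(5.5,), slopes=(1.8,),
        valid_range=(4.0, 7.4),
    )

    def test_exact_sigmoid_recovery(self):
        ph = np.linspace(4.0, 7.4, 9)
        model = fit_calibration(self.TRUE.forward(ph), ph, "sigmoid")
        assert model.bottom == pytest.approx(0.5, rel=0.01)
        assert model.top == pytest.approx(2.5, rel=0.01)
        assert model.midpoints[0] == pytest.approx(5.5, rel=0.01)
        assert model.slopes[0] == pytest.approx(1.8, rel=0.01)

    def test_constant_ratio_is_degenerate(self):
        ph = np.linspace(4.0, 7.4, 8)
        with pytest.raises(EstimationError):
            fit_calibration(np.ones_like(ph), ph, "sigmoid")

    def test_too_few_points_rejected(self):
        with pytest.raises(InputError):
            fit_calibration([1, 2, 3, 4], [4.0, 5.0, 6.0, 7.0], "sigmoid")

    def test_bi_sigmoid_round_trip_under_noise(self):
        # 8 calibration pH values, each measured over 25 punctae at 3%
        # intensity noise (a calibration point on the bench is never a
        # single spot); the fitted curve must invert the true curve to
        # better than 0.05 pH across the valid range
        true = CalibrationModel(
            kind="bi-sigmoid", bottom=0.3, top=2.6, midpoints=(4.8, 6.4),
            slopes=(1.5, 1.5), fraction=0.5, valid_range=(4.0, 7.4),
        )
        ph = np.repeat(np.linspace(4.0, 7.4, 8), 25)
        rng = np.random.default_rng(5)
        r = true.forward(ph) * (1 + rng.normal(0, 0.03, ph.shape))
        model = fit_calibration(r, ph, "bi-sigmoid")
        grid = np.linspace(4.1, 7.3, 30)
        back = np.array([pH_from_ratio(model, true.forward(p)) for p in grid])
        assert np.sqrt(np.mean((back - grid) ** 2)) < 0.05

    def test_forward_inverse_round_trip(self):
        grid = np.linspace(4.01, 7.39, 100)
        back = [pH_from_ratio(self.TRUE, self.TRUE.forward(p)) for p in grid]
        assert np.max(np.abs(np.array(back) - grid)) < 1e-6

    def test_midpoint_anchor(self):
        mid_r = self.TRUE.forward(5.5)
        assert pH_from_ratio(self.TRUE, mid_r) == pytest.approx(5.5, abs=1e-8)

    def test_out_of_range_ratio_rejected(self):
        with pytest.raises(ExtrapolationError):
            pH_from_ratio(self.TRUE, 3.0)  # beyond the top asymptote


class TestManders:
    def test_identical_images_fully_colocalize(self, rng):
        img = rng.uniform(0, 100, (32, 32))
        res = manders(img, img, 20.0, 20.0)
        assert res.M1 == 1.0 and res.M2 == 1.0

    def test_disjoint_masks_do_not_colocalize(self):
        a = np.zeros((16, 16))
        b = np.zeros((16, 16))
        a[:8], b[8:] = 50.0, 50.0
        res = manders(a, b, 1.0, 1.0)
        assert res.M1 == 0.0 and res.M2 == 0.0

    def test_constructed_sixty_percent_overlap(self):
        a = np.zeros((10, 10))
        b = np.zeros((10, 10))
        a[0, :10] = 10.0  # 100 units of A intensity
        b[0, :6] = 99.0  # B covers voxels holding 60% of it
        res = manders(a, b, 1.0, 1.0)
        assert res.M1 == pytest.approx(0.60)

    @settings(max_examples=20, derandomize=True, deadline=None)
    @given(scale=st.floats(0.1, 50.0))
    def test_invariant_to_intensity_rescaling(self, scale, rng):
        a = rng.uniform(0, 100, (24, 24))
        b = rng.uniform(0, 100, (24, 24))
        base = manders(a, b, 30.0, 40.0)
        scaled = manders(a * scale, b, 30.0 * scale, 40.0)
        assert scaled.M1 == pytest.approx(base.M1, rel=1e-9)
        assert scaled.M2 == pytest.approx(base.M2, rel=1e-9)

    def test_empty_channel_rejected(self):
        with pytest.raises(DataQualityError):
            manders(np.zeros((8, 8)), np.ones((8, 8)), 1.0, 0.5)


class TestMorphometrics:
    def test_cube_volume_and_distance(self):
        shape = (30, 30, 30)
        nucleus = np.zeros(shape, bool)
        nucleus[:, :, :6] = True  # outermost nucleus voxel at x = 5
        vesicles = np.zeros(shape, int)
        vesicles[10:13, 10:13, 15:18] = 1  # 3x3x3 cube, 10 voxels off the face
        out = morphometrics(vesicles, nucleus, (0.2, 0.2, 0.2))
        assert out.loc[0, "volume_um3"] == pytest.approx(27 * 0.008)
        assert out.loc[0, "distance_to_nucleus_um"] == pytest.approx(2.0, abs=0.1)

    def test_touching_vesicle_has_zero_distance(self):
        shape = (10, 10, 10)
        nucleus = np.zeros(shape, bool)
        nucleus[:, :, :5] = True
        vesicles = np.zeros(shape, int)
        vesicles[4:6, 4:6, 3:7] = 1  # overlaps the nucleus
        out = morphometrics(vesicles, nucleus, (0.2, 0.2, 0.2))
        assert out.loc[0, "distance_to_nucleus_um"] == 0.0

    def test_empty_nucleus_rejected(self):
        with pytest.raises(InputError):
            morphometrics(np.ones((4, 4, 4), int), np.zeros((4, 4, 4), bool), (1, 1, 1))
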