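"""Protonation chemistry, titration solver and buffer-capacity estimators."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import nanobuffer.buffer_model as bm
from nanobuffer import (
    ProtonatableSpecies,
    ProtonationSiteGroup,
    TitrationMixture,
    buffer_capacity,
    estimate_pKa,
    fold_buffer_ratio,
    protonation_fraction,
    simulate_titration,
    solve_pH,
)
from nanobuffer.constants import KW, hill_n_for_width
from nanobuffer.errors import (
    DataQualityError,
    DegenerateStepError,
    EstimationError,
    InputError,
)

WATER = TitrationMixture(species_loads=(), initial_volume=20.0)


def single_group_mixture(pKa, hill_n, mmol_sites, volume_ml=20.0, titrant=0.4, inc_ul=25.0):
    sp = ProtonatableSpecies(
        "base",
        (ProtonationSiteGroup(pKa=pKa, hill_n=hill_n, site_density=mmol_sites / 1000.0),),
    )  # 1 mg carries mmol_sites/1000 mmol; load 1000 mg -> mmol_sites
    return TitrationMixture(
        species_loads=((sp, 1000.0),),
        initial_volume=volume_ml,
        titrant_concentration=titrant,
        increment_volume=inc_ul,
    )


class TestProtonationFraction:
    def test_midpoint_is_half(self):
        g = ProtonationSiteGroup(pKa=6.2, hill_n=3.7)
        assert protonation_fraction(g, 6.2) == pytest.approx(0.5)

    def test_henderson_hasselbalch_one_unit_above(self):
        g = ProtonationSiteGroup(pKa=8.3, hill_n=1.0)
        assert protonation_fraction(g, 7.3) == pytest.approx(1 / (1 + 0.1), rel=1e-12)

    def test_ten_ninety_width_matches_hill_inversion(self):
        # n chosen for a 0.25-unit transition: f=0.9 and f=0.1 bracket it
        n = hill_n_for_width(0.25)
        g = ProtonationSiteGroup(pKa=5.3, hill_n=n)
        ph_hi = 5.3 + math.log10(9) / n
        ph_lo = 5.3 - math.log10(9) / n
        assert protonation_fraction(g, ph_lo) == pytest.approx(0.9, rel=1e-9)
        assert protonation_fraction(g, ph_hi) == pytest.approx(0.1, rel=1e-9)
        assert ph_hi - ph_lo == pytest.approx(0.25)

    @settings(max_examples=50, derandomize=True, deadline=None)
    @given(
        pka=st.floats(3.0, 11.0),
        n=st.floats(0.1, 12.0),
        ph1=st.floats(0.5, 13.5),
        ph2=st.floats(0.5, 13.5),
    )
    def test_bounded_and_strictly_decreasing(self, pka, n, ph1, ph2):
        g = ProtonationSiteGroup(pKa=pka, hill_n=n)
        f1, f2 = protonation_fraction(g, ph1), protonation_fraction(g, ph2)
        assert 0.0 <= f1 <= 1.0
        if ph1 < ph2:
            assert f1 >= f2

    def test_nonfinite_ph_rejected(self):
        g = ProtonationSiteGroup(pKa=5.0)
        with pytest.raises(InputError):
            protonation_fraction(g, float("nan"))


class TestSolvePH:
    def test_pure_water_is_neutral(self):
        assert solve_pH(WATER, 0.0) == pytest.approx(7.0, abs=1e-6)

    def test_strong_acid_closed_form(self):
        # 0.01 mmol HCl in 20 ml -> 5e-4 M -> pH 3.30 (dilution is ~0.1%)
        assert solve_pH(WATER, 0.01) == pytest.approx(-math.log10(5e-4), abs=0.005)

    def test_half_equivalence_hits_pKa(self):
        mix = single_group_mixture(pKa=6.0, hill_n=1.0, mmol_sites=0.2)
        assert solve_pH(mix, 0.1) == pytest.approx(6.0, abs=0.01)

    def test_charge_balance_residual_below_tolerance(self, ups44_mixture):
        pka, n, mmol = ups44_mixture.site_amounts_mmol()
        for acid in (0.0, 0.05, 0.128, 0.2):
            ph = solve_pH(ups44_mixture, acid)
            vol = ups44_mixture.initial_volume + acid / 0.4
            resid = bm._charge_imbalance(ph, pka, n, mmol, vol, acid / vol)
            assert abs(resid) < 1e-12

    def test_matches_closed_form_inverse(self, cq_mixture):
        for target in (9.0, 7.0, 5.0, 4.0):
            acid = bm.acid_to_reach(cq_mixture, target)
            assert solve_pH(cq_mixture, acid) == pytest.approx(target, abs=1e-9)

    @settings(max_examples=25, derandomize=True, deadline=None)
    @given(a1=st.floats(0.0, 0.3), a2=st.floats(0.0, 0.3))
    def test_monotone_in_added_acid(self, a1, a2, ups44_mixture):
        if a1 > a2:
            a1, a2 = a2, a1
        assert solve_pH(ups44_mixture, a2) <= solve_pH(ups44_mixture, a1) + 1e-12

    def test_negative_acid_rejected(self):
        with pytest.raises(InputError):
            solve_pH(WATER, -0.1)


class TestSimulateTitration:
    def test_curve_monotone_and_nonempty(self, ups44_mixture):
        curve = simulate_titration(ups44_mixture, stop_pH=3.0)
        assert curve.added_acid[-1] > 0
        assert np.all(np.diff(curve.pH) < 0)
        assert np.all(np.diff(curve.volumes) > 0)

    def test_cq_buffers_broadly_between_6_and_9(self, cq_mixture):
        curve = simulate_titration(cq_mixture, stop_pH=3.0)
        prof = buffer_capacity(curve, "solute-only")
        broad = prof.beta[(prof.pH_grid > 6.0) & (prof.pH_grid < 9.0)]
        low = prof.beta[(prof.pH_grid > 4.0) & (prof.pH_grid < 5.0)]
        assert broad.mean() > low.max()

    def test_ups_plateau_centred_at_pKa(self, ups44_mixture):
        curve = simulate_titration(ups44_mixture, stop_pH=3.0)
        slopes = np.abs(np.diff(curve.pH) / np.diff(curve.added_acid))
        mid_ph = 0.5 * (curve.pH[1:] + curve.pH[:-1])
        assert mid_ph[np.argmin(slopes)] == pytest.approx(4.4, abs=0.05)

    def test_stop_above_start_rejected(self, ups44_mixture):
        with pytest.raises(InputError):
            simulate_titration(ups44_mixture, stop_pH=8.0)


class TestBufferCapacity:
    def test_closed_form_at_pKa_classical(self):
        # beta = ln(10) C / 4 at pH = pKa for a monoprotic weak base
        mix = single_group_mixture(5.0, 1.0, mmol_sites=0.2, inc_ul=2.0)
        prof = buffer_capacity(simulate_titration(mix, 3.5), "solute-only")
        assert prof.at(5.0) == pytest.approx(math.log(10) * 0.2 / 4, rel=0.005)

    def test_closed_form_at_pKa_cooperative(self):
        mix = single_group_mixture(5.0, 4.0, mmol_sites=0.2, inc_ul=1.0)
        prof = buffer_capacity(simulate_titration(mix, 3.5), "solute-only")
        assert prof.at(5.0) == pytest.approx(math.log(10) * 0.2 * 4.0 / 4, rel=0.005)

    def test_water_autoionization_term_total_mode(self):
        grid = np.arange(6.0, 3.0, -0.05)
        curve = bm.titration_from_pH_grid(WATER, grid)
        prof = buffer_capacity(curve, "total")
        v_at_4 = float(np.interp(-4.0, -curve.pH, curve.volumes))
        expected = math.log(10) * (1e-4 + KW / 1e-4) * v_at_4
        assert prof.at(4.0) == pytest.approx(expected, rel=0.01)

    def test_finite_difference_matches_hill_closed_form_everywhere(self):
        # oracle equivalence: beta = ln10 * C * n * f(1-f) on a fine grid
        pKa, n, c = 5.3, hill_n_for_width(0.25), 0.128
        sp = ProtonatableSpecies(
            "u", (ProtonationSiteGroup(pKa, n, site_density=c / 40.0),)
        )
        mix = TitrationMixture(species_loads=((sp, 40.0),), titrant_concentration=1e6)
        grid = np.arange(6.5, 4.0, -0.01)
        prof = buffer_capacity(bm.titration_from_pH_grid(mix, grid), "solute-only")
        inner = (prof.pH_grid > 4.2) & (prof.pH_grid < 6.3)
        f = 1 / (1 + 10 ** (n * (prof.pH_grid[inner] - pKa)))
        oracle = math.log(10) * c * n * f * (1 - f)
        sig = oracle > 1e-6  # away from the vanishing tails
        assert np.allclose(prof.beta[inner][sig], oracle[sig], rtol=0.005)

    def test_mixture_beta_is_additive(self):
        ga = ProtonationSiteGroup(5.0, 1.0, site_density=2e-3)
        gb = ProtonationSiteGroup(7.0, 3.0, site_density=1e-3)
        a = ProtonatableSpecies("a", (ga,))
        b = ProtonatableSpecies("b", (gb,))
        kw = dict(initial_volume=20.0, titrant_concentration=1e9)  # no dilution
        grid = np.arange(7.9, 3.5, -0.02)  # below each species' zero-acid pH
        prof = {
            name: buffer_capacity(
                bm.titration_from_pH_grid(
                    TitrationMixture(species_loads=loads, **kw), grid
                ),
                "solute-only",
            )
            for name, loads in {
                "mix": ((a, 40.0), (b, 40.0)),
                "a": ((a, 40.0),),
                "b": ((b, 40.0),),
            }.items()
        }
        total = prof["a"].beta + prof["b"].beta
        ok = total > 1e-9
        assert np.allclose(prof["mix"].beta[ok], total[ok], rtol=1e-6)

    def test_total_equals_solute_plus_water(self):
        mix = single_group_mixture(5.0, 1.0, 0.2, titrant=1e9)
        grid = np.arange(6.5, 3.5, -0.02)
        curve = bm.titration_from_pH_grid(mix, grid)
        tot = buffer_capacity(curve, "total")
        sol = buffer_capacity(curve, "solute-only")
        water = buffer_capacity(
            bm.titration_from_pH_grid(
                TitrationMixture(species_loads=(), titrant_concentration=1e9), grid
            ),
            "total",
        )
        assert np.allclose(tot.beta, sol.beta + water.beta, rtol=1e-6, atol=1e-12)

    def test_degenerate_and_short_inputs(self):
        curve = bm.TitrationCurve(
            added_acid=[0, 0.01, 0.02],
            pH=[7.0, 6.0, 6.0],
            volumes=[20.0, 20.0, 20.1],
            reference_mass=40.0,
        )
        with pytest.raises(DegenerateStepError):
            buffer_capacity(curve)
        short = bm.TitrationCurve([0, 0.01], [7.0, 6.0], [20, 20], 40.0)
        with pytest.raises(InputError):
            buffer_capacity(short)


class TestEstimatePKa:
    def test_recovers_single_site_base(self):
        mix = single_group_mixture(5.0, 1.0, mmol_sites=0.2)
        assert estimate_pKa(simulate_titration(mix, 3.0)) == pytest.approx(5.0, abs=0.05)

    def test_recovers_sharp_nanobuffer(self, ups44_mixture):
        curve = simulate_titration(ups44_mixture, stop_pH=3.0)
        assert estimate_pKa(curve) == pytest.approx(4.4, abs=0.05)

    def test_strong_acid_into_water_has_no_plateau(self):
        with pytest.raises(EstimationError):
            estimate_pKa(simulate_titration(WATER, stop_pH=3.0))


class TestFoldBufferRatio:
    def test_identity(self, ups44_mixture):
        prof = buffer_capacity(simulate_titration(ups44_mixture, 3.0))
        assert fold_buffer_ratio(prof, prof, 4.4, a_stat="at_pH") == pytest.approx(1.0)

    def test_mode_mismatch_rejected(self, ups44_mixture):
        curve = simulate_titration(ups44_mixture, 3.0)
        with pytest.raises(InputError):
            fold_buffer_ratio(
                buffer_capacity(curve, "total"), buffer_capacity(curve, "solute-only"), 4.4
            )

    def test_vanishing_denominator_guarded(self, ups44_mixture):
        prof = buffer_capacity(simulate_titration(ups44_mixture, 3.0))
        floor = bm.BufferCapacityProfile(
            pH_grid=prof.pH_grid, beta=np.zeros_like(prof.beta),
            mode=prof.mode, reference_mass=prof.reference_mass,
        )
        with pytest.raises(DataQualityError):
            fold_buffer_ratio(prof, floor, 4.4)
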