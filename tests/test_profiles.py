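"""Profile processing: optics, MLD criteria, inventories, screening."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from weddellbloom import (BottleCast, Profile, ProfileSimConfig, calibrate,
                          dark_correct, despike, generate_profile,
                          integrate_column, ml_poc_chl_ratio, mld_density,
                          mld_temperature, screen_high_poc_profiles)
from weddellbloom.profiles import (CalibrationError, InsufficientDepthError,
                                   ScreenResult, dark_value)


def _profile(depth, **channels):
    return Profile(depth=np.asarray(depth, float),
                   units={"chl": "mg m-3", "poc": "mg m-3"}, **channels)


class TestDarkCorrection:
    def test_zero_deep_signal_leaves_profile_unchanged(self):
        z = np.arange(0.0, 700.0, 10.0)
        chl = np.where(z < 100, 5.0, 0.0)
        p = _profile(z, chl=chl)
        out = dark_correct(p, "chl")
        assert np.array_equal(out.chl, chl)

    def test_constant_offset_is_removed(self):
        z = np.arange(0.0, 700.0, 10.0)
        chl = np.where(z < 100, 55.0, 50.0)
        out = dark_correct(_profile(z, chl=chl), "chl")
        assert np.allclose(out.chl[z >= 400], 0.0)
        assert np.allclose(out.chl[z < 100], 5.0)
        assert out.meta["dark_chl"] == 50.0

    def test_synthetic_dark_offset_recovered_exactly(self):
        for offset in (10.0, 50.0, 80.0):
            p, truth = generate_profile(ProfileSimConfig(dark_offset=offset))
            assert dark_value(p, "chl") == pytest.approx(truth.dark_offset, abs=1e-9)

    def test_shallow_profile_rejected(self):
        p = _profile(np.arange(0.0, 200.0, 10.0), chl=np.ones(20))
        with pytest.raises(InsufficientDepthError):
            dark_correct(p, "chl")


class TestDespike:
    def test_constant_profile_has_zero_spikes(self):
        p = _profile(np.arange(10.0), chl=np.full(10, 3.0))
        _, spikes = despike(p, "chl")
        assert np.allclose(spikes, 0.0)

    def test_single_interior_spike_rolling_mean_arithmetic(self):
        # spike A on constant background: residual 2A/3 at the point,
        # -A/3 at the two neighbours (window 3)
        A = 9.0
        v = np.zeros(11)
        v[5] = A
        p = _profile(np.arange(11.0), chl=v)
        _, spikes = despike(p, "chl", window=3)
        assert spikes[5] == pytest.approx(2 * A / 3)
        assert spikes[4] == pytest.approx(-A / 3)
        assert spikes[6] == pytest.approx(-A / 3)

    def test_injected_spikes_are_local_maxima_of_residual(self):
        cfg = ProfileSimConfig(spike_depths=(150.0, 320.0, 500.0),
                               spike_amplitude=80.0)
        p, truth = generate_profile(cfg)
        _, spikes = despike(p, "chl")
        top3 = set(p.depth[np.argsort(spikes)[-3:]])
        assert top3 == set(truth.spike_depths_m)

    @settings(derandomize=True, max_examples=50)
    @given(st.lists(st.floats(-1e6, 1e6), min_size=3, max_size=200))
    def test_baseline_plus_spikes_reconstructs_raw_to_the_ulp(self, values):
        # exact for instrument-scale signals (see the ensemble test);
        # adversarial magnitude mixing can cost at most one ulp
        p = _profile(np.arange(float(len(values))), chl=np.array(values))
        baseline, spikes = despike(p, "chl")
        recon = baseline + spikes
        scale = np.maximum(np.abs(p.chl), np.abs(baseline))
        assert np.all(np.abs(recon - p.chl) <= np.spacing(scale))


class TestCalibration:
    def test_identity_bottles_give_unit_fit(self):
        z = np.arange(0.0, 200.0, 10.0)
        signal = np.linspace(10, 1, z.size)
        p = _profile(z, chl=signal)
        bottles = BottleCast(depths=z[:5], chl=signal[:5])
        _, fit = calibrate(p, "chl", bottles)
        assert fit.slope == pytest.approx(1.0)
        assert fit.intercept == pytest.approx(0.0, abs=1e-12)
        assert fit.r_squared == pytest.approx(1.0)

    def test_exact_linear_bottles_recovered(self):
        z = np.arange(0.0, 200.0, 10.0)
        signal = np.linspace(10, 1, z.size)
        p = _profile(z, chl=signal)
        bottles = BottleCast(depths=z[:5], chl=2.0 * signal[:5] + 1.0)
        cal, fit = calibrate(p, "chl", bottles)
        assert (fit.slope, fit.intercept) == (pytest.approx(2.0), pytest.approx(1.0))
        assert np.allclose(cal.chl, 2.0 * signal + 1.0)
        assert cal.units["chl"] == "mg m-3"

    def test_too_few_matches_rejected(self):
        p = _profile(np.arange(0.0, 100.0, 10.0), chl=np.arange(10.0))
        bottles = BottleCast(depths=np.array([500.0, 600.0]), chl=np.array([1.0, 2.0]))
        with pytest.raises(CalibrationError):
            calibrate(p, "chl", bottles, match_tolerance=5.0)


class TestMLD:
    def test_isothermal_profile_is_undetermined(self):
        p = _profile(np.arange(0.0, 100.0), temperature=np.full(100, 1.0))
        assert not mld_temperature(p).determined

    def test_two_layer_step_recovered_within_one_grid_step(self):
        p, truth = generate_profile(ProfileSimConfig(true_mld=50.0))
        assert mld_temperature(p).depth_m == pytest.approx(50.0, abs=1.0)
        assert mld_density(p).depth_m == pytest.approx(50.0, abs=1.0)

    def test_mld_invariant_to_constant_channel_offset(self):
        p, _ = generate_profile(ProfileSimConfig(true_mld=70.0))
        shifted = _profile(p.depth, temperature=p.temperature + 5.0,
                           sigma=p.sigma + 1.0)
        assert mld_temperature(shifted).depth_m == mld_temperature(p).depth_m
        assert mld_density(shifted).depth_m == mld_density(p).depth_m

    def test_density_delta_equal_to_stratification_is_undetermined(self):
        # strict ">": a step exactly equal to delta never exceeds it
        # (binary-exact values so the tie is a true tie in floats)
        z = np.arange(0.0, 200.0)
        sigma = np.where(z > 80, 27.5 + 0.03125, 27.5)
        p = _profile(z, sigma=sigma)
        assert not mld_density(p, delta=0.03125).determined
        assert mld_density(p, delta=0.03).determined

    def test_density_profile_shallower_than_reference_rejected(self):
        p = _profile(np.arange(0.0, 8.0), sigma=np.full(8, 27.4))
        with pytest.raises(InsufficientDepthError):
            mld_density(p, ref_depth=10.0)

    def test_temperature_inversion_detected_via_absolute_difference(self):
        z = np.arange(0.0, 100.0)
        temp = np.where(z > 40, 1.5, 1.0)  # warming below the ML
        p = _profile(z, temperature=temp)
        assert mld_temperature(p).depth_m == pytest.approx(40.0, abs=1.0)


class TestInventory:
    def test_constant_rectangle(self):
        z = np.arange(0.0, 201.0)
        p = _profile(z, poc=np.full(z.size, 100.0))
        inv = integrate_column(p, "poc", 0.0, 100.0)
        assert inv.value_g_m2 == pytest.approx(10.0)

    def test_linear_ramp_trapezoid(self):
        z = np.arange(0.0, 201.0)
        p = _profile(z, poc=2.0 * z)  # 0 -> 200 mg m-3 over 0-100 m
        assert integrate_column(p, "poc", 0.0, 100.0).value_g_m2 == pytest.approx(10.0)

    def test_additive_over_adjacent_ranges(self):
        p, _ = generate_profile(ProfileSimConfig())
        a = integrate_column(p, "poc", 0.0, 42.5).value_g_m2
        b = integrate_column(p, "poc", 42.5, 100.0).value_g_m2
        total = integrate_column(p, "poc", 0.0, 100.0).value_g_m2
        assert a + b == pytest.approx(total, rel=1e-12)

    def test_boundary_interpolated_when_sampling_is_coarse(self):
        z = np.array([0.0, 40.0, 80.0, 120.0])
        p = _profile(z, poc=np.array([100.0, 100.0, 100.0, 100.0]))
        assert integrate_column(p, "poc", 0.0, 100.0).value_g_m2 == pytest.approx(10.0)

    def test_no_samples_in_range_rejected(self):
        p = _profile(np.array([500.0, 600.0]), poc=np.array([1.0, 1.0]))
        with pytest.raises(InsufficientDepthError):
            integrate_column(p, "poc", 0.0, 100.0)


class TestRatioAndScreen:
    def test_proportional_channels_give_the_proportionality_constant(self):
        p, _ = generate_profile(ProfileSimConfig())
        p2 = _profile(p.depth, chl=p.poc / 200.0, poc=p.poc)
        mld = mld_density(_profile(p.depth, sigma=p.sigma))
        p2.sigma = p.sigma
        assert ml_poc_chl_ratio(p2, mld) == pytest.approx(200.0)

    def test_hand_division_constant_channels(self):
        z = np.arange(0.0, 100.0)
        p = _profile(z, chl=np.full(z.size, 1.5), poc=np.full(z.size, 300.0),
                     sigma=np.where(z > 30, 27.5, 27.4))
        mld = mld_density(p)
        assert ml_poc_chl_ratio(p, mld) == pytest.approx(200.0)

    def test_screen_hand_count(self):
        # 10 profiles: 4 above 15 g C m-2, one of those with ~95% of its
        # POC below the ML -> 3 selected, 30%
        z = np.arange(0.0, 200.0)
        profiles = []
        for k in range(10):
            if k < 4:
                if k == 0:  # deep POC slab under a 10 m ML
                    poc = np.where((z > 50) & (z <= 150), 400.0, 5.0)
                    sigma = np.where(z > 10, 27.6, 27.4)
                else:
                    poc = np.where(z <= 100, 300.0, 0.0)
                    sigma = np.where(z > 60, 27.6, 27.4)
            else:
                poc = np.full(z.size, 10.0)
                sigma = np.where(z > 60, 27.6, 27.4)
            profiles.append(_profile(z, poc=poc, sigma=sigma))
        res = screen_high_poc_profiles(profiles)
        assert (res.n_selected, res.n_total) == (3, 10)
        assert res.percentage == 30.0
        assert 0 not in res.selected_ids

    def test_all_below_threshold_gives_empty_selection(self):
        z = np.arange(0.0, 200.0)
        profiles = [_profile(z, poc=np.full(z.size, 10.0),
                             sigma=np.where(z > 60, 27.6, 27.4))
                    for _ in range(5)]
        res = screen_high_poc_profiles(profiles)
        assert res.n_selected == 0 and res.percentage == 0.0

    def test_archive_scale_percentage_reporting(self):
        assert ScreenResult.from_counts(34, 9500).percentage == 0.36
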