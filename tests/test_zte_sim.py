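"""³¹P spectroscopy and ZTE imaging physics."""

import dataclasses

import numpy as np
import pytest

from apatitemap.phantoms import RatHeadSpec, make_rat_head_phantom
from apatitemap.volume import resample_to
from apatitemap.zte_sim import (
    RAYLEIGH_SD_FACTOR,
    ZTEParams,
    acquisition_time_s,
    calibrate_noise_sd,
    default_noise_roi,
    ernst_angle_deg,
    excitation_amplitude,
    excited_extent_mm,
    fibonacci_sphere_directions,
    fit_t1_saturation,
    liquid_fraction,
    lorentzian_fwhm,
    simulate_spectrum,
    simulate_zte,
    steady_state_signal,
)


class TestClosedForms:
    def test_ernst_angle_of_bone_is_about_2_degrees(self):
        assert ernst_angle_deg(0.015, 20.0) == pytest.approx(2.22, abs=0.01)
        assert round(ernst_angle_deg(0.015, 20.0)) == 2

    def test_ernst_angle_limits_and_oracle(self):
        assert ernst_angle_deg(100.0, 1e-6) == pytest.approx(90.0)
        assert ernst_angle_deg(0.015, 2.0) == pytest.approx(7.01, abs=0.01)
        with pytest.raises(ValueError):
            ernst_angle_deg(-1.0, 20.0)

    def test_steady_state_zero_flip_gives_zero(self):
        assert steady_state_signal(0.0, 0.015, 20.0) == 0.0

    def test_steady_state_maximized_at_ernst_angle(self):
        """Numeric grid search over flip angle peaks at the Ernst angle."""
        flips = np.linspace(0.1, 30.0, 2000)
        signals = [steady_state_signal(f, 0.015, 20.0) for f in flips]
        best = flips[int(np.argmax(signals))]
        assert best == pytest.approx(ernst_angle_deg(0.015, 20.0), abs=0.05)

    def test_short_t1_species_enhanced_at_bone_ernst_angle(self):
        theta = ernst_angle_deg(0.015, 20.0)
        ratio = steady_state_signal(theta, 0.015, 2.0) / steady_state_signal(
            theta, 0.015, 20.0
        )
        assert ratio == pytest.approx(1.8, abs=0.1)

    def test_lorentzian_fwhm_of_bone_line(self):
        hz, ppm = lorentzian_fwhm(85e-6, 202.4)
        assert hz == pytest.approx(3744.8, abs=0.5)
        assert ppm == pytest.approx(18.5, abs=0.05)

    def test_lorentzian_fwhm_scaling(self):
        hz1, ppm1 = lorentzian_fwhm(1.0 / np.pi, 100.0)
        assert hz1 == pytest.approx(1.0)
        hz2, ppm2 = lorentzian_fwhm(2.0 / np.pi, 100.0)
        assert hz2 == pytest.approx(hz1 / 2)
        assert ppm2 == pytest.approx(ppm1 / 2)

    def test_hard_pulse_profile(self):
        assert excitation_amplitude(0.0, 15e-6) == pytest.approx(1.0)
        # first zero at 1/tau, so the central lobe spans 2/tau ~ 130 kHz
        assert excitation_amplitude(1 / 15e-6, 15e-6) == pytest.approx(0.0, abs=1e-12)
        assert 2 / 15e-6 == pytest.approx(133.3e3, rel=1e-3)
        assert abs(2 / 15e-6 - 130e3) < 5e3

    def test_excited_extent(self):
        assert excited_extent_mm(45e3, 250e3, 89.6) == pytest.approx(16.1, abs=0.05)
        assert excited_extent_mm(250e3, 250e3, 89.6) == pytest.approx(89.6)
        assert excited_extent_mm(125e3, 250e3, 89.6) == pytest.approx(44.8)
        with pytest.raises(ValueError):
            excited_extent_mm(300e3, 250e3, 89.6)

    def test_acquisition_times_match_protocol(self):
        assert acquisition_time_s(0.015, 13030, 96) == pytest.approx(18763.2)
        assert acquisition_time_s(0.015, 13030, 16) == pytest.approx(3127.2)
        assert acquisition_time_s(1, 1, 1) == 1.0

    def test_nominal_voxel_size(self):
        assert ZTEParams().nominal_voxel_mm == pytest.approx(1.4)


class TestSpectrum:
    def test_liquid_fraction_of_default_head(self, head_phantom, zte_default):
        spectrum = simulate_spectrum(head_phantom, zte_default)
        assert liquid_fraction(spectrum) == pytest.approx(0.07, abs=0.02)

    def test_no_mobile_pool_no_sharp_peaks(self, head_phantom, zte_default):
        ph = make_rat_head_phantom()
        ph.mobile_p31_molar.values[:] = 0.0
        assert liquid_fraction(simulate_spectrum(ph, zte_default)) == pytest.approx(
            0.0, abs=0.01
        )

    def test_only_sharp_lines_fraction_near_one(self, zte_default):
        ph = make_rat_head_phantom()
        ph.apatite_p31_molar.values[:] = 0.0
        assert liquid_fraction(simulate_spectrum(ph, zte_default)) > 0.9

    def test_area_equals_saturation_weighted_moles(self, head_phantom, zte_default):
        spectrum = simulate_spectrum(head_phantom, zte_default)
        p = zte_default
        analytic = head_phantom.total_apatite_mol() * p.saturation(
            p.t1_bone_s
        ) + head_phantom.total_mobile_mol() * p.saturation(p.t1_liquid_s)
        assert spectrum.integral() == pytest.approx(analytic, rel=0.01)

    def test_area_invariant_to_linewidths(self, head_phantom, zte_default):
        a = simulate_spectrum(head_phantom, zte_default).integral()
        wide = dataclasses.replace(
            zte_default, t2star_bone_s=2 * 85e-6, t2star_liquid_s=0.02
        )
        b = simulate_spectrum(head_phantom, wide).integral()
        assert b == pytest.approx(a, rel=0.01)

    def test_empty_phantom_gives_zero_spectrum(self, zte_default):
        ph = make_rat_head_phantom()
        ph.apatite_p31_molar.values[:] = 0.0
        ph.mobile_p31_molar.values[:] = 0.0
        spectrum = simulate_spectrum(ph, zte_default)
        assert spectrum.integral() == 0.0
        with pytest.raises(ValueError):
            liquid_fraction(spectrum)


class TestT1Fit:
    @pytest.mark.parametrize("t1_true", [20.0, 2.0])
    def test_recovers_generating_t1_noiseless(self, t1_true):
        trs = [0.005, 0.015, 0.05, 0.2, 1.0]
        flip = 2.2
        pts = [(tr, 3.7 * steady_state_signal(flip, tr, t1_true)) for tr in trs]
        t1, _ = fit_t1_saturation(pts, flip)
        assert t1 == pytest.approx(t1_true, rel=0.01)

    def test_too_few_or_degenerate_points_rejected(self):
        with pytest.raises(ValueError):
            fit_t1_saturation([(0.01, 1.0), (0.02, 1.5)], 2.0)
        with pytest.raises(ValueError):
            fit_t1_saturation([(0.01, 1.0)] * 5, 2.0)


class TestImaging:
    def test_uniform_bone_block_images_flat(self, uniform_bone_block):
        params = ZTEParams(noise_sd=0.0, excitation_profile=False)
        img = simulate_zte(uniform_bone_block, params)
        # interior of the block on the ZTE grid, away from edges
        block = resample_to(
            uniform_bone_block.labels.like(
                (uniform_bone_block.labels.values > 0).astype(float)
            ),
            img,
        ).values
        interior = block > 0.999
        from scipy import ndimage

        interior = ndimage.binary_erosion(interior, iterations=3)
        vals = img.values[interior]
        assert vals.max() <= vals.min() * 1.02

    def test_signal_linear_in_apatite_concentration(self, uniform_bone_block):
        params = ZTEParams(noise_sd=0.0)
        img1 = simulate_zte(uniform_bone_block, params)
        doubled = dataclasses.replace(uniform_bone_block)
        doubled.apatite_p31_molar = uniform_bone_block.apatite_p31_molar.like(
            2.0 * uniform_bone_block.apatite_p31_molar.values
        )
        img2 = simulate_zte(doubled, params)
        mask = resample_to(
            uniform_bone_block.labels.like(
                (uniform_bone_block.labels.values > 0).astype(float)
            ),
            img1,
        ).values >= 0.5
        ratio = img2.values[mask].mean() / img1.values[mask].mean()
        assert ratio == pytest.approx(2.0, rel=0.01)

    def test_skull_detected_soft_tissue_not(self, head_phantom, invivo_params):
        """Bone specificity: skull SNR ≥ 5, soft tissue away from bone < 1."""
        quiet = dataclasses.replace(invivo_params, noise_sd=0.0)
        img = simulate_zte(head_phantom, quiet)
        sigma = invivo_params.noise_sd / np.sqrt(invivo_params.n_averages)
        noise_floor = RAYLEIGH_SD_FACTOR * sigma
        snr = img.values / noise_floor

        bone = resample_to(
            head_phantom.labels.like(head_phantom.mask("cortical_bone").astype(float)),
            img,
        ).values >= 0.5
        assert snr[bone].mean() >= 5.0

        from scipy import ndimage

        soft = (
            head_phantom.mask("soft_tissue")
            | head_phantom.mask("muscle")
            | head_phantom.mask("brain")
        )
        # measure beyond one PSF of bone: blur bleed-through is resolution,
        # not tissue signal
        near_bone = ndimage.binary_dilation(
            head_phantom.mask("cortical_bone"), iterations=4
        )
        soft_far = resample_to(
            head_phantom.labels.like((soft & ~near_bone).astype(float)), img
        ).values >= 0.5
        assert snr[soft_far].mean() < 1.0

    def test_snr_scales_with_sqrt_averages(self, head_phantom, invivo_params):
        """SNR ratio between 96- and 16-average runs is √6 within 10%."""
        from apatitemap.calibration import snr_map

        bone = None
        ratios = []
        for seed in range(20):
            snrs = []
            for n_avg in (96, 16):
                params = dataclasses.replace(invivo_params, n_averages=n_avg)
                img = simulate_zte(head_phantom, params, seed=seed)
                s = snr_map(img, default_noise_roi(img))
                if bone is None:
                    bone = resample_to(
                        head_phantom.labels.like(
                            head_phantom.mask("cortical_bone").astype(float)
                        ),
                        img,
                    ).values >= 0.5
                snrs.append(s.values[bone].mean())
            ratios.append(snrs[0] / snrs[1])
        assert np.mean(ratios) == pytest.approx(np.sqrt(6.0), rel=0.10)

    def test_translation_equivariance_without_profiles(self, uniform_bone_block):
        params = ZTEParams(noise_sd=0.0, excitation_profile=False)
        img = simulate_zte(uniform_bone_block, params)
        shifted = dataclasses.replace(uniform_bone_block)
        for name in ("labels", "apatite_p31_molar", "mobile_p31_molar",
                     "activity", "mu_true"):
            vol = getattr(uniform_bone_block, name)
            setattr(shifted, name, vol.like(np.roll(vol.values, 2, axis=0)))
        img_shifted = simulate_zte(shifted, params)
        # 2 phantom voxels = 2.8 mm = 2 ZTE voxels
        expected = np.roll(img.values, 2, axis=0)
        err = np.abs(img_shifted.values - expected).max()
        assert err < 0.02 * img.values.max()

    def test_profile_weights_bounded(self, head_phantom):
        from apatitemap.zte_sim import _profile_weights

        params = ZTEParams(
            coil_profile={"axis": 1, "position_mm": 15.0, "decay_mm": 7.5}
        )
        w = _profile_weights(head_phantom.labels, params)
        assert np.all(w > 0) and np.all(w <= 1.0)

    def test_fov_must_cover_phantom(self, head_phantom):
        with pytest.raises(ValueError, match="FOV"):
            simulate_zte(head_phantom, ZTEParams(fov_mm=20.0))

    def test_fidelities_agree_on_small_phantom(self):
        """k-space and image-domain forward models match within 10% NRMS
        (normalized to the peak in-object signal), noiseless."""
        spec = RatHeadSpec(grid_shape=(32, 32, 32), spacing_mm=1.4)
        ph = make_rat_head_phantom(spec)
        base = ZTEParams(
            readout_points=32, fov_mm=44.8, n_half_projections=6000, noise_sd=0.0
        )
        a = simulate_zte(ph, dataclasses.replace(base, fidelity="image_domain"))
        b = simulate_zte(ph, dataclasses.replace(base, fidelity="kspace"))
        obj = ph.labels.values > 0
        diff = (b.values - a.values)[obj]
        nrms = np.sqrt((diff**2).mean()) / a.values[obj].max()
        assert nrms < 0.10

    def test_fibonacci_directions_unit_and_spread(self):
        d = fibonacci_sphere_directions(500)
        assert np.allclose(np.linalg.norm(d, axis=1), 1.0)
        assert np.abs(d.mean(axis=0)).max() < 0.05  # quasi-uniform coverage

    def test_noise_calibration_hits_target_snr(self, head_phantom, invivo_params):
        from apatitemap.calibration import snr_map

        img = simulate_zte(head_phantom, invivo_params, seed=11)
        s = snr_map(img, default_noise_roi(img))
        bone = resample_to(
            head_phantom.labels.like(head_phantom.mask("cortical_bone").astype(float)),
            img,
        ).values >= 0.5
        assert s.values[bone].mean() == pytest.approx(10.0, rel=0.1)

    def test_run_records_seed_and_time(self, head_phantom, invivo_params):
        img = simulate_zte(head_phantom, invivo_params, seed=3)
        assert img.meta["seed"] == 3
        assert img.meta["acquisition_time_s"] == pytest.approx(3127.2)
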