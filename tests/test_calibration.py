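"""SNR maps, √time normalization, registration and μ-map builders."""

import dataclasses

import numpy as np
import pytest

from apatitemap.calibration import (
    CalibrationResult,
    RigidTransform,
    SNRVolume,
    estimate_conversion_factor,
    nobone_mu_map,
    p31_ac_mu_map,
    p31_mu_map,
    normalize_snr_to_reference,
    rigid_register,
    snr_map,
)
from apatitemap.volume import Volume, centered_grid


def _image(values, t_acq=18763.2):
    vol = centered_grid(values.shape, (1.0, 1.0, 1.0), semantics="p31_signal")
    vol.values = values.astype(float)
    vol.meta["acquisition_time_s"] = t_acq
    return vol


class TestSNRMap:
    def test_constant_object_over_known_noise(self):
        vals = np.full((16, 16, 16), 60.0)
        noise = np.tile([0.0, 4.0], 300)  # nonnegative, sd exactly 2
        roi = np.zeros(vals.shape, dtype=bool)
        roi.ravel()[:600] = True
        vals.ravel()[:600] = noise
        s = snr_map(_image(vals), roi)
        assert s.values[~roi].mean() == pytest.approx(30.0, rel=1e-12)
        assert s.noise_sd == pytest.approx(2.0)

    def test_pure_noise_magnitude_has_rician_floor(self):
        """Background of a magnitude image has mean SNR ≈ 1.91 (Rayleigh)."""
        means = []
        for seed in range(10):
            rng = np.random.default_rng(seed)
            mag = np.abs(
                rng.normal(size=(24, 24, 24)) + 1j * rng.normal(size=(24, 24, 24))
            )
            roi = np.zeros(mag.shape, dtype=bool)
            roi[:6] = True
            s = snr_map(_image(mag), roi)
            means.append(s.values[~roi].mean())
        assert np.mean(means) == pytest.approx(np.sqrt(np.pi / (4 - np.pi)), rel=0.05)

    def test_degenerate_rois_rejected(self):
        vals = np.ones((8, 8, 8))
        small = np.zeros(vals.shape, dtype=bool)
        small[0, 0, :5] = True
        with pytest.raises(ValueError, match="too small"):
            snr_map(_image(vals), small)
        roi = np.zeros(vals.shape, dtype=bool)
        roi[:4] = True
        with pytest.raises(ValueError, match="zero standard deviation"):
            snr_map(_image(vals), roi)
        with pytest.raises(ValueError, match="overlaps"):
            rng = np.random.default_rng(1)
            snr_map(_image(rng.random(vals.shape)), roi, object_mask=roi)


class TestTimeNormalization:
    def _snr(self, value, t_acq):
        vol = _image(np.full((8, 8, 8), float(value)), t_acq)
        return SNRVolume(vol.like(vol.values, semantics="snr"), 1.0, 100, t_acq)

    def test_reference_time_is_fixed_point(self):
        s = self._snr(10.0, 18763.2)
        out = normalize_snr_to_reference(s, 18763.2)
        assert np.allclose(out.values, 10.0)

    def test_sqrt6_upscaling_from_16_to_96_averages(self):
        s = self._snr(10.0, 3127.2)
        out = normalize_snr_to_reference(s, 18763.2)
        assert out.values.flat[0] == pytest.approx(24.49, abs=0.01)
        assert out.acquisition_time_s == 18763.2

    def test_idempotent(self):
        s = self._snr(10.0, 3127.2)
        once = normalize_snr_to_reference(s, 18763.2)
        twice = normalize_snr_to_reference(once, 18763.2)
        assert np.allclose(once.values, twice.values)


class TestConversionFactor:
    def _uniform(self, mu_val, snr_val, n=6):
        grid = centered_grid((n, n, n), (1, 1, 1))
        mu = grid.like(np.full(grid.shape, mu_val), semantics="mu_cm^-1")
        snr = SNRVolume(
            grid.like(np.full(grid.shape, snr_val), semantics="snr"),
            1.0, 100, 18763.2,
        )
        mask = np.ones(grid.shape, dtype=bool)
        return mu, snr, mask

    def test_uniform_ratio(self):
        mu, snr, mask = self._uniform(0.126, 30.0)
        res = estimate_conversion_factor(mu, snr, mask)
        assert res.k == pytest.approx(0.0042)
        assert res.k_sd == pytest.approx(0.0, abs=1e-12)
        assert res.t_ref_s == 18763.2

    def test_zero_mu_rejected(self):
        mu, snr, mask = self._uniform(0.0, 30.0)
        with pytest.raises(ValueError, match="positive"):
            estimate_conversion_factor(mu, snr, mask)

    def test_floor_excludes_low_snr(self):
        mu, snr, mask = self._uniform(0.126, 30.0)
        snr.vol.values[:3] = 1.0  # below floor; their ratios would be huge
        res = estimate_conversion_factor(mu, snr, mask, snr_floor=3.0)
        assert res.k == pytest.approx(0.0042)

    def test_slope_estimator_agrees_on_proportional_data(self):
        grid = centered_grid((6, 6, 6), (1, 1, 1))
        rng = np.random.default_rng(3)
        snr_vals = rng.uniform(10, 40, grid.shape)
        mu = grid.like(0.0042 * snr_vals, semantics="mu_cm^-1")
        snr = SNRVolume(grid.like(snr_vals, semantics="snr"), 1.0, 100, 18763.2)
        mask = np.ones(grid.shape, dtype=bool)
        a = estimate_conversion_factor(mu, snr, mask, method="ratio_mean")
        b = estimate_conversion_factor(mu, snr, mask, method="slope")
        assert a.k == pytest.approx(b.k, rel=1e-9) == pytest.approx(0.0042)


class TestMuMaps:
    def _snr_head(self, values):
        vol = _image(values, t_acq=18763.2)
        return SNRVolume(vol.like(values, semantics="snr"), 1.0, 100, 18763.2)

    def _calib(self):
        return CalibrationResult(k=0.0042, k_sd=4e-4, n_voxels=100, t_ref_s=18763.2)

    def test_floor_zeroes_and_conversion(self):
        values = np.zeros((8, 8, 8))
        values[0, 0, 0] = 30.0
        values[0, 0, 1] = 4.0  # below floor
        mu = p31_mu_map(self._snr_head(values), self._calib(), snr_floor=5.0)
        assert mu.values[0, 0, 0] == pytest.approx(0.126)
        assert mu.values[0, 0, 1] == 0.0

    def test_monotone_in_snr(self):
        rng = np.random.default_rng(0)
        a = rng.uniform(0, 40, (8, 8, 8))
        b = a + rng.uniform(0, 5, a.shape)
        mu_a = p31_mu_map(self._snr_head(a), self._calib())
        mu_b = p31_mu_map(self._snr_head(b), self._calib())
        # voxels above the floor in both maps can only grow
        both = (a >= 5.0) & (b >= 5.0)
        assert np.all(mu_b.values[both] >= mu_a.values[both])

    def test_acquired_domain_floor_with_normalization(self):
        vol = _image(np.full((8, 8, 8), 10.0), t_acq=3127.2)
        snr = SNRVolume(vol.like(vol.values, semantics="snr"), 1.0, 100, 3127.2)
        mu = p31_mu_map(snr, self._calib(), snr_floor=5.0)
        # floored at acquired SNR 10 >= 5, then scaled by sqrt(6)
        assert mu.values.flat[0] == pytest.approx(0.0042 * 10 * np.sqrt(6), rel=1e-6)
        with pytest.raises(ValueError, match="acquisition time"):
            p31_mu_map(snr, self._calib(), auto_normalize=False)

    def test_clip_ceiling(self):
        values = np.full((8, 8, 8), 500.0)
        mu = p31_mu_map(self._snr_head(values), self._calib())
        assert np.all(mu.values == 0.25)

    def test_nobone_two_values_from_labels(self, head_phantom):
        mu = nobone_mu_map(head_phantom.labels)
        assert set(np.unique(mu.values)) == {0.0, 0.096}
        head = head_phantom.labels.values > 0
        assert np.all(mu.values[head] == 0.096)
        assert np.all(mu.values[~head] == 0.0)

    def test_nobone_empty_head_rejected(self):
        grid = centered_grid((8, 8, 8), (1, 1, 1), semantics="labels")
        with pytest.raises(ValueError, match="empty head mask"):
            nobone_mu_map(grid)

    def test_p31_ac_addition(self, head_phantom):
        nobone = nobone_mu_map(head_phantom.labels)
        mu31 = nobone.like(np.zeros(nobone.shape), semantics="mu_cm^-1")
        out = p31_ac_mu_map(nobone, mu31)
        assert np.array_equal(out.values, nobone.values)

        mu31.values[head_phantom.mask("cortical_bone")] = 0.126
        out = p31_ac_mu_map(nobone, mu31)
        skull = head_phantom.mask("cortical_bone")
        assert np.allclose(out.values[skull], 0.222)
        assert np.all(out.values >= nobone.values)
        assert out.values.max() <= 0.3

    def test_p31_ac_grid_mismatch(self, head_phantom):
        nobone = nobone_mu_map(head_phantom.labels)
        other = centered_grid((8, 8, 8), (1, 1, 1), semantics="mu_cm^-1")
        with pytest.raises(ValueError, match="grid mismatch"):
            p31_ac_mu_map(nobone, other)


class TestRigidRegistration:
    @pytest.fixture()
    def blob(self):
        # two unequal blobs: asymmetric enough that the rigid fit is
        # well conditioned in all six parameters
        grid = centered_grid((24, 24, 24), (1.0, 1.0, 1.0))
        x, y, z = grid.voxel_centers_mm()
        grid.values = np.exp(
            -((x - 2) ** 2 + y**2 + (z + 1) ** 2) / 18.0
        ) + 0.6 * np.exp(-((x + 4) ** 2 + (y - 3) ** 2 + z**2) / 8.0)
        return grid

    def test_identity_resample_is_exact_on_shared_grid(self, blob):
        out, t = rigid_register(blob, blob, RigidTransform())
        assert np.allclose(out.values, blob.values, atol=1e-9)

    def test_inverse_composition(self):
        t = RigidTransform((4.0, -3.0, 10.0), (1.0, -2.0, 0.5))
        pts = np.random.default_rng(0).uniform(-10, 10, (50, 3))
        center = np.zeros(3)
        back = t.inverse_apply(t.apply(pts, center), center)
        assert np.allclose(back, pts, atol=1e-9)

    def test_known_translation_recovered(self, blob):
        true = RigidTransform(translation_mm=(2.0, -2.0, 0.0))
        moved, _ = rigid_register(blob, blob, true)
        _, est = rigid_register(moved, blob, "estimate")
        # moved = blob shifted by +t; registering it back should find -t
        assert np.allclose(est.translation_mm, (-2.0, 2.0, 0.0), atol=0.5)

    def test_self_registration_is_near_identity(self, blob):
        _, est = rigid_register(blob, blob, "estimate")
        assert np.linalg.norm(est.translation_mm) < 0.25
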