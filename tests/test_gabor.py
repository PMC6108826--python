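"""Visual RF metrics: Gabor fits, collapse, separability, TDI."""

import numpy as np
import pytest

from predrf import gabor


@pytest.fixture(scope="module")
def grating_xt():
    x = np.arange(20)[:, None]
    t = np.arange(7)[None, :]
    return np.cos(2 * np.pi * (0.2 * x - 0.14 * t))


class TestOptimalTimestep:
    def test_power_in_one_bin(self, rng):
        rf = np.zeros((6, 6, 7))
        rf[:, :, 6] = rng.standard_normal((6, 6))
        assert gabor.optimal_timestep(rf) == 6

    def test_uniform_power_tie_goes_recent(self):
        rf = np.ones((6, 6, 7))
        assert gabor.optimal_timestep(rf) == 6

    def test_sign_invariant(self, rng):
        rf = rng.standard_normal((6, 6, 7))
        assert gabor.optimal_timestep(rf) == gabor.optimal_timestep(-rf)

    def test_zero_rejected(self):
        with pytest.raises(ValueError):
            gabor.optimal_timestep(np.zeros((6, 6, 7)))


class TestFitGabor:
    def test_noise_free_recovery(self):
        truth = dict(A=1.0, x0=10.0, y0=9.0, sigma_x=2.0, sigma_y=4.0,
                     theta=np.radians(30), f=0.15, phi=0.7)
        img = gabor.gabor_image((20, 20), **truth)
        fit = gabor.fit_gabor(img)
        dtheta = abs((fit.theta - truth["theta"] + np.pi / 2) % np.pi - np.pi / 2)
        assert np.degrees(dtheta) < 2
        assert abs(fit.f - truth["f"]) / truth["f"] < 0.02
        assert fit.fit_corr > 0.99

    def test_recovery_under_noise(self, rng):
        img = gabor.gabor_image((20, 20), 1.0, 10, 9, 2, 4, np.radians(30), 0.15, 0.7)
        noisy = img + 0.1 * rng.standard_normal(img.shape)
        fit = gabor.fit_gabor(noisy)
        assert fit.fit_corr > 0.9

    def test_pure_gaussian_blob_no_crash(self):
        img = gabor.gabor_image((20, 20), 1.0, 10, 10, 3, 3, 0.0, 0.001, 0.0)
        fit = gabor.fit_gabor(img)
        assert np.isfinite([fit.A, fit.x0, fit.sigma_x, fit.f]).all()
        assert fit.f < 0.05

    def test_population_recovery_rate(self, rng):
        """>= 95% of 50 random in-grid Gabors recover theta within 5 deg
        and f within 5% with correlation > 0.95."""
        good = 0
        for _ in range(50):
            theta = rng.uniform(0, np.pi)
            f = rng.uniform(0.08, 0.3)
            truth = dict(
                A=1.0, x0=rng.uniform(6, 13), y0=rng.uniform(6, 13),
                sigma_x=rng.uniform(1.2, 4), sigma_y=rng.uniform(1.2, 5),
                theta=theta, f=f, phi=rng.uniform(0, 2 * np.pi),
            )
            fit = gabor.fit_gabor(gabor.gabor_image((20, 20), **truth))
            dtheta = abs((fit.theta - theta + np.pi / 2) % np.pi - np.pi / 2)
            good += (
                np.degrees(dtheta) < 5
                and abs(fit.f - f) / f < 0.05
                and fit.fit_corr > 0.95
            )
        assert good >= 48  # 95% of 50, rounded up


class TestExclusions:
    def _fit(self, **kw):
        base = dict(A=1, x0=10, y0=10, sigma_x=2, sigma_y=2, theta=0.0,
                    f=0.2, phi=0.0, fit_corr=0.95, status="kept")
        base.update(kw)
        return gabor.GaborFit(**base)

    def test_low_correlation_rejected(self):
        assert gabor.apply_exclusions(self._fit(fit_corr=0.65)).status == "rejected_lowcorr"

    def test_center_outside_grid_rejected(self):
        assert gabor.apply_exclusions(self._fit(x0=25.0)).status == "rejected_center"
        assert gabor.apply_exclusions(self._fit(y0=-2.0)).status == "rejected_center"

    def test_narrow_envelope_rejected(self):
        assert gabor.apply_exclusions(self._fit(sigma_x=0.4)).status == "rejected_sigma"

    def test_good_fit_kept(self):
        assert gabor.apply_exclusions(self._fit()).status == "kept"


class TestCollapse:
    def test_vertical_grating_equals_column_sums(self):
        img = gabor.gabor_image((20, 20), 1.0, 9.5, 9.5, 3, 4, 0.0, 0.2, 0.3)
        rf3 = np.repeat(img[:, :, None], 7, axis=2)
        fit = gabor.apply_exclusions(gabor.fit_gabor(img))
        col = gabor.collapse_to_xt(rf3, fit)
        direct = img.sum(axis=0)
        peak = np.max(np.abs(direct))
        # x' direction is defined modulo pi: accept either axis orientation
        dev = min(
            np.max(np.abs(col[:, 0] - direct)),
            np.max(np.abs(col[::-1, 0] - direct)),
        )
        assert dev < 0.05 * peak

    def test_total_activity_preserved(self):
        blob = gabor.gabor_image((20, 20), 1.0, 10, 9, 3, 4, 0.6, 0.08, 0.1) ** 2
        rf3 = np.stack([(t + 1.0) * blob for t in range(7)], axis=2)
        fit = gabor.apply_exclusions(gabor.fit_gabor(rf3[:, :, 6]))
        col = gabor.collapse_to_xt(rf3, fit)
        for t in range(7):
            assert abs(col[:, t].sum() / rf3[:, :, t].sum() - 1.0) < 0.02

    def test_static_rf_has_identical_columns(self):
        img = gabor.gabor_image((20, 20), 1.0, 10, 10, 2.5, 3.5, 0.9, 0.18, 0.0)
        rf3 = np.repeat(img[:, :, None], 7, axis=2)
        fit = gabor.apply_exclusions(gabor.fit_gabor(img))
        col = gabor.collapse_to_xt(rf3, fit)
        assert np.allclose(col, col[:, [0]])

    def test_rejected_fit_refused(self):
        fit = gabor.GaborFit(1, 10, 10, 2, 2, 0, 0.2, 0, fit_corr=0.5,
                             status="rejected_lowcorr")
        with pytest.raises(ValueError):
            gabor.collapse_to_xt(np.ones((20, 20, 7)), fit)


class TestSeparability:
    def test_outer_product_separable(self, rng):
        rf = np.einsum("ij,t->ijt", rng.standard_normal((20, 20)), rng.standard_normal(7))
        ratio, label = gabor.separability(rf)
        assert ratio < 1e-10
        assert label == "separable"

    def test_two_orthogonal_components_inseparable(self):
        s1 = np.zeros(400)
        s1[10] = 1.0
        s2 = np.zeros(400)
        s2[20] = 1.0
        t1 = np.array([1.0, 0, 0, 0, 0, 0, 0])
        t2 = np.array([0, 1.0, 0, 0, 0, 0, 0])
        mat = np.outer(s1, t1) + np.outer(s2, t2)
        ratio, label = gabor.separability(mat.reshape(20, 20, 7))
        assert np.isclose(ratio, 1.0)
        assert label == "inseparable"

    def test_threshold_is_inclusive(self):
        s1 = np.zeros(400)
        s1[0] = 1.0
        s2 = np.zeros(400)
        s2[1] = 0.5
        mat = np.outer(s1, [1, 0, 0, 0, 0, 0, 0.0]) + np.outer(s2, [0, 1, 0, 0, 0, 0, 0.0])
        ratio, label = gabor.separability(mat.reshape(20, 20, 7))
        assert np.isclose(ratio, 0.5)
        assert label == "inseparable"

    def test_invariant_to_sign_and_scale(self, rng):
        rf = rng.standard_normal((20, 20, 7))
        r1, l1 = gabor.separability(rf)
        r2, l2 = gabor.separability(-3.2 * rf)
        assert np.isclose(r1, r2) and l1 == l2


class TestShapeIndices:
    def test_direct_products(self):
        fit = gabor.GaborFit(1, 10, 10, 1.0, 2.0, 0, 0.25, 0, fit_corr=0.9)
        idx = gabor.shape_indices(fit)
        assert idx.nx == 0.25 and idx.ny == 0.5

    def test_scale_invariance_of_indices(self):
        """Upscaling an RF 2x (sigma doubles, f halves) leaves nx, ny fixed."""
        small = gabor.gabor_image((20, 20), 1.0, 9.5, 9.5, 2.0, 3.0, 0.5, 0.24, 0.3)
        big = gabor.gabor_image((20, 20), 1.0, 9.5, 9.5, 4.0, 6.0, 0.5, 0.12, 0.3)
        fs = gabor.fit_gabor(small)
        fb = gabor.fit_gabor(big)
        ns = gabor.shape_indices(fs)
        nb = gabor.shape_indices(fb)
        assert abs(ns.nx - nb.nx) < 0.1 * ns.nx
        assert abs(ns.ny - nb.ny) < 0.1 * ns.ny

    def test_zero_frequency_zero_indices(self):
        fit = gabor.GaborFit(1, 10, 10, 2.0, 3.0, 0, 0.0, 0, fit_corr=0.9)
        idx = gabor.shape_indices(fit)
        assert idx.nx == 0.0 and idx.ny == 0.0

    def test_rejected_fit_refused(self):
        fit = gabor.GaborFit(1, 10, 10, 2, 2, 0, 0.2, 0, fit_corr=0.5,
                             status="rejected_lowcorr")
        with pytest.raises(ValueError):
            gabor.shape_indices(fit)


class TestTdi:
    def test_separable_rf_zero(self, rng):
        rf = np.outer(np.sin(2 * np.pi * 0.2 * np.arange(20)),
                      [1, 2, 1, 0.5, 0.2, 0.1, 0.05])
        assert gabor.tdi(rf).tdi == pytest.approx(0.0, abs=1e-12)

    def test_drifting_grating_high(self, grating_xt):
        assert gabor.tdi(grating_xt).tdi > 0.9

    def test_bounded_unit_interval(self, rng):
        for _ in range(100):
            res = gabor.tdi(rng.standard_normal((20, 7)))
            assert 0.0 <= res.tdi <= 1.0

    def test_time_reversal_preserves_value(self, grating_xt):
        fwd = gabor.tdi(grating_xt)
        rev = gabor.tdi(grating_xt[:, ::-1])
        assert np.isclose(fwd.tdi, rev.tdi, atol=1e-10)
        # roles of Rp and Rq swap under time reversal
        assert np.isclose(fwd.Rp, rev.Rp) and np.isclose(fwd.Rq, rev.Rq)

    def test_static_pattern_flagged(self):
        rf = np.outer(np.sin(2 * np.pi * 0.2 * np.arange(20)), np.ones(7))
        res = gabor.tdi(rf)
        assert res.static and res.tdi == 0.0


class TestPeakTemporalFrequency:
    def test_grating_one_cycle_per_7_bins(self):
        x = np.arange(20)[:, None]
        t = np.arange(7)[None, :]
        rf = np.cos(2 * np.pi * (0.2 * x - t / 7))
        # DFT temporal frequency 1/7 cycles/bin at 25 bins/s
        assert gabor.peak_temporal_frequency(rf) == pytest.approx(25 / 7)

    def test_static_pattern_zero(self):
        rf = np.outer(np.sin(np.arange(20)), np.ones(7))
        assert gabor.peak_temporal_frequency(rf) == 0.0

    def test_unit_conversion(self, grating_xt):
        # peak near 0.14 cycles/bin -> nearest DFT bin 1/7, x25 = 3.571 c/s
        assert gabor.peak_temporal_frequency(grating_xt) == pytest.approx(25 / 7)


class TestVisualTemporalProfile:
    def test_one_hot_in_time(self):
        rf = np.zeros((5, 20, 20, 7))
        rf[:, :, :, 3] = 1.0
        profile = gabor.temporal_power_profile_visual(rf)
        assert profile[3] == 1.0

    def test_sums_to_one(self, rng):
        profile = gabor.temporal_power_profile_visual(rng.standard_normal((4, 20, 20, 7)))
        assert abs(profile.sum() - 1.0) < 1e-10

    def test_shared_kernel_with_auditory(self, rng):
        from predrf import strf as astrf

        stack = rng.standard_normal((3, 8, 10))
        assert np.allclose(
            gabor.temporal_power_profile_visual(stack), astrf.temporal_power_profile(stack)
        )
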