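import numpy as np
import pytest
from scipy.integrate import quad
from scipy.ndimage import gaussian_filter
from scipy.special import erf

import waterpet as wp
from waterpet.resolution import (
    ReconstructionSpec,
    combine_with_filter,
    compute_recovery,
    default_fwhm_grid,
    load_catalog,
    match_resolution,
    reference_method_name,
    simulate_recovery_library,
)
from waterpet.synth import FWHM_TO_SIGMA


def blurred_ball_profile(r, R, sigma):
    """Value at radius r of a unit ball convolved with an isotropic Gaussian.

    Independent 1D radial oracle (closed form for the sphere-Gaussian
    overlap), used to cross-check the 3D image-domain computation.
    """
    if r < 1e-9:
        return erf(R / (sigma * np.sqrt(2))) - np.sqrt(2 / np.pi) * (R / sigma) * np.exp(
            -(R**2) / (2 * sigma**2)
        )
    s2 = sigma * np.sqrt(2)
    term1 = 0.5 * (erf((R - r) / s2) + erf((R + r) / s2))
    term2 = (sigma / (r * np.sqrt(2 * np.pi))) * (
        np.exp(-((R - r) ** 2) / (2 * sigma**2)) - np.exp(-((R + r) ** 2) / (2 * sigma**2))
    )
    return term1 - term2


def oracle_rc(diameter_mm, fwhm_mm, sphere_act, bkg_act):
    """Recovery coefficient by radial quadrature, background included."""
    R = diameter_mm / 2.0
    sigma = fwhm_mm * FWHM_TO_SIGMA
    integral, _ = quad(lambda r: blurred_ball_profile(r, R, sigma) * r**2, 0.0, R)
    mean_ball = 3.0 * integral / R**3
    return (bkg_act + (sphere_act - bkg_act) * mean_ball) / sphere_act


class TestRecoveryLibrary:
    def test_near_delta_kernel_near_unity(self, nema_1mm):
        lib = simulate_recovery_library(nema_1mm, np.array([1.0]))
        assert lib[0].rc[-1] >= 0.985  # 37 mm sphere barely affected

    def test_monotone_in_fwhm_and_diameter(self, nema_1mm):
        lib = simulate_recovery_library(nema_1mm, np.array([2.0, 5.0, 8.0, 11.0, 14.0]))
        rc = np.array([e.rc for e in lib])  # (n_fwhm, n_spheres)
        assert np.all(np.diff(rc, axis=0) < 0)  # decreasing with FWHM
        assert np.all(np.diff(rc, axis=1) > 0)  # increasing with diameter

    @pytest.mark.parametrize("fwhm", [5.0, 8.0])
    @pytest.mark.parametrize("sphere_index", [0, 3])
    def test_matches_radial_quadrature_oracle(self, nema_1mm, fwhm, sphere_index):
        lib = simulate_recovery_library(nema_1mm, np.array([float(fwhm)]))
        expected = oracle_rc(
            nema_1mm.sphere_diameters[sphere_index],
            fwhm,
            nema_1mm.sphere_activity,
            nema_1mm.background_activity,
        )
        assert lib[0].rc[sphere_index] == pytest.approx(expected, abs=0.01)

    def test_rc_bounded(self, recovery_library_1mm, nema_1mm):
        lower = nema_1mm.background_activity / nema_1mm.sphere_activity
        for entry in recovery_library_1mm:
            assert np.all(entry.rc >= lower)
            assert np.all(entry.rc <= 1.05)

    def test_too_coarse_grid_rejected(self, nema_2mm):
        with pytest.raises(ValueError):
            simulate_recovery_library(nema_2mm, np.array([1.0]))

    def test_gaussian_semigroup_in_recovery_space(self, nema_1mm):
        """Blur f1 then f2 matches a single blur at sqrt(f1^2+f2^2)."""
        f1, f2 = 4.0, 6.0
        combined = combine_with_filter(f1, f2)
        img = np.asarray(nema_1mm.volume, float)
        two_step = gaussian_filter(
            gaussian_filter(img, f1 * FWHM_TO_SIGMA), f2 * FWHM_TO_SIGMA
        )
        one_step = gaussian_filter(img, combined * FWHM_TO_SIGMA)
        rc2 = compute_recovery(two_step, nema_1mm).rc
        rc1 = compute_recovery(one_step, nema_1mm).rc
        assert np.abs(rc2 - rc1).max() < 0.005


class TestComputeRecovery:
    def test_unblurred_phantom_rc_unity(self, nema_1mm):
        rc = compute_recovery(np.asarray(nema_1mm.volume, float), nema_1mm).rc
        np.testing.assert_allclose(rc, 1.0, atol=1e-6)

    def test_extreme_blur_approaches_background_ratio(self, nema_1mm):
        img = gaussian_filter(np.asarray(nema_1mm.volume, float), 60.0 * FWHM_TO_SIGMA)
        rc = compute_recovery(img, nema_1mm).rc
        limit = nema_1mm.background_activity / nema_1mm.sphere_activity
        assert np.all(rc < limit + 0.12)
        assert np.all(rc > limit - 0.02)

    def test_scaling_contract(self, nema_1mm):
        # doubling the image without updating metadata doubles rc
        rc1 = compute_recovery(np.asarray(nema_1mm.volume, float), nema_1mm).rc
        rc2 = compute_recovery(2.0 * np.asarray(nema_1mm.volume, float), nema_1mm).rc
        np.testing.assert_allclose(rc2, 2 * rc1, rtol=1e-6)

    def test_wrong_grid_raises(self, nema_1mm):
        with pytest.raises(ValueError):
            compute_recovery(np.zeros((10, 10, 10)), nema_1mm)


class TestMatchResolution:
    def test_self_match(self, recovery_library_1mm):
        entry = next(e for e in recovery_library_1mm if e.fwhm == 6.0)
        fit = match_resolution(entry, recovery_library_1mm)
        assert fit.matched_fwhm == 6.0
        assert fit.rss_by_fwhm["rss"].min() == 0.0

    def test_off_grid_nearest_neighbor(self, nema_1mm, recovery_library_1mm):
        img = gaussian_filter(
            np.asarray(nema_1mm.volume, float), 6.05 * FWHM_TO_SIGMA / nema_1mm.voxel_size
        )
        fit = match_resolution(compute_recovery(img, nema_1mm), recovery_library_1mm)
        assert fit.matched_fwhm in (6.0, 6.1)

    def test_rss_unimodal_around_minimum(self, nema_1mm, recovery_library_1mm):
        img = gaussian_filter(
            np.asarray(nema_1mm.volume, float), 8.0 * FWHM_TO_SIGMA / nema_1mm.voxel_size
        )
        fit = match_resolution(compute_recovery(img, nema_1mm), recovery_library_1mm)
        rss = fit.rss_by_fwhm["rss"].to_numpy()
        i = int(np.argmin(rss))
        assert np.all(np.diff(rss[: i + 1]) <= 0)
        assert np.all(np.diff(rss[i:]) >= 0)

    def test_diameter_mismatch_raises(self, recovery_library_1mm):
        bad = wp.RecoveryCurve((10.0, 20.0, 30.0), np.array([0.5, 0.6, 0.7]))
        with pytest.raises(ValueError):
            match_resolution(bad, recovery_library_1mm)


class TestCombineWithFilter:
    def test_identity_with_zero_filter(self):
        assert combine_with_filter(7.2, 0.0) == 7.2

    def test_pythagorean_triple(self):
        assert combine_with_filter(3.0, 4.0) == pytest.approx(5.0)

    def test_filtered_resolution_span(self):
        assert combine_with_filter(7.63, 10.0) == pytest.approx(12.58, abs=0.005)

    def test_negative_rejected(self):
        with pytest.raises(ValueError):
            combine_with_filter(-1.0, 2.0)


class TestCatalog:
    def test_counts(self):
        catalog = load_catalog()
        assert len(catalog) == 20
        osem = [m for m in catalog if m.family != "BSREM"]
        bsrem = [m for m in catalog if m.family == "BSREM"]
        assert len(osem) == 14
        assert len(bsrem) == 6

    def test_reference_method_present(self):
        names = {m.name for m in load_catalog()}
        assert reference_method_name() in names

    def test_family_field_consistency(self):
        for m in load_catalog():
            if m.family == "BSREM":
                assert m.beta is not None and m.iterations is None
                assert m.filter_fwhm == 0.0
            else:
                assert m.beta is None and m.iterations is not None

    def test_effective_fwhm_span(self):
        eff = [m.effective_fwhm for m in load_catalog()]
        assert min(eff) == pytest.approx(5.5, abs=0.05)
        assert max(eff) == pytest.approx(12.6, abs=0.05)

    def test_invalid_spec_rejected(self):
        with pytest.raises(ValueError):
            ReconstructionSpec(
                name="bad", family="BSREM", tof=True, psf=True,
                iterations=3, subsets=16, filter_fwhm=0.0, beta=100,
                unfiltered_fwhm=6.0,
            )


class TestEndToEndResolutionRecovery:
    @pytest.mark.parametrize("true_fwhm", [5.5, 8.5, 12.6])
    def test_noise_free_recovery_within_tenth_mm(
        self, nema_1mm, recovery_library_1mm, true_fwhm
    ):
        img = gaussian_filter(
            np.asarray(nema_1mm.volume, float),
            true_fwhm * FWHM_TO_SIGMA / nema_1mm.voxel_size,
        )
        fit = match_resolution(compute_recovery(img, nema_1mm), recovery_library_1mm)
        assert abs(fit.matched_fwhm - true_fwhm) <= 0.1

    def test_noisy_recovery_within_three_tenths(self, nema_1mm, recovery_library_1mm):
        rng = np.random.default_rng(42)
        true_fwhm = 6.5
        img = gaussian_filter(
            np.asarray(nema_1mm.volume, float),
            true_fwhm * FWHM_TO_SIGMA / nema_1mm.voxel_size,
        )
        img = img + rng.standard_normal(img.shape) * 0.05 * nema_1mm.sphere_activity
        fit = match_resolution(compute_recovery(img, nema_1mm), recovery_library_1mm)
        assert abs(fit.matched_fwhm - true_fwhm) <= 0.3
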