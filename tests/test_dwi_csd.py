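"""Diffusion pipeline: simulation, tensor fit, response, CSD, AFDtotal."""

import numpy as np
import pytest

from strainmap.csd import afd_total, estimate_response, fit_csd
from strainmap.dwi import (
    fit_tensor,
    make_gradient_table,
    simulate_dwi,
    tensor_fa,
)
from strainmap.sh import fibonacci_sphere


def unit(v):
    v = np.asarray(v, dtype=float)
    return v / np.linalg.norm(v)


class TestSimulateDWI:
    def test_single_fiber_signal_geometry(self, single_shell_table):
        """Signal is maximal for gradients perpendicular to the fiber."""
        bvals, bvecs = single_shell_table
        dwi = simulate_dwi([[(np.array([0, 0, 1.0]), 1.0)]], bvals=bvals, bvecs=bvecs)
        s = dwi.signals[0, 0, 0][dwi.dwi_index]
        g = dwi.bvecs[dwi.dwi_index]
        cos2 = g[:, 2] ** 2
        assert np.argmax(s) == np.argmin(cos2)
        assert np.argmin(s) == np.argmax(cos2)

    def test_isotropic_voxel_uniform_signal(self, single_shell_table):
        bvals, bvecs = single_shell_table
        dwi = simulate_dwi([[]], bvals=bvals, bvecs=bvecs, iso_diffusivity=1e-3)
        s = dwi.signals[0, 0, 0][dwi.dwi_index]
        np.testing.assert_allclose(s, np.exp(-1000 * 1e-3), atol=1e-12)

    def test_gradient_table_validation(self):
        bvals = np.full(10, 1000.0)
        bvecs = np.tile(unit([1, 1, 0]), (10, 1))
        with pytest.raises(ValueError, match="b=0"):
            simulate_dwi([[]], bvals=bvals, bvecs=bvecs)
        bvals2 = np.concatenate([[0.0], bvals])
        bad = np.vstack([np.zeros(3), np.tile([1.0, 1.0, 0.0], (10, 1))])
        with pytest.raises(ValueError, match="unit norm"):
            simulate_dwi([[]], bvals=bvals2, bvecs=bad)

    def test_rician_noise_seeded(self, single_shell_table):
        bvals, bvecs = single_shell_table
        a = simulate_dwi([[]], bvals=bvals, bvecs=bvecs, snr=20, seed=5)
        b = simulate_dwi([[]], bvals=bvals, bvecs=bvecs, snr=20, seed=5)
        np.testing.assert_array_equal(a.signals, b.signals)
        assert not np.allclose(a.signals, simulate_dwi([[]], bvals=bvals, bvecs=bvecs).signals)


class TestTensorFit:
    def test_forward_simulated_tensor_recovered(self, single_shell_table):
        """Closed-form log-linear inversion recovers diagonal tensor to 1e-8."""
        bvals, bvecs = single_shell_table
        u = np.array([1.0, 0.0, 0.0])
        dwi = simulate_dwi([[(u, 1.0)]], response_params=(1.7e-3, 0.3e-3),
                           bvals=bvals, bvecs=bvecs)
        fit = fit_tensor(dwi)
        d = fit.tensor[0, 0, 0]
        np.testing.assert_allclose(d[[0, 2, 5]], [1.7e-3, 0.3e-3, 0.3e-3], atol=1e-8)
        np.testing.assert_allclose(d[[1, 3, 4]], 0.0, atol=1e-8)
        lam = np.array([1.7e-3, 0.3e-3, 0.3e-3])
        assert fit.fa[0, 0, 0] == pytest.approx(tensor_fa(lam), abs=1e-8)
        assert fit.md[0, 0, 0] == pytest.approx(lam.mean(), abs=1e-10)

    def test_isotropic_voxel_zero_fa(self, single_shell_table):
        bvals, bvecs = single_shell_table
        dwi = simulate_dwi([[]], bvals=bvals, bvecs=bvecs, iso_diffusivity=0.9e-3)
        fit = fit_tensor(dwi)
        assert fit.fa[0, 0, 0] == pytest.approx(0.0, abs=1e-8)
        assert fit.md[0, 0, 0] == pytest.approx(0.9e-3, abs=1e-10)

    def test_too_few_directions(self):
        bvals = np.array([0.0, 1000, 1000, 1000, 1000, 1000])
        vec = fibonacci_sphere(10)[:5]
        vec /= np.linalg.norm(vec, axis=1, keepdims=True)
        bvecs = np.vstack([np.zeros(3), vec])
        dwi = simulate_dwi([[]], bvals=bvals, bvecs=bvecs)
        with pytest.raises(ValueError, match=">= 6"):
            fit_tensor(dwi)


class TestResponse:
    def test_single_tensor_response_matches_analytic_projection(
        self, single_shell_table, calibrated_response
    ):
        """Calibrated coefficients equal the analytic m=0 projection."""
        from strainmap.sh import axial_kernel_coeffs

        b = 1000.0
        ax, rad = 1.7e-3, 0.3e-3
        analytic = axial_kernel_coeffs(
            lambda th: np.exp(-b * (rad + (ax - rad) * np.cos(th) ** 2)), lmax=8
        )
        np.testing.assert_allclose(calibrated_response.sh_coeffs, analytic, atol=2e-3)

    def test_high_threshold_is_error(self, single_shell_table):
        bvals, bvecs = single_shell_table
        dwi = simulate_dwi([[]] * 25, bvals=bvals, bvecs=bvecs)
        fit = fit_tensor(dwi)
        with pytest.raises(ValueError, match="lower the threshold"):
            estimate_response(dwi, fit, fa_threshold=1.0)

    def test_rotation_independent(self, single_shell_table):
        """Rotating fibers and gradients together leaves the response unchanged."""
        from scipy.stats import special_ortho_group

        bvals, bvecs = single_shell_table
        rng = np.random.default_rng(3)
        dirs = rng.standard_normal((40, 3))
        dirs /= np.linalg.norm(dirs, axis=1, keepdims=True)
        rot = special_ortho_group.rvs(3, random_state=4)

        def calibrate(dirset, vecs):
            dwi = simulate_dwi([[(d, 1.0)] for d in dirset], bvals=bvals, bvecs=vecs)
            return estimate_response(dwi, fit_tensor(dwi)).sh_coeffs

        base = calibrate(dirs, bvecs)
        rotated = calibrate(dirs @ rot.T, np.vstack([bvecs[:1], bvecs[1:] @ rot.T]))
        np.testing.assert_allclose(base, rotated, atol=1e-6)


class TestCSD:
    def test_single_fiber_peak_within_5_degrees(
        self, single_shell_table, calibrated_response
    ):
        bvals, bvecs = single_shell_table
        rng = np.random.default_rng(8)
        sphere = fibonacci_sphere(4000)
        for _ in range(5):
            u = unit(rng.standard_normal(3))
            dwi = simulate_dwi([[(u, 1.0)]], bvals=bvals, bvecs=bvecs)
            fodf = fit_csd(dwi, calibrated_response)
            amps = fodf.amplitudes(sphere)[0]
            peak = sphere[np.argmax(amps)]
            angle = np.degrees(np.arccos(min(1.0, abs(peak @ u))))
            assert angle < 5.0

    def test_isotropic_energy_concentrated_in_l0(
        self, single_shell_table, calibrated_response
    ):
        bvals, bvecs = single_shell_table
        dwi = simulate_dwi([[]], bvals=bvals, bvecs=bvecs, iso_diffusivity=0.7e-3)
        fodf = fit_csd(dwi, calibrated_response)
        c = fodf.sh_coeffs[0, 0, 0]
        assert c[0] ** 2 / (c**2).sum() >= 0.95

    def test_crossing_fibers_resolved(self, single_shell_table, calibrated_response):
        """Two equal orthogonal fibers give two peaks within 10 degrees."""
        bvals, bvecs = single_shell_table
        v1, v2 = np.array([1.0, 0, 0]), np.array([0, 1.0, 0])
        dwi = simulate_dwi([[(v1, 0.5), (v2, 0.5)]], bvals=bvals, bvecs=bvecs)
        fodf = fit_csd(dwi, calibrated_response)
        sphere = fibonacci_sphere(4000)
        amps = fodf.amplitudes(sphere)[0]
        top = sphere[np.argsort(amps)[-60:]]
        ang1 = np.degrees(np.arccos(np.clip(np.abs(top @ v1), 0, 1))).min()
        ang2 = np.degrees(np.arccos(np.clip(np.abs(top @ v2), 0, 1))).min()
        assert ang1 < 10.0 and ang2 < 10.0

    def test_signal_reconstruction(self, single_shell_table, calibrated_response):
        """Fitted fODF convolved with the response reproduces the signal."""
        from strainmap.sh import cart_to_spherical, convolution_weights, real_sym_sh_basis

        bvals, bvecs = single_shell_table
        u = unit([1.0, -2.0, 0.5])
        dwi = simulate_dwi([[(u, 1.0)]], bvals=bvals, bvecs=bvecs)
        fodf = fit_csd(dwi, calibrated_response)
        k = convolution_weights(calibrated_response.sh_coeffs[:5], fodf.lmax)
        g = dwi.bvecs[dwi.dwi_index]
        theta, phi = cart_to_spherical(g)
        basis = real_sym_sh_basis(fodf.lmax, theta, phi)
        predicted = basis @ (k * fodf.sh_coeffs[0, 0, 0])
        observed = dwi.signals[0, 0, 0][dwi.dwi_index]
        rel_rmse = np.sqrt(np.mean((predicted - observed) ** 2)) / np.sqrt(
            np.mean(observed**2)
        )
        assert rel_rmse < 0.05


class TestAFD:
    def test_basis_identities(self, single_shell_table, calibrated_response):
        """Constant fODF amplitude A has c00 = A*sqrt(4*pi); zero maps to zero."""
        from strainmap.csd import FODFField
        from strainmap.grid import VoxelGrid
        from strainmap.sh import n_coeffs

        grid = VoxelGrid(shape=(1, 1, 1), voxel_size=(2, 2, 2), affine=None)
        mask = np.ones(grid.shape, dtype=bool)
        coeffs = np.zeros(grid.shape + (45,))
        fodf = FODFField(grid=grid, sh_coeffs=coeffs, mask=mask, lmax=8)
        assert afd_total(fodf).values[0, 0, 0] == 0.0
        amp = 0.37
        coeffs2 = coeffs.copy()
        coeffs2[..., 0] = amp * np.sqrt(4 * np.pi)
        fodf2 = FODFField(grid=grid, sh_coeffs=coeffs2, mask=mask, lmax=8)
        sphere = fibonacci_sphere(200)
        np.testing.assert_allclose(fodf2.amplitudes(sphere)[0], amp, atol=1e-12)
        assert afd_total(fodf2).values[0, 0, 0] == pytest.approx(amp * np.sqrt(4 * np.pi))

    def test_afd_scales_linearly_with_signal(
        self, single_shell_table, calibrated_response
    ):
        bvals, bvecs = single_shell_table
        u = unit([0.3, 1.0, 0.2])
        dwi = simulate_dwi([[(u, 1.0)]], bvals=bvals, bvecs=bvecs)
        fodf = fit_csd(dwi, calibrated_response)
        base = afd_total(fodf).values[0, 0, 0]
        scaled = dwi
        scaled.signals = 2.0 * dwi.signals
        fodf2 = fit_csd(scaled, calibrated_response)
        # b0 normalization makes AFD invariant to global signal scaling
        assert afd_total(fodf2).values[0, 0, 0] == pytest.approx(base, rel=1e-6)

    def test_afd_monotone_in_fiber_fraction(
        self, single_shell_table, calibrated_response
    ):
        bvals, bvecs = single_shell_table
        u = np.array([0.0, 0.0, 1.0])
        afds = []
        for f in (0.2, 0.5, 0.8):
            dwi = simulate_dwi([[(u, f)]], bvals=bvals, bvecs=bvecs)
            afds.append(afd_total(fit_csd(dwi, calibrated_response)).values[0, 0, 0])
        assert afds[0] < afds[1] < afds[2]

    def test_rotational_equivariance(self, single_shell_table, calibrated_response):
        """Rotating gradients and fibers together leaves AFDtotal unchanged."""
        from scipy.stats import special_ortho_group

        bvals, bvecs = single_shell_table
        u = unit([1.0, 0.5, -0.2])
        rot = special_ortho_group.rvs(3, random_state=12)
        a = simulate_dwi([[(u, 1.0)]], bvals=bvals, bvecs=bvecs)
        b = simulate_dwi([[(rot @ u, 1.0)]], bvals=bvals,
                         bvecs=np.vstack([bvecs[:1], bvecs[1:] @ rot.T]))
        # the fixed constraint sphere limits exact equivariance; the residual
        # is pure discretization error and vanishes with a denser sphere
        afd_a = afd_total(fit_csd(a, calibrated_response)).values[0, 0, 0]
        afd_b = afd_total(fit_csd(b, calibrated_response)).values[0, 0, 0]
        assert afd_b == pytest.approx(afd_a, abs=5e-5)
        dense_a = afd_total(fit_csd(a, calibrated_response,
                                    n_constraint_dirs=2400)).values[0, 0, 0]
        dense_b = afd_total(fit_csd(b, calibrated_response,
                                    n_constraint_dirs=2400)).values[0, 0, 0]
        assert dense_b == pytest.approx(dense_a, abs=1e-6)
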