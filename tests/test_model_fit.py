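import math

import numpy as np
import pytest

from ricstf.correlation import CorrelationSurface
from ricstf.geometry import ScanGeometry, PSFModel
from ricstf.model_fit import (
    model_rics_acf,
    diffusion_kernel,
    immobile_kernel,
    two_component_acf,
    fit_fast_axis,
    fit_two_component,
    fit_ccf,
    compute_psi,
    amplitude_to_concentration,
    axial_displacement_factor,
    fit_bead_3d,
)
from ricstf.simulate import simulate_bead_stack


def make_surface(values, max_lag=32, pair="gg"):
    x = np.arange(-max_lag, max_lag + 1)
    y = np.arange(-max_lag if pair == "gc" else 0, max_lag + 1)
    return CorrelationSurface(values, x, y, pair=pair)


def synth_two_component(A, D, phi, geometry, psf, B=0.0, max_lag=32):
    x = np.arange(-max_lag, max_lag + 1)
    y = np.arange(0, max_lag + 1)
    DX, DY = np.meshgrid(x, y)
    vals = two_component_acf(DX, DY, A, D, phi, geometry, psf.w0_um, psf.wz_um, B)
    return make_surface(vals, max_lag)


class TestKernels:
    def test_zero_lag_normalization(self, geometry_256, psf):
        assert model_rics_acf(0, 0, 0.05, 2.0, geometry_256, psf) == pytest.approx(0.05)

    def test_zero_diffusion_is_pure_gaussian(self, geometry_256, psf):
        dx, dy = np.arange(-10, 11), np.zeros(21)
        got = model_rics_acf(dx, dy, 1.0, 0.0, geometry_256, psf, B=0.0)
        dr = geometry_256.pixel_size_um
        expect = np.exp(-(dr**2) * dx**2 / psf.w0_um**2)
        assert np.allclose(got, expect)

    def test_infinite_diffusion_limit_reaches_background(self, geometry_256, psf):
        val = model_rics_acf(5, 5, 1.0, 1e9, geometry_256, psf, B=0.01)
        assert val == pytest.approx(0.01, abs=1e-6)

    def test_kernel_symmetric_in_lag_sign(self, geometry_256, psf):
        a = diffusion_kernel(np.array([5.0]), np.array([3.0]), 2.0, geometry_256, psf.w0_um, psf.wz_um)
        b = diffusion_kernel(np.array([-5.0]), np.array([-3.0]), 2.0, geometry_256, psf.w0_um, psf.wz_um)
        assert a == pytest.approx(b)

    def test_slow_axis_decays_faster_than_fast_axis(self, geometry_256, psf):
        # line time >> pixel dwell: diffusion erodes the slow axis more
        g_fast = diffusion_kernel(np.array([8.0]), np.array([0.0]), 2.0, geometry_256, psf.w0_um, psf.wz_um)
        g_slow = diffusion_kernel(np.array([0.0]), np.array([8.0]), 2.0, geometry_256, psf.w0_um, psf.wz_um)
        assert g_slow < g_fast

    def test_invalid_parameters_rejected(self, geometry_256, psf):
        with pytest.raises(ValueError):
            model_rics_acf(0, 0, -1.0, 2.0, geometry_256, psf)
        with pytest.raises(ValueError):
            model_rics_acf(0, 0, 1.0, -2.0, geometry_256, psf)


class TestFastAxisFit:
    def test_recovers_amplitude_from_gaussian_cut(self, geometry_256, psf):
        # cut generated from the fit's own Gaussian model: exact recovery
        surf = synth_two_component(0.02, 0.0, 1.0, geometry_256, psf)
        res = fit_fast_axis(surf, psf, geometry_256)
        assert res.ok
        assert res.amplitude == pytest.approx(0.02, abs=1e-6)
        assert abs(res.background) <= 1e-3

    def test_diffusive_cut_amplitude_within_half_percent(self, geometry_256, psf):
        # microsecond pixel dwells make the fast-axis of a freely
        # diffusing species nearly Gaussian; the amplitude error of the
        # Gaussian approximation stays below 0.5%
        surf = synth_two_component(0.02, 2.0, 0.0, geometry_256, psf)
        res = fit_fast_axis(surf, psf, geometry_256)
        assert res.ok
        assert res.amplitude == pytest.approx(0.02, rel=5e-3)

    def test_pure_noise_surface_flagged(self, rng, geometry_256, psf):
        vals = rng.normal(0, 1e-4, size=(33, 65))
        res = fit_fast_axis(make_surface(vals), psf, geometry_256)
        assert not res.ok

    def test_too_few_lags_flagged(self, geometry_256, psf):
        surf = synth_two_component(0.02, 2.0, 0.0, geometry_256, psf, max_lag=5)
        res = fit_fast_axis(surf, psf, geometry_256)
        assert not res.ok
        assert "too_few_lags" in res.flags


class TestTwoComponentFit:
    def test_single_case_recovery(self, geometry_256, psf):
        surf = synth_two_component(0.05, 2.0, 0.5, geometry_256, psf)
        res = fit_two_component(surf, 0.05, geometry_256, psf, seed=0)
        assert res.ok
        assert res.phi == pytest.approx(0.5, abs=0.02)
        assert res.d_um2_s == pytest.approx(2.0, rel=0.05)

    def test_all_immobile_pins_phi_high(self, geometry_256, psf):
        surf = synth_two_component(0.05, 2.0, 1.0, geometry_256, psf)
        res = fit_two_component(surf, 0.05, geometry_256, psf, seed=1)
        assert res.phi > 0.97

    def test_nonzero_background_recovered(self, geometry_256, psf):
        surf = synth_two_component(0.05, 1.0, 0.3, geometry_256, psf, B=5e-4)
        res = fit_two_component(surf, 0.05, geometry_256, psf, seed=2)
        assert res.background == pytest.approx(5e-4, abs=1e-4)
        assert res.phi == pytest.approx(0.3, abs=0.02)


class TestCCFFit:
    def synth_cross(self, A_cc, dx0_nm, dy0_nm, geometry, psf, max_lag=32):
        x = np.arange(-max_lag, max_lag + 1)
        y = np.arange(-max_lag, max_lag + 1)
        DX, DY = np.meshgrid(x, y)
        dr = geometry.pixel_size_um
        vals = A_cc * np.exp(
            -((dr * DX - dx0_nm * 1e-3) ** 2 + (dr * DY - dy0_nm * 1e-3) ** 2) / psf.w0_um**2
        )
        return make_surface(vals, max_lag, pair="gc")

    def test_displacement_recovered_within_10nm(self, geometry_256, psf):
        surf = self.synth_cross(0.02, 64.0, -32.0, geometry_256, psf)
        res = fit_ccf(surf, psf, psf, geometry_256, seed=0)
        assert res.ok
        assert res.amplitude == pytest.approx(0.02, rel=0.01)
        assert res.dx0_nm == pytest.approx(64.0, abs=10.0)
        assert res.dy0_nm == pytest.approx(-32.0, abs=10.0)

    def test_noise_only_amplitude_set_to_zero(self, rng, geometry_256, psf):
        vals = rng.normal(0, 1e-3, size=(65, 65))
        surf = make_surface(vals, pair="gc")
        res = fit_ccf(surf, psf, psf, geometry_256, seed=1)
        assert res.amplitude_raw == 0.0
        assert "below_noise_floor" in res.flags

    def test_axial_factor_scales_amplitude(self, geometry_256, psf):
        surf = self.synth_cross(0.02, 0.0, 0.0, geometry_256, psf)
        res = fit_ccf(surf, psf, psf, geometry_256, axial_factor=1.02, seed=2)
        assert res.amplitude == pytest.approx(1.02 * res.amplitude_raw)


class TestPsiAndConcentration:
    def test_psi_trivials(self):
        assert compute_psi(0.0, 0.05) == 0.0
        assert compute_psi(0.05, 0.05) == 1.0
        assert compute_psi(0.1, 0.05) == 1.0  # clipped
        assert np.isnan(compute_psi(0.02, 0.0))

    def test_gamma_over_amplitude_counts_molecules(self, psf):
        n, _ = amplitude_to_concentration(psf.gamma, psf)
        assert n == pytest.approx(1.0)

    def test_known_volume_conversion(self):
        # gamma = 1 convention: V = pi^{3/2} w0^2 wz = 0.522 um^3 and
        # 10 molecules -> 31.8 nM
        psf = PSFModel(w0_um=0.25, wz_um=1.5, gamma=1.0)
        assert psf.observation_volume_um3 == pytest.approx(0.522, rel=2e-3)
        _, c = amplitude_to_concentration(0.1, psf)
        assert c == pytest.approx(31.8, rel=5e-3)

    def test_amplitude_concentration_round_trip(self, psf):
        from ricstf.geometry import molecules

        c_true = 30.0
        n = molecules(c_true, psf.observation_volume_um3)
        _, c = amplitude_to_concentration(psf.gamma / n, psf)
        assert c == pytest.approx(c_true, rel=1e-9)


class TestAxialFactor:
    def test_zero_displacement_is_unity(self):
        assert axial_displacement_factor(0.0, 1.5, 1.5) == 1.0

    def test_inverts_to_known_value(self):
        dz = math.sqrt(math.log(1.02) * (1.5**2 + 1.5**2) / 2)
        assert axial_displacement_factor(dz, 1.5, 1.5) == pytest.approx(1.02)

    def test_monotone_in_displacement(self):
        f = [axial_displacement_factor(d, 1.5, 1.5) for d in (0.0, 0.1, 0.2, 0.4)]
        assert all(a < b for a, b in zip(f, f[1:]))


@pytest.fixture(scope="module")
def fitted():
    stack = simulate_bead_stack(offsets_nm=(60.0, 30.0, 100.0), n_beads=4, seed=3)
    return stack, fit_bead_3d(stack)


class TestBeadRegistration:
    def test_axial_offset_recovered(self, fitted):
        _, res = fitted
        assert res.dz0_um == pytest.approx(0.1, abs=0.02)

    def test_lateral_offsets_recovered(self, fitted):
        _, res = fitted
        assert res.dx0_um == pytest.approx(0.06, abs=0.02)
        assert res.dy0_um == pytest.approx(0.03, abs=0.02)

    def test_fwhm_z_matches_generating_psf(self, fitted):
        stack, res = fitted
        expect = stack.psf_green.wz_um * math.sqrt(2 * math.log(2))
        assert np.allclose(res.fwhm_z_green, expect, rtol=0.05)

    def test_zero_offset_recovers_zero(self):
        stack = simulate_bead_stack(offsets_nm=(0.0, 0.0, 0.0), n_beads=3, seed=4)
        res = fit_bead_3d(stack)
        assert abs(res.dz0_um) < 0.01
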