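"""Dispersal kernel: closed form, discretization, and convolution."""

import numpy as np
import pytest
from scipy import integrate

import mpbspread as mp
from mpbspread.dispersal import KernelParams, compute_beetle_pressure, discretize_kernel


FIELD_PARAMS = KernelParams()  # field-estimated defaults: nu=1.45, rho=0.0118 km


class TestKernelDensity:
    def test_prefactor_at_zero(self):
        expected = (FIELD_PARAMS.nu - 1) / (2 * np.pi * FIELD_PARAMS.nu * FIELD_PARAMS.rho**2)
        assert mp.kernel_density(0.0, FIELD_PARAMS) == pytest.approx(expected, rel=1e-12)
        assert expected == pytest.approx(3.547e2, rel=1e-3)

    def test_normalizes_to_one_by_quadrature(self):
        val, err = integrate.quad(
            lambda r: 2 * np.pi * r * mp.kernel_density(r, FIELD_PARAMS), 0, np.inf,
            limit=200,
        )
        assert val == pytest.approx(1.0, abs=1e-8)

    @pytest.mark.parametrize("R", [1.0, 10.0, 100.0])
    def test_mass_within_matches_quadrature(self, R):
        """Analytic CDF 1-(1+R^2/(nu rho^2))^((1-nu)/2) vs adaptive quadrature."""
        q, _ = integrate.quad(
            lambda r: 2 * np.pi * r * mp.kernel_density(r, FIELD_PARAMS), 0, R, limit=200
        )
        assert mp.kernel_mass_within(R, FIELD_PARAMS) == pytest.approx(q, abs=1e-8)

    def test_strictly_decreasing(self):
        r = np.linspace(0, 50, 200)
        d = mp.kernel_density(r, FIELD_PARAMS)
        assert np.all(np.diff(d) < 0)
        assert np.all(d > 0)

    def test_invalid_parameters(self):
        with pytest.raises(ValueError):
            KernelParams(nu=1.0)
        with pytest.raises(ValueError):
            KernelParams(rho=0.0)
        with pytest.raises(ValueError):
            mp.kernel_density(-1.0, FIELD_PARAMS)


class TestDiscretization:
    def test_single_midpoint_reduces_to_density_times_area(self):
        """subpixel_n=1 with a wide kernel ~ D(center distance) * pixel area."""
        params = KernelParams(nu=3.0, rho=5.0)
        k = discretize_kernel(params, subpixel_n=1, support_radius=5,
                              refine_center=False)
        for di, dj in [(0, 0), (1, 2), (3, 4)]:
            expected = mp.kernel_density(np.hypot(di, dj), params) * 1.0
            assert k.value(di, dj) == pytest.approx(expected, rel=1e-12)

    def test_symmetry(self, kernel_default_small):
        k = kernel_default_small
        for di, dj in [(1, 3), (5, 2), (0, 7)]:
            vals = {k.value(di, dj), k.value(-di, dj), k.value(di, -dj),
                    k.value(-di, -dj), k.value(dj, di)}
            assert max(vals) - min(vals) < 1e-15 * max(vals)

    def test_grid_refinement_convergence(self):
        """Plain midpoint Dbar(0,0) converges under sub-grid refinement; the
        Richardson-extrapolated limit agrees with the center-refined value."""
        params = KernelParams(nu=3.0, rho=0.3)
        vals = [
            discretize_kernel(params, subpixel_n=n, support_radius=3,
                              refine_center=False).value(0, 0)
            for n in (10, 20, 40)
        ]
        d1, d2 = vals[1] - vals[0], vals[2] - vals[1]
        assert abs(d2) < abs(d1)  # converging
        rate = d1 / d2
        richardson = vals[2] + d2 / (rate - 1.0)
        refined = discretize_kernel(params, subpixel_n=20, support_radius=3).value(0, 0)
        assert refined == pytest.approx(richardson, rel=5e-3)

    def test_total_mass_matches_analytic_tail(self, kernel_default_small):
        """Discretized mass over the support ~ analytic mass within its radius."""
        R_km = kernel_default_small.support_radius * kernel_default_small.pixel_size
        assert kernel_default_small.total_mass == pytest.approx(
            mp.kernel_mass_within(R_km, FIELD_PARAMS), rel=0.01
        )

    def test_serialization_round_trip(self, tmp_path, kernel_wide):
        path = tmp_path / "kernel.npz"
        kernel_wide.save(path)
        loaded = mp.TransitionKernel.load(path)
        np.testing.assert_array_equal(loaded.array, kernel_wide.array)
        assert loaded.params == kernel_wide.params
        assert loaded.subpixel_n == kernel_wide.subpixel_n

    def test_parameter_validation(self):
        with pytest.raises(ValueError):
            discretize_kernel(subpixel_n=0)
        with pytest.raises(ValueError):
            discretize_kernel(support_radius=0)


class TestBeetlePressure:
    def test_zero_sources_zero_pressure(self, kernel_wide):
        z = np.zeros((12, 12))
        bp = compute_beetle_pressure(z, np.ones_like(z), np.ones_like(z), kernel_wide)
        assert np.all(bp.B == 0)

    def test_single_source_reproduces_kernel_column(self, kernel_wide):
        n = 21
        src = np.zeros((n, n))
        src[10, 10] = 1.0
        bp = compute_beetle_pressure(src, np.ones_like(src), np.ones_like(src),
                                     kernel_wide)
        for di, dj in [(0, 0), (2, -3), (-5, 5)]:
            assert bp.B[10 + di, 10 + dj] == pytest.approx(
                kernel_wide.value(di, dj), rel=1e-10
            )

    def test_matches_double_sum_oracle(self, kernel_wide, rng):
        """FFT convolution equals brute-force double summation to 1e-10."""
        n = 10
        src = rng.poisson(3.0, (n, n)).astype(float)
        brood = rng.uniform(0.5, 2.0, (n, n))
        theta = rng.uniform(0.1, 1.0, (n, n))
        bp = compute_beetle_pressure(src, brood, theta, kernel_wide)
        S = src * brood * theta
        direct = np.zeros((n, n))
        for yi in range(n):
            for yj in range(n):
                acc = 0.0
                for xi in range(n):
                    for xj in range(n):
                        acc += S[xi, xj] * kernel_wide.value(yi - xi, yj - xj)
                direct[yi, yj] = acc
        assert np.max(np.abs(bp.B - direct)) < 1e-10

    def test_linearity(self, kernel_wide, rng):
        n = 12
        ones = np.ones((n, n))
        s1 = rng.poisson(2.0, (n, n)).astype(float)
        s2 = rng.poisson(2.0, (n, n)).astype(float)
        b1 = compute_beetle_pressure(s1, ones, ones, kernel_wide).B
        b2 = compute_beetle_pressure(s2, ones, ones, kernel_wide).B
        combo = compute_beetle_pressure(2 * s1 + 3 * s2, ones, ones, kernel_wide).B
        np.testing.assert_allclose(combo, 2 * b1 + 3 * b2, rtol=1e-9, atol=1e-12)

    def test_group_scaling_decomposition(self, kernel_wide, rng):
        """Doubling c on one source group exactly doubles that group's term."""
        n = 14
        ones = np.ones((n, n))
        src = rng.poisson(2.0, (n, n)).astype(float)
        group_J = np.zeros((n, n), dtype=bool)
        group_J[:, n // 2:] = True
        B_L = compute_beetle_pressure(src, ones, ones, kernel_wide, mask=~group_J).B
        B_J = compute_beetle_pressure(src, ones, ones, kernel_wide, mask=group_J).B
        for c_J in (0.5, 1.0, 2.0):
            brood = np.where(group_J, c_J, 1.0)
            full = compute_beetle_pressure(src, brood, ones, kernel_wide).B
            np.testing.assert_allclose(full, B_L + c_J * B_J, rtol=1e-9, atol=1e-12)

    def test_survival_fraction_scales(self, kernel_wide, rng):
        n = 10
        ones = np.ones((n, n))
        src = rng.poisson(2.0, (n, n)).astype(float)
        full = compute_beetle_pressure(src, ones, ones, kernel_wide).B
        half = compute_beetle_pressure(src, ones, ones, kernel_wide,
                                       survival_fraction=0.5).B
        np.testing.assert_allclose(half, 0.5 * full, rtol=1e-12)

    def test_input_validation(self, kernel_wide):
        ones = np.ones((8, 8))
        with pytest.raises(ValueError):
            compute_beetle_pressure(-ones, ones, ones, kernel_wide)
        with pytest.raises(ValueError):
            compute_beetle_pressure(ones, ones, 2 * ones, kernel_wide)
        with pytest.raises(ValueError):
            compute_beetle_pressure(np.ones((8, 9)), ones, ones, kernel_wide)
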