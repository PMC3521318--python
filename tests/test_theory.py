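"""Well-mixed turbid-medium theory: LIE, shares, isolines, extinction."""

import numpy as np
import pytest
from scipy.integrate import quad

from lightshare.sky import build_sky
from lightshare.theory import (
    TheoryInputs,
    ellipsoidal_x_from_inclination,
    extinction_directional,
    extinction_from_inclination,
    isolines,
    lie_mixture,
    share_theoretical,
)


class TestLieMixture:
    def test_empty_canopy_limit(self):
        pred = lie_mixture(TheoryInputs(K=(0.5, 0.5), LAI=(0.0, 0.0)))
        assert pred.lie_by_species == (0.0, 0.0)
        assert pred.total_interception == 0.0

    def test_closed_form_two_species(self):
        pred = lie_mixture(TheoryInputs(K=(0.5, 0.5), LAI=(1.0, 1.0)))
        expected = 0.5 * (1.0 - np.exp(-1.0))
        assert pred.lie_by_species[0] == pytest.approx(expected, rel=1e-12)
        assert pred.share_species1 == pytest.approx(0.5, rel=1e-12)

    def test_dense_single_species_saturates(self):
        pred = lie_mixture(TheoryInputs(K=(0.6,), LAI=(100.0,)))
        assert pred.lie_by_species[0] == pytest.approx(1.0, abs=1e-12)

    def test_lie_sums_to_total(self):
        rng = np.random.default_rng(3)
        for _ in range(100):
            K = tuple(rng.uniform(0.2, 1.5, 3))
            L = tuple(rng.uniform(0.0, 4.0, 3))
            pred = lie_mixture(TheoryInputs(K=K, LAI=L))
            assert sum(pred.lie_by_species) == pytest.approx(
                pred.total_interception, abs=1e-12
            )
            assert 0.0 <= pred.total_interception < 1.0

    def test_negative_inputs_rejected(self):
        with pytest.raises(ValueError):
            TheoryInputs(K=(-0.1, 0.5), LAI=(1.0, 1.0))


class TestShare:
    def test_identical_species_share_equals_p(self):
        p = np.linspace(0.0, 1.0, 11)
        np.testing.assert_allclose(share_theoretical(1.0, p), p, atol=1e-15)

    def test_boundaries(self):
        assert share_theoretical(3.7, 0.0) == 0.0
        assert share_theoretical(3.7, 1.0) == 1.0

    def test_direct_arithmetic(self):
        assert share_theoretical(10.0, 0.5) == pytest.approx(10.0 / 11.0, rel=1e-12)

    def test_out_of_range_p_rejected(self):
        with pytest.raises(ValueError):
            share_theoretical(1.0, 1.2)
        with pytest.raises(ValueError):
            share_theoretical(0.0, 0.5)

    def test_consistent_with_lie_ratio(self):
        # the exponential factor cancels: the LAI-share formula must equal
        # the LIE ratio for any total LAI
        rng = np.random.default_rng(11)
        for _ in range(1000):
            K = rng.uniform(0.1, 2.0, 2)
            L = rng.uniform(1e-3, 5.0, 2)
            pred = lie_mixture(TheoryInputs(K=tuple(K), LAI=tuple(L)))
            p = L[0] / L.sum()
            s = share_theoretical(K[0] / K[1], p)
            assert s == pytest.approx(pred.share_species1, abs=1e-12)

    def test_strictly_increasing_in_p_and_alpha(self):
        p = np.linspace(0.01, 0.99, 50)
        for alpha in (0.2, 1.0, 4.0):
            s = share_theoretical(alpha, p)
            assert np.all(np.diff(s) > 0)
        alphas = np.linspace(0.1, 10.0, 50)
        s = np.array([share_theoretical(a, 0.4) for a in alphas])
        assert np.all(np.diff(s) > 0)


class TestIsolines:
    def test_alpha_one_is_identity(self):
        grid = isolines(alpha_values=[1.0])
        np.testing.assert_allclose(grid.shares[0], grid.p_grid, atol=1e-15)

    def test_reciprocal_alpha_symmetry(self):
        # s_alpha(p) = 1 - s_(1/alpha)(1 - p)
        p = np.linspace(0.0, 1.0, 41)
        for alpha in (0.1, 0.37, 2.9, 10.0):
            lhs = share_theoretical(alpha, p)
            rhs = 1.0 - share_theoretical(1.0 / alpha, 1.0 - p)
            np.testing.assert_allclose(lhs, rhs, atol=1e-12)

    def test_all_isolines_pass_through_corners(self):
        grid = isolines()
        assert np.all(grid.shares[:, 0] == 0.0)
        assert np.all(grid.shares[:, -1] == 1.0)
        # monotone along p
        assert np.all(np.diff(grid.shares, axis=1) >= 0)


def _ellipsoidal_g_numeric(x: float, zenith_deg: float) -> float:
    """Mean projection G(theta) by direct integration of the ellipsoidal
    leaf-angle density against the standard projection kernel."""
    th = np.radians(zenith_deg)

    def kernel(al):
        if np.tan(th) * np.tan(al) <= 1.0:
            return np.cos(th) * np.cos(al)
        b = np.arccos(1.0 / (np.tan(th) * np.tan(al)))
        return np.cos(th) * np.cos(al) * (1.0 + 2.0 * (np.tan(b) - b) / np.pi)

    def density(al):
        return (
            2.0 * x**3 * np.sin(al)
            / (np.cos(al) ** 2 + x**2 * np.sin(al) ** 2) ** 2
        )

    norm, _ = quad(density, 0.0, np.pi / 2.0, limit=200)
    g, _ = quad(lambda al: density(al) * kernel(al), 0.0, np.pi / 2.0,
                points=[np.pi / 2 - th], limit=200)
    return g / norm


class TestExtinction:
    def test_horizontal_leaves_give_unit_k(self):
        for zen in (0.0, 30.0, 75.0):
            assert extinction_directional(0.0, zen) == pytest.approx(1.0, abs=1e-3)
        assert extinction_from_inclination(0.0) == pytest.approx(1.0, abs=1e-3)

    def test_spherical_distribution_g_half(self):
        # x = 1 (mean inclination ~ 56 deg): G = 0.5 in every direction,
        # verified against direct numerical integration of the kernel
        incl = np.degrees(9.65 * (3.0 + 1.0) ** -1.65)
        assert ellipsoidal_x_from_inclination(incl) == pytest.approx(1.0, rel=1e-6)
        for zen in (10.0, 40.0, 70.0):
            g_num = _ellipsoidal_g_numeric(1.0, zen)
            assert g_num == pytest.approx(0.5, abs=5e-3)
            k = extinction_directional(incl, zen)
            assert k == pytest.approx(g_num / np.cos(np.radians(zen)), rel=0.01)

    def test_vertical_leaves_near_zenith_beam(self):
        # the mean-angle inversion is approximate at the fully erect limit,
        # so the coefficient vanishes only to a few parts in a thousand
        assert extinction_directional(90.0, 0.0) == pytest.approx(0.0, abs=5e-3)

    def test_campbell_k_matches_numeric_g(self):
        # the closed-form directional coefficient tracks the integrated
        # ellipsoidal projection within ~2 % over realistic angles
        for incl in (25.0, 40.0, 65.0):
            x = ellipsoidal_x_from_inclination(incl)
            for zen in (18.0, 54.0, 72.0):
                k_closed = extinction_directional(incl, zen)
                k_num = _ellipsoidal_g_numeric(x, zen) / np.cos(np.radians(zen))
                assert k_closed == pytest.approx(k_num, rel=0.02)

    def test_diffuse_k_erect_below_planophile(self):
        sky = build_sky()
        k_erect = extinction_from_inclination(65.0, sky)
        k_flat = extinction_from_inclination(20.0, sky)
        assert k_erect < k_flat
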