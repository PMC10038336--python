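"""Lineshapes, orientation factor, overlap integral and rate matrix."""

import numpy as np
import pytest
from hypothesis import given, strategies as st

import frlap
from frlap.photophysics import (DEFAULT_GRID, LineshapeParams, MediumParams,
                                FORSTER_PREFACTOR, build_rate_matrix,
                                forster_radius, kappa_squared,
                                make_lineshape, overlap_integral, pair_rate)


class TestLineshapes:
    def test_alpha_band_positions(self, spectra):
        sm = spectra["alpha"]
        assert sm.grid[np.argmax(sm.absorption)] == pytest.approx(709.0)
        assert sm.grid[np.argmax(sm.emission)] == pytest.approx(714.0)

    def test_beta_band_position(self, spectra):
        sm = spectra["beta"]
        assert sm.grid[np.argmax(sm.absorption)] == pytest.approx(621.0)

    @pytest.mark.parametrize("cls", ["alpha", "beta"])
    def test_emission_area_normalised(self, spectra, cls):
        sm = spectra[cls]
        assert np.trapezoid(sm.emission, sm.grid) == pytest.approx(
            1.0, abs=1e-6)

    def test_absorption_non_negative(self, spectra):
        for sm in spectra.values():
            assert np.all(sm.absorption >= 0)

    def test_peak_outside_grid_rejected(self):
        with pytest.raises(ValueError):
            make_lineshape("alpha", LineshapeParams(
                abs_peak_nm=450.0, em_peak_nm=460.0, abs_width_wn=200.0,
                peak_extinction=1e5))

    def test_negative_stokes_shift_rejected(self):
        with pytest.raises(ValueError):
            make_lineshape("alpha", LineshapeParams(
                abs_peak_nm=709.0, em_peak_nm=700.0, abs_width_wn=200.0,
                peak_extinction=1e5))


class TestKappaSquared:
    def test_parallel_perpendicular_to_r(self):
        assert kappa_squared([0, 1, 0], [0, 1, 0],
                             [1, 0, 0]) == pytest.approx(1.0)

    def test_collinear_head_to_tail(self):
        assert kappa_squared([1, 0, 0], [1, 0, 0],
                             [1, 0, 0]) == pytest.approx(4.0)

    def test_crossed_dipoles(self):
        assert kappa_squared([0, 1, 0], [0, 0, 1],
                             [1, 0, 0]) == pytest.approx(0.0)

    def test_zero_separation_rejected(self):
        with pytest.raises(ValueError):
            kappa_squared([0, 1, 0], [0, 1, 0], [0, 0, 0])

    @given(st.tuples(*[st.floats(-1, 1) for _ in range(9)]))
    def test_range_zero_to_four(self, coords):
        v = np.array(coords).reshape(3, 3)
        if np.any(np.linalg.norm(v, axis=1) < 1e-3):
            return
        mu_d, mu_a = (v[0] / np.linalg.norm(v[0]),
                      v[1] / np.linalg.norm(v[1]))
        k2 = kappa_squared(mu_d, mu_a, v[2])
        assert -1e-12 <= k2 <= 4.0 + 1e-12


class TestOverlapIntegral:
    @staticmethod
    def _gauss_pair(center_d, center_a, sigma=10.0, eps=1e5):
        grid = np.arange(500.0, 800.0 + 1e-9, 0.5)
        from frlap.photophysics import SpectralModel
        em = np.exp(-0.5 * ((grid - center_d) / sigma) ** 2)
        em /= np.trapezoid(em, grid)
        ab = eps * np.exp(-0.5 * ((grid - center_a) / sigma) ** 2)
        donor = SpectralModel("alpha", grid, np.zeros_like(grid), em,
                              center_d, center_d)
        acceptor = SpectralModel("beta", grid, ab, np.zeros_like(grid),
                                 center_a, center_a)
        return donor, acceptor

    def test_disjoint_support_is_zero(self):
        donor, acceptor = self._gauss_pair(520.0, 780.0, sigma=3.0)
        assert overlap_integral(donor, acceptor) < 1e-3 * overlap_integral(
            *self._gauss_pair(650.0, 650.0, sigma=3.0))

    def test_matches_fine_grid_quadrature_oracle(self):
        """Same-centre unit Gaussians: J against brute-force trapezoidal
        quadrature at 0.01 nm."""
        donor, acceptor = self._gauss_pair(650.0, 650.0, sigma=10.0)
        fine = np.arange(550.0, 750.0, 0.01)
        em = np.exp(-0.5 * ((fine - 650.0) / 10.0) ** 2)
        em /= np.trapezoid(em, fine)
        ab = 1e5 * np.exp(-0.5 * ((fine - 650.0) / 10.0) ** 2)
        oracle = np.trapezoid(em * ab * fine ** 4, fine)
        assert overlap_integral(donor, acceptor) == pytest.approx(
            oracle, rel=1e-3)

    def test_linearity_in_extinction(self):
        d1, a1 = self._gauss_pair(650.0, 660.0, eps=1e5)
        d2, a2 = self._gauss_pair(650.0, 660.0, eps=2e5)
        assert overlap_integral(d2, a2) == pytest.approx(
            2.0 * overlap_integral(d1, a1), rel=1e-12)

    def test_grid_halving_convergence(self, spectra):
        j_half = overlap_integral(
            make_lineshape("beta", grid=np.arange(500.0, 800.0, 0.25)),
            make_lineshape("alpha", grid=np.arange(500.0, 800.0, 0.25)))
        j = overlap_integral(spectra["beta"], spectra["alpha"])
        assert abs(j - j_half) / j < 1e-3


class TestForsterRadius:
    MEDIUM = MediumParams(refractive_index=1.33, donor_quantum_yield=0.5,
                          donor_lifetime_ps=1500.0)

    def test_zero_overlap_zero_radius(self):
        assert forster_radius(0.0, 2 / 3, self.MEDIUM) == 0.0

    def test_kappa_scaling_sixth_root(self):
        r1 = forster_radius(1e15, 2 / 3, self.MEDIUM)
        r2 = forster_radius(1e15, 4 / 3, self.MEDIUM)
        assert r2 / r1 == pytest.approx(2 ** (1 / 6), rel=1e-12)

    def test_closed_form_oracle(self):
        # independent evaluation of R0 = (8.79e-5 κ² n⁻⁴ Φ J)^(1/6)
        expected = (8.79e-5 * (2 / 3) * 1.33 ** -4 * 0.5 * 1e15) ** (1 / 6)
        assert forster_radius(1e15, 2 / 3, self.MEDIUM) == pytest.approx(
            expected, rel=1e-12)
        assert expected == pytest.approx(45.91, abs=0.01)

    def test_monotonicity(self):
        base = forster_radius(1e15, 2 / 3, self.MEDIUM)
        assert forster_radius(2e15, 2 / 3, self.MEDIUM) > base
        denser = MediumParams(refractive_index=1.5,
                              donor_quantum_yield=0.5,
                              donor_lifetime_ps=1500.0)
        assert forster_radius(1e15, 2 / 3, denser) < base


class TestPairRate:
    MEDIUM = MediumParams()

    def _rate_at(self, dist, J=1e15):
        return pair_rate(np.zeros(3), [0, 1, 0], [dist, 0, 0], [0, 1, 0],
                         J, self.MEDIUM)

    def test_rate_at_forster_radius_is_inverse_lifetime(self):
        r0 = forster_radius(1e15, 1.0, self.MEDIUM)
        assert self._rate_at(r0) == pytest.approx(
            1.0 / self.MEDIUM.donor_lifetime_ps, rel=1e-10)

    def test_half_distance_64x(self):
        r0 = forster_radius(1e15, 1.0, self.MEDIUM)
        assert self._rate_at(r0 / 2) == pytest.approx(
            64.0 / self.MEDIUM.donor_lifetime_ps, rel=1e-10)

    def test_orthogonal_geometry_zero(self):
        k = pair_rate(np.zeros(3), [0, 1, 0], [30, 0, 0], [0, 0, 1],
                      1e15, self.MEDIUM)
        assert k == pytest.approx(0.0, abs=1e-15)

    def test_coincident_positions_rejected(self):
        with pytest.raises(ValueError):
            pair_rate(np.zeros(3), [0, 1, 0], np.zeros(3), [0, 1, 0],
                      1e15, self.MEDIUM)


class TestRateMatrix:
    def test_column_sums_close_mass_balance(self, lattice13, spectra):
        rm = build_rate_matrix(lattice13, spectra, decay=1 / 889.0,
                               trap={0: 0.5})
        sums = rm.K.sum(axis=0)
        assert np.allclose(sums, -(rm.decay + rm.trap), atol=1e-12)

    def test_invalid_trap_site(self, lattice13, spectra):
        with pytest.raises(ValueError):
            build_rate_matrix(lattice13, spectra, trap={99: 1.0})

    def test_fastest_rate_is_adjacent_pair_beta_to_alpha(self, calibrated):
        """The strongest channel is β→α across the ~21 Å adjacent-protomer
        pair, on the sub-picosecond scale of the measured transfer."""
        k = calibrated.rate_matrix.K.copy()
        np.fill_diagonal(k, 0.0)
        i, j = np.unravel_index(np.argmax(k), k.shape)
        donor = calibrated.lattice.sites[j]
        acceptor = calibrated.lattice.sites[i]
        assert donor.subunit_class == "beta"
        assert acceptor.subunit_class == "alpha"
        assert acceptor.protomer_index == donor.protomer_index + 1
        assert 0.5 < k[i, j] < 10.0  # ps⁻¹, ~1/500 fs scale

    def test_r_minus_6_scaling(self, lattice13, spectra):
        """Doubling all coordinates scales every transfer rate by 2⁻⁶."""
        from dataclasses import replace
        scaled_pl = replace(
            lattice13.placement,
            alpha_radius=2 * lattice13.placement.alpha_radius,
            beta_radius=2 * lattice13.placement.beta_radius,
            alpha_offset_z=2 * lattice13.placement.alpha_offset_z,
            beta_offset_z=2 * lattice13.placement.beta_offset_z)
        scaled_h = replace(lattice13.helix,
                           rise_per_repeat=2 * 72.6)
        big = frlap.build_nanotube(scaled_h, scaled_pl, 13)
        k1 = build_rate_matrix(lattice13, spectra).K
        k2 = build_rate_matrix(big, spectra).K
        off = ~np.eye(26, dtype=bool)
        assert np.allclose(k2[off], k1[off] / 64.0, rtol=1e-9)

    def test_forward_backward_ratio_is_overlap_ratio(self, lattice13,
                                                     spectra):
        """k(β→α)/k(α→β) for any pair equals J(β→α)/J(α→β): same κ² and
        distance, no hidden asymmetry."""
        rm = build_rate_matrix(lattice13, spectra)
        j_ba = overlap_integral(spectra["beta"], spectra["alpha"])
        j_ab = overlap_integral(spectra["alpha"], spectra["beta"])
        a6 = lattice13.site(6, "alpha").site_id
        b5 = lattice13.site(5, "beta").site_id
        assert rm.K[a6, b5] / rm.K[b5, a6] == pytest.approx(
            j_ba / j_ab, rel=1e-9)

    def test_distance_cutoff_drops_far_pairs(self, lattice13, spectra):
        rm = build_rate_matrix(lattice13, spectra, distance_cutoff=30.0)
        d = frlap.pairwise_distances(lattice13)
        off = ~np.eye(26, dtype=bool)
        assert np.all(rm.K[off][d[off] > 30.0] == 0.0)

    def test_subnetwork_mass_balance(self, calibrated):
        alpha = calibrated.lattice.alpha_indices()
        sub = calibrated.rate_matrix.subnetwork(alpha)
        assert np.allclose(sub.K.sum(axis=0), -(sub.decay + sub.trap),
                           atol=1e-12)
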