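"""Master-equation propagation, multi-exponential fits, trapping
efficiency, first-passage times and the Monte-Carlo cross-check."""

import numpy as np
import pytest

import frlap
from frlap.dynamics import (decayed_fraction, default_time_grid,
                            fit_multiexponential, kinetic_monte_carlo,
                            mean_first_passage_time, propagate,
                            trapping_efficiency)
from frlap.photophysics import RateMatrix


def make_rm(K, decay=None, trap=None):
    n = K.shape[0]
    decay = np.zeros(n) if decay is None else np.asarray(decay, float)
    trap = np.zeros(n) if trap is None else np.asarray(trap, float)
    K = K.astype(float).copy()
    np.fill_diagonal(K, 0.0)
    np.fill_diagonal(K, -(K.sum(axis=0) + decay + trap))
    return RateMatrix(K=K, site_ids=np.arange(n), decay=decay, trap=trap)


def random_rm(n, seed, decay_scale=0.01):
    rng = np.random.default_rng(seed)
    K = rng.random((n, n)) * 0.5
    decay = rng.random(n) * decay_scale
    trap = np.zeros(n)
    trap[rng.integers(n)] = 0.3
    return make_rm(K, decay, trap)


class TestPropagate:
    def test_single_site_decay_closed_form(self):
        kd = 0.37
        rm = make_rm(np.zeros((1, 1)), decay=[kd])
        t = np.linspace(0.0, 20.0, 101)
        traj = propagate(rm, [1.0], t)
        assert np.allclose(traj.populations[:, 0], np.exp(-kd * t),
                           atol=1e-9)
        assert np.allclose(traj.decayed, 1 - np.exp(-kd * t), atol=1e-9)

    def test_two_site_cascade_closed_form(self):
        """Irreversible transfer k then decay kd: Bateman two-compartment
        solution."""
        k, kd = 2.0, 0.05
        K = np.array([[0.0, 0.0], [k, 0.0]])
        rm = make_rm(K, decay=[0.0, kd])
        t = np.geomspace(1e-3, 50.0, 200)
        traj = propagate(rm, [1.0, 0.0], t)
        p1 = np.exp(-k * t)
        p2 = k / (kd - k) * (np.exp(-k * t) - np.exp(-kd * t))
        assert np.allclose(traj.populations[:, 0], p1, atol=1e-9)
        assert np.allclose(traj.populations[:, 1], p2, atol=1e-9)

    def test_mass_balance_on_calibrated_network(self, calibrated):
        traj = propagate(calibrated.trapped_network(),
                         calibrated.uniform_beta_p0())
        assert np.allclose(traj.total, 1.0, atol=1e-9)

    def test_populations_non_negative(self, calibrated):
        traj = propagate(calibrated.rate_matrix,
                         calibrated.uniform_beta_p0())
        assert traj.populations.min() > -1e-10

    def test_matches_matrix_exponential(self):
        from scipy.linalg import expm
        rm = random_rm(20, seed=5)
        t = np.array([0.3, 3.0, 30.0])
        traj = propagate(rm, np.full(20, 1 / 20), t)
        for i, ti in enumerate(t):
            direct = expm(rm.K * ti) @ np.full(20, 1 / 20)
            assert np.allclose(traj.populations[i], direct, atol=1e-8)

    def test_rejects_bad_inputs(self):
        rm = make_rm(np.zeros((1, 1)), decay=[0.1])
        with pytest.raises(ValueError):
            propagate(rm, [-0.5])
        bad = make_rm(np.zeros((1, 1)), decay=[0.1])
        bad.K[0, 0] = np.nan
        with pytest.raises(ValueError):
            propagate(bad, [1.0])


class TestMultiExpFit:
    def test_single_exponential_exact(self):
        t = np.geomspace(0.1, 1000.0, 200)
        trace = 0.8 * np.exp(-t / 100.0)
        fit = fit_multiexponential(t, trace, 1)
        assert fit.lifetimes_ps[0] == pytest.approx(100.0, rel=1e-4)
        assert fit.amplitudes[0] == pytest.approx(0.8, rel=1e-4)

    def test_biexponential_12_to_1(self):
        t = np.geomspace(1e-2, 500.0, 400)
        trace = (12 / 13) * np.exp(-t / 0.5) + (1 / 13) * np.exp(-t / 40.0)
        fit = fit_multiexponential(t, trace, 2,
                                   initial_lifetimes=np.array([0.2, 10.0]))
        assert fit.lifetimes_ps[0] == pytest.approx(0.5, rel=1e-3)
        assert fit.lifetimes_ps[1] == pytest.approx(40.0, rel=1e-3)
        assert fit.amplitudes[0] / fit.amplitudes[1] == pytest.approx(
            12.0, rel=1e-3)

    def test_fixed_lifetime_honoured_exactly(self):
        t = np.geomspace(1e-2, 5000.0, 300)
        trace = np.exp(-t / 0.5) + 0.1 * np.exp(-t / 889.0)
        fit = fit_multiexponential(t, trace, 2,
                                   fixed_lifetimes={1: 889.0},
                                   initial_lifetimes=np.array([1.0, 889.0]))
        assert fit.lifetimes_ps[1] == 889.0
        assert fit.fixed[1]

    def test_too_few_points_rejected(self):
        with pytest.raises(ValueError):
            fit_multiexponential(np.arange(5.0), np.ones(5), 2)


class TestTrappingEfficiency:
    def test_trap_only_exit_is_unity(self):
        rm = make_rm(np.array([[0.0, 0.1], [0.2, 0.0]]),
                     trap=[0.5, 0.0])
        assert trapping_efficiency(rm, [0.5, 0.5]) == pytest.approx(1.0)

    def test_single_site_branching_ratio(self):
        kt, kd = 0.3, 0.7
        rm = make_rm(np.zeros((1, 1)), decay=[kd], trap=[kt])
        assert trapping_efficiency(rm, [1.0]) == pytest.approx(
            kt / (kt + kd), rel=1e-12)

    def test_efficiency_plus_decay_is_unity(self):
        rm = random_rm(8, seed=3)
        p0 = np.full(8, 1 / 8)
        assert trapping_efficiency(rm, p0) + decayed_fraction(
            rm, p0) == pytest.approx(1.0, abs=1e-9)

    def test_requires_trap_channel(self):
        rm = make_rm(np.array([[0.0, 0.1], [0.2, 0.0]]), decay=[0.1, 0.1])
        with pytest.raises(ValueError):
            trapping_efficiency(rm, [1.0, 0.0])

    def test_matches_kinetic_monte_carlo_random_network(self):
        rm = random_rm(10, seed=11)
        p0 = np.full(10, 0.1)
        analytic = trapping_efficiency(rm, p0)
        mc = kinetic_monte_carlo(rm, p0, n_traj=30_000, seed=4)
        assert abs(mc.efficiency - analytic) < 3 * mc.std_error


class TestMFPT:
    def test_two_site_single_hop(self):
        rm = make_rm(np.array([[0.0, 0.0], [0.25, 0.0]]))
        assert mean_first_passage_time(rm, 0, [1]) == pytest.approx(4.0)

    def test_irreversible_chain_sums_stage_means(self):
        """Uniform 1-D chain of m irreversible hops: MFPT = m/k."""
        m, k = 6, 0.5
        K = np.zeros((m + 1, m + 1))
        for i in range(m):
            K[i + 1, i] = k
        rm = make_rm(K)
        assert mean_first_passage_time(rm, 0, [m]) == pytest.approx(m / k)

    def test_source_in_target_set(self):
        rm = make_rm(np.array([[0.0, 0.1], [0.1, 0.0]]))
        assert mean_first_passage_time(rm, 1, [1]) == 0.0

    def test_unreachable_target_flagged_infinite(self):
        K = np.zeros((3, 3))
        K[1, 0] = 0.3  # 0→1 only; site 2 unreachable
        rm = make_rm(K)
        assert mean_first_passage_time(rm, 0, [2]) == np.inf

    def test_monotone_in_nanotube_length(self, calibrated):
        """End-to-end migration time grows with protomer count (same
        calibrated rate prefactor throughout)."""
        from frlap.photophysics import build_rate_matrix
        from frlap.calibration import terminal_site_ids
        times = []
        for n in (5, 9, 13, 20):
            lat = frlap.build_nanotube(n_protomers=n)
            rm = build_rate_matrix(lat, calibrated.spectra,
                                   calibrated.medium,
                                   prefactor=calibrated.prefactor)
            ids = terminal_site_ids(lat)
            pair = [lat.site(1, "alpha").site_id,
                    lat.site(0, "beta").site_id]
            times.append(mean_first_passage_time(rm, ids["beta"], pair))
        assert times == sorted(times)

    def test_rate_rescaling_inverse_scales_mfpt(self, calibrated):
        rm = calibrated.rate_matrix.transfer_only()
        t1 = mean_first_passage_time(rm, 25, [1, 2])
        scaled = RateMatrix(K=3.0 * rm.K, site_ids=rm.site_ids,
                            decay=rm.decay, trap=rm.trap)
        t3 = mean_first_passage_time(scaled, 25, [1, 2])
        assert t3 == pytest.approx(t1 / 3.0, rel=1e-9)


class TestKineticMonteCarlo:
    def test_single_site_all_exit_via_trap(self):
        rm = make_rm(np.zeros((1, 1)), trap=[0.4])
        mc = kinetic_monte_carlo(rm, [1.0], n_traj=500, seed=1)
        assert mc.exit_counts == {"decay": 0, "trap": 500}

    def test_fair_coin_branching(self):
        rm = make_rm(np.zeros((1, 1)), decay=[0.2], trap=[0.2])
        mc = kinetic_monte_carlo(rm, [1.0], n_traj=100_000, seed=2)
        assert abs(mc.efficiency - 0.5) < 3 * mc.std_error

    def test_seed_reproducibility(self):
        rm = random_rm(6, seed=9)
        p0 = np.full(6, 1 / 6)
        a = kinetic_monte_carlo(rm, p0, n_traj=2000, seed=77)
        b = kinetic_monte_carlo(rm, p0, n_traj=2000, seed=77)
        assert a.efficiency == b.efficiency
        assert a.exit_counts == b.exit_counts

    def test_efficiency_invariant_under_global_rate_scaling(self):
        rm = random_rm(6, seed=13)
        p0 = np.full(6, 1 / 6)
        scaled = RateMatrix(K=5.0 * rm.K, site_ids=rm.site_ids,
                            decay=5.0 * rm.decay, trap=5.0 * rm.trap)
        assert trapping_efficiency(scaled, p0) == pytest.approx(
            trapping_efficiency(rm, p0), rel=1e-10)
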