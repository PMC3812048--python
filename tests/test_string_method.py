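import numpy as np
import pytest

from pmfkit.constants import kt
from pmfkit.landscape import (ConfinementWall, GaussianWell, LangevinSettings,
                              ModelPotential)
from pmfkit.string_method import (ConvergenceMetrics, PathImage, SteeringError,
                                  SwarmSettings, TransitionString,
                                  convergence_metrics, cv_rmsd,
                                  distance_to_path, iterate_string,
                                  read_string_checkpoint, relax_to_cv,
                                  reparametrize, reparametrize_cvs, steer_path,
                                  subsample_to_images, swarm_drift,
                                  tail_averaged_cvs, write_string_checkpoint,
                                  zero_temperature_string)


def harmonic_valley(k=4.0):
    # U = 1/2 k y^2, flat along x: valley floor is the x axis
    return ModelPotential(np.array([[-5.0, -5.0], [5.0, 5.0]]),
                          wall=ConfinementWall((0.0, 0.0),
                                               (5.0, np.sqrt(2.0 / k)),
                                               amplitude=1.0, exponent=2))


def straight_string(n=9, lo=(-1.0, 0.0), hi=(1.0, 0.0)):
    cvs = np.linspace(lo, hi, n)
    return TransitionString([PathImage(i, cv) for i, cv in enumerate(cvs)])


class TestSteerPath:
    def test_start_within_stop_rmsd_terminates_immediately(self, flat_potential):
        s = LangevinSettings(n_steps=10, diffusion_coefficient=0.001, seed=0)
        result = steer_path((0.0, 0.0), (0.01, 0.0), flat_potential, s,
                            speed=0.001, stop_rmsd=0.02)
        assert len(result.trajectory) == 1 and result.string is None

    def test_flat_potential_reaches_stop_rmsd(self, flat_potential):
        s = LangevinSettings(diffusion_coefficient=0.0005, seed=1)
        result = steer_path((-2.0, 0.0), (2.0, 1.0), flat_potential, s,
                            speed=0.001, stop_rmsd=0.02)
        assert cv_rmsd(result.trajectory[-1], (2.0, 1.0)) <= 0.02
        assert result.string is not None and len(result.string) >= 3

    def test_ramp_schedule_is_monotone_and_linear(self, flat_potential):
        # the target-RMSD schedule is the closed-form decreasing ramp
        s = LangevinSettings(diffusion_coefficient=0.0005, seed=2)
        start, target = np.array([-1.5, 0.0]), np.array([1.5, 0.0])
        r0 = cv_rmsd(start, target)
        speed = 0.002
        result = steer_path(start, target, flat_potential, s, speed=speed,
                            stop_rmsd=0.02)
        steps = np.arange(len(result.schedule))
        ramp = np.maximum(r0 - speed * steps, 0.0)
        assert np.all(np.diff(result.schedule) <= 0)
        assert np.allclose(result.schedule, ramp, atol=1e-12)

    def test_nonconvergence_raises_with_final_rmsd(self, flat_potential):
        s = LangevinSettings(diffusion_coefficient=0.0005, seed=3)
        with pytest.raises(SteeringError, match="final RMSD"):
            steer_path((-2.0, 0.0), (2.0, 0.0), flat_potential, s,
                       speed=1e-5, stop_rmsd=0.001, max_steps=100)


class TestSubsample:
    def test_straight_line_one_angstrom_gives_at_least_six(self):
        # cv-rmsd length of the diagonal x=y line: 1.0
        t = np.linspace([0.0, 0.0], [1.0, 1.0], 200)
        string = subsample_to_images(t, max_adjacent_rmsd=0.2)
        assert len(string) >= 6
        assert np.allclose(string.images[0].cv_values, t[0])
        assert np.allclose(string.images[-1].cv_values, t[-1])

    def test_mean_adjacent_rmsd_below_threshold(self):
        rng = np.random.default_rng(5)
        walk = np.cumsum(rng.normal(0, 0.05, size=(300, 2)), axis=0)
        string = subsample_to_images(walk, max_adjacent_rmsd=0.2)
        cvs = string.cv_array()
        adj = [cv_rmsd(cvs[i], cvs[i + 1]) for i in range(len(cvs) - 1)]
        assert np.mean(adj) < 0.2

    def test_short_trajectory_rejected(self):
        with pytest.raises(ValueError):
            subsample_to_images(np.zeros((1, 2)))


class TestSwarmDrift:
    def test_zero_diffusion_at_minimum_zero_drift(self):
        pot = ModelPotential(np.array([[-3.0, -3.0], [3.0, 3.0]]),
                             basins=[GaussianWell((0.0, 0.0), 2.0, (1.0, 1.0))])
        image = PathImage(0, (0.0, 0.0))
        s = LangevinSettings(diffusion_coefficient=0.0, seed=0)
        drift = swarm_drift(image, pot, SwarmSettings(10, 20, 10), s, seed=0)
        assert np.allclose(drift, 0.0)

    def test_harmonic_drift_matches_discrete_closed_form(self):
        # E[x_t] = x0 (1 - a)^t exactly for the Euler-Maruyama chain
        k = 2.0
        pot = harmonic_valley(k)
        x0 = np.array([0.0, 1.0])
        s = LangevinSettings(diffusion_coefficient=0.002, seed=4)
        steps = 50
        n_traj = 400
        drift = swarm_drift(PathImage(0, x0), pot,
                            SwarmSettings(n_traj, steps, 10), s, seed=4)
        a = s.diffusion_coefficient * k / kt()
        expected = x0[1] * ((1 - a) ** steps - 1)
        # SE of the mean displacement
        var = 2 * s.diffusion_coefficient * steps
        se = np.sqrt(var / n_traj)
        assert abs(drift[1] - expected) < 3 * se
        assert abs(drift[0]) < 3 * se

    def test_same_seed_identical_drift(self, cycle_potential):
        image = PathImage(3, (7.0, -5.0))
        s = LangevinSettings(diffusion_coefficient=0.002, seed=9)
        d1 = swarm_drift(image, cycle_potential, SwarmSettings(20, 30, 10), s, 9)
        d2 = swarm_drift(image, cycle_potential, SwarmSettings(20, 30, 10), s, 9)
        assert np.array_equal(d1, d2)


class TestRelax:
    def test_target_equals_current_stays_put_in_expectation(self):
        pot = harmonic_valley()
        s = LangevinSettings(diffusion_coefficient=0.002, seed=1)
        finals = [relax_to_cv((0.5, 0.0), (0.5, 0.0), pot, 2000, 40.0,
                              s, rng=np.random.default_rng(i))
                  for i in range(40)]
        mean = np.mean(finals, axis=0)
        assert np.allclose(mean, (0.5, 0.0), atol=0.06)

    def test_stationary_spread_sqrt_kt_over_k(self, flat_potential):
        k = 40.0
        s = LangevinSettings(diffusion_coefficient=0.005, seed=2)
        finals = np.array([relax_to_cv((0.0, 0.0), (0.0, 0.0), flat_potential,
                                       600, k, s, rng=np.random.default_rng(i))
                           for i in range(300)])
        spread = finals.std(axis=0)
        expected = np.sqrt(kt() / k)   # ~0.12 A
        assert np.allclose(spread, expected, rtol=0.2)

    def test_quadrupled_k_halves_spread(self, flat_potential):
        # keep beta*D*k*dt << 1 so the discrete chain tracks the continuum law
        s = LangevinSettings(diffusion_coefficient=0.001, seed=3)

        def spread(k):
            finals = np.array([relax_to_cv((0.0, 0.0), (0.0, 0.0),
                                           flat_potential, 600, k, s,
                                           rng=np.random.default_rng(1000 + i))
                               for i in range(300)])
            return finals.std(axis=0).mean()

        assert spread(40.0) / spread(160.0) == pytest.approx(2.0, rel=0.2)


class TestReparametrize:
    def test_already_equidistant_unchanged(self):
        string = straight_string(7)
        out = reparametrize(string)
        assert np.allclose(out.cv_array(), string.cv_array(), atol=1e-12)

    def test_three_collinear_images_middle_to_half(self):
        cvs = np.array([[0.0, 0.0], [0.9, 0.0], [1.0, 0.0]])
        out = reparametrize_cvs(cvs)
        assert np.allclose(out[1], [0.5, 0.0], atol=1e-12)

    def test_quarter_circle_matches_arc_length_oracle(self):
        rng = np.random.default_rng(6)
        t = np.sort(np.concatenate([[0, np.pi / 2], rng.uniform(0, np.pi / 2, 18)]))
        pts = np.stack([np.cos(t), np.sin(t)], axis=1)
        out = reparametrize_cvs(pts)
        adj = np.linalg.norm(np.diff(out, axis=0), axis=1)
        assert adj.std() / adj.mean() < 1e-9
        # independent oracle: brute-force bisection for the equal-chord
        # positions on the same polyline
        seg = np.linalg.norm(np.diff(pts, axis=0), axis=1)
        arc = np.concatenate([[0], np.cumsum(seg)])

        def point_at(s):
            return np.array([np.interp(s, arc, pts[:, 0]),
                             np.interp(s, arc, pts[:, 1])])

        def chords_for(L):
            # walk the polyline placing points a chord L apart; return end gap
            s, positions = 0.0, [pts[0]]
            for _ in range(len(pts) - 1):
                lo, hi = s, arc[-1]
                for _ in range(80):  # bisect for next arc position
                    mid = 0.5 * (lo + hi)
                    if np.linalg.norm(point_at(mid) - positions[-1]) < L:
                        lo = mid
                    else:
                        hi = mid
                s = 0.5 * (lo + hi)
                positions.append(point_at(s))
            return np.array(positions)

        lo, hi = 0.0, arc[-1]
        for _ in range(60):  # bisect on the common chord length
            L = 0.5 * (lo + hi)
            end = chords_for(L)[-1]
            if np.linalg.norm(end - pts[0]) < np.linalg.norm(pts[-1] - pts[0]):
                lo = L
            else:
                hi = L
        oracle = chords_for(0.5 * (lo + hi))
        assert np.allclose(out, oracle, atol=1e-6)

    def test_idempotent(self):
        rng = np.random.default_rng(7)
        pts = np.cumsum(rng.normal(0, 0.3, size=(15, 2)), axis=0)
        once = reparametrize_cvs(pts)
        twice = reparametrize_cvs(once)
        assert np.allclose(once, twice, atol=1e-12)

    def test_duplicates_collapsed_then_proceed(self):
        cvs = np.array([[0.0, 0.0], [0.0, 0.0], [1.0, 0.0], [2.0, 0.0]])
        out = reparametrize_cvs(cvs)
        adj = np.linalg.norm(np.diff(out, axis=0), axis=1)
        assert np.allclose(adj, adj[0])

    def test_zero_arc_length_rejected(self):
        with pytest.raises(ValueError):
            reparametrize_cvs(np.zeros((4, 2)))


class TestIterateString:
    def test_zero_iterations_returns_input(self, cycle_potential):
        string = straight_string(5, (5.5, 0.0), (10.0, -5.0))
        s = LangevinSettings(diffusion_coefficient=0.002, seed=0)
        out = iterate_string(string, cycle_potential, SwarmSettings(5, 10, 10),
                             s, 0, seed=0)
        assert np.array_equal(out.cv_array(), string.cv_array())

    def test_endpoints_bit_identical(self, three_well_potential):
        a, b = three_well_potential.meta["endpoints"]
        string = straight_string(9, a, b)
        s = LangevinSettings(diffusion_coefficient=0.002, seed=5)
        out = iterate_string(string, three_well_potential,
                             SwarmSettings(10, 20, 100), s, 5, seed=5)
        assert np.array_equal(out.cv_array()[0], np.asarray(a, float))
        assert np.array_equal(out.cv_array()[-1], np.asarray(b, float))

    def test_zero_diffusion_equidistant_on_flat_is_invariant(self, flat_potential):
        string = straight_string(7, (-1.0, -1.0), (1.0, 1.0))
        s = LangevinSettings(diffusion_coefficient=0.0, seed=0)
        out = iterate_string(string, flat_potential, SwarmSettings(3, 5, 5),
                             s, 3, seed=0)
        assert np.allclose(out.cv_array(), string.cv_array(), atol=1e-12)

    def test_string_on_valley_floor_stays_near_floor(self):
        pot = harmonic_valley(k=4.0)
        string = straight_string(9, (-2.0, 0.0), (2.0, 0.0))
        s = LangevinSettings(diffusion_coefficient=0.002, seed=6)
        out = iterate_string(string, pot, SwarmSettings(100, 20, 400), s,
                             10, seed=6)
        # valley floor is y = 0; images fluctuate within the relax spread
        y = out.cv_array()[:, 1]
        assert np.abs(y).max() < 2 * np.sqrt(kt() / 40.0) + 0.1

    def test_converges_to_steepest_descent_mfep(self, three_well_potential):
        a, b = three_well_potential.meta["endpoints"]
        oracle = zero_temperature_string(three_well_potential, a, b,
                                         n_images=151, step=2e-3)
        string = straight_string(21, a, b)
        s = LangevinSettings(diffusion_coefficient=0.0015, seed=7)
        out = iterate_string(string, three_well_potential,
                             SwarmSettings(60, 50, 1000), s, 25, seed=7)
        d = distance_to_path(out.cv_array(), oracle)
        assert d.mean() < 0.15

    def test_history_grows_per_iteration(self, flat_potential):
        string = straight_string(5)
        s = LangevinSettings(diffusion_coefficient=0.001, seed=8)
        out = iterate_string(string, flat_potential, SwarmSettings(3, 5, 5),
                             s, 4, seed=8)
        assert len(out.history) == 5
        assert out.iteration == 4


class TestConvergenceMetrics:
    def test_constant_history_all_zero_plateau(self):
        from pmfkit.fixtures import make_string_history
        hist = make_string_history("frozen", n_iterations=12)
        m = convergence_metrics(hist)
        assert np.allclose(m.rmsd_to_initial, 0.0)
        assert np.allclose(m.rmsd_to_lag[4:], 0.0)
        assert np.isnan(m.rmsd_to_lag[:4]).all()
        assert m.plateau

    def test_drift_then_freeze_lag_drops_to_zero(self):
        from pmfkit.fixtures import make_string_history
        hist = make_string_history("drift-then-freeze", n_iterations=20,
                                   freeze_after=8, drift_per_iter=0.1)
        m = convergence_metrics(hist)
        # lag-4 metric reads 0 from iteration freeze+4 onward
        assert np.allclose(m.rmsd_to_lag[12:], 0.0, atol=1e-12)
        assert m.rmsd_to_lag[8] > 0
        assert m.plateau

    def test_noisy_plateau_level(self):
        from pmfkit.fixtures import make_string_history
        amp = 0.05
        hist = make_string_history("noisy", n_iterations=400, amplitude=amp,
                                   n_images=40, seed=3)
        m = convergence_metrics(hist)
        level = np.nanmean(m.rmsd_to_lag[4:])
        # iid snapshots, d=2 components: per-image rmsd is amp*sqrt(2) times
        # a chi_2/sqrt(2) variate with mean sqrt(pi)/2
        expected = amp * np.sqrt(2) * np.sqrt(np.pi) / 2
        assert level == pytest.approx(expected, rel=0.05)
        assert level == pytest.approx(amp * np.sqrt(2), rel=0.2)

    def test_metrics_match_independent_recomputation(self, flat_potential):
        string = straight_string(5)
        s = LangevinSettings(diffusion_coefficient=0.002, seed=9)
        out = iterate_string(string, flat_potential, SwarmSettings(4, 5, 5),
                             s, 6, seed=9)
        m = convergence_metrics(out.history)
        for i, snap in enumerate(out.history):
            manual = np.mean([cv_rmsd(x, y)
                              for x, y in zip(snap, out.history[0])])
            assert m.rmsd_to_initial[i] == pytest.approx(manual)

    def test_empty_history_rejected(self):
        with pytest.raises(ValueError):
            convergence_metrics([])


class TestCheckpointIO:
    def test_roundtrip_exact(self, flat_potential):
        string = straight_string(5)
        s = LangevinSettings(diffusion_coefficient=0.002, seed=10)
        out = iterate_string(string, flat_potential, SwarmSettings(3, 5, 5),
                             s, 3, seed=10)
        path = "scratch_checkpoint.txt"
        import os
        try:
            write_string_checkpoint(out, path)
            back = read_string_checkpoint(path)
            assert len(back.history) == len(out.history)
            for a, b in zip(back.history, out.history):
                assert np.array_equal(a, b)
        finally:
            os.unlink(path)


class TestOracleHelpers:
    def test_zero_t_string_follows_quadratic_valley(self):
        pot = harmonic_valley(k=4.0)
        path = zero_temperature_string(pot, (-2.0, 1.0), (2.0, -1.0),
                                       n_images=51, step=5e-3)
        # fixed off-floor endpoints: the middle of the path hugs y = 0
        n = len(path)
        assert np.abs(path[n // 3:2 * n // 3, 1]).max() < 0.05

    def test_distance_to_path_simple(self):
        path = np.array([[0.0, 0.0], [1.0, 0.0]])
        d = distance_to_path(np.array([[0.5, 0.3], [2.0, 0.0]]), path)
        assert np.allclose(d, [0.3, 1.0])

    def test_tail_average(self):
        hist = [np.full((3, 2), v) for v in (0.0, 1.0, 2.0, 3.0)]
        assert np.allclose(tail_averaged_cvs(hist, 2), 2.5)
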