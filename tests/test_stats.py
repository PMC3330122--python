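"""Trajectory and segregation statistics against closed-form oracles."""

import itertools
import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from termd.insulation import MobilityClass
from termd.simulate import (DEFAULT_MOTION, MotionParams, SimConfig,
                            simulate_trajectories)
from termd.stats import (Trajectory, apparent_diffusion, coloc_index,
                         interfocal_stats, mobility_comparison, msd_curve,
                         summarize_group, travelled_distance,
                         trajectory_stats)


def make_traj(xy, dt=10.0, poles=None):
    xy = np.asarray(xy, dtype=float)
    return Trajectory("L", "c", np.arange(len(xy)) * dt, xy[:, 0], xy[:, 1],
                      poles=poles)


class TestTravelledDistance:
    def test_static_trajectory_travels_zero(self):
        assert travelled_distance(make_traj([[1, 1]] * 31)) == 0.0

    def test_straight_line_steps(self):
        xy = [[0.1 * i, 0.0] for i in range(31)]
        assert travelled_distance(make_traj(xy)) == pytest.approx(3.0)

    def test_free_motion_matches_rayleigh_closed_form(self):
        # 30 steps of mean sqrt(pi D dt): 300-trajectory average within 3 SE
        D, dt = 1e-3, 10.0
        trajs = simulate_trajectories(
            MotionParams(D=D, r_c=None, sigma_loc=0.0),
            SimConfig(dt=dt), n=300, seed=42)
        td = np.array([travelled_distance(t) for t in trajs])
        expect = 30 * math.sqrt(math.pi * D * dt)
        se = td.std(ddof=1) / math.sqrt(td.size)
        assert abs(td.mean() - expect) < 3 * se

    def test_fewer_than_two_frames_rejected(self):
        with pytest.raises(ValueError):
            Trajectory("L", "c", [0.0], [0.0], [0.0])

    def test_non_uniform_interval_warns_but_computes(self):
        tr = Trajectory("L", "c", [0, 10, 25], [0, 1, 1], [0, 0, 0])
        with pytest.warns(UserWarning, match="non-uniform"):
            assert travelled_distance(tr) == pytest.approx(1.0)

    @settings(max_examples=30, deadline=None, derandomize=True)
    @given(st.lists(st.tuples(st.floats(-5, 5), st.floats(-5, 5)),
                    min_size=2, max_size=20),
           st.floats(-10, 10), st.floats(-10, 10),
           st.floats(0, 2 * math.pi))
    def test_invariant_under_rigid_motion(self, pts, dx, dy, theta):
        xy = np.asarray(pts)
        c, s = math.cos(theta), math.sin(theta)
        rot = xy @ np.array([[c, -s], [s, c]]).T + [dx, dy]
        d0 = travelled_distance(make_traj(xy))
        d1 = travelled_distance(make_traj(rot))
        assert d1 == pytest.approx(d0, rel=1e-9, abs=1e-9)

    @settings(max_examples=30, deadline=None, derandomize=True)
    @given(st.lists(st.tuples(st.floats(-5, 5), st.floats(-5, 5)),
                    min_size=2, max_size=20))
    def test_at_least_net_displacement(self, pts):
        xy = np.asarray(pts)
        net = float(np.hypot(*(xy[-1] - xy[0])))
        assert travelled_distance(make_traj(xy)) >= net - 1e-9

    def test_cell_frame_removes_rigid_drift(self):
        # focus fixed relative to a drifting, rotating cell
        n = 20
        t = np.arange(n) * 10.0
        theta = np.linspace(0, np.pi / 3, n)
        p1 = np.column_stack([t * 0.01, t * 0.02])
        axis = np.column_stack([np.cos(theta), np.sin(theta)]) * 3.0
        p2 = p1 + axis
        focus = p1 + axis * 0.25
        tr = Trajectory("L", "c", t, focus[:, 0], focus[:, 1],
                        poles=np.hstack([p1, p2]))
        assert travelled_distance(tr) > 0.1       # lab frame sees the drift
        assert travelled_distance(tr, frame="cell") < 1e-9


class TestMsdAndApparentDiffusion:
    def test_static_trajectory(self):
        tr = make_traj([[2, 3]] * 31)
        msd = msd_curve(tr)
        assert msd[0] == (0.0, 0.0)
        assert all(v == 0 for _, v in msd)
        D, b, _ = apparent_diffusion(tr)
        assert D == 0.0 and b == pytest.approx(0.0)

    def test_recovers_simulation_parameter_within_ten_percent(self):
        D, dt = 1e-3, 10.0
        trajs = simulate_trajectories(
            MotionParams(D=D, r_c=None, sigma_loc=0.04),
            SimConfig(dt=dt), n=100, seed=21)
        curves = [msd_curve(t, max_lag=4) for t in trajs]
        avg = [(k * dt, float(np.mean([c[k][1] for c in curves])))
               for k in range(5)]
        D_fit, _, _ = apparent_diffusion(avg)
        assert D_fit == pytest.approx(D, rel=0.10)

    def test_pure_noise_gives_zero_slope_and_noise_floor_intercept(self):
        sigma = 0.05
        trajs = simulate_trajectories(
            MotionParams(D=0.0, r_c=None, sigma_loc=sigma),
            SimConfig(), n=400, seed=33)
        curves = [msd_curve(t, max_lag=4) for t in trajs]
        avg = [(k * 10.0, float(np.mean([c[k][1] for c in curves])))
               for k in range(5)]
        D_fit, intercept, _ = apparent_diffusion(avg)
        assert abs(D_fit) < 2e-6
        assert intercept == pytest.approx(4 * sigma ** 2, rel=0.15)

    def test_single_lag_fit_rejected(self):
        tr = make_traj([[0, 0], [1, 0], [2, 0]])
        with pytest.raises(ValueError):
            apparent_diffusion(tr, fit_lags=1)


class TestGroupSummary:
    def test_constant_group(self):
        g = summarize_group([2.0] * 30)
        assert (g.n, g.mean, g.sd) == (30, 2.0, 0.0)

    def test_one_two_three(self):
        g = summarize_group([1.0, 2.0, 3.0], expected_n=3)
        assert g.mean == 2.0 and g.sd == pytest.approx(1.0)

    def test_warns_off_convention_count(self):
        with pytest.warns(UserWarning, match="convention"):
            summarize_group([1.0, 2.0], expected_n=30)

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            summarize_group([])

    @settings(max_examples=30, deadline=None, derandomize=True)
    @given(st.lists(st.floats(0, 10), min_size=2, max_size=50))
    def test_matches_direct_formulas(self, vals):
        g = summarize_group(vals, expected_n=0)
        arr = np.array(vals)
        assert g.mean == pytest.approx(arr.mean())
        assert g.sd == pytest.approx(arr.std(ddof=1), abs=1e-12)


class TestColocIndex:
    def test_equal_counts_give_zero(self):
        assert coloc_index(2.5, 2.5) == 0.0

    def test_half_merged(self):
        assert coloc_index(2.0, 1.0) == 0.5

    def test_invalid_inputs_rejected(self):
        with pytest.raises(ValueError):
            coloc_index(0.0, 1.0)
        with pytest.raises(ValueError):
            coloc_index(2.0, -0.1)

    @settings(max_examples=50, deadline=None, derandomize=True)
    @given(st.floats(0.1, 10), st.floats(0, 10))
    def test_normalization_identity(self, nb_th, nb_obs):
        assert coloc_index(nb_th, nb_obs) + nb_obs / nb_th == \
            pytest.approx(1.0, abs=1e-12)
        assert coloc_index(nb_th, nb_obs) <= 1.0


class TestInterfocal:
    def test_identical_positions(self):
        r = interfocal_stats([((0, 0), (0, 0))] * 5)
        assert r.fraction_below_0p4 == 1.0 and r.fraction_above_0p3 == 0.0

    def test_distant_pairs(self):
        r = interfocal_stats([((0, 0), (1, 0))] * 5)
        assert r.fraction_below_0p4 == 0.0 and r.fraction_above_0p3 == 1.0

    def test_matches_brute_force_distances(self):
        rng = np.random.default_rng(0)
        pairs = [((a, b), (c, d)) for a, b, c, d in rng.normal(size=(50, 4))]
        r = interfocal_stats(pairs)
        brute = np.array([math.hypot(a[0] - b[0], a[1] - b[1])
                          for a, b in pairs])
        assert np.allclose(np.sort(r.distances), np.sort(brute))
        assert r.counts.sum() == 50
        assert r.fraction_below_0p4 == pytest.approx((brute < 0.4).mean())


class TestMobilityComparison:
    def test_identical_groups(self):
        r = mobility_comparison([1.0, 1.0, 1.0], [1.0, 1.0, 1.0])
        assert r["ratio"] == 1.0 and r["p_value"] == 1.0

    def test_free_vs_constrained_simulated_defaults(self):
        cfg = SimConfig()
        free = [travelled_distance(t) for t in simulate_trajectories(
            DEFAULT_MOTION[MobilityClass.FREE], cfg, n=30, seed=1)]
        cons = [travelled_distance(t) for t in simulate_trajectories(
            DEFAULT_MOTION[MobilityClass.CONSTRAINED], cfg, n=30, seed=2)]
        r = mobility_comparison(free, cons)
        assert r["ratio"] > 1.5 and r["p_value"] < 0.01

    def test_agrees_with_exhaustive_permutation_on_small_n(self):
        a, b = [5.1, 4.9, 5.3, 5.0], [1.2, 1.0, 0.9, 1.1]
        welch_p = mobility_comparison(a, b)["p_value"]
        pooled = a + b
        obs = abs(np.mean(a) - np.mean(b))
        count = 0
        total = 0
        for idx in itertools.combinations(range(8), 4):
            ga = [pooled[i] for i in idx]
            gb = [pooled[i] for i in range(8) if i not in idx]
            total += 1
            if abs(np.mean(ga) - np.mean(gb)) >= obs - 1e-12:
                count += 1
        perm_p = count / total
        assert welch_p < 0.05 and perm_p < 0.05

    def test_small_groups_rejected(self):
        with pytest.raises(ValueError):
            mobility_comparison([1.0], [1.0, 2.0])


class TestPipelineOrdering:
    def test_mobility_ordering_free_structured_ter(self):
        cfg = SimConfig()
        means = {}
        for i, cls in enumerate([MobilityClass.FREE, MobilityClass.STRUCTURED,
                                 MobilityClass.TER_ANCHORED]):
            trajs = simulate_trajectories(DEFAULT_MOTION[cls], cfg, n=30,
                                          seed=50 + i)
            means[cls] = np.mean([travelled_distance(t) for t in trajs])
        assert means[MobilityClass.FREE] > means[MobilityClass.STRUCTURED] \
            > means[MobilityClass.TER_ANCHORED]

    def test_trajectory_stats_bundle(self):
        tr = simulate_trajectories(DEFAULT_MOTION[MobilityClass.FREE],
                                   SimConfig(), n=1, seed=3)[0]
        s = trajectory_stats(tr)
        assert s.travelled_distance > 0
        assert s.msd[0] == (0.0, 0.0)
        assert s.D_app == pytest.approx(
            apparent_diffusion(tr)[0])
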