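"""Geometry, SASA, salt bridges, interaction statistics, event times."""

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st_
from scipy.optimize import minimize
from scipy.spatial.transform import Rotation

from cadhesion.errors import AnalysisError, GeometryError, TopologyError
from cadhesion.io import AtomRecord, CoordinateFrame, TimeSeries, Trajectory
from cadhesion.structure import (charged_pair_distances, chain,
                                 conversion_time, convert_force_units,
                                 delta_sasa, dissociation_time,
                                 interaction_episodes, interaction_occupancy,
                                 kabsch_superpose, rmsd_trace, rmsf_profile,
                                 salt_bridge_call, shrake_rupley_sasa)
from cadhesion.synth import gen_distance_trace, gen_event_trace, gen_toy_dimer


def _frame(coords, time=0.0, names=None, residues=None, chains=None, elements=None):
    n = len(coords)
    atoms = [AtomRecord(
        serial=i + 1,
        atom_name=(names or ["CA"] * n)[i],
        element=(elements or ["C"] * n)[i],
        residue_name=(residues or ["GLY"] * n)[i],
        residue_index=i + 1,
        chain_id=(chains or ["A"] * n)[i],
        position=np.asarray(coords[i], dtype=float),
    ) for i in range(n)]
    return CoordinateFrame(atoms=atoms, time=time)


class TestKabsch:
    def test_identical_frames(self, rng):
        f = _frame(rng.uniform(-5, 5, (8, 3)))
        sup = kabsch_superpose(f, f)
        assert sup.rmsd == pytest.approx(0.0, abs=1e-12)
        np.testing.assert_allclose(sup.rotation, np.eye(3), atol=1e-10)

    def test_rigid_motion_invariance(self, rng):
        coords = rng.uniform(-5, 5, (10, 3))
        R = Rotation.from_euler("z", 90, degrees=True).as_matrix()
        moved = coords @ R.T + np.array([3.0, -2.0, 7.0])
        sup = kabsch_superpose(_frame(moved), _frame(coords))
        assert sup.rmsd <= 1e-10

    def test_rotation_is_proper_orthonormal(self, rng):
        a = _frame(rng.uniform(-5, 5, (10, 3)))
        b = _frame(rng.uniform(-5, 5, (10, 3)))
        sup = kabsch_superpose(a, b)
        np.testing.assert_allclose(sup.rotation.T @ sup.rotation, np.eye(3), atol=1e-10)
        assert np.linalg.det(sup.rotation) == pytest.approx(1.0, abs=1e-10)

    def test_matches_brute_force_optimizer(self, rng):
        P = rng.uniform(-5, 5, (10, 3))
        Q = P @ Rotation.random(random_state=3).as_matrix().T + rng.normal(0, 0.3, (10, 3))
        sup = kabsch_superpose(_frame(P), _frame(Q))

        Pc, Qc = P - P.mean(0), Q - Q.mean(0)

        def cost(v):
            R = Rotation.from_rotvec(v).as_matrix()
            return np.sqrt(np.mean(np.sum((Pc @ R.T - Qc) ** 2, axis=1)))

        best = min(
            (minimize(cost, x0, method="Nelder-Mead",
                      options={"xatol": 1e-10, "fatol": 1e-12, "maxiter": 5000})
             for x0 in (np.zeros(3), np.array([1, 0.5, -0.5]), np.array([-2, 1, 2]))),
            key=lambda r: r.fun)
        assert sup.rmsd == pytest.approx(best.fun, abs=1e-6)

    def test_degenerate_geometry_raises(self):
        line = _frame([(0, 0, 0), (1, 0, 0), (2, 0, 0), (3, 0, 0)])
        with pytest.raises(GeometryError):
            kabsch_superpose(line, line)
        with pytest.raises(GeometryError):
            kabsch_superpose(_frame([(0, 0, 0), (1, 1, 1)]),
                             _frame([(0, 0, 0), (1, 1, 1)]))


class TestRmsdTrace:
    def test_self_trajectory_is_zero(self, rng):
        coords = rng.uniform(-5, 5, (6, 3))
        traj = Trajectory(frames=[_frame(coords, t) for t in (0.0, 1.0, 2.0)])
        ts = rmsd_trace(traj, traj.frames[0])
        np.testing.assert_allclose(ts.value, 0.0, atol=1e-12)

    def test_rigid_tumbling_is_zero(self, rng):
        coords = rng.uniform(-5, 5, (6, 3))
        frames = []
        for i in range(5):
            R = Rotation.random(random_state=i).as_matrix()
            frames.append(_frame(coords @ R.T + rng.normal(0, 4, 3), float(i)))
        ts = rmsd_trace(Trajectory(frames=frames), _frame(coords))
        assert np.max(ts.value) <= 1e-9

    def test_planted_uniform_displacement_without_superposition(self, rng):
        coords = rng.uniform(-5, 5, (6, 3))
        d = 1.7
        dirs = rng.normal(size=(6, 3))
        dirs /= np.linalg.norm(dirs, axis=1, keepdims=True)
        traj = Trajectory(frames=[_frame(coords + d * dirs, 0.0)])
        ts = rmsd_trace(traj, _frame(coords), superpose=False)
        assert ts.value[0] == pytest.approx(d, abs=1e-9)

    def test_topology_mismatch(self, rng):
        traj = Trajectory(frames=[_frame(rng.uniform(-5, 5, (6, 3)))])
        ref = _frame(rng.uniform(-5, 5, (5, 3)))
        with pytest.raises(TopologyError):
            rmsd_trace(traj, ref)


class TestRmsf:
    def test_static_trajectory_zero(self, rng):
        coords = rng.uniform(-5, 5, (8, 3))
        traj = Trajectory(frames=[_frame(coords, float(t)) for t in range(12)])
        prof = rmsf_profile(traj)
        assert max(prof.values.values()) == pytest.approx(0.0, abs=1e-12)

    def test_rigid_motion_removed(self, rng):
        coords = rng.uniform(-5, 5, (8, 3))
        frames = []
        for i in range(12):
            R = Rotation.random(random_state=100 + i).as_matrix()
            frames.append(_frame(coords @ R.T + rng.normal(0, 5, 3), float(i)))
        prof = rmsf_profile(Trajectory(frames=frames))
        assert max(prof.values.values()) <= 1e-8

    def test_window_selects_frames(self, rng):
        coords = rng.uniform(-5, 5, (8, 3))
        traj = Trajectory(frames=[_frame(coords, float(t)) for t in range(30)])
        prof = rmsf_profile(traj, window=(10.0, 25.0))
        assert prof.window == (10.0, 25.0)
        with pytest.raises(AnalysisError):
            rmsf_profile(traj, window=(100.0, 200.0))


class TestSasa:
    def test_isolated_sphere_closed_form(self):
        f = _frame([(0, 0, 0)], elements=["O"])
        res = shrake_rupley_sasa(f, radii={"O": 1.5}, probe=1.4)
        assert res.total == pytest.approx(4 * np.pi * 2.9 ** 2, rel=0.02)

    def test_caged_atom_is_buried(self):
        # central atom inside a 3×3×3 cage of large spheres
        centers = [(2.0 * i, 2.0 * j, 2.0 * k)
                   for i in (-1, 0, 1) for j in (-1, 0, 1) for k in (-1, 0, 1)
                   if not (i == j == k == 0)]
        coords = [(0.0, 0.0, 0.0)] + centers
        f = _frame(coords, elements=["C"] * len(coords))
        res = shrake_rupley_sasa(f, radii={"C": 2.0}, probe=1.4, n_points=192)
        assert res.per_atom[0] == 0.0

    def test_two_sphere_analytic_caps(self):
        r1 = r2 = 1.7 + 1.4  # inflated radii
        d = 4.0
        f = _frame([(0, 0, 0), (d, 0, 0)])
        res = shrake_rupley_sasa(f, probe=1.4)
        h = r1 - (d ** 2 + r1 ** 2 - r2 ** 2) / (2 * d)  # buried cap height
        expected = 4 * np.pi * r1 ** 2 - 2 * np.pi * r1 * h
        np.testing.assert_allclose(res.per_atom, expected, rtol=0.02)

    def test_total_is_sum_of_per_atom(self, rng):
        f = _frame(rng.uniform(-3, 3, (5, 3)))
        res = shrake_rupley_sasa(f, n_points=192)
        assert res.total == pytest.approx(res.per_atom.sum())

    def test_adding_neighbors_never_increases_exposure(self):
        positions = [(0, 0, 0), (3.0, 0, 0), (-3.0, 0, 0), (0, 3.0, 0)]
        last = np.inf
        for k in range(1, 5):
            f = _frame(positions[:k])
            area0 = shrake_rupley_sasa(f, n_points=192).per_atom[0]
            assert area0 <= last + 1e-9
            last = area0

    def test_missing_radius_names_element(self):
        f = _frame([(0, 0, 0)], elements=["ZZ"])
        with pytest.raises(Exception, match="ZZ"):
            shrake_rupley_sasa(f)


class TestDeltaSasa:
    def test_separated_chains_zero(self):
        f = _frame([(0, 0, 0), (1.5, 0, 0), (100.0, 0, 0), (101.5, 0, 0)],
                   chains=["A", "A", "B", "B"])
        d = delta_sasa(f, chain("A"), chain("B"), n_points=192)
        assert d == pytest.approx(0.0, abs=1e-6)

    def test_touching_dimer_positive(self):
        f = _frame([(0, 0, 0), (3.2, 0, 0)], chains=["A", "B"])
        assert delta_sasa(f, chain("A"), chain("B"), n_points=960) > 0

    def test_two_sphere_buried_caps_match_analytic(self):
        d = 4.0
        r = 1.7 + 1.4
        f = _frame([(0, 0, 0), (d, 0, 0)], chains=["A", "B"])
        ds = delta_sasa(f, chain("A"), chain("B"), n_points=960)
        h = r - d / 2.0
        expected = 2 * (2 * np.pi * r * h)  # one cap buried per sphere
        assert ds == pytest.approx(expected, rel=0.03)

    def test_overlapping_selection_rejected(self):
        f = _frame([(0, 0, 0), (3, 0, 0)], chains=["A", "B"])
        with pytest.raises(GeometryError):
            delta_sasa(f, chain("A"), lambda a: True)

    def test_toy_dimer_far_separation_zero(self):
        traj, _ = gen_toy_dimer(8, 100.0, 0.0, 1, seed=0)
        d = delta_sasa(traj.frames[0], chain("A"), chain("B"), n_points=192)
        assert d == pytest.approx(0.0, abs=1e-6)


class TestSaltBridge:
    def test_constant_distances(self):
        t = np.arange(100.0)
        stable = salt_bridge_call(TimeSeries(time=t, value=np.full(100, 3.0)))
        unstable = salt_bridge_call(TimeSeries(time=t, value=np.full(100, 5.0)))
        assert stable.stable and not unstable.stable

    def test_cutoff_is_strict(self):
        t = np.arange(10.0)
        call = salt_bridge_call(TimeSeries(time=t, value=np.full(10, 4.0)))
        assert call.median_distance == 4.0 and not call.stable

    @pytest.mark.parametrize("occ,expected", [(0.6, True), (0.4, False)])
    def test_telegraph_occupancy_determines_call(self, occ, expected):
        ts = gen_distance_trace(occ, 3.0, 6.0, 10_000, seed=13)
        call = salt_bridge_call(ts, window=(0.0, float(ts.time[-1])))
        assert call.stable is expected

    def test_lowering_distances_cannot_destabilize(self, rng):
        t = np.arange(200.0)
        v = rng.uniform(2.0, 8.0, 200)
        before = salt_bridge_call(TimeSeries(time=t, value=v))
        after = salt_bridge_call(TimeSeries(time=t, value=v - 0.5))
        assert (not before.stable) or after.stable


class TestChargedPairs:
    def _dimer_frame(self, od2_dist):
        coords = [(0, 0, 0), (5.0, 0, 0), (od2_dist, 0, 0)]
        return _frame(coords, names=["NZ", "OD1", "OD2"],
                      residues=["LYS", "ASP", "ASP"],
                      chains=["A", "B", "B"], elements=["N", "O", "O"])

    def test_minimum_rule_over_acceptor_oxygens(self):
        traj = Trajectory(frames=[self._dimer_frame(3.2)])
        ts = charged_pair_distances(traj)
        assert ts.value[0] == pytest.approx(3.2, abs=1e-12)

    def test_constant_pair(self):
        frames = [self._dimer_frame(3.0), self._dimer_frame(3.0)]
        frames[1] = CoordinateFrame(atoms=frames[1].atoms, time=1.0)
        ts = charged_pair_distances(Trajectory(frames=frames))
        np.testing.assert_allclose(ts.value, 3.0)

    def test_empty_selection_raises(self):
        traj = Trajectory(frames=[_frame([(0, 0, 0), (1, 1, 1), (2, 0, 1)])])
        with pytest.raises(GeometryError):
            charged_pair_distances(traj)


class TestInteractionStats:
    def test_occupancy_boundaries(self):
        t = np.arange(1000.0)
        ts41 = TimeSeries(time=t, value=(np.arange(1000) < 410).astype(float))
        ts39 = TimeSeries(time=t, value=(np.arange(1000) < 390).astype(float))
        occ, persistent = interaction_occupancy(ts41)
        assert occ == pytest.approx(0.41) and persistent
        occ, persistent = interaction_occupancy(ts39)
        assert occ == pytest.approx(0.39) and not persistent
        assert interaction_occupancy(TimeSeries(time=t, value=np.ones(1000)))[0] == 1.0
        occ, persistent = interaction_occupancy(TimeSeries(time=t, value=np.zeros(1000)))
        assert occ == 0.0 and not persistent

    def test_occupancy_boundary_inclusive(self):
        v = np.concatenate([np.ones(40), np.zeros(60)])
        _, persistent = interaction_occupancy(TimeSeries(time=np.arange(100.0), value=v))
        assert persistent  # exactly 40% counts as persistent

    def test_episode_duration_strictly_above_cutoff(self):
        dt = 2.0  # ps
        n_run = 100  # exactly 0.2 ns
        v = np.concatenate([np.zeros(10), np.ones(n_run), np.zeros(10)])
        ts = TimeSeries(time=np.arange(v.size) * dt, value=v)
        assert interaction_episodes(ts, min_duration_ns=0.2) == []
        v2 = np.concatenate([np.zeros(10), np.ones(150), np.zeros(10)])
        ts2 = TimeSeries(time=np.arange(v2.size) * dt, value=v2)
        eps = interaction_episodes(ts2, min_duration_ns=0.2)
        assert len(eps) == 1
        start, end = eps[0]
        assert start == pytest.approx(10 * dt)
        assert end - start == pytest.approx(150 * dt)

    def test_alternating_frames_have_no_episodes(self):
        v = np.tile([1.0, 0.0], 100)
        ts = TimeSeries(time=np.arange(200.0) * 2.0, value=v)
        assert interaction_episodes(ts, min_duration_ns=0.2) == []


class TestEventTimes:
    def test_noiseless_conversion_exact(self):
        ts = gen_event_trace("rmsd", 1000.0, 2.0, 3000.0, 0.0, seed=0)
        assert conversion_time(ts).time == 1000.0

    def test_monotone_trace_has_no_conversion(self):
        ts = TimeSeries(time=np.arange(200.0), value=np.linspace(1, 5, 200))
        assert conversion_time(ts, smooth_frames=5).time is None

    def test_noisy_conversion_bias_within_smoothing_window(self):
        ests = [conversion_time(
            gen_event_trace("rmsd", 1012.0, 2.0, 3000.0, 0.5, seed=s)).time
            for s in range(100)]
        assert abs(np.mean(ests) - 1012.0) <= 2.0 * 25

    def test_noiseless_dissociation_exact(self):
        ts = gen_event_trace("dsasa", 5000.0, 2.0, 8000.0, 0.0, seed=0)
        assert dissociation_time(ts, epsilon=0.0).time == 5000.0

    def test_single_frame_dip_ignored_by_hold(self):
        v = np.full(100, 500.0)
        v[40] = 0.0
        ts = TimeSeries(time=np.arange(100.0), value=v)
        assert dissociation_time(ts, epsilon=25.0, hold_frames=5).time is None

    def test_never_dissociating_trace(self):
        ts = TimeSeries(time=np.arange(50.0), value=np.full(50, 300.0))
        assert dissociation_time(ts).time is None


class TestForceUnitConversion:
    def test_constant_pulling_force(self):
        assert abs(convert_force_units(400.0) - 665.0) < 1.0

    @pytest.mark.parametrize("f,expected", [(0.0, 0.0), (1.0, 1.660539)])
    def test_linearity(self, f, expected):
        assert convert_force_units(f) == pytest.approx(expected, abs=1e-5)


@given(seed=st_.integers(0, 50))
def test_rmsd_invariant_under_random_rigid_motion(seed):
    rng = np.random.default_rng(seed)
    coords = rng.uniform(-5, 5, (7, 3))
    R = Rotation.random(random_state=seed).as_matrix()
    moved = coords @ R.T + rng.normal(0, 10, 3)
    sup = kabsch_superpose(_frame(moved), _frame(coords))
    assert sup.rmsd <= 1e-9
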