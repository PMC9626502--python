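import numpy as np
import pytest

import icegrowth as ig
from icegrowth.core import Frame, SimulationBox, Trajectory
from icegrowth.mobility import (lateral_track, mi_fraction_near, propensity,
                                shell_diffusion)
from icegrowth.synthetic import (PolymerSpec, _random_water_orientation,
                                 _water_topology_arrays, build_polymer,
                                 build_shell_system, isoca_ensemble)


@pytest.fixture(scope="module")
def water_box():
    rng = np.random.default_rng(5)
    n = 400
    box = SimulationBox([6, 6, 6], periodic=[True, True, True])
    o = rng.uniform(0, 6, (n, 3))
    topo = _water_topology_arrays(n, 1, 1)
    pos = np.vstack([_random_water_orientation(p, rng) for p in o])
    return topo, Frame(0.0, pos), box


class TestPropensity:
    def test_frozen_molecules_have_zero_dp_and_fill_mi(self, water_box):
        topo, frame0, box = water_box
        n = len(topo.water_oxygen_idx)
        dmap = {m: 1e-4 for m in range(1, n + 1)}
        frozen = set(range(1, 31))
        runs = isoca_ensemble(topo, frame0, box, 4, dmap, frozen=frozen,
                              t_star=10.0, seed=1)
        field = propensity(runs, topo, t_star=10.0)
        dp = dict(zip(field.water_ids, field.dp))
        assert all(dp[m] == 0.0 for m in frozen)
        assert set(field.mi) <= frozen

    def test_single_run_dp_is_squared_displacement(self, water_box):
        topo, frame0, box = water_box
        n = len(topo.water_oxygen_idx)
        dmap = {m: 1e-4 for m in range(1, n + 1)}
        runs = isoca_ensemble(topo, frame0, box, 1, dmap, t_star=10.0, seed=2)
        field = propensity(runs, topo, t_star=10.0)
        from icegrowth.core import unwrap_positions
        un = unwrap_positions(runs[0], topo.water_oxygen_idx)
        expect = np.sum((un[-1] - un[0]) ** 2, axis=1)
        assert np.allclose(field.dp, expect)

    def test_two_population_mi_purity(self, water_box):
        topo, frame0, box = water_box
        n = len(topo.water_oxygen_idx)
        dmap = {m: (1e-5 if m <= n // 2 else 2e-4) for m in range(1, n + 1)}
        runs = isoca_ensemble(topo, frame0, box, 10, dmap, t_star=20.0,
                              dt=2.0, seed=3)
        field = propensity(runs, topo, t_star=20.0)
        assert np.mean(field.mi <= n // 2) >= 0.95
        assert np.mean(field.mm > n // 2) >= 0.95

    def test_tail_sizes_and_disjointness(self, water_box):
        topo, frame0, box = water_box
        n = len(topo.water_oxygen_idx)
        dmap = {m: 1e-4 for m in range(1, n + 1)}
        runs = isoca_ensemble(topo, frame0, box, 2, dmap, t_star=5.0, seed=4)
        field = propensity(runs, topo, t_star=5.0)
        k = round(0.05 * n)
        assert len(field.mi) == len(field.mm) == k
        assert len(np.intersect1d(field.mi, field.mm)) == 0

    def test_mismatched_initial_configurations_raise(self, water_box):
        topo, frame0, box = water_box
        n = len(topo.water_oxygen_idx)
        dmap = {m: 1e-4 for m in range(1, n + 1)}
        a = isoca_ensemble(topo, frame0, box, 1, dmap, t_star=5.0, seed=5)[0]
        shifted = Frame(0.0, frame0.positions + 0.1)
        b = isoca_ensemble(topo, shifted, box, 1, dmap, t_star=5.0, seed=6)[0]
        with pytest.raises(ValueError, match="initial configuration"):
            propensity([a, b], topo, t_star=5.0)

    def test_dp_invariant_under_global_translation(self, water_box):
        topo, frame0, box = water_box
        n = len(topo.water_oxygen_idx)
        dmap = {m: 1e-4 for m in range(1, n + 1)}
        runs = isoca_ensemble(topo, frame0, box, 2, dmap, t_star=5.0, seed=7)
        field0 = propensity(runs, topo, t_star=5.0)
        shift = np.array([1.3, -0.4, 2.2])
        moved = [Trajectory([Frame(f.time, box.wrap(f.positions + shift))
                             for f in tr], box) for tr in runs]
        field1 = propensity(moved, topo, t_star=5.0)
        assert np.allclose(field0.dp, field1.dp, atol=1e-9)


class TestMiFractionNear:
    def test_no_polymer_flags_undefined(self, water_box):
        topo, frame0, box = water_box
        n = len(topo.water_oxygen_idx)
        dmap = {m: 1e-4 for m in range(1, n + 1)}
        runs = isoca_ensemble(topo, frame0, box, 2, dmap, t_star=5.0, seed=8)
        field = propensity(runs, topo, t_star=5.0)
        res = mi_fraction_near(field, runs[0], topo, 0.5)
        assert not res.defined

    def test_slow_shell_around_polymer_is_mi(self):
        system, dmap = build_shell_system(
            shells=(0.6, 1.2, 2.4), d_values=(1e-5, 2e-4, 2e-4),
            n_per_shell=120, seed=2)
        topo, frame0, box = system
        runs = isoca_ensemble(topo, frame0, box, 8, dmap, t_star=20.0,
                              dt=2.0, seed=9)
        field = propensity(runs, topo, t_star=20.0)
        res = mi_fraction_near(field, runs[0], topo, 0.6)
        assert res.defined
        assert res.frac_mi_near > 0.95   # MI sits in the slow inner shell


class TestShellDiffusion:
    def test_recovers_generator_coefficients(self):
        system, dmap = build_shell_system(n_per_shell=400, seed=3)
        topo, frame0, box = system
        runs = isoca_ensemble(topo, frame0, box, 10, dmap, t_star=14.0,
                              dt=1.0, seed=10)
        ds = [shell_diffusion(tr, topo, fit_window=(2, 10),
                              origin_stride=100).diffusion for tr in runs]
        d = np.nanmean(ds, axis=0)
        for got, want in zip(d, system.metadata["d_values"]):
            assert got == pytest.approx(want, rel=0.05)

    def test_recovered_ordering_matches_generator(self):
        system, dmap = build_shell_system(n_per_shell=150, seed=4)
        topo, frame0, box = system
        tr = isoca_ensemble(topo, frame0, box, 1, dmap, t_star=14.0,
                            dt=1.0, seed=11)[0]
        d = shell_diffusion(tr, topo, fit_window=(2, 10),
                            origin_stride=100).diffusion
        assert d[0] < d[1] < d[2]   # mobility grows away from the polymer

    def test_static_molecules_have_zero_d(self):
        system, dmap = build_shell_system(n_per_shell=60, seed=5)
        topo, frame0, box = system
        zero = {m: 0.0 for m in dmap}
        tr = isoca_ensemble(topo, frame0, box, 1, zero, t_star=14.0,
                            dt=1.0, seed=12)[0]
        res = shell_diffusion(tr, topo, fit_window=(2, 10), origin_stride=100)
        assert np.allclose(res.diffusion, 0.0)

    def test_empty_shell_reported_absent(self):
        system, dmap = build_shell_system(shells=(0.5, 1.0, 2.0),
                                          n_per_shell=60, seed=6)
        topo, frame0, box = system
        tr = isoca_ensemble(topo, frame0, box, 1, dmap, t_star=14.0,
                            dt=1.0, seed=13)[0]
        res = shell_diffusion(tr, topo, shells=(0.02, 0.5, 1.0, 2.0),
                              fit_window=(2, 10), origin_stride=100)
        assert np.isnan(res.diffusion[0])
        assert res.counts[0] == 0

    def test_no_polymer_is_error(self, water_box):
        topo, frame0, box = water_box
        tr = Trajectory([Frame(float(t), frame0.positions)
                         for t in range(30)], box)
        with pytest.raises(ValueError):
            shell_diffusion(tr, topo, fit_window=(2, 10))


class TestLateralTrack:
    @staticmethod
    def _com_trajectory(com_path, dt=10.0):
        pm = build_polymer(PolymerSpec(8, 0.4, seed=1))
        box = SimulationBox([20, 20, 10], periodic=[True, True, False])
        frames = []
        for t, com in enumerate(com_path):
            pos = pm.coordinates + (np.asarray(com) -
                                    pm.coordinates.mean(axis=0))
            frames.append(Frame(t * dt, pos))
        return Trajectory(frames, box), pm.topology

    def test_two_dwells_one_migration(self):
        path = [[5, 5, 5]] * 80
        path += [[5 + 0.35 * k, 5 + 0.35 * k, 5] for k in range(20)]
        path += [[12, 12, 5]] * 100
        traj, topo = self._com_trajectory(path)
        track = lateral_track(traj, topo, dwell_window=100.0, dwell_rms=0.1)
        kinds = [s[0] for s in track.segments]
        assert kinds == ["DWELL", "MIGRATE", "DWELL"]

    def test_stationary_polymer_single_dwell(self):
        traj, topo = self._com_trajectory([[5, 5, 5]] * 50)
        track = lateral_track(traj, topo)
        assert [s[0] for s in track.segments] == ["DWELL"]

    def test_brownian_com_dwell_fraction_matches_oracle(self):
        # simulate the COM walk; classify both with the same window rule
        rng = np.random.default_rng(21)
        D, dt, n = 5e-4, 10.0, 400
        steps = rng.normal(0, np.sqrt(2 * D * dt), (n, 2))
        xy = np.cumsum(np.vstack([[0, 0], steps]), axis=0) + 10.0
        path = [[x, y, 5.0] for x, y in xy]
        traj, topo = self._com_trajectory(path)
        track = lateral_track(traj, topo, dwell_window=100.0, dwell_rms=0.25)
        # oracle: rolling rms on the raw path, identical definition
        half = 5
        expect = []
        for i in range(len(xy)):
            lo, hi = max(0, i - half), min(len(xy), i + half + 1)
            seg = xy[lo:hi]
            rms = np.sqrt(np.mean(np.sum((seg - seg.mean(0)) ** 2, axis=1)))
            expect.append("DWELL" if rms < 0.25 else "MIGRATE")
        assert list(track.labels) == expect

    def test_unwrapped_path_crosses_boundary(self):
        path = [[19.5 + 0.2 * k, 5, 5] for k in range(20)]   # wraps in x
        pm = build_polymer(PolymerSpec(8, 0.4, seed=1))
        box = SimulationBox([20, 20, 10], periodic=[True, True, False])
        frames = []
        for t, com in enumerate(path):
            pos = pm.coordinates + (np.asarray(com) -
                                    pm.coordinates.mean(axis=0))
            frames.append(Frame(t * 10.0, box.wrap(pos)))
        traj = Trajectory(frames, box)
        track = lateral_track(traj, pm.topology)
        assert track.xy[-1, 0] - track.xy[0, 0] == pytest.approx(3.8, abs=0.2)
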