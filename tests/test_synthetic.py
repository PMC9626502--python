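import numpy as np
import pytest

import icegrowth as ig
from icegrowth.core import AMU_PER_NM3_TO_G_CM3, pairs_within
from icegrowth.synthetic import (GroundTruthLog, build_polymer,
                                 degree_of_branching_from_counts)

WATER_MASS = 18.015


class TestIceSlab:
    def test_basal_layer_spacing_is_one_basal_layer(self, slab):
        topo, frame, box = slab
        lat = slab.lattice
        o = frame.positions[topo.water_oxygen_idx]
        per = lat.sites_per_layer
        cents = [o[m * per:(m + 1) * per, 2].mean() for m in range(4)]
        assert np.diff(cents) == pytest.approx([0.37] * 3, abs=0.005)

    def test_slab_mass_density_matches_ice(self, slab):
        topo, frame, _ = slab
        lat = slab.lattice
        n_mol = len(topo.water_oxygen_idx)
        vol = lat.lx * lat.ly * (4 * lat.c / 2.0)
        dens = n_mol * WATER_MASS / vol * AMU_PER_NM3_TO_G_CM3
        assert dens == pytest.approx(0.92, rel=0.02)

    def test_bulk_oxygen_has_four_neighbors_at_ih_distance(self, slab):
        topo, frame, box = slab
        o = frame.positions[topo.water_oxygen_idx]
        counts = np.zeros(len(o), dtype=int)
        for i, j in pairs_within(o, box, 0.30):
            d = np.linalg.norm(box.min_image(o[i] - o[j]))
            assert d == pytest.approx(0.276, abs=0.01)
            counts[i] += 1
            counts[j] += 1
        # interior oxygens are 4-coordinated; surface ones 3-coordinated
        assert set(counts.tolist()) == {3, 4}
        lat = slab.lattice
        interior = (o[:, 2] > lat.layer_z(0)[1] + 0.01) & \
                   (o[:, 2] < lat.layer_z(3)[0] - 0.01)
        assert np.all(counts[interior] == 4)

    def test_every_water_has_two_hydrogens_on_bonds(self, slab):
        topo, frame, _ = slab
        topo.validate()
        o_idx = topo.water_oxygen_idx
        for i in o_idx[:20]:
            h = np.where(topo.parent == topo.ids[i])[0]
            d = np.linalg.norm(frame.positions[h] - frame.positions[i], axis=1)
            assert d == pytest.approx([0.1, 0.1], abs=1e-9)

    @pytest.mark.parametrize("plane", ["prism1", "prism2"])
    def test_prism_orientations_permute_growth_axis(self, plane):
        basal = ig.build_ice_slab(2, 2, 2, plane="basal")
        prism = ig.build_ice_slab(2, 2, 2, plane=plane)
        # same atom count and same sorted extent multiset, axes permuted
        assert prism.topology.n_atoms == basal.topology.n_atoms
        assert sorted(prism.box.lengths) == pytest.approx(
            sorted(basal.box.lengths))

    def test_rejects_nonpositive_dimensions(self):
        with pytest.raises(ValueError):
            ig.build_ice_slab(0, 2, 2)


class TestPolymer:
    def test_linear_chain_has_zero_db(self):
        pm = build_polymer(ig.PolymerSpec(30, 0.0, seed=1))
        assert pm.unit_counts["D"] == 0
        assert pm.db == 0.0
        assert pm.unit_counts["T"] == 2

    def test_degenerate_two_units(self):
        pm = build_polymer(ig.PolymerSpec(2, 0.0, seed=1))
        assert pm.unit_types == ["T", "T"]
        assert pm.db == 0.0

    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_target_db_realised_within_band(self, seed):
        pm = build_polymer(ig.PolymerSpec(100, 0.6, seed=seed))
        assert 0.55 <= pm.db <= 0.65

    def test_db_recomputed_from_graph_matches_generator(self):
        pm = build_polymer(ig.PolymerSpec(80, 0.5, seed=4))
        counts = {"D": 0, "L13": 0, "L14": 0, "T": 0}
        for v in pm.graph.nodes:
            deg = pm.graph.degree(v)
            t = "T" if deg == 1 else ("D" if deg >= 3 else
                                      pm.unit_types[v])
            counts[t] += 1
        assert counts == pm.unit_counts
        assert degree_of_branching_from_counts(counts) == pm.db

    def test_infeasible_target_raises(self):
        with pytest.raises(ValueError, match="infeasible"):
            build_polymer(ig.PolymerSpec(5, 1.0, seed=0))

    def test_self_avoiding_walk_keeps_units_apart(self):
        pm = build_polymer(ig.PolymerSpec(60, 0.4, seed=7))
        o = pm.coordinates[pm.unit_oxygen_rows]
        d = np.linalg.norm(o[:, None] - o[None, :], axis=2)
        np.fill_diagonal(d, 1.0)
        assert d.min() > 0.25


class TestMixedSystem:
    def test_liquid_region_density(self, mixed):
        topo, frame, box = mixed
        meta = mixed.metadata
        n_liq = len(topo.water_oxygen_idx) - meta["n_slab_molecules"]
        vol = box.lengths[0] * box.lengths[1] * \
            (meta["liquid_top"] - meta["liquid_bottom"])
        dens = n_liq * WATER_MASS / vol * AMU_PER_NM3_TO_G_CM3
        assert dens == pytest.approx(1.00, rel=0.03)

    def test_polymer_com_two_nm_above_seed(self, mixed):
        topo, frame, _ = mixed
        meta = mixed.metadata
        com_z = frame.positions[topo.polymer_idx].mean(axis=0)[2]
        assert com_z - meta["slab_top"] == pytest.approx(2.0, abs=0.1)

    def test_no_heavy_atom_pair_below_min_separation(self, mixed):
        topo, frame, box = mixed
        meta = mixed.metadata
        o_idx = topo.water_oxygen_idx
        liquid = o_idx[meta["n_slab_molecules"]:]
        sites = np.vstack([frame.positions[liquid],
                           frame.positions[topo.polymer_heavy_idx]])
        d = np.linalg.norm(box.min_image(sites[:, None] - sites[None, :]),
                           axis=2)
        np.fill_diagonal(d, 1.0)
        # polymer unit beads are chained at 0.36 nm; liquid placement
        # sites keep the 0.24 nm rejection distance from everything
        n_liq = len(liquid)
        dl = d[:n_liq]
        assert dl.min() >= 0.24

    def test_rejects_nonpositive_depth(self):
        with pytest.raises(ValueError):
            ig.build_mixed_system(2, 2, 2, liquid_depth=0.0)


class TestScriptedGrowth:
    def test_front_is_three_step_staircase(self, scripted):
        traj, truth = scripted
        h = np.array(truth.front_height)
        rises = np.diff(np.unique(h))
        assert len(truth.step_times) == 3
        assert np.unique(h).size == 4
        assert rises == pytest.approx([0.3685] * 3, abs=1e-9)

    def test_empty_script_keeps_front_constant(self, mixed):
        traj, truth = ig.scripted_growth(mixed, [], 10, seed=5)
        assert len(set(truth.front_height)) == 1
        assert truth.step_times == []

    def test_scripted_event_fires_geometric_detector(self, mixed, scripted):
        traj, truth = scripted
        topo = mixed.topology
        ev = truth.hbond_events[0]
        rec = ig.detect_hbonds(traj[ev["frame"]], topo, traj.box,
                               polymer_only=True)
        assert ev["water_id"] in set(rec["donor_mol"]) | set(rec["acceptor_mol"])

    def test_every_frame_bond_set_equals_script(self, mixed, scripted):
        from icegrowth.hbond import _polymer_water_pairs
        traj, truth = scripted
        topo = mixed.topology
        for f in range(traj.n_frames):
            rec = _polymer_water_pairs(
                ig.detect_hbonds(traj[f], topo, traj.box, polymer_only=True),
                topo)
            got = sorted((int(r.water_mol), r.segment)
                         for r in rec.itertuples())
            exp = sorted((e["water_id"], e["segment"])
                         for e in truth.hbond_events if e["frame"] == f)
            assert got == exp, f"frame {f}"

    def test_scripting_frozen_water_raises(self, mixed):
        _, truth = ig.scripted_growth(mixed, [150], 30, seed=1)
        frozen_member = truth.layer_members[3][0]
        topo = mixed.topology
        unit = topo.ids[(topo.kinds == "POLYMER") & (topo.elements == "O")][0]
        with pytest.raises(ValueError, match="frozen"):
            ig.scripted_growth(mixed, [150], 30, seed=1,
                               hbond_script=[ig.ScriptedHBond(
                                   20, frozen_member, int(unit))])

    def test_generator_is_deterministic(self, mixed):
        t1, _ = ig.scripted_growth(mixed, [150], 20, seed=9)
        t2, _ = ig.scripted_growth(mixed, [150], 20, seed=9)
        for a, b in zip(t1, t2):
            assert np.array_equal(a.positions, b.positions)

    def test_ground_truth_log_json_round_trip(self, scripted, tmp_path):
        _, truth = scripted
        p = tmp_path / "truth.json"
        truth.to_json(p)
        back = GroundTruthLog.from_json(p)
        assert back.layer_members == truth.layer_members
        assert back.hbond_events == truth.hbond_events
        assert back.step_times == truth.step_times


class TestIsocaEnsemble:
    def test_frozen_molecules_do_not_move(self, random_liquid):
        from icegrowth.synthetic import (_water_topology_arrays,
                                         _random_water_orientation)
        from icegrowth.core import Frame
        pts, box = random_liquid
        rng = np.random.default_rng(0)
        topo = _water_topology_arrays(len(pts), 1, 1)
        pos = np.vstack([_random_water_orientation(p, rng) for p in pts])
        frame0 = Frame(0.0, pos)
        dmap = {m: 1e-4 for m in range(1, len(pts) + 1)}
        frozen = set(range(1, 51))
        runs = ig.isoca_ensemble(topo, frame0, box, M=3, diffusion_map=dmap,
                                 frozen=frozen, t_star=5.0, dt=1.0, seed=2)
        o_idx = topo.water_oxygen_idx
        for tr in runs:
            disp = tr[-1].positions[o_idx[:50]] - tr[0].positions[o_idx[:50]]
            assert np.abs(disp).max() == 0.0

    def test_reproducible_under_seed(self, random_liquid):
        from icegrowth.synthetic import (_water_topology_arrays,
                                         _random_water_orientation)
        from icegrowth.core import Frame
        pts, box = random_liquid
        rng = np.random.default_rng(0)
        topo = _water_topology_arrays(len(pts), 1, 1)
        frame0 = Frame(0.0, np.vstack(
            [_random_water_orientation(p, rng) for p in pts]))
        dmap = {m: 1e-4 for m in range(1, len(pts) + 1)}
        a = ig.isoca_ensemble(topo, frame0, box, 1, dmap, t_star=5.0, seed=3)
        b = ig.isoca_ensemble(topo, frame0, box, 1, dmap, t_star=5.0, seed=3)
        for fa, fb in zip(a[0], b[0]):
            assert np.array_equal(fa.positions, fb.positions)

    def test_msd_matches_brownian_closed_form(self, random_liquid):
        from icegrowth.synthetic import (_water_topology_arrays,
                                         _random_water_orientation)
        from icegrowth.core import Frame, unwrap_positions
        pts, box = random_liquid
        rng = np.random.default_rng(0)
        topo = _water_topology_arrays(len(pts), 1, 1)
        frame0 = Frame(0.0, np.vstack(
            [_random_water_orientation(p, rng) for p in pts]))
        D = 2e-4
        dmap = {m: D for m in range(1, len(pts) + 1)}
        t_star = 20.0
        runs = ig.isoca_ensemble(topo, frame0, box, M=4, diffusion_map=dmap,
                                 t_star=t_star, dt=1.0, seed=5)
        msds = []
        for tr in runs:
            un = unwrap_positions(tr, topo.water_oxygen_idx)
            msds.append(np.mean(np.sum((un[-1] - un[0]) ** 2, axis=1)))
        # MSD(t*)/t* -> 6 D for a 3D Brownian walk
        assert np.mean(msds) / t_star == pytest.approx(6 * D, rel=0.05)

    def test_negative_diffusion_raises(self, random_liquid):
        from icegrowth.synthetic import (_water_topology_arrays,
                                         _random_water_orientation)
        from icegrowth.core import Frame
        pts, box = random_liquid
        rng = np.random.default_rng(0)
        topo = _water_topology_arrays(len(pts), 1, 1)
        frame0 = Frame(0.0, np.vstack(
            [_random_water_orientation(p, rng) for p in pts]))
        with pytest.raises(ValueError):
            ig.isoca_ensemble(topo, frame0, box, 1, {1: -1e-4}, t_star=2.0)
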