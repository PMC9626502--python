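import numpy as np
import pytest

import icegrowth as ig
from icegrowth.synthetic import ScriptedHBond


@pytest.fixture(scope="session")
def slab():
    """Ideal 4-layer basal ice Ih slab."""
    return ig.build_ice_slab(3, 2, 4)


@pytest.fixture(scope="session")
def mixed():
    """Seed slab + liquid + one branched polymer 2 nm above the seed."""
    return ig.build_mixed_system(
        3, 2, 3, liquid_depth=2.5,
        polymers=(ig.PolymerSpec(20, 0.6, seed=3),),
        seed=42, headroom=2.0)


@pytest.fixture(scope="session")
def scripted(mixed):
    """Scripted 3-step growth with H-bond events and its ground truth.

    Events cover: repeat contact (majority segment D with multiplicity 2),
    a single L13 contact, and a contact on a layer-3 water before it
    freezes.
    """
    _, truth_plan = ig.scripted_growth(mixed, [150, 300, 450], 60, seed=1)
    topo = mixed.topology
    members3 = truth_plan.layer_members[3]
    members4 = truth_plan.layer_members[4]
    seg_atoms = {
        s: topo.ids[(topo.kinds == "POLYMER") & (topo.elements == "O") &
                    (topo.segments == s)]
        for s in ("L13", "L14", "D", "T")}
    events = [
        ScriptedHBond(5, members4[0], int(seg_atoms["D"][0])),
        ScriptedHBond(6, members4[0], int(seg_atoms["D"][0])),
        ScriptedHBond(6, members4[0], int(seg_atoms["T"][0])),
        ScriptedHBond(10, members4[1], int(seg_atoms["L13"][0])),
        ScriptedHBond(8, members3[0], int(seg_atoms["T"][1])),
    ]
    traj, truth = ig.scripted_growth(mixed, [150, 300, 450], 60,
                                     hbond_script=events, seed=1)
    return traj, truth


@pytest.fixture(scope="session")
def scripted_labels(mixed, scripted):
    traj, _ = scripted
    return ig.classify_phase(traj, mixed.topology)


@pytest.fixture(scope="session")
def random_liquid():
    """500 random points with 0.24 nm minimum separation (bulk liquid)."""
    from icegrowth.core import SimulationBox
    rng = np.random.default_rng(17)
    box = SimulationBox([2.5, 2.5, 2.5], periodic=[True, True, True])
    pts = []
    while len(pts) < 500:
        p = rng.uniform(0, 2.5, 3)
        if not pts or np.min(np.linalg.norm(
                box.min_image(np.array(pts) - p), axis=1)) > 0.24:
            pts.append(p)
    return np.array(pts), box
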