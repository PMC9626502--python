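"""Synthetic ice/water/polymer systems with ground-truth logs.

Everything the analysis stages consume can be generated here without
running molecular dynamics: an ideal ice Ih slab with liquid water above
it, bead-per-unit polyglycerol-like polymers with a prescribed degree of
branching, scripted stepwise growth trajectories in which whole basal
layers freeze at chosen times, scripted polymer-water hydrogen-bond
events, and iso-configurational ensembles of overdamped random walks.
Every generator is deterministic under a fixed seed, and every scripted
fact is emitted to a :class:`GroundTruthLog` so the analyses can be tested
for exact recovery.

The ice Ih oxygen sublattice uses the hexagonal lattice constants
a = 0.452 nm and c = 0.737 nm; one basal layer is a puckered bilayer and
adjacent bilayers are spaced c/2 = 0.3685 nm apart. Hydrogens are placed
proton-naively along O-O bond directions (no Bernal-Fowler bookkeeping):
the analyses here depend on oxygen geometry and local H-bond geometry,
not proton order.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict

import networkx as nx
import numpy as np
from scipy.optimize import linear_sum_assignment

from .core import (
    POLYMER, WATER, Frame, SimulationBox, Topology, Trajectory,
    concat_topologies, neighbor_lists,
)

ICE_A = 0.452   # nm, hexagonal a
ICE_C = 0.737   # nm, hexagonal c
BASAL_SPACING = ICE_C / 2.0   # one basal layer, 0.3685 nm
OH_BOND = 0.1   # nm
WATER_MASS = {"O": 15.999, "H": 1.008}
PG_UNIT_O_MASS = 73.07  # glycerol repeat unit minus the hydroxyl proton

# in-plane oxygen sites of the two wurtzite sublattices, in fractions of
# the orthorhombic cell (a, a*sqrt(3))
_A_FRAC = ((0.0, 1.0 / 3.0), (0.5, 5.0 / 6.0))
_B_FRAC = ((0.5, 1.0 / 6.0), (0.0, 2.0 / 3.0))

PLANES = ("basal", "prism1", "prism2")


@dataclass
class IceLattice:
    """Geometry bookkeeping for a generated ice slab (basal orientation)."""

    nx: int
    ny: int
    n_layers: int
    plane: str = "basal"
    a: float = ICE_A
    c: float = ICE_C
    z0: float = 0.1

    @property
    def lx(self) -> float:
        return self.nx * self.a

    @property
    def ly(self) -> float:
        return self.ny * self.a * np.sqrt(3.0)

    @property
    def layer_spacing(self) -> float:
        if self.plane == "basal":
            return self.c / 2.0
        if self.plane == "prism1":
            return self.a * np.sqrt(3.0) / 2.0
        return self.a / 2.0

    @property
    def sites_per_layer(self) -> int:
        return 4 * self.nx * self.ny

    def layer_z(self, m: int) -> tuple[float, float]:
        """(lower, upper) sublayer z of bilayer m (basal)."""
        lo = self.z0 + m * self.c / 2.0
        return lo, lo + self.c / 8.0

    def layer_sites(self, m: int) -> np.ndarray:
        """Oxygen positions of basal bilayer m, sorted deterministically."""
        lo, up = self.layer_z(m)
        lower_frac = _A_FRAC if m % 2 == 0 else _B_FRAC
        upper_frac = _B_FRAC if m % 2 == 0 else _A_FRAC
        pts = []
        for ix in range(self.nx):
            for iy in range(self.ny):
                for fx, fy in lower_frac:
                    pts.append(((ix + fx) * self.a,
                                (iy + fy) * self.a * np.sqrt(3.0), lo))
                for fx, fy in upper_frac:
                    pts.append(((ix + fx) * self.a,
                                (iy + fy) * self.a * np.sqrt(3.0), up))
        pts = np.array(pts)
        order = np.lexsort((pts[:, 0], pts[:, 1], pts[:, 2]))
        return pts[order]


@dataclass
class System:
    """A generated structure: topology + coordinates + box + metadata.

    Unpacks as ``topology, frame, box = system`` for interoperability.
    """

    topology: Topology
    frame: Frame
    box: SimulationBox
    lattice: IceLattice | None = None
    metadata: dict = field(default_factory=dict)

    def __iter__(self):
        return iter((self.topology, self.frame, self.box))


def _water_topology_arrays(n_molecules, first_atom_id, first_mol_id,
                           resname="SOL"):
    n = 3 * n_molecules
    ids = np.arange(first_atom_id, first_atom_id + n)
    names = np.array(["OW", "HW1", "HW2"] * n_molecules, dtype=object)
    elements = np.array(["O", "H", "H"] * n_molecules, dtype=object)
    mol = np.repeat(np.arange(first_mol_id, first_mol_id + n_molecules), 3)
    resnames = np.full(n, resname, dtype=object)
    kinds = np.full(n, WATER, dtype=object)
    segments = np.full(n, "NONE", dtype=object)
    masses = np.array([WATER_MASS["O"], WATER_MASS["H"], WATER_MASS["H"]]
                      * n_molecules)
    parent = np.empty(n, dtype=int)
    parent[0::3] = -1
    parent[1::3] = ids[0::3]
    parent[2::3] = ids[0::3]
    donor = np.zeros(n, dtype=bool)
    donor[0::3] = True
    acceptor = donor.copy()
    return Topology(ids, names, elements, mol, resnames, kinds, segments,
                    masses, parent, donor, acceptor)


def water_hydrogens_along_bonds(oxygens: np.ndarray, box: SimulationBox,
                                r_bond: float = 0.30) -> np.ndarray:
    """Place 2 H per O along O-O directions (proton-naive ice rule).

    Returns an (n*3, 3) array in O,H,H order. The two neighbours used are
    the first two in a deterministic (z, y, x)-sorted neighbour list.
    """
    nbrs = neighbor_lists(oxygens, box, r_bond)
    out = np.empty((len(oxygens) * 3, 3))
    for i, o in enumerate(oxygens):
        picks = list(nbrs[i][:2])
        dirs = []
        for j in picks:
            d = box.min_image(oxygens[j] - o)
            dirs.append(d / np.linalg.norm(d))
        while len(dirs) < 2:  # isolated oxygen: fall back to fixed axes
            dirs.append(np.array([1.0, 0.0, 0.0]) if len(dirs) == 0
                        else np.array([0.0, 1.0, 0.0]))
        out[3 * i] = o
        out[3 * i + 1] = o + OH_BOND * dirs[0]
        out[3 * i + 2] = o + OH_BOND * dirs[1]
    return out


def build_ice_slab(nx: int, ny: int, n_layers: int, plane: str = "basal",
                   z0: float = 0.1, z_pad: float = 0.5) -> System:
    """Ideal ice Ih slab with the growth axis along z.

    One layer is a basal bilayer (c/2 = 0.3685 nm thick). For the prism
    orientations the same lattice is built and the axes permuted so the
    requested plane normal lies along z.
    """
    if nx < 1 or ny < 1 or n_layers < 1:
        raise ValueError("slab dimensions must be positive")
    if plane not in PLANES:
        raise ValueError(f"plane must be one of {PLANES}")
    lat = IceLattice(nx=nx, ny=ny, n_layers=n_layers, plane=plane, z0=z0)
    oxy = np.vstack([lat.layer_sites(m) for m in range(n_layers)])
    lengths = np.array([lat.lx, lat.ly,
                        z0 + n_layers * lat.c / 2.0 + z_pad])
    if plane == "prism1":      # growth axis = original y
        oxy = oxy[:, [0, 2, 1]]
        lengths = lengths[[0, 2, 1]]
    elif plane == "prism2":    # growth axis = original x
        oxy = oxy[:, [2, 1, 0]]
        lengths = lengths[[2, 1, 0]]
    box = SimulationBox(lengths, periodic=[True, True, False])
    pos = water_hydrogens_along_bonds(oxy, box)
    topo = _water_topology_arrays(len(oxy), 1, 1)
    frame = Frame(0.0, pos)
    meta = {"temperature_K": 268.0, "n_seed_layers": n_layers}
    return System(topo, frame, box, lattice=lat, metadata=meta)


# -- polymer --------------------------------------------------------------

@dataclass(frozen=True)
class PolymerSpec:
    """Bead-per-unit branched polymer specification.

    ``target_db`` is the degree of branching 2D/(2D+L13+L14) the generated
    unit counts should realise; ``l14_fraction`` splits the linear units
    between 1,3- and 1,4-linked types.
    """

    n_units: int
    target_db: float = 0.0
    seed: int = 0
    l14_fraction: float = 0.0
    bond_length: float = 0.36

    def __post_init__(self):
        if self.n_units < 2:
            raise ValueError("n_units must be >= 2")
        if not 0.0 <= self.target_db <= 1.0:
            raise ValueError("target_db must lie in [0, 1]")


@dataclass
class PolymerMolecule:
    """A generated polymer: topology subgraph, coordinates, unit graph."""

    topology: Topology
    coordinates: np.ndarray
    graph: nx.Graph
    unit_types: list[str]
    unit_counts: dict[str, int]
    db: float
    unit_oxygen_rows: np.ndarray  # row of each unit's O in coordinates

    def __iter__(self):
        return iter((self.topology, self.coordinates))


def _grow_unit_tree(n: int, d_target: int, rng: np.random.Generator) -> nx.Graph:
    g = nx.Graph()
    g.add_edge(0, 1)
    branches = 0
    for i in range(2, n):
        remaining = n - i
        need = d_target - branches
        deg2 = [v for v in g if g.degree(v) == 2]
        force = need >= remaining
        want_branch = need > 0 and deg2 and (force or rng.random() < need / remaining)
        if want_branch:
            host = deg2[rng.integers(len(deg2))]
            branches += 1
        else:
            leaves = [v for v in g if g.degree(v) == 1]
            host = leaves[rng.integers(len(leaves))]
        g.add_edge(host, i)
    return g


def degree_of_branching_from_counts(counts: dict[str, int]) -> float:
    d, l13, l14 = counts.get("D", 0), counts.get("L13", 0), counts.get("L14", 0)
    denom = 2 * d + l13 + l14
    if denom == 0:
        return 0.0
    return 2 * d / denom


def build_polymer(spec: PolymerSpec, start=np.zeros(3),
                  rng: np.random.Generator | None = None) -> PolymerMolecule:
    """Grow a branched bead-per-unit polymer by random attachment.

    Unit types come from graph degree (leaf -> T, degree 2 -> L13/L14 split
    by ``l14_fraction``, branch -> D); coordinates from a self-avoiding
    walk; each unit carries a hydroxyl O (donor+acceptor) and its H.
    """
    rng = rng if rng is not None else np.random.default_rng(spec.seed)
    n = spec.n_units
    if n == 2:
        g = nx.Graph([(0, 1)])
        d_target = 0
    else:
        d_max = (n - 2) // 2
        d_target = int(round(spec.target_db * (n - 2) / 2.0))
        if d_target > d_max:
            raise ValueError(
                f"target_db={spec.target_db} infeasible for n_units={n}")
        g = _grow_unit_tree(n, d_target, rng)
    types: list[str] = []
    for v in range(n):
        deg = g.degree(v)
        if deg == 1:
            types.append("T")
        elif deg == 2:
            types.append("L14" if rng.random() < spec.l14_fraction else "L13")
        else:
            types.append("D")
    counts = {t: types.count(t) for t in ("D", "L13", "L14", "T")}

    # self-avoiding walk over the tree in BFS order
    pos = np.zeros((n, 3))
    placed = {0}
    pos[0] = np.asarray(start, dtype=float)
    for parent_node, child in nx.bfs_edges(g, 0):
        for _ in range(500):
            d = rng.normal(size=3)
            d /= np.linalg.norm(d)
            cand = pos[parent_node] + spec.bond_length * d
            dists = np.linalg.norm(pos[list(placed)] - cand, axis=1)
            if np.all(dists > 0.25):
                pos[child] = cand
                placed.add(child)
                break
        else:
            raise RuntimeError("self-avoiding walk failed; too compact")

    coords = np.empty((2 * n, 3))
    for v in range(n):
        h_dir = rng.normal(size=3)
        h_dir /= np.linalg.norm(h_dir)
        coords[2 * v] = pos[v]
        coords[2 * v + 1] = pos[v] + OH_BOND * h_dir

    ids = np.arange(1, 2 * n + 1)
    names = np.array(["OU", "HU"] * n, dtype=object)
    elements = np.array(["O", "H"] * n, dtype=object)
    mol = np.ones(2 * n, dtype=int)
    resnames = np.full(2 * n, "PGU", dtype=object)
    kinds = np.full(2 * n, POLYMER, dtype=object)
    segments = np.array([s for t in types for s in (t, t)], dtype=object)
    masses = np.array([PG_UNIT_O_MASS, WATER_MASS["H"]] * n)
    parent = np.empty(2 * n, dtype=int)
    parent[0::2] = -1
    parent[1::2] = ids[0::2]
    donor = np.zeros(2 * n, dtype=bool)
    donor[0::2] = True
    acceptor = donor.copy()
    topo = Topology(ids, names, elements, mol, resnames, kinds, segments,
                    masses, parent, donor, acceptor)
    return PolymerMolecule(topo, coords, g, types, counts,
                           degree_of_branching_from_counts(counts),
                           np.arange(0, 2 * n, 2))


# -- mixed systems --------------------------------------------------------

LIQUID_NUMBER_DENSITY = 33.4  # molecules/nm^3, ~1.00 g/cm^3
MIN_SEPARATION = 0.24         # nm between placement sites (heavy atoms)


class _CellList:
    """Cell list over an orthorhombic box, periodic in the flagged axes.

    Cell widths are >= the query radius, so the 27 neighbouring cells
    (index-wrapped on periodic axes) always cover a radius-r ball.
    """

    def __init__(self, box: SimulationBox, cell: float):
        self.box = box
        self.ncell = np.maximum(1, (box.lengths // cell).astype(int))
        self.width = box.lengths / self.ncell
        self.data: dict[tuple, list[np.ndarray]] = {}

    def _key(self, p):
        k = np.floor(np.asarray(p) / self.width).astype(int)
        for ax in range(3):
            if self.box.periodic[ax]:
                k[ax] %= self.ncell[ax]
            else:
                k[ax] = min(max(k[ax], 0), self.ncell[ax] - 1)
        return tuple(k)

    def add(self, p):
        p = self.box.wrap(np.asarray(p, dtype=float))
        self.data.setdefault(self._key(p), []).append(p)

    def any_within(self, p, r) -> bool:
        if np.any(self.width < r - 1e-12):
            raise ValueError("cell list built with cells smaller than query radius")
        p = self.box.wrap(np.asarray(p, dtype=float))
        kx, ky, kz = self._key(p)
        for dx in (-1, 0, 1):
            for dy in (-1, 0, 1):
                for dz in (-1, 0, 1):
                    key = [kx + dx, ky + dy, kz + dz]
                    for ax in range(3):
                        if self.box.periodic[ax]:
                            key[ax] %= self.ncell[ax]
                    for q in self.data.get(tuple(key), ()):
                        if np.linalg.norm(self.box.min_image(p - q)) < r:
                            return True
        return False

    def add_many(self, pts):
        for p in pts:
            self.add(p)


def _random_water_orientation(o, rng):
    """O,H,H positions with ~104.5 deg HOH angle, random orientation."""
    d1 = rng.normal(size=3)
    d1 /= np.linalg.norm(d1)
    # second direction at 104.5 degrees from d1, random azimuth
    ref = np.array([1.0, 0.0, 0.0])
    if abs(d1 @ ref) > 0.9:
        ref = np.array([0.0, 1.0, 0.0])
    u = np.cross(d1, ref)
    u /= np.linalg.norm(u)
    v = np.cross(d1, u)
    phi = rng.uniform(0, 2 * np.pi)
    ang = np.deg2rad(104.5)
    d2 = np.cos(ang) * d1 + np.sin(ang) * (np.cos(phi) * u + np.sin(phi) * v)
    return np.vstack([o, o + OH_BOND * d1, o + OH_BOND * d2])


def build_mixed_system(nx: int, ny: int, n_layers: int,
                       liquid_depth: float,
                       polymers: tuple[PolymerSpec, ...] = (),
                       polymer_z_offset: float = 2.0,
                       plane: str = "basal",
                       number_density: float = LIQUID_NUMBER_DENSITY,
                       min_sep: float = MIN_SEPARATION,
                       headroom: float = 1.0,
                       liquid_gap: float = 0.15,
                       seed: int = 0,
                       max_tries: int = 2000) -> System:
    """Ice slab + liquid layer (+ polymers 2 nm above the seed by default).

    Liquid waters are placed by rejection sampling at ``number_density``
    (33.4/nm^3, about 1.00 g/cm^3) with a minimum heavy-atom separation,
    starting ``liquid_gap`` above the slab top (the clearance the growth
    scripting maintains at the front; it keeps the seed's top layer
    crystalline for the classifier). Polymer centres of mass sit
    ``polymer_z_offset`` above the slab top.
    """
    if liquid_depth <= 0:
        raise ValueError("liquid_depth must be positive")
    rng = np.random.default_rng(seed)
    slab = build_ice_slab(nx, ny, n_layers, plane=plane, z_pad=0.0)
    lat = slab.lattice
    slab_top = lat.layer_z(n_layers - 1)[1]
    liquid_bottom = slab_top + liquid_gap
    lengths = np.array([slab.box.lengths[0], slab.box.lengths[1],
                        liquid_bottom + liquid_depth + headroom])
    box = SimulationBox(lengths, periodic=[True, True, False])

    occupied = _CellList(box, min_sep + 0.1)
    slab_oxy = slab.frame.positions[slab.topology.water_oxygen_idx]
    occupied.add_many(slab_oxy)

    # polymers first so liquid sampling avoids them
    poly_mols: list[PolymerMolecule] = []
    poly_coords: list[np.ndarray] = []
    for k, spec in enumerate(polymers):
        pm = build_polymer(spec, rng=np.random.default_rng([seed, 1000 + k]))
        for attempt in range(max_tries):
            com_xy = rng.uniform([0, 0], lengths[:2])
            target = np.array([com_xy[0], com_xy[1],
                               slab_top + polymer_z_offset])
            shift = target - pm.coordinates.mean(axis=0)
            cand = box.wrap(pm.coordinates + shift)
            heavy = cand[pm.unit_oxygen_rows]
            if np.all((heavy[:, 2] > slab_top + 0.3) &
                      (heavy[:, 2] < lengths[2] - 0.2)) and \
                    not any(occupied.any_within(p, min_sep + 0.05) for p in heavy):
                poly_mols.append(pm)
                poly_coords.append(cand)
                occupied.add_many(heavy)
                break
        else:
            raise RuntimeError(f"could not insert polymer {k} without overlap")

    n_liquid = int(round(number_density * lengths[0] * lengths[1] * liquid_depth))
    liquid_o = []
    tries = 0
    while len(liquid_o) < n_liquid:
        p = rng.uniform([0.0, 0.0, liquid_bottom],
                        [lengths[0], lengths[1], liquid_bottom + liquid_depth])
        if not occupied.any_within(p, min_sep):
            occupied.add(p)
            liquid_o.append(p)
            tries = 0
        else:
            tries += 1
            if tries > max_tries:
                raise RuntimeError("liquid insertion failed; density too high")

    parts_topo = [slab.topology]
    parts_pos = [slab.frame.positions]
    n_slab_mol = len(slab_oxy)
    next_atom = slab.topology.n_atoms + 1
    next_mol = n_slab_mol + 1
    if liquid_o:
        lt = _water_topology_arrays(len(liquid_o), next_atom, next_mol)
        lp = np.vstack([_random_water_orientation(o, rng) for o in liquid_o])
        parts_topo.append(lt)
        parts_pos.append(lp)
        next_atom += lt.n_atoms
        next_mol += len(liquid_o)
    polymer_mol_ids = []
    for pm, coords in zip(poly_mols, poly_coords):
        pt = pm.topology
        shifted = Topology(
            ids=pt.ids + (next_atom - 1), names=pt.names, elements=pt.elements,
            molecule_ids=np.full(pt.n_atoms, next_mol),
            resnames=pt.resnames, kinds=pt.kinds, segments=pt.segments,
            masses=pt.masses,
            parent=np.where(pt.parent > 0, pt.parent + (next_atom - 1), -1),
            donor=pt.donor, acceptor=pt.acceptor)
        parts_topo.append(shifted)
        parts_pos.append(coords)
        polymer_mol_ids.append(next_mol)
        next_atom += pt.n_atoms
        next_mol += 1

    topo = concat_topologies(parts_topo)
    topo.validate()
    frame = Frame(0.0, np.vstack(parts_pos))
    meta = {"temperature_K": 268.0,
            "n_seed_layers": n_layers,
            "slab_top": float(slab_top),
            "liquid_bottom": float(liquid_bottom),
            "liquid_top": float(liquid_bottom + liquid_depth),
            "n_slab_molecules": n_slab_mol,
            "polymer_molecule_ids": polymer_mol_ids,
            "polymer_unit_counts": [pm.unit_counts for pm in poly_mols],
            "polymer_db": [pm.db for pm in poly_mols],
            "seed": seed}
    return System(topo, frame, box, lattice=lat, metadata=meta)


# -- scripted growth ------------------------------------------------------

@dataclass
class ScriptedHBond:
    """One scripted polymer-water H-bond event (frame-resolved)."""

    frame: int
    water_id: int          # water molecule id
    unit_atom_id: int      # polymer hydroxyl O atom id
    polymer_mol_id: int = -1   # filled by the generator
    segment: str = ""          # filled by the generator


@dataclass
class GroundTruthLog:
    """Every scripted fact of a synthetic trajectory, for exact recovery."""

    step_times: list[float] = field(default_factory=list)     # ps
    step_heights: list[float] = field(default_factory=list)   # nm
    front_height: list[float] = field(default_factory=list)   # per frame, nm
    layer_members: dict = field(default_factory=dict)         # layer -> [mol ids]
    hbond_events: list[dict] = field(default_factory=list)
    mobility_classes: dict = field(default_factory=dict)      # mol id -> label
    diffusion_map: dict = field(default_factory=dict)         # mol id -> nm^2/ns
    dt: float = 0.0
    seed: int = 0

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(asdict(self), fh, indent=1, default=float)

    @classmethod
    def from_json(cls, path) -> "GroundTruthLog":
        with open(path) as fh:
            raw = json.load(fh)
        raw["layer_members"] = {int(k): v for k, v in raw["layer_members"].items()}
        raw["mobility_classes"] = {int(k): v for k, v in
                                   raw["mobility_classes"].items()}
        raw["diffusion_map"] = {int(k): v for k, v in raw["diffusion_map"].items()}
        return cls(**raw)


# z-biased approach directions for scripted bond geometry
_EVENT_DIRS = [np.array([0.0, 0.0, 1.0])] + [
    np.array([np.sin(np.pi / 3) * np.cos(phi),
              np.sin(np.pi / 3) * np.sin(phi),
              np.cos(np.pi / 3)])
    for phi in (0.0, 2 * np.pi / 3, 4 * np.pi / 3)
]
_EVENT_OO = 0.28   # nm scripted donor-acceptor distance


def _park_positions(n_atoms, box, liquid_top, spacing=0.3, clearance=0.5):
    """Deterministic grid in the headroom above the liquid."""
    z0 = liquid_top + clearance
    nxg = max(1, int(box.lengths[0] // spacing))
    nyg = max(1, int(box.lengths[1] // spacing))
    pts = []
    k = 0
    z = z0
    while len(pts) < n_atoms:
        if z > box.lengths[2] - 0.1:
            raise RuntimeError("not enough headroom to park the polymer; "
                               "increase the box height")
        ix, iy = k % nxg, (k // nxg) % nyg
        pts.append([ (ix + 0.5) * box.lengths[0] / nxg,
                     (iy + 0.5) * box.lengths[1] / nyg, z])
        k += 1
        if k % (nxg * nyg) == 0:
            z += spacing
    return np.array(pts)


def scripted_growth(system: System,
                    step_times,
                    n_frames: int,
                    dt: float = 10.0,
                    step_height: float | None = None,
                    hbond_script=(),
                    polymer_path=None,
                    jitter: float = 0.0,
                    seed: int = 0) -> tuple[Trajectory, GroundTruthLog]:
    """Scripted stepwise basal growth with optional H-bond events.

    At each step time one whole liquid layer snaps onto the lattice sites
    atop the current front (rise = one basal layer, c/2). Scripted H-bond
    events are realised geometrically: the named polymer hydroxyl is
    placed within the detection geometry of the named water for exactly
    the scripted frames, and any bystander water that would fall inside
    the detection distance is pushed clear, so the emitted log is the
    exact set of polymer-water bonds present.
    """
    topo, frame0, box = system
    lat = system.lattice
    if lat is None or lat.plane != "basal":
        raise ValueError("scripted growth requires a basal-plane ice system")
    rng = np.random.default_rng(seed)
    step_times = sorted(float(t) for t in step_times)
    times = np.arange(n_frames) * dt
    if step_times and step_times[-1] > times[-1]:
        raise ValueError("step times must lie within the trajectory span")
    rise = step_height if step_height is not None else lat.layer_spacing

    o_idx = topo.water_oxygen_idx
    mol_of_o = topo.molecule_ids[o_idx]
    n_seed = system.metadata["n_seed_layers"]
    n_slab_mol = system.metadata.get("n_slab_molecules",
                                     lat.sites_per_layer * n_seed)
    liquid_o_rows = np.arange(len(o_idx))[n_slab_mol:]

    poly_rows = topo.polymer_idx
    poly_mol_ids = sorted(set(topo.molecule_ids[poly_rows].tolist()))
    id_to_row = topo.index_of_id()

    # plan which liquid waters freeze at which step
    log = GroundTruthLog(dt=dt, seed=seed)
    per_layer = lat.sites_per_layer
    for m in range(n_seed):
        log.layer_members[m] = mol_of_o[m * per_layer:(m + 1) * per_layer].tolist()

    frozen_at = {}           # water mol id -> (frame index, site, h positions)
    available = list(liquid_o_rows)
    step_frames = []
    liquid_pos0 = frame0.positions[o_idx]
    current_top_layer = n_seed - 1
    slab_oxy_all = [frame0.positions[o_idx[:n_slab_mol]]]
    for k, t_step in enumerate(step_times):
        fidx = int(np.searchsorted(times, t_step - 1e-9))
        step_frames.append(fidx)
        layer = n_seed + k
        sites = lat.layer_sites(layer)
        if len(available) < len(sites):
            raise ValueError("not enough liquid water to freeze the next layer")
        cand = sorted(available, key=lambda r: liquid_pos0[r][2])[:3 * len(sites)]
        cpos = liquid_pos0[np.array(cand)]
        cost = np.linalg.norm(
            box.min_image(cpos[:, None, :] - sites[None, :, :]), axis=2)
        ri, ci = linear_sum_assignment(cost)
        chosen = {}
        for r, c in zip(ri, ci):
            chosen[int(cand[r])] = sites[c]
        for r in chosen:
            available.remove(r)
        # hydrogen directions on the full lattice context
        all_o = np.vstack(slab_oxy_all + [sites])
        full = water_hydrogens_along_bonds(all_o, box)
        site_h = {tuple(np.round(s, 6)): full[3 * (len(all_o) - len(sites) + j) + 1:
                                              3 * (len(all_o) - len(sites) + j) + 3]
                  for j, s in enumerate(sites)}
        for r, s in chosen.items():
            frozen_at[int(mol_of_o[r])] = (fidx, s, site_h[tuple(np.round(s, 6))])
        slab_oxy_all.append(sites)
        log.layer_members[layer] = sorted(int(mol_of_o[r]) for r in chosen)
        log.step_times.append(times[fidx])
        log.step_heights.append(rise)
        current_top_layer = layer

    # normalise the script
    events: list[ScriptedHBond] = []
    for ev in hbond_script:
        ev = ScriptedHBond(ev.frame, ev.water_id, ev.unit_atom_id) \
            if not isinstance(ev, ScriptedHBond) else ev
        if ev.frame < 0 or ev.frame >= n_frames:
            raise ValueError(f"scripted event frame {ev.frame} out of range")
        if ev.unit_atom_id not in id_to_row:
            raise ValueError(f"unknown polymer atom id {ev.unit_atom_id}")
        row = id_to_row[ev.unit_atom_id]
        if topo.kinds[row] != POLYMER or topo.elements[row] != "O":
            raise ValueError(f"atom {ev.unit_atom_id} is not a polymer hydroxyl O")
        wmol = ev.water_id
        wrows = np.where((topo.molecule_ids == wmol) & (topo.kinds == WATER))[0]
        if len(wrows) == 0:
            raise ValueError(f"unknown water molecule {wmol}")
        if wmol in frozen_at and times[ev.frame] >= times[frozen_at[wmol][0]]:
            raise ValueError(f"water {wmol} is already frozen at frame {ev.frame}")
        ev.polymer_mol_id = int(topo.molecule_ids[row])
        ev.segment = str(topo.segments[row])
        events.append(ev)
        log.hbond_events.append({"frame": ev.frame, "time": float(times[ev.frame]),
                                 "water_id": int(wmol),
                                 "unit_atom_id": int(ev.unit_atom_id),
                                 "polymer_mol_id": ev.polymer_mol_id,
                                 "segment": ev.segment})
    events_by_frame: dict[int, list[ScriptedHBond]] = {}
    for ev in events:
        events_by_frame.setdefault(ev.frame, []).append(ev)

    liquid_top = system.metadata.get("liquid_top", box.lengths[2] - 1.0)
    park = None
    if len(poly_rows) and (events or polymer_path is None):
        # the liquid ceiling rises as layers freeze; park above its final
        # level so parked beads can never touch lifted waters
        n_rem_final = len(liquid_o_rows) - len(step_times) * per_layer
        area = box.lengths[0] * box.lengths[1]
        front_final = lat.layer_z(n_seed - 1 + len(step_times))[1]
        ceiling_final = max(liquid_top, front_final + 0.15 +
                            n_rem_final / (LIQUID_NUMBER_DENSITY * area)
                            * 1.15)
        park = _park_positions(len(poly_rows), box, ceiling_final)

    # evolve a persistent base state: freezing a layer snaps the chosen
    # waters onto lattice sites and lifts displaced bystander liquid above
    # the new front (a layer cannot grow through liquid occupying it)
    base = frame0.positions.copy()
    frames = []
    h0 = lat.layer_z(n_seed - 1)[1]
    mol_rows = {int(m): np.where(topo.molecule_ids == m)[0]
                for m in np.unique(topo.molecule_ids)}
    front_z = h0
    for fi in range(n_frames):
        # step events that fire at this frame
        newly = [wm for wm, (fidx, _, _) in frozen_at.items() if fidx == fi]
        if newly:
            for wmol in newly:
                _, site, hpos = frozen_at[wmol]
                rows = mol_rows[wmol]
                orow = rows[topo.elements[rows] == "O"][0]
                hrows = rows[topo.elements[rows] == "H"]
                base[orow] = site
                base[hrows[0]] = hpos[0]
                base[hrows[1]] = hpos[1]
            layer = max(m for m, t in
                        ((n_seed + k, f) for k, f in enumerate(step_frames))
                        if t <= fi)
            front_z = lat.layer_z(layer)[1]
            _lift_displaced_liquid(base, topo, box, mol_of_o, o_idx,
                                   liquid_o_rows, frozen_at, fi, front_z,
                                   liquid_top, rng)
        log.front_height.append(float(front_z))
        pos = base.copy()
        if jitter > 0:
            jrng = np.random.default_rng([seed, 7, fi])
            for r in liquid_o_rows:
                wmol = int(mol_of_o[r])
                if wmol in frozen_at and fi >= frozen_at[wmol][0]:
                    continue
                pos[mol_rows[wmol]] += jrng.normal(scale=jitter, size=3)
        # polymer placement
        if len(poly_rows):
            if polymer_path is not None:
                way = np.asarray(polymer_path, dtype=float)
                com = np.array([np.interp(times[fi], way[:, 0], way[:, 1 + ax])
                                for ax in range(3)])
                pos[poly_rows] += com - pos[poly_rows].mean(axis=0)
            elif park is not None:
                pos[poly_rows] = park
        # scripted events last: they override everything else
        if fi in events_by_frame:
            _realise_events(pos, topo, box, events_by_frame[fi], id_to_row,
                            frozen_at, fi, times)
        frames.append(Frame(times[fi], pos))
    traj = Trajectory(frames, box)
    return traj, log


def _lift_displaced_liquid(base, topo, box, mol_of_o, o_idx, liquid_o_rows,
                           frozen_at, fi, front_z, liquid_top, rng,
                           clearance=0.24):
    """Move unfrozen liquid below/inside the new front above it.

    The liquid ceiling rises with the front so the remaining waters never
    exceed bulk liquid density (freezing displaces the interface upward).
    """
    frozen_now = {m for m, (f, _, _) in frozen_at.items() if f <= fi}
    lifted_region_lo = front_z + 0.15
    n_rem = sum(1 for r in liquid_o_rows
                if int(mol_of_o[r]) not in frozen_now)
    area = box.lengths[0] * box.lengths[1]
    needed = n_rem / (LIQUID_NUMBER_DENSITY * area) * 1.15
    ceiling = min(max(liquid_top, lifted_region_lo + needed),
                  box.lengths[2] - 0.1)
    cells = _CellList(box, 0.34)
    for r in liquid_o_rows:
        wmol = int(mol_of_o[r])
        if wmol in frozen_now or base[o_idx[r], 2] >= lifted_region_lo:
            cells.add(base[o_idx[r]])
    for r in liquid_o_rows:
        wmol = int(mol_of_o[r])
        if wmol in frozen_now or base[o_idx[r], 2] >= lifted_region_lo:
            continue
        for _ in range(5000):
            p = rng.uniform([0.0, 0.0, lifted_region_lo],
                            [box.lengths[0], box.lengths[1], ceiling])
            if not cells.any_within(p, clearance):
                break
        else:
            raise RuntimeError("could not relocate displaced liquid water; "
                               "increase the box headroom")
        rows = np.where(topo.molecule_ids == wmol)[0]
        orow = o_idx[r]
        delta = p - base[orow]
        base[rows] += delta
        cells.add(p)


def _realise_events(pos, topo, box, evs, id_to_row, frozen_at, fi, times):
    by_water: dict[int, list[ScriptedHBond]] = {}
    for ev in evs:
        by_water.setdefault(ev.water_id, []).append(ev)
    placed_units = []
    for wmol, wevs in by_water.items():
        wrows = np.where(topo.molecule_ids == wmol)[0]
        orow = wrows[topo.elements[wrows] == "O"][0]
        hrows = wrows[topo.elements[wrows] == "H"]
        o = pos[orow]
        # point the water's own hydrogens down, away from the approach cone
        pos[hrows[0]] = o + OH_BOND * np.array([0.3, 0.0, -0.954])
        pos[hrows[1]] = o + OH_BOND * np.array([-0.3, 0.0, -0.954])
        if len(wevs) > len(_EVENT_DIRS):
            raise ValueError("at most 4 simultaneous scripted bonds per water")
        for d, ev in zip(_EVENT_DIRS, wevs):
            urow = id_to_row[ev.unit_atom_id]
            hrow = topo.hydrogens_of(urow)
            uo = o + _EVENT_OO * d
            pos[urow] = uo
            if len(hrow):
                pos[hrow[0]] = o + (_EVENT_OO - OH_BOND) * d
            placed_units.append(urow)
    # push bystander liquid waters out of detection range
    frozen_rows = set()
    for m, (fidx, _, _) in frozen_at.items():
        if fi >= fidx:
            frozen_rows.update(np.where(topo.molecule_ids == m)[0].tolist())
    event_waters = set(by_water)
    o_idx = topo.water_oxygen_idx
    for _ in range(5):
        dirty = False
        for urow in placed_units:
            u = pos[urow]
            d = np.linalg.norm(box.min_image(pos[o_idx] - u), axis=1)
            for j in np.where(d < 0.45)[0]:
                orow = o_idx[j]
                wm = int(topo.molecule_ids[orow])
                if wm in event_waters or orow in frozen_rows:
                    continue
                vec = box.min_image(pos[orow] - u)
                nrm = np.linalg.norm(vec)
                vec = vec / nrm if nrm > 1e-9 else np.array([0, 0, 1.0])
                shift = (0.5 - nrm) * vec if nrm > 1e-9 else 0.5 * vec
                rows = np.where(topo.molecule_ids == wm)[0]
                pos[rows] += shift
                dirty = True
        if not dirty:
            break


def build_shell_system(shells=(0.5, 1.0, 2.0),
                       d_values=(0.05e-3, 0.15e-3, 0.20e-3),
                       n_per_shell: int = 400,
                       box_length: float = 10.0,
                       polymer_units: int = 10,
                       margin: float = 0.12,
                       seed: int = 0):
    """Waters stratified into distance shells around a central polymer.

    Each shell band (inner margin to outer margin inside the shell
    boundaries) receives ``n_per_shell`` waters, and every water is
    assigned the band's diffusion coefficient (nm^2/ps). Returns
    (System, diffusion_map); feed both to :func:`isoca_ensemble` and the
    shell-diffusion analysis to test parameter recovery with known truth.
    """
    if len(shells) != len(d_values):
        raise ValueError("need one diffusion coefficient per shell")
    rng = np.random.default_rng(seed)
    box = SimulationBox([box_length] * 3, periodic=[True, True, True])
    pm = build_polymer(PolymerSpec(polymer_units, 0.5, seed=seed))
    center = np.full(3, box_length / 2.0)
    pcoords = pm.coordinates + (
        center - pm.coordinates[pm.unit_oxygen_rows].mean(axis=0))
    pheavy = pcoords[pm.unit_oxygen_rows]
    bounds = [0.0] + list(shells)
    oxy, dmap = [], {}
    for s, (lo, hi) in enumerate(zip(bounds[:-1], bounds[1:])):
        lo_b, hi_b = lo + margin + (0.08 if s == 0 else 0.0), hi - margin
        placed = 0
        while placed < n_per_shell:
            p = rng.uniform(0, box_length, 3)
            d = np.linalg.norm(box.min_image(p - pheavy), axis=1).min()
            if lo_b <= d <= hi_b:
                oxy.append(p)
                dmap[len(oxy)] = d_values[s]
                placed += 1
    oxy = np.array(oxy)
    n = len(oxy)
    wt = _water_topology_arrays(n, 1, 1)
    pt = pm.topology
    pt2 = Topology(ids=pt.ids + wt.n_atoms, names=pt.names,
                   elements=pt.elements,
                   molecule_ids=np.full(pt.n_atoms, n + 1),
                   resnames=pt.resnames, kinds=pt.kinds, segments=pt.segments,
                   masses=pt.masses,
                   parent=np.where(pt.parent > 0, pt.parent + wt.n_atoms, -1),
                   donor=pt.donor, acceptor=pt.acceptor)
    topo = concat_topologies([wt, pt2])
    wpos = np.vstack([_random_water_orientation(p, rng) for p in oxy])
    frame = Frame(0.0, np.vstack([wpos, pcoords]))
    meta = {"shells": list(shells), "d_values": list(d_values),
            "n_per_shell": n_per_shell, "seed": seed}
    return System(topo, frame, box, metadata=meta), dmap


# -- iso-configurational ensembles ----------------------------------------

def isoca_ensemble(topo: Topology, frame0: Frame, box: SimulationBox,
                   M: int, diffusion_map: dict[int, float],
                   frozen: set[int] = frozenset(),
                   t_star: float = 100.0, dt: float = 1.0,
                   seed: int = 0) -> list[Trajectory]:
    """M overdamped random walks from one shared initial configuration.

    Each water molecule m takes Gaussian steps with variance 2*D_m*dt per
    axis (D in nm^2/ps); frozen molecules do not move. Run seeds derive
    deterministically from (seed, run index), so the ensemble is
    reproducible and runs are independent.
    """
    if M < 1:
        raise ValueError("M must be >= 1")
    for v in diffusion_map.values():
        if v < 0:
            raise ValueError("diffusion coefficients must be non-negative")
    o_idx = topo.water_oxygen_idx
    mols = topo.molecule_ids[o_idx]
    n_frames = int(round(t_star / dt)) + 1
    sigma = np.array([0.0 if m in frozen
                      else np.sqrt(2.0 * diffusion_map.get(int(m), 0.0) * dt)
                      for m in mols])
    mol_rows = [np.where(topo.molecule_ids == m)[0] for m in mols]
    out = []
    for run in range(M):
        rng = np.random.default_rng([seed, run])
        pos = frame0.positions.copy()
        frames = [Frame(0.0, pos.copy())]
        for t in range(1, n_frames):
            steps = rng.normal(size=(len(mols), 3)) * sigma[:, None]
            for j, rows in enumerate(mol_rows):
                pos[rows] += steps[j]
            frames.append(Frame(t * dt, box.wrap(pos)))
        out.append(Trajectory(frames, box))
    return out
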