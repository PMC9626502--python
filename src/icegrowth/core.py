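"""Core domain types for structures, trajectories and periodic geometry.

Units throughout the package: lengths in nm, times in ps, masses in amu,
densities in g/cm^3 unless a function says otherwise.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterator, Sequence

import numpy as np
from scipy.spatial import cKDTree

# molecule kinds
WATER = "WATER"
POLYMER = "POLYMER"
OTHER = "OTHER"
KINDS = (WATER, POLYMER, OTHER)

# polymer segment vocabulary: linear 1,3- and 1,4-linked units, dendritic
# (branch) units and terminal units; NONE for everything that is not polymer.
SEGMENTS = ("L13", "L14", "D", "T", "NONE")

#: amu/nm^3 -> g/cm^3
AMU_PER_NM3_TO_G_CM3 = 1.66053906660e-3

ELEMENT_MASSES = {
    "H": 1.008, "O": 15.999, "C": 12.011, "N": 14.007, "M": 0.0,
}

WATER_RESNAMES = {"SOL", "HOH", "WAT", "TIP3", "TIP4", "TIP4P", "T4P", "SPC"}


class ParseError(ValueError):
    """Malformed structure/trajectory input."""


@dataclass(frozen=True)
class SimulationBox:
    """Orthorhombic simulation cell.

    Parameters
    ----------
    lengths : 3 extents in nm.
    periodic : per-axis periodicity flags; analyses honour these.
    """

    lengths: np.ndarray
    periodic: np.ndarray = field(default_factory=lambda: np.array([True, True, False]))

    def __post_init__(self):
        object.__setattr__(self, "lengths", np.asarray(self.lengths, dtype=float))
        object.__setattr__(self, "periodic", np.asarray(self.periodic, dtype=bool))
        if self.lengths.shape != (3,) or np.any(self.lengths <= 0):
            raise ValueError("box extents must be three positive lengths")
        if self.periodic.shape != (3,):
            raise ValueError("periodic must have three flags")

    @property
    def volume(self) -> float:
        return float(np.prod(self.lengths))

    def min_image(self, d: np.ndarray) -> np.ndarray:
        """Minimum-image displacement vectors for the periodic axes."""
        d = np.asarray(d, dtype=float).copy()
        for ax in range(3):
            if self.periodic[ax]:
                L = self.lengths[ax]
                d[..., ax] -= L * np.round(d[..., ax] / L)
        return d

    def wrap(self, pos: np.ndarray) -> np.ndarray:
        """Wrap positions into [0, L) on periodic axes."""
        pos = np.asarray(pos, dtype=float).copy()
        for ax in range(3):
            if self.periodic[ax]:
                pos[..., ax] %= self.lengths[ax]
        return pos


@dataclass
class Frame:
    """One trajectory frame: time in ps and per-atom positions in nm."""

    time: float
    positions: np.ndarray

    def __post_init__(self):
        self.positions = np.asarray(self.positions, dtype=float)
        if self.positions.ndim != 2 or self.positions.shape[1] != 3:
            raise ValueError("positions must be (n_atoms, 3)")
        if not np.all(np.isfinite(self.positions)):
            raise ValueError("positions must be finite")

    @property
    def n_atoms(self) -> int:
        return self.positions.shape[0]


@dataclass
class Trajectory:
    """Time-ordered frames over a constant-atom-count system."""

    frames: list[Frame]
    box: SimulationBox

    def __post_init__(self):
        if not self.frames:
            raise ValueError("trajectory must contain at least one frame")
        n = self.frames[0].n_atoms
        for i, fr in enumerate(self.frames):
            if fr.n_atoms != n:
                raise ValueError(f"frame {i}: atom count {fr.n_atoms} != {n}")
        times = self.times
        if np.any(np.diff(times) <= 0) and len(times) > 1:
            raise ValueError("frame times must be strictly increasing")

    @property
    def n_frames(self) -> int:
        return len(self.frames)

    @property
    def n_atoms(self) -> int:
        return self.frames[0].n_atoms

    @property
    def times(self) -> np.ndarray:
        return np.array([f.time for f in self.frames])

    def __iter__(self) -> Iterator[Frame]:
        return iter(self.frames)

    def __getitem__(self, i) -> Frame:
        return self.frames[i]

    def positions_array(self) -> np.ndarray:
        """(n_frames, n_atoms, 3) stacked positions."""
        return np.stack([f.positions for f in self.frames])


@dataclass
class Topology:
    """Per-atom identity and chemistry needed by the analyses.

    ``parent`` maps a hydrogen to the id of the heavy atom it is bonded to
    (donor bookkeeping); it is -1 for heavy atoms and unbonded sites.
    """

    ids: np.ndarray
    names: np.ndarray
    elements: np.ndarray
    molecule_ids: np.ndarray
    resnames: np.ndarray
    kinds: np.ndarray
    segments: np.ndarray
    masses: np.ndarray
    parent: np.ndarray
    donor: np.ndarray      # heavy atoms able to donate (have attached H)
    acceptor: np.ndarray   # heavy atoms able to accept

    def __post_init__(self):
        n = len(self.ids)
        self.ids = np.asarray(self.ids, dtype=int)
        self.names = np.asarray(self.names, dtype=object)
        self.elements = np.asarray(self.elements, dtype=object)
        self.molecule_ids = np.asarray(self.molecule_ids, dtype=int)
        self.resnames = np.asarray(self.resnames, dtype=object)
        self.kinds = np.asarray(self.kinds, dtype=object)
        self.segments = np.asarray(self.segments, dtype=object)
        self.masses = np.asarray(self.masses, dtype=float)
        self.parent = np.asarray(self.parent, dtype=int)
        self.donor = np.asarray(self.donor, dtype=bool)
        self.acceptor = np.asarray(self.acceptor, dtype=bool)
        for arr in (self.names, self.elements, self.molecule_ids, self.resnames,
                    self.kinds, self.segments, self.masses, self.parent,
                    self.donor, self.acceptor):
            if len(arr) != n:
                raise ValueError("all topology arrays must have equal length")

    @property
    def n_atoms(self) -> int:
        return len(self.ids)

    def validate(self) -> None:
        """Enforce the structural invariants."""
        if len(np.unique(self.ids)) != self.n_atoms:
            raise ValueError("atom ids must be unique")
        bad = (self.segments != "NONE") & (self.kinds != POLYMER)
        if np.any(bad):
            raise ValueError("segment labels are only valid on polymer atoms")
        for kind in np.unique(self.kinds):
            if kind not in KINDS:
                raise ValueError(f"unknown molecule kind {kind!r}")
        for seg in np.unique(self.segments):
            if seg not in SEGMENTS:
                raise ValueError(f"unknown segment {seg!r}")
        for mol in np.unique(self.molecule_ids[self.kinds == WATER]):
            el = self.elements[self.molecule_ids == mol]
            n_o = int(np.sum(el == "O"))
            n_h = int(np.sum(el == "H"))
            if n_o != 1 or n_h != 2:
                raise ValueError(
                    f"water molecule {mol} has {n_o} O and {n_h} H (need 1 and 2)")

    # -- convenience selections -------------------------------------------

    def index_of_id(self) -> dict[int, int]:
        return {int(a): i for i, a in enumerate(self.ids)}

    @property
    def water_oxygen_idx(self) -> np.ndarray:
        return np.where((self.kinds == WATER) & (self.elements == "O"))[0]

    @property
    def water_molecule_ids(self) -> np.ndarray:
        """Molecule ids of waters, in oxygen (file) order."""
        return self.molecule_ids[self.water_oxygen_idx]

    @property
    def polymer_idx(self) -> np.ndarray:
        return np.where(self.kinds == POLYMER)[0]

    @property
    def polymer_heavy_idx(self) -> np.ndarray:
        return np.where((self.kinds == POLYMER) & (self.elements != "H"))[0]

    def hydrogens_of(self, heavy_index: int) -> np.ndarray:
        """Indices of hydrogens bonded to the heavy atom at ``heavy_index``."""
        return np.where(self.parent == self.ids[heavy_index])[0]

    def subset(self, idx: np.ndarray) -> "Topology":
        idx = np.asarray(idx, dtype=int)
        return Topology(*(getattr(self, f)[idx] for f in (
            "ids", "names", "elements", "molecule_ids", "resnames", "kinds",
            "segments", "masses", "parent", "donor", "acceptor")))


def concat_topologies(parts: Sequence[Topology]) -> Topology:
    fields = ("ids", "names", "elements", "molecule_ids", "resnames", "kinds",
              "segments", "masses", "parent", "donor", "acceptor")
    return Topology(*(np.concatenate([getattr(p, f) for p in parts]) for f in fields))


# -- periodic neighbour search --------------------------------------------

def _padded_tree(pos: np.ndarray, box: SimulationBox) -> tuple[cKDTree, np.ndarray]:
    """KD-tree honouring per-axis periodicity.

    scipy's boxsize implies full periodicity, so non-periodic axes get a
    boxsize padded far beyond the data range (wrap can then never trigger).
    """
    pos = np.asarray(pos, dtype=float)
    shifted = pos.copy()
    boxsize = np.empty(3)
    for ax in range(3):
        if box.periodic[ax]:
            boxsize[ax] = box.lengths[ax]
            shifted[:, ax] %= box.lengths[ax]
        else:
            lo = shifted[:, ax].min()
            span = shifted[:, ax].max() - lo
            shifted[:, ax] -= lo
            boxsize[ax] = 10.0 * (span + 1.0)
    return cKDTree(shifted, boxsize=boxsize), shifted


def pairs_within(pos: np.ndarray, box: SimulationBox, r_cut: float) -> np.ndarray:
    """All index pairs (i < j) with minimum-image distance <= r_cut."""
    tree, _ = _padded_tree(pos, box)
    pairs = tree.query_pairs(r_cut, output_type="ndarray")
    return pairs.reshape(-1, 2)


def neighbor_lists(pos: np.ndarray, box: SimulationBox, r_cut: float) -> list[np.ndarray]:
    """Per-point neighbour index lists within r_cut (self excluded)."""
    n = len(pos)
    nbrs: list[list[int]] = [[] for _ in range(n)]
    for i, j in pairs_within(pos, box, r_cut):
        nbrs[i].append(j)
        nbrs[j].append(i)
    return [np.array(sorted(v), dtype=int) for v in nbrs]


def cross_pairs_within(a: np.ndarray, b: np.ndarray, box: SimulationBox,
                       r_cut: float) -> np.ndarray:
    """Index pairs (i in a, j in b) with min-image distance <= r_cut."""
    if len(a) == 0 or len(b) == 0:
        return np.empty((0, 2), dtype=int)
    both = np.concatenate([a, b])
    tree, shifted = _padded_tree(both, box)
    ta = cKDTree(shifted[: len(a)], boxsize=tree.boxsize)
    tb = cKDTree(shifted[len(a):], boxsize=tree.boxsize)
    out = []
    for i, js in enumerate(ta.query_ball_tree(tb, r_cut)):
        for j in js:
            out.append((i, j))
    return np.array(out, dtype=int).reshape(-1, 2)


def unwrap_positions(traj: Trajectory, idx: np.ndarray | None = None) -> np.ndarray:
    """Unwrapped (n_frames, n_sel, 3) positions via cumulative minimum-image steps."""
    pos = traj.positions_array()
    if idx is not None:
        pos = pos[:, np.asarray(idx, dtype=int), :]
    out = np.empty_like(pos)
    out[0] = pos[0]
    for t in range(1, pos.shape[0]):
        step = traj.box.min_image(pos[t] - pos[t - 1])
        out[t] = out[t - 1] + step
    return out
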