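"""Readers and writers for structures, trajectories and label sidecars.

GRO and XYZ are handled in-package (multi-frame GRO trajectories and
per-frame XYZ time comments with byte-deterministic output); PDB and the
binary trajectory formats (XTC/DCD) go through MDAnalysis. Coordinates are
nm internally; PDB angstroms are converted on read/write.

The label sidecar is a tab-separated table with header
``atom_id  kind  segment`` assigning molecule kind (WATER/POLYMER/OTHER)
and polymer segment unit (L13/L14/D/T); atoms not listed fall back to a
residue-name water heuristic with segment NONE.
"""

from __future__ import annotations

import os
import re

import numpy as np
import pandas as pd

from .core import (
    ELEMENT_MASSES, KINDS, OTHER, POLYMER, SEGMENTS, WATER, WATER_RESNAMES,
    Frame, ParseError, SimulationBox, Topology, Trajectory,
)

_TIME_RE = re.compile(r"t\s*=\s*([-+0-9.eE]+)")


def _element_from_name(name: str) -> str:
    stripped = name.strip().lstrip("0123456789")
    if not stripped:
        return "X"
    if stripped[:2].upper() in ("MW",) or stripped.upper() in ("M", "MW", "EP"):
        return "M"  # massless virtual site of 4-site water models
    return stripped[0].upper()


def _infer_kinds(resnames: np.ndarray) -> np.ndarray:
    kinds = np.full(len(resnames), OTHER, dtype=object)
    for i, rn in enumerate(resnames):
        if str(rn).strip().upper() in WATER_RESNAMES:
            kinds[i] = WATER
    return kinds


def _assign_parents(elements, molecule_ids, positions) -> np.ndarray:
    """Bond each hydrogen to the nearest heavy atom of its molecule."""
    n = len(elements)
    parent = np.full(n, -1, dtype=int)
    order = np.arange(n)
    for mol in np.unique(molecule_ids):
        sel = order[molecule_ids == mol]
        heavies = [i for i in sel if elements[i] not in ("H", "M")]
        if not heavies:
            continue
        hpos = positions[heavies]
        for i in sel:
            if elements[i] == "H":
                d = np.linalg.norm(hpos - positions[i], axis=1)
                parent[i] = heavies[int(np.argmin(d))] + 1  # ids are 1-based
    return parent


def _build_topology(names, resids, resnames, positions,
                    label_path=None) -> Topology:
    n = len(names)
    ids = np.arange(1, n + 1)
    elements = np.array([_element_from_name(nm) for nm in names], dtype=object)
    kinds = _infer_kinds(np.asarray(resnames, dtype=object))
    segments = np.full(n, "NONE", dtype=object)

    if label_path is not None:
        labels = read_labels(label_path)
        known = set(ids.tolist())
        for _, row in labels.iterrows():
            aid = int(row["atom_id"])
            if aid not in known:
                raise ParseError(f"sidecar references unknown atom id {aid}")
            kinds[aid - 1] = row["kind"]
            segments[aid - 1] = row["segment"]

    masses = np.array([ELEMENT_MASSES.get(e, 12.0) for e in elements])
    parent = _assign_parents(elements, np.asarray(resids), np.asarray(positions))
    heavy = (elements != "H") & (elements != "M")
    has_h = np.isin(ids, parent)
    donor = heavy & has_h & np.isin(elements, ("O", "N"))
    acceptor = heavy & np.isin(elements, ("O", "N"))
    topo = Topology(ids=ids, names=np.asarray(names, dtype=object),
                    elements=elements,
                    molecule_ids=np.asarray(resids, dtype=int),
                    resnames=np.asarray(resnames, dtype=object),
                    kinds=kinds, segments=segments, masses=masses,
                    parent=parent, donor=donor, acceptor=acceptor)
    topo.validate()
    return topo


def read_labels(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", dtype={"atom_id": int, "kind": str,
                                            "segment": str})
    required = {"atom_id", "kind", "segment"}
    if not required.issubset(df.columns):
        raise ParseError(f"label sidecar must have columns {sorted(required)}")
    for k in df["kind"]:
        if k not in KINDS:
            raise ParseError(f"unknown kind {k!r} in sidecar")
    for s in df["segment"]:
        if s not in SEGMENTS:
            raise ParseError(f"unknown segment {s!r} in sidecar")
    return df


def write_labels(topo: Topology, path) -> None:
    pd.DataFrame({"atom_id": topo.ids, "kind": topo.kinds,
                  "segment": topo.segments}).to_csv(path, sep="\t", index=False)


# -- GRO ------------------------------------------------------------------

def _parse_gro_block(lines, start, path):
    """Parse one GRO frame starting at lines[start]; return (frame data, next)."""
    if start + 2 > len(lines):
        raise ParseError(f"{path}: truncated GRO frame at line {start + 1}")
    title = lines[start].rstrip("\n")
    try:
        natoms = int(lines[start + 1])
    except ValueError as e:
        raise ParseError(f"{path}: bad atom count at line {start + 2}") from e
    end = start + 2 + natoms
    if end + 1 > len(lines):
        raise ParseError(
            f"{path}: atom count header ({natoms}) exceeds records in file")
    resids, resnames, names, xyz = [], [], [], []
    for ln in range(start + 2, end):
        line = lines[ln].rstrip("\n")
        try:
            resids.append(int(line[0:5]))
            resnames.append(line[5:10].strip())
            names.append(line[10:15].strip())
            xyz.append((float(line[20:28]), float(line[28:36]),
                        float(line[36:44])))
        except (ValueError, IndexError) as e:
            raise ParseError(f"{path}: malformed GRO record at line {ln + 1}") from e
    try:
        bvals = [float(v) for v in lines[end].split()]
        box = np.array(bvals[:3])
    except (ValueError, IndexError) as e:
        raise ParseError(f"{path}: malformed box line at line {end + 1}") from e
    m = _TIME_RE.search(title)
    time = float(m.group(1)) if m else None
    return (resids, resnames, names, np.array(xyz), box, time), end + 1


def _read_gro_frames(path):
    with open(path) as fh:
        lines = fh.readlines()
    pos = 0
    frames = []
    while pos < len(lines) and lines[pos].strip() != "":
        block, pos = _parse_gro_block(lines, pos, path)
        frames.append(block)
    if not frames:
        raise ParseError(f"{path}: empty GRO file")
    return frames


def _write_gro_frame(fh, topo: Topology, frame: Frame, box: SimulationBox):
    fh.write(f"icegrowth t= {frame.time:.5f}\n")
    fh.write(f"{frame.n_atoms:5d}\n")
    for i in range(frame.n_atoms):
        x, y, z = frame.positions[i]
        fh.write(f"{int(topo.molecule_ids[i]) % 100000:5d}"
                 f"{str(topo.resnames[i])[:5]:<5s}"
                 f"{str(topo.names[i])[:5]:>5s}"
                 f"{int(topo.ids[i]) % 100000:5d}"
                 f"{x:8.3f}{y:8.3f}{z:8.3f}\n")
    fh.write(f"{box.lengths[0]:10.5f}{box.lengths[1]:10.5f}{box.lengths[2]:10.5f}\n")


# -- XYZ ------------------------------------------------------------------

def _read_xyz_frames(path):
    with open(path) as fh:
        lines = fh.readlines()
    pos = 0
    frames = []
    while pos < len(lines) and lines[pos].strip() != "":
        try:
            natoms = int(lines[pos])
        except ValueError as e:
            raise ParseError(f"{path}: bad XYZ atom count at line {pos + 1}") from e
        comment = lines[pos + 1].rstrip("\n")
        end = pos + 2 + natoms
        if end > len(lines):
            raise ParseError(f"{path}: truncated XYZ frame at line {pos + 1}")
        els, xyz = [], []
        for ln in range(pos + 2, end):
            parts = lines[ln].split()
            if len(parts) < 4:
                raise ParseError(f"{path}: malformed XYZ record at line {ln + 1}")
            els.append(parts[0])
            xyz.append([float(v) for v in parts[1:4]])
        m = _TIME_RE.search(comment)
        time = float(m.group(1)) if m else None
        bm = re.search(r"box\s*=\s*([-\d.eE]+)\s+([-\d.eE]+)\s+([-\d.eE]+)", comment)
        box = np.array([float(bm.group(k)) for k in (1, 2, 3)]) if bm else None
        frames.append((els, np.array(xyz), box, time))
        pos = end
    if not frames:
        raise ParseError(f"{path}: empty XYZ file")
    return frames


def _write_xyz_frame(fh, topo: Topology, frame: Frame, box: SimulationBox):
    pbc = " ".join("1" if p else "0" for p in box.periodic)
    fh.write(f"{frame.n_atoms}\n")
    fh.write(f"t= {frame.time:.5f} ps box= "
             f"{box.lengths[0]:.5f} {box.lengths[1]:.5f} {box.lengths[2]:.5f} "
             f"pbc= {pbc} units= nm\n")
    for i in range(frame.n_atoms):
        x, y, z = frame.positions[i]
        fh.write(f"{str(topo.elements[i]):<2s} {x:12.6f} {y:12.6f} {z:12.6f}\n")


# -- public API -----------------------------------------------------------

def read_structure(path, label_path=None):
    """Read a GRO or PDB structure (+ optional label sidecar).

    Returns
    -------
    (Topology, Frame, SimulationBox)
    """
    ext = os.path.splitext(str(path))[1].lower()
    if ext == ".gro":
        resids, resnames, names, xyz, boxl, time = _read_gro_frames(path)[0]
        box = SimulationBox(boxl)
        frame = Frame(time or 0.0, xyz)
    elif ext == ".pdb":
        import MDAnalysis as mda
        u = mda.Universe(str(path))
        xyz = u.atoms.positions / 10.0
        names = [a.name for a in u.atoms]
        resids = [a.resid for a in u.atoms]
        resnames = [a.resname for a in u.atoms]
        dims = u.dimensions
        if dims is None or not np.all(dims[:3] > 0):
            span = xyz.max(axis=0) - xyz.min(axis=0) + 1.0
            box = SimulationBox(span, periodic=[False, False, False])
        else:
            box = SimulationBox(np.asarray(dims[:3]) / 10.0)
        frame = Frame(0.0, xyz)
    else:
        raise ParseError(f"unsupported structure format {ext!r}")
    topo = _build_topology(names, resids, resnames, frame.positions, label_path)
    return topo, frame, box


def read_trajectory(path, topology: Topology, box: SimulationBox | None = None,
                    stride: float = 1.0) -> Trajectory:
    """Read a multi-frame GRO/PDB/XYZ (or XTC/DCD) trajectory.

    Frames without an explicit time stamp get times synthesized from
    ``stride`` (ps between frames). Atom counts are checked frame by frame.
    """
    ext = os.path.splitext(str(path))[1].lower()
    frames: list[Frame] = []
    box_out = box
    if ext == ".gro":
        for i, (_, _, _, xyz, boxl, time) in enumerate(_read_gro_frames(path)):
            if len(xyz) != topology.n_atoms:
                raise ParseError(f"frame {i}: atom count {len(xyz)} != "
                                 f"{topology.n_atoms}")
            frames.append(Frame(time if time is not None else i * stride, xyz))
            box_out = box_out or SimulationBox(boxl)
    elif ext == ".xyz":
        for i, (_, xyz, boxl, time) in enumerate(_read_xyz_frames(path)):
            if len(xyz) != topology.n_atoms:
                raise ParseError(f"frame {i}: atom count {len(xyz)} != "
                                 f"{topology.n_atoms}")
            frames.append(Frame(time if time is not None else i * stride, xyz))
            if box_out is None and boxl is not None:
                box_out = SimulationBox(boxl)
    elif ext in (".pdb", ".xtc", ".dcd"):
        import MDAnalysis as mda
        if ext == ".pdb":
            u = mda.Universe(str(path))
            if box_out is None:   # some readers drop CRYST1 into limbo
                with open(path) as fh:
                    for line in fh:
                        if line.startswith("CRYST1"):
                            dims = np.array([float(line[6:15]),
                                             float(line[15:24]),
                                             float(line[24:33])])
                            if np.all(dims > 0):
                                box_out = SimulationBox(dims / 10.0)
                            break
        else:
            u = mda.Universe.empty(topology.n_atoms, trajectory=True)
            u.load_new(str(path))
        for i, ts in enumerate(u.trajectory):
            if ts.positions.shape[0] != topology.n_atoms:
                raise ParseError(f"frame {i}: atom count {ts.positions.shape[0]}"
                                 f" != {topology.n_atoms}")
            t = float(getattr(ts, "time", 0.0)) or i * stride
            frames.append(Frame(t, ts.positions / 10.0))
            if box_out is None and ts.dimensions is not None and \
                    np.all(ts.dimensions[:3] > 0):
                box_out = SimulationBox(np.asarray(ts.dimensions[:3]) / 10.0)
    else:
        raise ParseError(f"unsupported trajectory format {ext!r}")
    if box_out is None:
        raise ParseError(f"{path}: no box information; pass box= explicitly")
    # guard against identical synthesized times
    times = [f.time for f in frames]
    if len(set(times)) != len(times):
        for i, f in enumerate(frames):
            f.time = i * stride
    return Trajectory(frames, box_out)


def write_trajectory(traj: Trajectory, topology: Topology, path) -> None:
    """Write a trajectory as multi-frame GRO, XYZ or PDB.

    Output is byte-deterministic for identical inputs; GRO uses fixed-column
    nm with 3 decimals, XYZ carries time (ps) and box in the comment line.
    """
    if traj.n_frames == 0:
        raise ValueError("cannot write an empty trajectory")
    if topology.n_atoms != traj.n_atoms:
        raise ValueError("topology/trajectory atom count mismatch")
    ext = os.path.splitext(str(path))[1].lower()
    if ext == ".gro":
        with open(path, "w") as fh:
            for fr in traj:
                _write_gro_frame(fh, topology, fr, traj.box)
    elif ext == ".xyz":
        with open(path, "w") as fh:
            for fr in traj:
                _write_xyz_frame(fh, topology, fr, traj.box)
    elif ext == ".pdb":
        import MDAnalysis as mda
        mols = np.unique(topology.molecule_ids)
        resindex = np.searchsorted(mols, topology.molecule_ids)
        first = [int(np.argmax(topology.molecule_ids == m)) for m in mols]
        u = mda.Universe.empty(topology.n_atoms, n_residues=len(mols),
                               atom_resindex=resindex, trajectory=True)
        u.add_TopologyAttr("names", [str(n) for n in topology.names])
        u.add_TopologyAttr("resids", mols.tolist())
        u.add_TopologyAttr("resnames",
                           [str(topology.resnames[i]) for i in first])
        u.add_TopologyAttr("elements", [str(e) for e in topology.elements])
        u.dimensions = [*(traj.box.lengths * 10.0), 90, 90, 90]
        with mda.Writer(str(path), topology.n_atoms, multiframe=True) as w:
            for fr in traj:
                u.atoms.positions = fr.positions * 10.0
                w.write(u.atoms)
    else:
        raise ParseError(f"unsupported trajectory format {ext!r}")


def write_structure(topo: Topology, frame: Frame, box: SimulationBox, path) -> None:
    """Write a single-frame GRO structure."""
    with open(path, "w") as fh:
        _write_gro_frame(fh, topo, frame, box)
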