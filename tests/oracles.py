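"""Independent brute-force reference implementations for the tests.

Everything here is written as plain O(N^2) loops with explicit
minimum-image arithmetic, deliberately sharing no code with the package's
neighbour-list implementations, so agreement is meaningful.
"""

import numpy as np
from scipy.special import sph_harm_y


def min_image_brute(d, lengths, periodic):
    d = np.array(d, dtype=float)
    for ax in range(3):
        if periodic[ax]:
            L = lengths[ax]
            while d[ax] > L / 2:
                d[ax] -= L
            while d[ax] < -L / 2:
                d[ax] += L
    return d


def brute_neighbors(pos, lengths, periodic, r_cut):
    n = len(pos)
    out = [[] for _ in range(n)]
    for i in range(n):
        for j in range(i + 1, n):
            d = min_image_brute(pos[j] - pos[i], lengths, periodic)
            if np.sqrt(float(d @ d)) <= r_cut:
                out[i].append(j)
                out[j].append(i)
    return out


def brute_classify(pos, lengths, periodic, r_cut=0.35, q_threshold=0.7,
                   min_connections=3):
    """Loop-based degree-6 bond-orientational ice classification."""
    n = len(pos)
    nbrs = brute_neighbors(pos, lengths, periodic, r_cut)
    q = np.zeros((n, 13), dtype=complex)
    for i in range(n):
        if not nbrs[i]:
            continue
        acc = np.zeros(13, dtype=complex)
        for j in nbrs[i]:
            d = min_image_brute(pos[j] - pos[i], lengths, periodic)
            r = np.sqrt(float(d @ d))
            theta = np.arccos(max(-1.0, min(1.0, d[2] / r)))
            phi = np.arctan2(d[1], d[0])
            for mi, m in enumerate(range(-6, 7)):
                acc[mi] += sph_harm_y(6, m, theta, phi)
        acc /= len(nbrs[i])
        norm = np.sqrt(float(np.sum(np.abs(acc) ** 2)))
        if norm > 0:
            q[i] = acc / norm
    labels = np.zeros(n, dtype=bool)
    ncon = np.zeros(n, dtype=int)
    for i in range(n):
        c = 0
        for j in nbrs[i]:
            dot = float(np.real(np.sum(q[i] * np.conj(q[j]))))
            if dot > q_threshold:
                c += 1
        ncon[i] = c
        labels[i] = c >= min_connections
    return labels, ncon


def brute_hbonds(pos, topo, lengths, periodic, d_max=0.35, angle_min=150.0):
    """Loop-based geometric H-bond detection; returns (d, h, a) id triples."""
    ids = topo.ids
    out = set()
    donors = [i for i in range(topo.n_atoms) if topo.donor[i]]
    acceptors = [i for i in range(topo.n_atoms) if topo.acceptor[i]]
    hydrogens = {}
    for i in range(topo.n_atoms):
        if topo.parent[i] > 0:
            hydrogens.setdefault(int(topo.parent[i]), []).append(i)
    for di in donors:
        for ai in acceptors:
            if di == ai or topo.molecule_ids[di] == topo.molecule_ids[ai]:
                continue
            d = min_image_brute(pos[ai] - pos[di], lengths, periodic)
            if np.sqrt(float(d @ d)) > d_max:
                continue
            for hi in hydrogens.get(int(ids[di]), []):
                vd = min_image_brute(pos[di] - pos[hi], lengths, periodic)
                va = min_image_brute(pos[ai] - pos[hi], lengths, periodic)
                cosang = float(vd @ va) / (np.sqrt(float(vd @ vd)) *
                                           np.sqrt(float(va @ va)))
                ang = np.degrees(np.arccos(max(-1.0, min(1.0, cosang))))
                if ang >= angle_min:
                    out.add((int(ids[di]), int(ids[hi]), int(ids[ai])))
    return out


def brute_multiplicity(records_by_frame, water_of_mol, polymer_of_mol):
    """Count simultaneous (water, polymer) bonds per frame from triples.

    ``records_by_frame``: list of sets of (donor_mol, acceptor_mol) bond
    instances (with repetition as tuples including ids). Returns the
    multiplicity histogram counts {1, 2, 3, '4+'}.
    """
    counts = {1: 0, 2: 0, 3: 0, "4+": 0}
    for frame_records in records_by_frame:
        per_pair = {}
        for dm, am in frame_records:
            if dm in water_of_mol and am in polymer_of_mol:
                key = (dm, am)
            elif am in water_of_mol and dm in polymer_of_mol:
                key = (am, dm)
            else:
                continue
            per_pair[key] = per_pair.get(key, 0) + 1
        for m in per_pair.values():
            counts[m if m < 4 else "4+"] += 1
    return counts
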