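"""Independent brute-force oracles used to validate the analysis kernels.

These deliberately avoid the package's accelerated kernels (neighbour
searches, vectorized energy sums): distances come from direct
minimum-image arithmetic over all pairs, so agreement is a genuine
cross-check rather than a tautology.
"""

from __future__ import annotations

import numpy as np

from memint.molecular_model import Frame, Topology


def min_image_dist(a: np.ndarray, b: np.ndarray, box: np.ndarray) -> float:
    d = np.asarray(b, float) - np.asarray(a, float)
    d -= box * np.round(d / box)
    return float(np.linalg.norm(d))


def min_image_vec(a: np.ndarray, b: np.ndarray, box: np.ndarray) -> np.ndarray:
    d = np.asarray(b, float) - np.asarray(a, float)
    d -= box * np.round(d / box)
    return d


def brute_force_hbonds(
    frame: Frame,
    topology: Topology,
    selection_a="polymer",
    selection_b="lipids",
    d_max: float = 4.0,
    a_max: float = 60.0,
):
    """Exhaustive all-pairs hydrogen-bond detection (best-H per pair).

    Returns sorted (donor, hydrogen, acceptor) triples.
    """
    coords, box = frame.coordinates, frame.box
    sel_a = set(topology.select(selection_a) if isinstance(selection_a, str) else selection_a)
    sel_b = set(topology.select(selection_b) if isinstance(selection_b, str) else selection_b)
    out = []
    for di, datom in enumerate(topology.atoms):
        if not datom.is_donor:
            continue
        for ai, aatom in enumerate(topology.atoms):
            if not aatom.is_acceptor or ai == di:
                continue
            if not (
                (di in sel_a and ai in sel_b) or (di in sel_b and ai in sel_a)
            ):
                continue
            if min_image_dist(coords[di], coords[ai], box) > d_max:
                continue
            best = None
            for h in datom.bonded_hydrogens:
                hd = min_image_vec(coords[h], coords[di], box)
                ha = min_image_vec(coords[h], coords[ai], box)
                cosang = np.dot(hd, ha) / (np.linalg.norm(hd) * np.linalg.norm(ha))
                dev = 180.0 - np.degrees(np.arccos(np.clip(cosang, -1.0, 1.0)))
                if dev <= a_max and (best is None or dev < best[1]):
                    best = (h, dev)
            if best is not None:
                out.append((di, best[0], ai))
    return sorted(out)


def charmm_switch(r: float, switch_on: float, cutoff: float) -> float:
    if r <= switch_on:
        return 1.0
    if r >= cutoff:
        return 0.0
    rc2, ro2, r2 = cutoff**2, switch_on**2, r**2
    return (rc2 - r2) ** 2 * (rc2 + 2 * r2 - 3 * ro2) / (rc2 - ro2) ** 3


def brute_force_energy(
    frame: Frame,
    topology: Topology,
    group_a,
    group_b,
    cutoff: float = 12.0,
    switch_on: float = 10.0,
    coulomb_constant: float = 332.0636,
):
    """Plain double-loop switched Coulomb + Lennard-Jones sums."""
    coords, box = frame.coordinates, frame.box
    ia = topology.select(group_a) if isinstance(group_a, str) else group_a
    ib = topology.select(group_b) if isinstance(group_b, str) else group_b
    elec = vdw = 0.0
    for i in ia:
        for j in ib:
            r = min_image_dist(coords[i], coords[j], box)
            if r >= cutoff or r < 1e-9:
                continue
            s = charmm_switch(r, switch_on, cutoff)
            elec += coulomb_constant * topology.charges[i] * topology.charges[j] / r * s
            eps = np.sqrt(topology.lj_epsilon[i] * topology.lj_epsilon[j])
            rmin = topology.lj_rmin_half[i] + topology.lj_rmin_half[j]
            vdw += eps * ((rmin / r) ** 12 - 2 * (rmin / r) ** 6) * s
    return elec, vdw


def image_enumeration_distance(a, b, box) -> float:
    """Minimum distance over all 27 periodic images of b."""
    a = np.asarray(a, float)
    b = np.asarray(b, float)
    box = np.asarray(box, float)
    best = np.inf
    for dx in (-1, 0, 1):
        for dy in (-1, 0, 1):
            for dz in (-1, 0, 1):
                shift = np.array([dx, dy, dz]) * box
                best = min(best, float(np.linalg.norm(b + shift - a)))
    return best
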