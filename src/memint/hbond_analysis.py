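"""Geometric hydrogen-bond detection and aggregation.

A donor-H···acceptor triple is a hydrogen bond when the donor-acceptor
minimum-image distance is at most ``d_max`` (default 4.0 Å) and the
deviation of the D-H···A angle from linearity is at most ``a_max``
(default 60°, i.e. ∠D-H-A ≥ 120°). Both boundaries are inclusive.

The 60° figure is conventionally quoted as "donor-H-acceptor angle
≤ 60°"; a literal ∠DHA ≤ 60° is geometrically near-impossible for a
bonded hydrogen, so the default reads it as deviation from linearity
(the standard MD-analysis convention). The literal reading is available
via ``angle_convention="literal"``.

Among multiple hydrogens on one donor each is tested independently, but
a donor-acceptor pair contributes at most one record per frame (the
best-angle hydrogen), keeping counts comparable to standard tools.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from MDAnalysis.lib.distances import capped_distance

from .constants import HBOND_AMAX, HBOND_DMAX
from .molecular_model import (
    Frame,
    MoleculeKind,
    Topology,
    Trajectory,
    minimum_image,
)

__all__ = [
    "HBondRecord",
    "HBondSummary",
    "detect_hbonds",
    "summarize_hbonds",
    "group_label",
]


@dataclass(frozen=True)
class HBondRecord:
    frame_index: int
    donor_id: int
    hydrogen_id: int
    acceptor_id: int
    distance: float  # donor-acceptor, Å
    angle_deviation: float  # 180° - ∠D-H-A, degrees
    donor_group: str
    acceptor_group: str


@dataclass
class HBondSummary:
    mean_per_frame: float
    se_per_frame: float
    per_frame_counts: np.ndarray
    counts_by_pairing: pd.DataFrame  # (donor_group, acceptor_group, lipid) -> mean
    participating_sidearms: set
    n_frames: int
    records: list = field(default_factory=list)


_GROUP_LABELS = {
    (MoleculeKind.POLYMER, "ND"): "amide N-H",
    (MoleculeKind.POLYMER, "OE"): "ester carbonyl O",
    (MoleculeKind.POLYMER, "OB"): "imide carbonyl O",
    (MoleculeKind.POPE, "N"): "PE ammonium N-H",
    (MoleculeKind.POPE, "OP1"): "phosphate O",
    (MoleculeKind.POPE, "OP2"): "phosphate O",
    (MoleculeKind.POPG, "OP1"): "phosphate O",
    (MoleculeKind.POPG, "OP2"): "phosphate O",
    (MoleculeKind.POPG, "O1"): "PG hydroxyl O",
    (MoleculeKind.POPG, "O2"): "PG hydroxyl O",
}


def group_label(topology: Topology, index: int) -> str:
    a = topology.atoms[index]
    return _GROUP_LABELS.get((a.molecule_kind, a.name), f"{a.molecule_kind.value}:{a.name}")


def _resolve(topology: Topology, selection) -> np.ndarray:
    if isinstance(selection, str):
        return topology.select(selection)
    return np.asarray(selection, dtype=int)


def _angle_deviation(
    d_pos: np.ndarray, h_pos: np.ndarray, a_pos: np.ndarray, box: np.ndarray
) -> float:
    """180° minus the D-H···A angle, with minimum-image vectors."""
    hd, _ = minimum_image(h_pos, d_pos, box)
    ha, _ = minimum_image(h_pos, a_pos, box)
    nd, na = np.linalg.norm(hd), np.linalg.norm(ha)
    if nd == 0 or na == 0:
        return 180.0
    cosang = np.clip(np.dot(hd, ha) / (nd * na), -1.0, 1.0)
    return 180.0 - float(np.degrees(np.arccos(cosang)))


def _detect_directed(
    frame: Frame,
    topology: Topology,
    donors: np.ndarray,
    acceptors: np.ndarray,
    d_max: float,
    a_max: float,
    angle_convention: str,
    frame_index: int,
) -> list[HBondRecord]:
    if len(donors) == 0 or len(acceptors) == 0:
        return []
    coords = frame.coordinates
    box = np.array([*frame.box, 90.0, 90.0, 90.0])
    pairs, dists = capped_distance(
        coords[donors].astype(np.float32),
        coords[acceptors].astype(np.float32),
        max_cutoff=d_max * 1.001 + 0.01,
        box=box.astype(np.float32),
        return_distances=True,
    )
    records = []
    for (pi, pj) in pairs:
        di, ai = int(donors[pi]), int(acceptors[pj])
        if di == ai:
            continue
        # recompute in double precision for a clean inclusive boundary
        _, dist = minimum_image(coords[di], coords[ai], frame.box)
        dist = float(dist)
        if dist > d_max:
            continue
        best = None
        for h in topology.atoms[di].bonded_hydrogens:
            dev = _angle_deviation(coords[di], coords[h], coords[ai], frame.box)
            if angle_convention == "literal":
                ok = (180.0 - dev) <= a_max
            else:
                ok = dev <= a_max
            if ok and (best is None or dev < best[1]):
                best = (h, dev)
        if best is not None:
            records.append(
                HBondRecord(
                    frame_index=frame_index,
                    donor_id=di,
                    hydrogen_id=int(best[0]),
                    acceptor_id=ai,
                    distance=dist,
                    angle_deviation=float(best[1]),
                    donor_group=group_label(topology, di),
                    acceptor_group=group_label(topology, ai),
                )
            )
    return records


def detect_hbonds(
    frame: Frame,
    topology: Topology,
    d_max: float = HBOND_DMAX,
    a_max: float = HBOND_AMAX,
    selection_a="polymer",
    selection_b="lipids",
    angle_convention: str = "deviation",
    frame_index: int = 0,
) -> list[HBondRecord]:
    """All donor-H···acceptor triples between two selections in one frame.

    Direction-agnostic: donors in either selection are paired with
    acceptors in the other. Distances are minimum-image; both criteria
    are inclusive at their boundaries.
    """
    idx_a = _resolve(topology, selection_a)
    idx_b = _resolve(topology, selection_b)
    donors_a = idx_a[topology.donor_mask[idx_a]]
    donors_b = idx_b[topology.donor_mask[idx_b]]
    acc_a = idx_a[topology.acceptor_mask[idx_a]]
    acc_b = idx_b[topology.acceptor_mask[idx_b]]
    if (
        len(donors_a) == 0
        and len(donors_b) == 0
        and len(acc_a) == 0
        and len(acc_b) == 0
    ):
        warnings.warn(
            "selections contain no donors or acceptors; returning no bonds",
            stacklevel=2,
        )
        return []
    records = _detect_directed(
        frame, topology, donors_a, acc_b, d_max, a_max, angle_convention, frame_index
    )
    records += _detect_directed(
        frame, topology, donors_b, acc_a, d_max, a_max, angle_convention, frame_index
    )
    records.sort(key=lambda r: (r.donor_id, r.acceptor_id))
    return records


def _lipid_species(topology: Topology, record: HBondRecord) -> str:
    for i in (record.donor_id, record.acceptor_id):
        kind = topology.atoms[i].molecule_kind
        if kind in (MoleculeKind.POPE, MoleculeKind.POPG):
            return kind.value
    return "none"


def _block_se(values: np.ndarray, n_blocks: int = 5) -> float:
    """Standard error from contiguous block averages."""
    n = len(values)
    if n < 2:
        return 0.0
    n_blocks = min(n_blocks, n)
    blocks = np.array_split(values, n_blocks)
    means = np.array([b.mean() for b in blocks])
    if len(means) < 2:
        return 0.0
    return float(means.std(ddof=1) / np.sqrt(len(means)))


def summarize_hbonds(
    trajectory: Trajectory,
    topology: Topology | None = None,
    d_max: float = HBOND_DMAX,
    a_max: float = HBOND_AMAX,
    selection_a="polymer",
    selection_b="lipids",
    angle_convention: str = "deviation",
    n_blocks: int = 5,
    keep_records: bool = False,
) -> HBondSummary:
    """Per-frame hydrogen-bond counts with block-averaged uncertainty.

    Counts are broken down by (donor group, acceptor group, lipid
    species), and the number of distinct polymer side arms participating
    in any bond is reported.
    """
    if topology is None:
        topology = trajectory.topology
    if len(trajectory) == 0:
        raise ValueError("empty trajectory")
    counts = []
    all_records: list[HBondRecord] = []
    for fi, frame in enumerate(trajectory):
        recs = detect_hbonds(
            frame,
            topology,
            d_max,
            a_max,
            selection_a,
            selection_b,
            angle_convention,
            frame_index=fi,
        )
        counts.append(len(recs))
        all_records.extend(recs)
    counts = np.asarray(counts, dtype=float)
    rows = [
        {
            "donor_group": r.donor_group,
            "acceptor_group": r.acceptor_group,
            "lipid_species": _lipid_species(topology, r),
        }
        for r in all_records
    ]
    if rows:
        pairing = (
            pd.DataFrame(rows)
            .value_counts(["donor_group", "acceptor_group", "lipid_species"])
            .rename("mean_per_frame")
            / len(trajectory)
        ).to_frame()
    else:
        pairing = pd.DataFrame(
            columns=["mean_per_frame"],
            index=pd.MultiIndex.from_arrays(
                [[], [], []], names=["donor_group", "acceptor_group", "lipid_species"]
            ),
        )
    sidearms = set()
    for r in all_records:
        for i in (r.donor_id, r.acceptor_id):
            a = topology.atoms[i]
            if a.molecule_kind is MoleculeKind.POLYMER and a.sidearm_id is not None:
                sidearms.add((a.chain_id, a.sidearm_id))
    return HBondSummary(
        mean_per_frame=float(counts.mean()),
        se_per_frame=_block_se(counts, n_blocks),
        per_frame_counts=counts,
        counts_by_pairing=pairing,
        participating_sidearms=sidearms,
        n_frames=len(trajectory),
        records=all_records if keep_records else [],
    )
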