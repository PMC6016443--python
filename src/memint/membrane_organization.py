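"""Leaflet assignment, pair correlations, lateral densities, conformations.

These operations quantify how polymers reorganize a bilayer: radial
distribution functions g(r) between hydrogen-bonding partners, 2-D
lateral number-density maps per leaflet with Pearson colocalization,
polymer conformation metrics (radius of gyration, end-to-end distance,
head-group contacts) and detection of side arms sequestered past the
phosphate plane.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from MDAnalysis.lib.distances import capped_distance

from .molecular_model import (
    Frame,
    MoleculeKind,
    Topology,
    Trajectory,
    minimum_image,
)

__all__ = [
    "RDFResult",
    "DensityMap",
    "ConformationMetrics",
    "assign_leaflets",
    "radial_distribution",
    "coordination_number",
    "number_density_2d",
    "density_colocalization",
    "conformation_metrics",
    "sequestered_sidearms",
    "select_beads",
]

HEADGROUP_NAMES = {"P", "OP1", "OP2", "N", "O1", "O2"}


def _resolve(topology: Topology, selection) -> np.ndarray:
    if isinstance(selection, str):
        return topology.select(selection)
    return np.asarray(selection, dtype=int)


def select_beads(topology: Topology, kind: MoleculeKind, name: str) -> np.ndarray:
    """One representative bead per molecule of the given kind (e.g. the
    phosphate P of each PG lipid, or the cationic Q bead of each arm)."""
    return topology.indices_where(
        lambda a: a.molecule_kind is kind and a.name == name
    )


def assign_leaflets(frame: Frame, topology: Topology) -> dict[int, str]:
    """Label each lipid molecule upper/lower by its phosphate z.

    The midplane is the mean phosphate z; lipids exactly at the midplane
    are assigned upper, with a warning.
    """
    p_idx = topology.indices_where(
        lambda a: a.name == "P"
        and a.molecule_kind in (MoleculeKind.POPE, MoleculeKind.POPG)
    )
    if len(p_idx) == 0:
        raise ValueError("no phosphate atoms; cannot assign leaflets")
    z = frame.coordinates[p_idx, 2]
    midplane = float(z.mean())
    labels: dict[int, str] = {}
    ties = 0
    for i, zi in zip(p_idx, z):
        mol = topology.atoms[i].molecule_id
        if zi > midplane:
            labels[mol] = "upper"
        elif zi < midplane:
            labels[mol] = "lower"
        else:
            labels[mol] = "upper"
            ties += 1
    if ties:
        warnings.warn(
            f"{ties} lipid(s) exactly at the midplane assigned 'upper'",
            stacklevel=2,
        )
    return labels


@dataclass
class RDFResult:
    bin_centers: np.ndarray  # Å
    g: np.ndarray
    counts: np.ndarray  # raw pair counts per bin, summed over frames
    r_max: float
    dr: float
    n_frames: int
    n_a: int
    n_b: int
    params: dict = field(default_factory=dict)

    def first_peak(self) -> tuple[float, float]:
        """(position, height) of the global maximum of g(r)."""
        i = int(np.argmax(self.g))
        return float(self.bin_centers[i]), float(self.g[i])


def radial_distribution(
    frames,
    topology: Topology,
    group_a,
    group_b,
    r_max: float = 12.0,
    dr: float = 0.1,
) -> RDFResult:
    """Pair correlation g(r) between two groups under minimum image.

    Standard normalization: the A-B distance histogram divided by shell
    volume × ideal-gas density of B × N_A × frames. Self-pairs are
    excluded when the groups share atoms. r_max may not exceed half the
    smallest box length.
    """
    if isinstance(frames, (Frame,)):
        frames = [frames]
    elif isinstance(frames, Trajectory):
        frames = list(frames)
    idx_a = _resolve(topology, group_a)
    idx_b = _resolve(topology, group_b)
    if len(idx_a) == 0 or len(idx_b) == 0:
        raise ValueError("both groups must be non-empty")
    edges = np.arange(0.0, r_max + dr / 2, dr)
    hist = np.zeros(len(edges) - 1)
    shared = len(np.intersect1d(idx_a, idx_b)) > 0
    rho_sum = 0.0
    for frame in frames:
        box = frame.box
        if r_max > min(box) / 2:
            raise ValueError(
                f"r_max={r_max} exceeds half the smallest box length "
                f"({min(box) / 2:.2f} Å); minimum image is ill-defined beyond"
            )
        mda_box = np.array([*box, 90.0, 90.0, 90.0], dtype=np.float32)
        pairs = capped_distance(
            frame.coordinates[idx_a].astype(np.float32),
            frame.coordinates[idx_b].astype(np.float32),
            max_cutoff=r_max + 0.01,
            box=mda_box,
            return_distances=False,
        )
        ga = idx_a[pairs[:, 0]]
        gb = idx_b[pairs[:, 1]]
        if shared:
            keep = ga != gb
            ga, gb = ga[keep], gb[keep]
        # exact float64 minimum-image distances for clean binning
        d = frame.coordinates[gb] - frame.coordinates[ga]
        d -= box * np.round(d / box)
        dists = np.linalg.norm(d, axis=1)
        hist += np.histogram(dists[dists <= r_max], bins=edges)[0]
        volume = float(np.prod(box))
        n_b_eff = len(idx_b) - (1 if shared else 0)
        rho_sum += n_b_eff / volume
    n_frames = len(frames)
    rho_mean = rho_sum / n_frames
    shell = 4.0 / 3.0 * np.pi * (edges[1:] ** 3 - edges[:-1] ** 3)
    norm = n_frames * len(idx_a) * shell * rho_mean
    g = np.divide(hist, norm, out=np.zeros_like(hist), where=norm > 0)
    return RDFResult(
        bin_centers=(edges[1:] + edges[:-1]) / 2,
        g=g,
        counts=hist,
        r_max=r_max,
        dr=dr,
        n_frames=n_frames,
        n_a=len(idx_a),
        n_b=len(idx_b),
        params={"group_a": str(group_a), "group_b": str(group_b)},
    )


def coordination_number(result: RDFResult, r_lo: float, r_hi: float) -> float:
    """Average number of B neighbours per A atom with r in [r_lo, r_hi]."""
    mask = (result.bin_centers >= r_lo) & (result.bin_centers <= r_hi)
    return float(result.counts[mask].sum() / (result.n_frames * result.n_a))


@dataclass
class DensityMap:
    density: np.ndarray  # Å⁻², shape (nx, ny)
    x_edges: np.ndarray
    y_edges: np.ndarray
    grid_spacing: float
    leaflet: str | None
    n_frames: int
    group: str = ""

    def integral(self) -> float:
        """Integrated density = mean particle count per frame."""
        cell = np.diff(self.x_edges)[:, None] * np.diff(self.y_edges)[None, :]
        return float((self.density * cell).sum())

    def local_maxima(self, n: int = 2, min_separation: float = 8.0):
        """Positions of the n strongest well-separated cells."""
        xc = (self.x_edges[:-1] + self.x_edges[1:]) / 2
        yc = (self.y_edges[:-1] + self.y_edges[1:]) / 2
        flat = np.argsort(self.density, axis=None)[::-1]
        found = []
        for k in flat:
            i, j = np.unravel_index(k, self.density.shape)
            pos = (float(xc[i]), float(yc[j]))
            if all(
                (pos[0] - p[0]) ** 2 + (pos[1] - p[1]) ** 2 >= min_separation**2
                for p in found
            ):
                found.append(pos)
            if len(found) == n:
                break
        return found


def number_density_2d(
    frames,
    topology: Topology,
    group,
    leaflet: str | None = None,
    grid_spacing: float = 1.0,
) -> DensityMap:
    """Time-averaged lateral number density (Å⁻²) on the xy plane.

    Coordinates are wrapped into the box. If ``leaflet`` is given, lipid
    atoms are restricted to molecules assigned to that leaflet (from the
    first frame); non-lipid atoms in the group are dropped in that case.
    """
    if grid_spacing <= 0:
        raise ValueError("grid_spacing must be positive")
    if isinstance(frames, Frame):
        frames = [frames]
    elif isinstance(frames, Trajectory):
        frames = list(frames)
    idx = _resolve(topology, group)
    if leaflet is not None:
        labels = assign_leaflets(frames[0], topology)
        idx = np.array(
            [
                i
                for i in idx
                if labels.get(topology.atoms[i].molecule_id) == leaflet
            ],
            dtype=int,
        )
    box = frames[0].box
    nx = max(int(round(box[0] / grid_spacing)), 1)
    ny = max(int(round(box[1] / grid_spacing)), 1)
    x_edges = np.linspace(0.0, box[0], nx + 1)
    y_edges = np.linspace(0.0, box[1], ny + 1)
    grid = np.zeros((nx, ny))
    if len(idx) == 0:
        warnings.warn("empty group: density map is all zero", stacklevel=2)
    else:
        for frame in frames:
            if not np.allclose(frame.box[:2], box[:2]):
                raise ValueError("frames must share box x-y dimensions")
            xy = frame.wrapped()[idx, :2]
            grid += np.histogram2d(xy[:, 0], xy[:, 1], bins=[x_edges, y_edges])[0]
        grid /= len(frames)
    cell_area = (box[0] / nx) * (box[1] / ny)
    return DensityMap(
        density=grid / cell_area,
        x_edges=x_edges,
        y_edges=y_edges,
        grid_spacing=grid_spacing,
        leaflet=leaflet,
        n_frames=len(frames),
        group=str(group),
    )


def density_colocalization(map_a: DensityMap, map_b: DensityMap) -> float:
    """Pearson correlation of two density maps over grid cells, in [-1, 1]."""
    if map_a.density.shape != map_b.density.shape:
        raise ValueError(
            f"grid mismatch: {map_a.density.shape} vs {map_b.density.shape}"
        )
    a = map_a.density.ravel()
    b = map_b.density.ravel()
    if a.std() == 0 or b.std() == 0:
        raise ValueError("zero-variance density map; correlation undefined")
    return float(np.corrcoef(a, b)[0, 1])


@dataclass
class ConformationMetrics:
    rg: np.ndarray  # per-frame, Å
    end_to_end: np.ndarray  # per-frame, Å
    in_plane_extension: np.ndarray  # per-frame, Å
    headgroup_contacts: np.ndarray  # per-frame counts
    classification: str  # "extended" | "compact"
    rod_rg: float  # Rg of an ideal straight rod with this backbone
    chain_id: int


def _rod_rg(n_beads: int, bond: float) -> float:
    # discrete rod of n equally spaced beads: Rg² = b²(n²-1)/12
    return bond * np.sqrt((n_beads**2 - 1) / 12.0)


def conformation_metrics(
    trajectory: Trajectory,
    topology: Topology | None = None,
    chain_id: int = 0,
    contact_cutoff: float = 4.0,
    extended_fraction: float = 0.75,
) -> ConformationMetrics:
    """Per-frame size and contact metrics for one polymer chain.

    Coordinates are used unwrapped (chains are assumed not to straddle
    the periodic boundary). The chain is classified "extended" when its
    mean Rg is at least ``extended_fraction`` of the ideal straight-rod
    Rg of its backbone, else "compact".
    """
    if topology is None:
        topology = trajectory.topology
    chain_idx = topology.select(f"chain:{chain_id}")
    if len(chain_idx) < 2:
        raise KeyError(f"chain {chain_id} not found or has fewer than 2 atoms")
    backbone = np.array(
        [i for i in chain_idx if topology.atoms[i].name == "CB"], dtype=int
    )
    heavy = np.array(
        [i for i in chain_idx if not topology.atoms[i].name.startswith("H")],
        dtype=int,
    )
    head_idx = topology.indices_where(
        lambda a: a.molecule_kind in (MoleculeKind.POPE, MoleculeKind.POPG)
        and a.name in HEADGROUP_NAMES
    )
    rg, e2e, inplane, contacts = [], [], [], []
    for frame in trajectory:
        pos = frame.coordinates[chain_idx]
        com = pos.mean(axis=0)
        rg.append(float(np.sqrt(((pos - com) ** 2).sum(axis=1).mean())))
        if len(backbone) >= 2:
            e2e.append(
                float(
                    np.linalg.norm(
                        frame.coordinates[backbone[-1]]
                        - frame.coordinates[backbone[0]]
                    )
                )
            )
        else:
            e2e.append(0.0)
        xy = pos[:, :2]
        diff = xy[:, None, :] - xy[None, :, :]
        inplane.append(float(np.sqrt((diff**2).sum(-1)).max()))
        if len(head_idx):
            mda_box = np.array([*frame.box, 90, 90, 90], dtype=np.float32)
            pairs = capped_distance(
                frame.coordinates[heavy].astype(np.float32),
                frame.coordinates[head_idx].astype(np.float32),
                max_cutoff=contact_cutoff,
                box=mda_box,
                return_distances=False,
            )
            contacts.append(len(pairs))
        else:
            contacts.append(0)
    rg = np.array(rg)
    n_bb = max(len(backbone), 2)
    bond = (
        float(
            np.linalg.norm(
                trajectory.frames[0].coordinates[backbone[1]]
                - trajectory.frames[0].coordinates[backbone[0]]
            )
        )
        if len(backbone) >= 2
        else 1.0
    )
    rod = _rod_rg(n_bb, bond)
    # a chain whose backbone has zero extent is compact by definition
    label = (
        "extended" if rod > 0 and rg.mean() >= extended_fraction * rod else "compact"
    )
    return ConformationMetrics(
        rg=rg,
        end_to_end=np.array(e2e),
        in_plane_extension=np.array(inplane),
        headgroup_contacts=np.array(contacts),
        classification=label,
        rod_rg=rod,
        chain_id=chain_id,
    )


def sequestered_sidearms(
    frame: Frame,
    topology: Topology,
    chain_id: int | None = None,
    offset: float = 0.0,
) -> list:
    """Side arms inserted past the upper-leaflet mean phosphate plane.

    An arm is sequestered iff any of its heavy atoms lies strictly below
    the plane (mean phosphate z of the upper leaflet, minus ``offset``).
    Returns (chain_id, arm_id) pairs, or bare arm ids when a chain is
    given. Lowering an arm can only add it to the list (monotone).
    """
    labels = assign_leaflets(frame, topology)
    p_idx = topology.indices_where(
        lambda a: a.name == "P" and labels.get(a.molecule_id) == "upper"
    )
    if len(p_idx) == 0:
        raise ValueError("no upper-leaflet phosphates")
    plane = float(frame.coordinates[p_idx, 2].mean()) - offset
    arms: dict[tuple[int, int], bool] = {}
    for i, a in enumerate(topology.atoms):
        if a.molecule_kind is not MoleculeKind.POLYMER or a.sidearm_id is None:
            continue
        if chain_id is not None and a.chain_id != chain_id:
            continue
        if a.name.startswith("H"):
            continue
        key = (a.chain_id, a.sidearm_id)
        arms[key] = arms.get(key, False) or frame.coordinates[i, 2] < plane
    seq = sorted(k for k, v in arms.items() if v)
    if chain_id is not None:
        return [arm for _, arm in seq]
    return seq
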