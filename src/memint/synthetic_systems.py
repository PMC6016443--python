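"""Synthetic inputs with known ground truth for every analysis stage.

The generator builds desk-scale analogs of a polymer/bacterial-membrane
simulation system: a bilayer patch of PE-like and PG-like pseudo-lipids
(default 90 POPE + 38 POPG, split over two leaflets) with four cationic
polymer chains of 12 monomers each hovering 12-18 Å above the upper
leaflet. Pseudo-lipids are coarse beads, not atomistic lipids: analyses
only need donor/acceptor/phosphate/tail roles and charges, and coarse
beads admit exact oracles.

Bead layout per molecule (names match the default chemistry table):

* POPE:   P, OP1, OP2 (phosphate + acceptor oxygens), N + HN (ammonium
  donor), T1, T2 (tails)
* POPG:   P, OP1, OP2, O1 + HO1 and O2 + HO2 (hydroxyl donors/acceptors),
  T1, T2
* polymer monomer: CB + OB (backbone + imide carbonyl acceptor), Q
  (cationic side-arm bead), then per chemistry: ND + HD (amide N-H
  donor), CE + OE (ester carbonyl, acceptor only), or C1 + C2 (hexyl,
  inert)

Hydrogen-bond planting places donor-H-acceptor triples that satisfy the
geometric criteria with safety margins (≥0.5 Å / ≥10° away from the
cutoffs), while every non-planted polymer-lipid donor/acceptor pair
violates the distance criterion by at least 0.5 Å.

All generators are seed-deterministic.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd

from .binding_thermo import (
    DEFAULT_CELL_VOLUME_ML,
    ITCIsotherm,
    one_site_heats,
)
from .molecular_model import Frame, MoleculeKind, Topology, _annotate
from .spectrum import Spectrum

__all__ = [
    "BilayerSpec",
    "GroundTruth",
    "SyntheticSystem",
    "PackingError",
    "CapacityError",
    "default_chemistry_table",
    "write_default_chemistry_table",
    "build_system",
    "plant_hbonds",
    "insert_sidearms",
    "build_demo_pose",
    "polymer_molarity_mM",
    "simulate_itc",
    "default_injection_schedule",
    "synth_emission",
    "synth_raman",
    "synth_raman_series",
]


class PackingError(ValueError):
    """Lipid area too small to place the requested lipids."""


class CapacityError(ValueError):
    """More planted features requested than the system can host."""


# --------------------------------------------------------------------------
# chemistry defaults for the pseudo-beads
# --------------------------------------------------------------------------

_CHEMISTRY_ROWS = [
    # resname, atomname, charge, epsilon, rmin_half, is_donor, is_acceptor
    ("POPE", "P", 0.50, 0.20, 2.10, False, False),
    ("POPE", "OP1", -0.75, 0.12, 1.70, False, True),
    ("POPE", "OP2", -0.75, 0.12, 1.70, False, True),
    ("POPE", "N", 0.60, 0.20, 1.85, True, False),
    ("POPE", "HN", 0.40, 0.00, 0.22, False, False),
    ("POPE", "T1", 0.00, 0.20, 2.20, False, False),
    ("POPE", "T2", 0.00, 0.20, 2.20, False, False),
    ("POPG", "P", 0.50, 0.20, 2.10, False, False),
    ("POPG", "OP1", -0.75, 0.12, 1.70, False, True),
    ("POPG", "OP2", -0.75, 0.12, 1.70, False, True),
    ("POPG", "O1", -0.40, 0.15, 1.77, True, True),
    ("POPG", "HO1", 0.40, 0.00, 0.22, False, False),
    ("POPG", "O2", -0.40, 0.15, 1.77, True, True),
    ("POPG", "HO2", 0.40, 0.00, 0.22, False, False),
    ("POPG", "T1", 0.00, 0.20, 2.20, False, False),
    ("POPG", "T2", 0.00, 0.20, 2.20, False, False),
    ("POL", "CB", 0.30, 0.10, 2.00, False, False),
    ("POL", "OB", -0.30, 0.12, 1.70, False, True),
    ("POL", "Q", 1.00, 0.15, 2.10, False, False),
    ("POL", "ND", -0.40, 0.17, 1.85, True, False),
    ("POL", "HD", 0.40, 0.00, 0.22, False, False),
    ("POL", "CE", 0.40, 0.08, 2.00, False, False),
    ("POL", "OE", -0.40, 0.12, 1.70, False, True),
    ("POL", "C1", 0.00, 0.08, 2.00, False, False),
    ("POL", "C2", 0.00, 0.08, 2.00, False, False),
]


def default_chemistry_table() -> pd.DataFrame:
    """Annotation table for the synthetic pseudo-atoms (editable by users)."""
    df = pd.DataFrame(
        _CHEMISTRY_ROWS,
        columns=[
            "resname",
            "atomname",
            "charge",
            "epsilon",
            "rmin_half",
            "is_donor",
            "is_acceptor",
        ],
    )
    return df.set_index(["resname", "atomname"])


def write_default_chemistry_table(path: str | Path) -> None:
    default_chemistry_table().reset_index().to_csv(path, index=False)


# bead offsets relative to the lipid head reference, scaled by leaflet
# sign s (+1 upper, -1 lower); tails point toward the midplane
def _pope_beads(s: float):
    return [
        ("P", (0.0, 0.0, 0.0)),
        ("OP1", (-1.2, 0.0, 0.5 * s)),
        ("OP2", (1.2, 0.0, 0.5 * s)),
        ("N", (0.0, 2.2, 1.5 * s)),
        ("HN", (0.0, 2.2, 2.5 * s)),
        ("T1", (0.0, -0.8, -5.0 * s)),
        ("T2", (0.0, 0.8, -9.0 * s)),
    ]


def _popg_beads(s: float):
    return [
        ("P", (0.0, 0.0, 0.0)),
        ("OP1", (-1.2, 0.0, 0.5 * s)),
        ("OP2", (1.2, 0.0, 0.5 * s)),
        ("O1", (0.0, 2.2, 1.2 * s)),
        ("HO1", (0.0, 2.2, 2.2 * s)),
        ("O2", (0.0, -2.2, 1.2 * s)),
        ("HO2", (0.0, -2.2, 2.2 * s)),
        ("T1", (0.0, -0.8, -5.0 * s)),
        ("T2", (0.0, 0.8, -9.0 * s)),
    ]


_ARM_BEADS = {
    "amide": [("ND", (0.0, 0.0, -3.3)), ("HD", (0.0, 0.0, -4.3))],
    "ester": [("CE", (0.0, 0.5, -3.9)), ("OE", (0.0, 0.0, -3.3))],
    "hexyl": [("C1", (0.0, 0.0, -3.3)), ("C2", (0.0, 0.0, -4.3))],
}

_BACKBONE_SPACING = 3.0  # Å between successive monomers


@dataclass
class BilayerSpec:
    """Composition and geometry of a synthetic polymer-bilayer system."""

    n_pope: int = 90
    n_popg: int = 38
    area_per_lipid: float = 70.0  # Å²
    leaflet_separation: float = 38.0  # Å between head-group planes
    polymer_chains: int = 4
    monomers_per_chain: int = 12
    polymer_kind: str = "amide"  # amide | ester | hexyl
    seed: int = 0
    n_popg_clusters: int = 2
    place_chains_near_popg: bool = False

    def __post_init__(self) -> None:
        if self.n_pope < 0 or self.n_popg < 0:
            raise ValueError("lipid counts must be >= 0")
        if self.area_per_lipid <= 0:
            raise ValueError("area_per_lipid must be positive")
        if self.polymer_kind not in _ARM_BEADS:
            raise ValueError(f"polymer_kind must be one of {sorted(_ARM_BEADS)}")


@dataclass
class GroundTruth:
    """What the generator planted, for use as a test oracle."""

    planted_hbond_pairs: list = field(default_factory=list)  # (D, H, A) atom ids
    planted_density_centers: list = field(default_factory=list)  # (x, y) Å
    leaflet_counts: dict = field(default_factory=dict)
    lipid_leaflets: dict = field(default_factory=dict)  # molecule_id -> label
    sequestered_sidearm_ids: list = field(default_factory=list)  # (chain, arm)
    planted_arm_ids: list = field(default_factory=list)  # (chain, arm)

    def to_json(self, path: str | Path) -> None:
        payload = {
            "planted_hbond_pairs": [list(t) for t in self.planted_hbond_pairs],
            "planted_density_centers": [list(c) for c in self.planted_density_centers],
            "leaflet_counts": self.leaflet_counts,
            "lipid_leaflets": {str(k): v for k, v in self.lipid_leaflets.items()},
            "sequestered_sidearm_ids": [list(t) for t in self.sequestered_sidearm_ids],
            "planted_arm_ids": [list(t) for t in self.planted_arm_ids],
        }
        Path(path).write_text(json.dumps(payload, indent=1, sort_keys=True))


@dataclass
class SyntheticSystem:
    topology: Topology
    frame: Frame
    ground_truth: GroundTruth

    def __iter__(self):
        return iter((self.topology, self.frame, self.ground_truth))


def build_system(spec: BilayerSpec) -> SyntheticSystem:
    """Build a pseudo-bilayer with polymers hovering above the upper leaflet.

    Lipids sit on jittered square grids in two leaflets; PG lipids are
    assigned to the grid sites closest to ``n_popg_clusters`` planted
    cluster centers (recorded in the ground truth). Polymer chains run
    along x at staggered heights 12-18 Å above the upper head-group
    plane.
    """
    rng = np.random.default_rng(spec.seed)
    spacing = math.sqrt(spec.area_per_lipid)
    if spacing < 6.0:
        raise PackingError(
            f"area_per_lipid {spec.area_per_lipid} Å² packs lipids closer than "
            "6 Å; beads would overlap"
        )
    n_upper = {
        "POPE": spec.n_pope - spec.n_pope // 2,
        "POPG": spec.n_popg - spec.n_popg // 2,
    }
    n_lower = {
        "POPE": spec.n_pope // 2,
        "POPG": spec.n_popg // 2,
    }
    per_leaflet = max(sum(n_upper.values()), sum(n_lower.values()), 1)
    nx = math.ceil(math.sqrt(per_leaflet))
    ny = math.ceil(per_leaflet / nx)
    lx, ly = nx * spacing, ny * spacing
    margin = 31.0
    lz = spec.leaflet_separation + 2 * margin
    z_mid = lz / 2.0
    z_head = {
        "upper": z_mid + spec.leaflet_separation / 2.0,
        "lower": z_mid - spec.leaflet_separation / 2.0,
    }
    centers = [
        ((0.5 + i) * lx / max(spec.n_popg_clusters, 1) * 0.9 + 0.05 * lx,
         (0.5 + i) * ly / max(spec.n_popg_clusters, 1) * 0.9 + 0.05 * ly)
        for i in range(spec.n_popg_clusters)
    ]

    names: list[str] = []
    resnames: list[str] = []
    resids: list[int] = []
    coords: list[tuple[float, float, float]] = []
    resid = 0
    lipid_leaflets: dict[int, str] = {}

    def add_lipid(kind: str, x: float, y: float, leaflet: str) -> None:
        nonlocal resid
        resid += 1
        s = 1.0 if leaflet == "upper" else -1.0
        beads = _pope_beads(s) if kind == "POPE" else _popg_beads(s)
        z0 = z_head[leaflet]
        for nm, (dx, dy, dz) in beads:
            names.append(nm)
            resnames.append(kind)
            resids.append(resid)
            coords.append((x + dx, y + dy, z0 + dz))
        lipid_leaflets[resid - 1] = leaflet  # molecule_id is 0-based

    for leaflet, counts in (("upper", n_upper), ("lower", n_lower)):
        n_lip = sum(counts.values())
        sites = [
            ((i + 0.5) * spacing, (j + 0.5) * spacing)
            for j in range(ny)
            for i in range(nx)
        ][:n_lip]
        # PG lipids claim the sites nearest the planted cluster centers
        if counts["POPG"] > 0 and centers:
            dist_to_center = [
                min((sx - cx) ** 2 + (sy - cy) ** 2 for cx, cy in centers)
                for sx, sy in sites
            ]
            order = np.argsort(dist_to_center, kind="stable")
        else:
            order = np.arange(len(sites))
        popg_sites = set(order[: counts["POPG"]].tolist())
        for idx, (sx, sy) in enumerate(sites):
            jx, jy = rng.uniform(-0.15, 0.15, size=2)
            kind = "POPG" if idx in popg_sites else "POPE"
            add_lipid(kind, sx + jx, sy + jy, leaflet)

    # polymer chains along x, dispersed 12-18 Å above the upper leaflet
    heights = (
        np.linspace(12.0, 18.0, spec.polymer_chains)
        if spec.polymer_chains > 1
        else np.array([15.0])
    )
    contour = (spec.monomers_per_chain - 1) * _BACKBONE_SPACING
    arm_beads = _ARM_BEADS[spec.polymer_kind]
    for c in range(spec.polymer_chains):
        resid += 1
        if spec.place_chains_near_popg and centers:
            cx, cy = centers[c % len(centers)]
        else:
            cx = lx / 2.0
            cy = ly * (c + 0.5) / max(spec.polymer_chains, 1)
        x0 = cx - contour / 2.0
        z0 = z_head["upper"] + float(heights[c])
        for m in range(spec.monomers_per_chain):
            xm = x0 + m * _BACKBONE_SPACING
            for nm, (dx, dy, dz) in (
                [("CB", (0.0, 0.0, 0.0)), ("OB", (0.0, 0.9, 0.8)),
                 ("Q", (0.0, 0.0, -2.0))] + arm_beads
            ):
                names.append(nm)
                resnames.append("POL")
                resids.append(resid)
                coords.append((xm + dx, cy + dy, z0 + dz))

    atoms = _annotate(names, resnames, resids, default_chemistry_table())
    topology = Topology(atoms)
    frame = Frame(
        coordinates=np.array(coords, dtype=float),
        box=np.array([lx, ly, lz]),
        time=0.0,
    )
    truth = GroundTruth(
        planted_density_centers=list(centers),
        leaflet_counts={
            "upper": sum(n_upper.values()),
            "lower": sum(n_lower.values()),
            "upper_popg": n_upper["POPG"],
            "lower_popg": n_lower["POPG"],
        },
        lipid_leaflets=lipid_leaflets,
    )
    return SyntheticSystem(topology, frame, truth)


def _h_direction(w: np.ndarray, alpha_deg: float) -> np.ndarray:
    """Unit vector tilted alpha degrees off w, in a fixed perpendicular."""
    w = w / np.linalg.norm(w)
    p = np.cross(w, np.array([0.0, 1.0, 0.0]))
    if np.linalg.norm(p) < 1e-8:
        p = np.cross(w, np.array([1.0, 0.0, 0.0]))
    p /= np.linalg.norm(p)
    a = math.radians(alpha_deg)
    return math.cos(a) * w + math.sin(a) * p


def _arm_indices(topology: Topology) -> dict[tuple[int, int], list[int]]:
    """Atom indices of each polymer side arm keyed by (chain_id, arm_id)."""
    arms: dict[tuple[int, int], list[int]] = {}
    for i, a in enumerate(topology.atoms):
        if a.molecule_kind is MoleculeKind.POLYMER and a.sidearm_id is not None:
            arms.setdefault((a.chain_id, a.sidearm_id), []).append(i)
    return arms


def _lipid_atom_index(topology: Topology, molecule_id: int, name: str) -> int:
    for i, a in enumerate(topology.atoms):
        if a.molecule_id == molecule_id and a.name == name:
            return i
    raise KeyError(f"molecule {molecule_id} has no atom {name}")


def plant_hbonds(
    system: SyntheticSystem,
    k: int,
    seed: int = 0,
    distance: float = 3.0,
    h_tilt_deg: float = 15.0,
) -> tuple[Frame, GroundTruth]:
    """Pose exactly k polymer-lipid hydrogen bonds with safety margins.

    Amide polymers donate: k side arms are moved so their N-H points at
    the OP1 phosphate oxygen of k distinct upper-leaflet PE lipids at the
    given donor-acceptor distance (default 3.0 Å, i.e. 1.0 Å inside the
    4.0 Å cutoff) with a small angular deviation. Ester and hexyl
    polymers accept: their carbonyl (OE) or backbone imide (OB) oxygens
    are moved onto the hydroxyl O-H axis of k distinct upper-leaflet PG
    lipids. All non-planted polymer-lipid donor/acceptor pairs stay more
    than 4.5 Å apart by construction.
    """
    topology, frame, truth = system.topology, system.frame, system.ground_truth
    rng = np.random.default_rng(seed)
    coords = frame.coordinates.copy()
    arms = _arm_indices(topology)
    polymer_has_donor = any(
        a.is_donor and a.molecule_kind is MoleculeKind.POLYMER for a in topology.atoms
    )
    planted: list[tuple[int, int, int]] = []
    planted_arms: list[tuple[int, int]] = []

    if polymer_has_donor:
        donor_arms = [
            key
            for key, idxs in sorted(arms.items())
            if any(topology.atoms[i].name == "ND" for i in idxs)
        ]
        targets = [
            mol
            for mol, leaf in sorted(truth.lipid_leaflets.items())
            if leaf == "upper"
            and topology.atoms[_lipid_atom_index(topology, mol, "P")].molecule_kind
            is MoleculeKind.POPE
        ]
        if k > min(len(donor_arms), len(targets)):
            raise CapacityError(
                f"cannot plant {k} bonds: {len(donor_arms)} donor arms, "
                f"{len(targets)} PE target lipids"
            )
        chosen_arms = [donor_arms[i] for i in rng.choice(len(donor_arms), k, False)]
        chosen_lip = [targets[i] for i in rng.choice(len(targets), k, False)]
        theta = math.radians(27.0)
        approach = np.array([-math.sin(theta), 0.0, math.cos(theta)])
        for (chain, arm), mol in zip(chosen_arms, chosen_lip):
            idxs = arms[(chain, arm)]
            nd = next(i for i in idxs if topology.atoms[i].name == "ND")
            hd = next(i for i in idxs if topology.atoms[i].name == "HD")
            acc = _lipid_atom_index(topology, mol, "OP1")
            a_pos = coords[acc]
            d_pos = a_pos + distance * approach
            shift = d_pos - coords[nd]
            for i in idxs:
                coords[i] += shift
            coords[hd] = d_pos + _h_direction(a_pos - d_pos, h_tilt_deg)
            planted.append((nd, hd, acc))
            planted_arms.append((chain, arm))
    else:
        acceptor_units: list[tuple[tuple[int, int] | None, list[int], int]] = []
        for key, idxs in sorted(arms.items()):
            oe = [i for i in idxs if topology.atoms[i].name == "OE"]
            if oe:
                acceptor_units.append((key, idxs, oe[0]))
        if not acceptor_units:  # hexyl: fall back to backbone imide oxygens
            for i, a in enumerate(topology.atoms):
                if a.molecule_kind is MoleculeKind.POLYMER and a.name == "OB":
                    acceptor_units.append((None, [i], i))
        targets = [
            mol
            for mol, leaf in sorted(truth.lipid_leaflets.items())
            if leaf == "upper"
            and topology.atoms[_lipid_atom_index(topology, mol, "P")].molecule_kind
            is MoleculeKind.POPG
        ]
        if k > min(len(acceptor_units), len(targets)):
            raise CapacityError(
                f"cannot plant {k} bonds: {len(acceptor_units)} acceptor units, "
                f"{len(targets)} PG target lipids"
            )
        chosen_units = [
            acceptor_units[i] for i in rng.choice(len(acceptor_units), k, False)
        ]
        chosen_lip = [targets[i] for i in rng.choice(len(targets), k, False)]
        for (key, idxs, acc_atom), mol in zip(chosen_units, chosen_lip):
            don = _lipid_atom_index(topology, mol, "O1")
            hyd = _lipid_atom_index(topology, mol, "HO1")
            h_dir = coords[hyd] - coords[don]
            h_dir /= np.linalg.norm(h_dir)
            a_pos = coords[don] + distance * h_dir
            shift = a_pos - coords[acc_atom]
            for i in idxs:
                coords[i] += shift
            planted.append((don, hyd, acc_atom))
            if key is not None:
                planted_arms.append(key)

    new_truth = replace(
        truth,
        planted_hbond_pairs=planted,
        planted_arm_ids=planted_arms,
        sequestered_sidearm_ids=list(truth.sequestered_sidearm_ids),
    )
    return Frame(coords, frame.box.copy(), frame.time), new_truth


def insert_sidearms(
    system: SyntheticSystem,
    arm_ids: list[tuple[int, int]],
    depth: float = 2.5,
) -> tuple[Frame, GroundTruth]:
    """Push the given side arms past the upper-leaflet phosphate plane.

    Each arm is translated so its deepest heavy bead sits ``depth`` Å
    below the mean upper-leaflet phosphate z, laterally snapped to the
    nearest gap between lipid grid sites to avoid bead overlap. Inserted
    poses are meant for energy/conformation analyses; unlike planted
    hydrogen bonds they carry no margin guarantees for the H-bond
    detector.
    """
    topology, frame, truth = system.topology, system.frame, system.ground_truth
    coords = frame.coordinates.copy()
    arms = _arm_indices(topology)
    p_z = [
        coords[i][2]
        for i, a in enumerate(topology.atoms)
        if a.name == "P" and truth.lipid_leaflets.get(a.molecule_id) == "upper"
    ]
    if not p_z:
        raise ValueError("no upper-leaflet phosphates; build the system first")
    plane = float(np.mean(p_z))
    spacing = math.sqrt(70.0)
    sequestered = list(truth.sequestered_sidearm_ids)
    for key in arm_ids:
        if key not in arms:
            raise KeyError(f"no side arm {key}")
        idxs = arms[key]
        heavy = [i for i in idxs if not topology.atoms[i].name.startswith("H")]
        low = min(coords[i][2] for i in heavy)
        dz = (plane - depth) - low
        xy = coords[idxs[0]][:2]
        snapped = (np.floor(xy / spacing) + 1.0) * spacing  # grid-line crossing
        shift = np.array([snapped[0] - xy[0], snapped[1] - xy[1], dz])
        for i in idxs:
            coords[i] += shift
        if key not in sequestered:
            sequestered.append(key)
    new_truth = replace(truth, sequestered_sidearm_ids=sequestered)
    return Frame(coords, frame.box.copy(), frame.time), new_truth


def build_demo_pose(kind: str, seed: int = 0) -> SyntheticSystem:
    """A posed system expressing the expected amide > ester > hexyl contrast.

    The amide system gets many planted hydrogen bonds, deep side-arm
    insertion and chains over the PG clusters; the ester and hexyl
    systems get progressively fewer/shallower contacts and dispersed
    chains. This encodes the qualitative contrast by construction — it is
    a smoke-test fixture, not evidence about real polymers.
    """
    recipe = {
        "amide": dict(k=10, n_insert=8, depth=4.0, near=True),
        "ester": dict(k=3, n_insert=4, depth=2.0, near=False),
        "hexyl": dict(k=1, n_insert=3, depth=2.0, near=False),
    }[kind]
    spec = BilayerSpec(
        polymer_kind=kind, seed=seed, place_chains_near_popg=recipe["near"]
    )
    system = build_system(spec)
    frame, truth = plant_hbonds(system, recipe["k"], seed=seed + 1)
    system = SyntheticSystem(system.topology, frame, truth)
    free_arms = [
        key for key in sorted(_arm_indices(system.topology))
        if key not in truth.planted_arm_ids
    ]
    rng = np.random.default_rng(seed + 2)
    chosen = [free_arms[i] for i in rng.choice(len(free_arms), recipe["n_insert"], False)]
    frame, truth = insert_sidearms(system, chosen, depth=recipe["depth"])
    return SyntheticSystem(system.topology, frame, truth)


# --------------------------------------------------------------------------
# ITC
# --------------------------------------------------------------------------


def polymer_molarity_mM(mass_conc_ug_per_mL: float = 50.0, mw_Da: float = 6000.0):
    """Molar polymer concentration (mM) from mass concentration and Mw.

    The quaternized-polymer molar mass is approximate (only the
    precursor Mw ~6000 Da is well defined), so it is an explicit knob.
    """
    return mass_conc_ug_per_mL / mw_Da


def default_injection_schedule(n_inj: int = 40) -> np.ndarray:
    """Injection volumes (μL): a 2 μL priming shot then 5 μL injections."""
    v = np.full(n_inj, 5.0)
    if n_inj > 0:
        v[0] = 2.0
    return v


def simulate_itc(
    n_inj: int = 40,
    injection_volumes_uL: np.ndarray | None = None,
    cell_conc_mM: float | None = None,
    syringe_conc_mM: float = 1.0,
    n_sites: float = 1.0,
    Ka_per_M: float = 1e6,
    dH_kcal_per_mol: float = 2.5,
    dilution_heat_ucal: float = 0.0,
    noise_sd_ucal: float = 0.0,
    seed: int = 0,
    cell_volume_mL: float = DEFAULT_CELL_VOLUME_ML,
    temperature_K: float = 310.15,
    lipid_polymer_ratio: float = 30.0,
) -> ITCIsotherm:
    """Simulate a one-site reverse titration (lipid into polymer).

    Defaults mirror the experimental regime: 1 mM lipid titrated over 40
    injections of 5 μL (2 μL first) into polymer at a lipid:polymer
    molar ratio of 30:1 (cell concentration = syringe/30). The
    quaternized-polymer molar mass is not well defined, so the working
    ratio — which the experiment states directly — fixes the default
    cell concentration; :func:`polymer_molarity_mM` converts a mass
    concentration instead if you prefer a Mw-based cell concentration.
    Heats are the forward model plus a constant dilution heat plus
    Gaussian noise; ground-truth parameters are stored in the metadata.
    """
    if cell_conc_mM is None:
        cell_conc_mM = syringe_conc_mM / lipid_polymer_ratio
    if injection_volumes_uL is None:
        injection_volumes_uL = default_injection_schedule(n_inj)
    vols = np.asarray(injection_volumes_uL, dtype=float)
    rng = np.random.default_rng(seed)
    heats = one_site_heats(
        n_sites,
        Ka_per_M,
        dH_kcal_per_mol,
        vols,
        cell_volume_mL,
        cell_conc_mM,
        syringe_conc_mM,
    )
    heats = heats + dilution_heat_ucal
    if noise_sd_ucal > 0:
        heats = heats + rng.normal(0.0, noise_sd_ucal, size=len(vols))
    return ITCIsotherm(
        injection_volumes_uL=vols,
        heats_ucal=heats,
        cell_volume_mL=cell_volume_mL,
        cell_conc_mM=cell_conc_mM,
        syringe_conc_mM=syringe_conc_mM,
        temperature_K=temperature_K,
        metadata={
            "true_n_sites": n_sites,
            "true_Ka_per_M": Ka_per_M,
            "true_dH_kcal_per_mol": dH_kcal_per_mol,
            "dilution_heat_ucal": dilution_heat_ucal,
            "noise_sd_ucal": noise_sd_ucal,
            "seed": seed,
        },
    )


# --------------------------------------------------------------------------
# spectra
# --------------------------------------------------------------------------


def synth_emission(
    i440: float = 600.0,
    i490: float = 400.0,
    bandwidth_nm: float = 20.0,
    noise_sd: float = 0.0,
    seed: int = 0,
) -> Spectrum:
    """Two-band Laurdan-like emission spectrum on a 400-550 nm grid.

    Gaussian bands sit at 440 and 490 nm; amplitudes are solved so the
    noiseless spectrum passes exactly through the requested intensities
    at the band centers (the bands overlap slightly).
    """
    if i440 < 0 or i490 < 0:
        raise ValueError("intensities must be non-negative")
    axis = np.arange(400.0, 550.0 + 0.25, 0.5)
    c = math.exp(-((490.0 - 440.0) ** 2) / (2.0 * bandwidth_nm**2))
    a440 = (i440 - c * i490) / (1.0 - c * c)
    a490 = (i490 - c * i440) / (1.0 - c * c)
    intensity = a440 * np.exp(
        -((axis - 440.0) ** 2) / (2 * bandwidth_nm**2)
    ) + a490 * np.exp(-((axis - 490.0) ** 2) / (2 * bandwidth_nm**2))
    if noise_sd > 0:
        rng = np.random.default_rng(seed)
        intensity = intensity + rng.normal(0.0, noise_sd, size=len(axis))
    return Spectrum(axis, intensity, "wavelength_nm", {"i440": i440, "i490": i490})


def synth_raman(
    peaks: list[tuple[float, float, float]],
    baseline: tuple[float, ...] = (0.0,),
    noise_sd: float = 0.0,
    seed: int = 0,
) -> Spectrum:
    """Sum of Lorentzians + polynomial baseline on a 400-1800 cm⁻¹ grid.

    Each peak is (center cm⁻¹, FWHM cm⁻¹, amplitude), with amplitude the
    peak height. Baseline coefficients are in np.polyval order over the
    raw wavenumber axis.
    """
    axis = np.arange(400.0, 1800.0 + 0.5, 1.0)
    intensity = np.polyval(list(baseline), axis).astype(float)
    for center, fwhm, amp in peaks:
        gamma = fwhm / 2.0
        intensity = intensity + amp * gamma**2 / ((axis - center) ** 2 + gamma**2)
    if noise_sd > 0:
        rng = np.random.default_rng(seed)
        intensity = intensity + rng.normal(0.0, noise_sd, size=len(axis))
    meta = {"peaks": [tuple(p) for p in peaks], "baseline": tuple(baseline)}
    return Spectrum(axis, intensity, "wavenumber_cm1", meta)


def synth_raman_series(
    temperatures_C: list[float] | None = None,
    onset_C: float = 36.0,
    band_center: float = 1680.0,
    band_fwhm: float = 12.0,
    band_amp_max: float = 80.0,
    noise_sd: float = 1.0,
    seed: int = 0,
) -> dict[float, Spectrum]:
    """Temperature series in which an amide-I-like band emerges above onset.

    Below ``onset_C`` the 1680 cm⁻¹ band is absent (hydrogen-bonded,
    spectroscopically silent analog); at and above onset its amplitude
    ramps to ``band_amp_max`` over ~4 °C. Fixed companion bands at 1740
    and 1770 cm⁻¹ are present at every temperature.
    """
    if temperatures_C is None:
        temperatures_C = list(np.arange(25.0, 41.0, 1.0))
    out: dict[float, Spectrum] = {}
    for j, t in enumerate(temperatures_C):
        ramp = min(1.0, max(0.0, (t - onset_C + 1.0) / 4.0)) if t >= onset_C else 0.0
        peaks = [
            (1740.0, 10.0, 60.0),
            (1770.0, 10.0, 40.0),
        ]
        if ramp > 0:
            peaks.append((band_center, band_fwhm, band_amp_max * ramp))
        spec = synth_raman(peaks, baseline=(5.0,), noise_sd=noise_sd, seed=seed + j)
        spec.metadata["temperature_C"] = t
        out[float(t)] = spec
    return out
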