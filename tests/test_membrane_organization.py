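import numpy as np
import pytest
from scipy import stats

from conftest import make_point_topology
from memint.membrane_organization import (
    assign_leaflets,
    conformation_metrics,
    coordination_number,
    density_colocalization,
    number_density_2d,
    radial_distribution,
    select_beads,
    sequestered_sidearms,
)
from memint.molecular_model import Atom, Frame, MoleculeKind, Topology, Trajectory
from memint.synthetic_systems import BilayerSpec, build_system, insert_sidearms


class TestLeaflets:
    def test_default_bilayer_matches_ground_truth(self, default_system):
        labels = assign_leaflets(default_system.frame, default_system.topology)
        assert labels == default_system.ground_truth.lipid_leaflets
        assert sum(v == "upper" for v in labels.values()) == 64

    def test_single_leaflet_all_upper_with_warning(self):
        atoms = [
            Atom(i, "P", "P", i, MoleculeKind.POPE, -1, None, 0.5, 0.2, 2.1,
                 False, False)
            for i in range(4)
        ]
        top = Topology(atoms)
        coords = np.array([[x, 0.0, 30.0] for x in (0, 5, 10, 15)])
        with pytest.warns(UserWarning, match="midplane"):
            labels = assign_leaflets(Frame(coords, [40, 40, 60]), top)
        assert set(labels.values()) == {"upper"}

    def test_no_phosphates_rejected(self):
        top = make_point_topology(3)
        with pytest.raises(ValueError, match="phosphate"):
            assign_leaflets(Frame(np.zeros((3, 3)) + 1.0, [10, 10, 10]), top)


class TestRDF:
    def test_ideal_gas_converges_to_unity(self):
        rng = np.random.default_rng(21)
        N, L = 2000, 40.0
        top = make_point_topology(N)
        frame = Frame(rng.uniform(0, L, (N, 3)), [L, L, L])
        result = radial_distribution(frame, top, np.arange(N), np.arange(N),
                                     r_max=15.0, dr=0.1)
        window = (result.bin_centers >= 5.0) & (result.bin_centers <= 15.0)
        assert result.g[window].mean() == pytest.approx(1.0, abs=0.05)
        assert np.all(result.g >= 0)

    def test_ideal_gas_error_shrinks_with_n(self):
        rng = np.random.default_rng(22)
        L = 40.0
        devs = {}
        for n in (500, 5000):
            top = make_point_topology(n)
            frame = Frame(rng.uniform(0, L, (n, 3)), [L, L, L])
            r = radial_distribution(frame, top, np.arange(n), np.arange(n),
                                    r_max=15.0, dr=0.25)
            window = r.bin_centers >= 5.0
            devs[n] = np.abs(r.g[window] - 1.0).max()
        assert devs[5000] < devs[500]

    def test_simple_cubic_first_shell(self):
        a, n = 5.0, 6
        pts = np.array(
            [[i * a, j * a, k * a] for i in range(n) for j in range(n)
             for k in range(n)],
            dtype=float,
        )
        top = make_point_topology(len(pts))
        frame = Frame(pts, [n * a] * 3)
        result = radial_distribution(frame, top, np.arange(len(pts)),
                                     np.arange(len(pts)), r_max=12.0, dr=0.1)
        # every atom has exactly 6 nearest neighbours at r = a
        assert coordination_number(result, 4.5, 5.5) == pytest.approx(6.0)
        shell = (result.bin_centers > a - 2 * 0.1) & (result.bin_centers < a + 2 * 0.1)
        assert result.g[shell].max() > 10.0  # sharp crystalline peak
        # no pairs below the lattice spacing
        assert result.counts[result.bin_centers < 4.5].sum() == 0

    def test_r_max_beyond_half_box_rejected(self):
        top = make_point_topology(10)
        frame = Frame(np.random.default_rng(0).uniform(0, 10, (10, 3)),
                      [10, 10, 10])
        with pytest.raises(ValueError, match="half the smallest box"):
            radial_distribution(frame, top, np.arange(10), np.arange(10),
                                r_max=8.0)

    def test_empty_group_rejected(self, default_system):
        with pytest.raises(ValueError, match="non-empty"):
            radial_distribution(default_system.frame, default_system.topology,
                                np.array([], dtype=int), np.arange(5))


class TestDensityMaps:
    def test_integral_equals_mean_count(self):
        rng = np.random.default_rng(31)
        N, L = 1500, 40.0
        top = make_point_topology(N)
        frames = [Frame(rng.uniform(0, L, (N, 3)), [L, L, L]) for _ in range(3)]
        dm = number_density_2d(frames, top, np.arange(N), grid_spacing=2.0)
        assert dm.integral() == pytest.approx(N, rel=1e-3)

    def test_uniform_points_poisson_consistent(self):
        rng = np.random.default_rng(32)
        N, L = 4000, 64.0
        top = make_point_topology(N)
        frame = Frame(rng.uniform(0, L, (N, 3)), [L, L, L])
        dm = number_density_2d(frame, top, np.arange(N), grid_spacing=8.0)
        counts = (dm.density * 64.0).ravel()  # cell area 8x8
        lam = counts.mean()
        # chi-square GOF against Poisson(lam), pooling the tail
        edges = [-0.5] + [k + 0.5 for k in range(int(lam * 2))] + [np.inf]
        observed, _ = np.histogram(counts, bins=edges)
        expect = np.diff([stats.poisson.cdf(e, lam) for e in edges]) * counts.size
        keep = expect > 1.0
        chi2 = ((observed[keep] - expect[keep]) ** 2 / expect[keep]).sum()
        p = 1 - stats.chi2.cdf(chi2, keep.sum() - 2)
        assert p > 0.01

    def test_planted_blobs_recovered(self):
        rng = np.random.default_rng(33)
        L = 64.0
        centers = [(16.0, 16.0), (48.0, 48.0)]
        pts = np.concatenate(
            [rng.normal(c, 2.0, size=(300, 2)) % L for c in centers]
        )
        coords = np.column_stack([pts, np.full(len(pts), 5.0)])
        top = make_point_topology(len(coords))
        dm = number_density_2d(Frame(coords, [L, L, 20]), top,
                               np.arange(len(coords)), grid_spacing=1.0)
        maxima = dm.local_maxima(2, min_separation=10.0)
        for found in maxima:
            best = min(np.hypot(found[0] - cx, found[1] - cy)
                       for cx, cy in centers)
            assert best <= 2.0

    def test_empty_group_warns_zero_map(self, default_system):
        with pytest.warns(UserWarning, match="empty group"):
            dm = number_density_2d(default_system.frame, default_system.topology,
                                   np.array([], dtype=int))
        assert dm.density.sum() == 0.0

    def test_invalid_spacing_rejected(self, default_system):
        with pytest.raises(ValueError, match="grid_spacing"):
            number_density_2d(default_system.frame, default_system.topology,
                              np.arange(5), grid_spacing=0.0)


class TestColocalization:
    def _map(self, density):
        from memint.membrane_organization import DensityMap

        n = density.shape[0]
        edges = np.linspace(0, n, n + 1)
        return DensityMap(density, edges, edges, 1.0, None, 1)

    def test_identical_maps(self):
        rng = np.random.default_rng(41)
        d = rng.random((16, 16))
        assert density_colocalization(self._map(d), self._map(d)) == pytest.approx(1.0)

    def test_negated_about_mean(self):
        rng = np.random.default_rng(42)
        d = rng.random((16, 16))
        neg = 2 * d.mean() - d
        assert density_colocalization(self._map(d), self._map(neg)) == pytest.approx(-1.0)

    def test_independent_maps_near_zero(self):
        rng = np.random.default_rng(43)
        a, b = rng.random((64, 64)), rng.random((64, 64))
        assert abs(density_colocalization(self._map(a), self._map(b))) < 0.1

    def test_grid_mismatch_rejected(self):
        with pytest.raises(ValueError, match="grid mismatch"):
            density_colocalization(self._map(np.ones((4, 4))),
                                   self._map(np.ones((8, 8))))

    def test_zero_variance_rejected(self):
        with pytest.raises(ValueError, match="zero-variance"):
            density_colocalization(self._map(np.ones((4, 4))),
                                   self._map(np.random.default_rng(0).random((4, 4))))


def make_rod(n=12, spacing=3.0):
    """A straight 12-bead polymer backbone along x."""
    atoms = [
        Atom(i, "CB", "C", 0, MoleculeKind.POLYMER, 0, None, 0.0, 0.1, 2.0,
             False, False)
        for i in range(n)
    ]
    coords = np.column_stack(
        [np.arange(n) * spacing, np.zeros(n), np.zeros(n)]
    ) + 50.0
    return Topology(atoms), Frame(coords, [200.0] * 3)


class TestConformation:
    def test_straight_rod_closed_form(self):
        top, frame = make_rod()
        metrics = conformation_metrics(Trajectory(top, [frame]), chain_id=0)
        assert metrics.end_to_end[0] == pytest.approx(33.0)
        # discrete rod: Rg^2 = b^2 (n^2 - 1) / 12 = 107.25
        assert metrics.rg[0] == pytest.approx(np.sqrt(107.25), rel=1e-9)
        assert metrics.classification == "extended"

    def test_coincident_beads_zero_rg(self):
        top, frame = make_rod()
        collapsed = Frame(np.tile(frame.coordinates[:1], (12, 1)), frame.box)
        metrics = conformation_metrics(Trajectory(top, [collapsed]), chain_id=0)
        assert metrics.rg[0] == 0.0
        assert metrics.classification == "compact"

    def test_rigid_motion_invariance(self):
        top, frame = make_rod()
        theta = 0.7
        rot = np.array(
            [[np.cos(theta), -np.sin(theta), 0],
             [np.sin(theta), np.cos(theta), 0],
             [0, 0, 1]]
        )
        moved = Frame(frame.coordinates @ rot.T + np.array([5.0, -3.0, 2.0]),
                      frame.box)
        m1 = conformation_metrics(Trajectory(top, [frame]), chain_id=0)
        m2 = conformation_metrics(Trajectory(top, [moved]), chain_id=0)
        assert m1.rg[0] == pytest.approx(m2.rg[0])
        assert m1.end_to_end[0] == pytest.approx(m2.end_to_end[0])

    def test_unknown_chain_rejected(self, default_system):
        traj = Trajectory(default_system.topology, [default_system.frame])
        with pytest.raises(KeyError):
            conformation_metrics(traj, chain_id=99)

    def test_headgroup_contacts_rise_on_insertion(self, default_system):
        frame_in, _ = insert_sidearms(default_system, [(0, i) for i in range(6)],
                                      depth=2.5)
        top = default_system.topology
        before = conformation_metrics(
            Trajectory(top, [default_system.frame]), chain_id=0,
            contact_cutoff=6.0,
        ).headgroup_contacts[0]
        after = conformation_metrics(
            Trajectory(top, [frame_in]), chain_id=0, contact_cutoff=6.0
        ).headgroup_contacts[0]
        assert after > before


class TestSequestration:
    def test_ground_truth_arms_recovered(self, default_system):
        arms = [(0, 2), (0, 5), (2, 9)]
        frame, truth = insert_sidearms(default_system, arms, depth=3.0)
        assert sequestered_sidearms(frame, default_system.topology) == sorted(arms)
        assert sequestered_sidearms(frame, default_system.topology, chain_id=0) == [2, 5]

    def test_hovering_polymer_has_none(self, default_system):
        assert sequestered_sidearms(default_system.frame,
                                    default_system.topology) == []

    def test_arm_exactly_at_plane_not_sequestered(self, default_system):
        top, frame = default_system.topology, default_system.frame
        labels = default_system.ground_truth.lipid_leaflets
        p_idx = top.indices_where(
            lambda a: a.name == "P" and labels.get(a.molecule_id) == "upper"
        )
        plane = frame.coordinates[p_idx, 2].mean()
        coords = frame.coordinates.copy()
        arm_idx = top.indices_where(
            lambda a: a.chain_id == 0 and a.sidearm_id == 3
            and not a.name.startswith("H")
        )
        lowest = arm_idx[np.argmin(coords[arm_idx, 2])]
        coords[arm_idx, 2] += plane - coords[lowest, 2]  # lowest bead at plane
        at_plane = Frame(coords, frame.box)
        assert (0, 3) not in sequestered_sidearms(at_plane, top)
        coords[arm_idx, 2] -= 0.01  # strictly below
        below = Frame(coords, frame.box)
        assert (0, 3) in sequestered_sidearms(below, top)

    def test_monotone_under_lowering(self, default_system):
        frame, _ = insert_sidearms(default_system, [(1, 4)], depth=1.0)
        top = default_system.topology
        seq1 = set(sequestered_sidearms(frame, top))
        deeper, _ = insert_sidearms(default_system, [(1, 4)], depth=6.0)
        seq2 = set(sequestered_sidearms(deeper, top))
        assert seq1 <= seq2

    def test_representative_bead_selection(self, default_system):
        popg_p = select_beads(default_system.topology, MoleculeKind.POPG, "P")
        assert len(popg_p) == 38
        chains_cb = select_beads(default_system.topology, MoleculeKind.POLYMER, "CB")
        assert len(chains_cb) == 48
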