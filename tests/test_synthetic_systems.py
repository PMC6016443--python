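import numpy as np
import pytest

from memint.binding_thermo import laurdan_gp, one_site_heats
from memint.hbond_analysis import detect_hbonds
from memint.molecular_model import MoleculeKind
from memint.synthetic_systems import (
    BilayerSpec,
    CapacityError,
    PackingError,
    build_system,
    default_injection_schedule,
    insert_sidearms,
    plant_hbonds,
    simulate_itc,
    synth_emission,
    synth_raman,
    synth_raman_series,
)
from oracles import min_image_dist


class TestBuildSystem:
    def test_default_composition(self, default_system):
        top = default_system.topology
        lipids = {a.molecule_id for a in top.atoms
                  if a.molecule_kind in (MoleculeKind.POPE, MoleculeKind.POPG)}
        assert len(lipids) == 128
        chains = {a.chain_id for a in top.atoms
                  if a.molecule_kind is MoleculeKind.POLYMER}
        assert len(chains) == 4
        arms = {(a.chain_id, a.sidearm_id) for a in top.atoms
                if a.sidearm_id is not None}
        assert len(arms) == 4 * 12

    def test_leaflet_split_recorded(self, default_system):
        counts = default_system.ground_truth.leaflet_counts
        assert counts["upper"] == 64 and counts["lower"] == 64
        assert counts["upper_popg"] + counts["lower_popg"] == 38

    def test_seed_determinism(self):
        a = build_system(BilayerSpec(seed=42))
        b = build_system(BilayerSpec(seed=42))
        assert np.array_equal(a.frame.coordinates, b.frame.coordinates)
        c = build_system(BilayerSpec(seed=43))
        assert not np.array_equal(a.frame.coordinates, c.frame.coordinates)

    def test_polymer_only_system(self):
        s = build_system(BilayerSpec(n_pope=0, n_popg=0, seed=0))
        kinds = {a.molecule_kind for a in s.topology.atoms}
        assert kinds == {MoleculeKind.POLYMER}
        assert s.ground_truth.leaflet_counts["upper"] == 0

    def test_overpacked_area_rejected(self):
        with pytest.raises(PackingError):
            build_system(BilayerSpec(area_per_lipid=20.0))

    def test_polymers_start_above_upper_leaflet(self, default_system):
        top, frame = default_system.topology, default_system.frame
        p_upper = [
            frame.coordinates[i, 2]
            for i, a in enumerate(top.atoms)
            if a.name == "P"
            and default_system.ground_truth.lipid_leaflets[a.molecule_id] == "upper"
        ]
        plane = np.mean(p_upper)
        backbone_z = [
            frame.coordinates[i, 2]
            for i, a in enumerate(top.atoms)
            if a.molecule_kind is MoleculeKind.POLYMER and a.name == "CB"
        ]
        assert min(backbone_z) >= plane + 12.0 - 1e-9
        assert max(backbone_z) <= plane + 18.0 + 1e-9


class TestPlantHbonds:
    @pytest.mark.parametrize("kind", ["amide", "ester", "hexyl"])
    def test_planted_triples_meet_criteria_with_margin(self, kind):
        s = build_system(BilayerSpec(polymer_kind=kind, seed=2))
        frame, truth = plant_hbonds(s, 5, seed=3)
        for d, h, a in truth.planted_hbond_pairs:
            assert min_image_dist(
                frame.coordinates[d], frame.coordinates[a], frame.box
            ) <= 4.0 - 0.5
        recs = detect_hbonds(frame, s.topology)
        assert all(r.angle_deviation <= 60.0 - 10.0 for r in recs)

    def test_nonplanted_pairs_violate_distance_margin(self):
        s = build_system(BilayerSpec(seed=4))
        frame, truth = plant_hbonds(s, 8, seed=5)
        planted = {(d, a) for d, _, a in truth.planted_hbond_pairs}
        top = s.topology
        poly = set(top.select("polymer"))
        lip = set(top.select("lipids"))
        for di, datom in enumerate(top.atoms):
            if not datom.is_donor:
                continue
            for ai, aatom in enumerate(top.atoms):
                if not aatom.is_acceptor or (di, ai) in planted:
                    continue
                if not (
                    (di in poly and ai in lip) or (di in lip and ai in poly)
                ):
                    continue
                assert min_image_dist(
                    frame.coordinates[di], frame.coordinates[ai], frame.box
                ) >= 4.0 + 0.5

    def test_k_zero_plants_nothing(self, default_system):
        frame, truth = plant_hbonds(default_system, 0, seed=1)
        assert truth.planted_hbond_pairs == []
        assert detect_hbonds(frame, default_system.topology) == []

    def test_capacity_error(self, default_system):
        with pytest.raises(CapacityError):
            plant_hbonds(default_system, 1000, seed=0)


class TestInsertSidearms:
    def test_ground_truth_matches_request(self, default_system):
        arms = [(0, 2), (0, 5), (1, 9)]
        _, truth = insert_sidearms(default_system, arms, depth=3.0)
        assert truth.sequestered_sidearm_ids == arms

    def test_unknown_arm_rejected(self, default_system):
        with pytest.raises(KeyError):
            insert_sidearms(default_system, [(9, 99)])


class TestSimulateITC:
    def test_noiseless_equals_forward_model(self):
        iso = simulate_itc(noise_sd_ucal=0.0, dilution_heat_ucal=0.0)
        expected = one_site_heats(
            1.0, 1e6, 2.5, iso.injection_volumes_uL,
            iso.cell_volume_mL, iso.cell_conc_mM, iso.syringe_conc_mM,
        )
        assert np.array_equal(iso.heats_ucal, expected)

    def test_default_schedule(self):
        iso = simulate_itc()
        assert iso.n_injections == 40
        assert iso.injection_volumes_uL[0] == 2.0
        assert np.all(iso.injection_volumes_uL[1:] == 5.0)

    def test_saturating_titration_mass_balance(self):
        # strong binding, titrant in large excess: total heat approaches
        # n * (cell moles) * dH
        vols = default_injection_schedule(40)
        cell_mM, V0, n, dH = 0.01, 1.4285, 1.0, 2.5
        heats = one_site_heats(n, 1e12, dH, vols, V0, cell_mM, 5.0)
        expected = n * cell_mM * 1e-3 * V0 * 1e-3 * dH * 1e9  # ucal
        assert heats.sum() == pytest.approx(expected, rel=0.01)

    def test_dilution_offset_and_noise_determinism(self):
        a = simulate_itc(noise_sd_ucal=0.5, dilution_heat_ucal=2.0, seed=9)
        b = simulate_itc(noise_sd_ucal=0.5, dilution_heat_ucal=2.0, seed=9)
        assert np.array_equal(a.heats_ucal, b.heats_ucal)
        base = simulate_itc(noise_sd_ucal=0.0, dilution_heat_ucal=0.0)
        shifted = simulate_itc(noise_sd_ucal=0.0, dilution_heat_ucal=2.0)
        assert np.allclose(shifted.heats_ucal - base.heats_ucal, 2.0)


class TestSynthEmission:
    @pytest.mark.parametrize(
        "i440,i490,gp", [(600, 400, 0.2), (500, 500, 0.0), (600, 0, 1.0)]
    )
    def test_requested_intensities_give_expected_gp(self, i440, i490, gp):
        spec = synth_emission(i440, i490, noise_sd=0.0)
        import warnings

        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            assert laurdan_gp(spec) == pytest.approx(gp, abs=1e-9)

    def test_negative_intensity_rejected(self):
        with pytest.raises(ValueError):
            synth_emission(-1.0, 100.0)


class TestSynthRaman:
    def test_single_peak_position(self):
        spec = synth_raman([(1100.0, 6.0, 100.0)], noise_sd=0.0)
        assert spec.axis[np.argmax(spec.intensity)] == pytest.approx(1100.0, abs=1.0)
        assert spec.intensity.max() == pytest.approx(100.0, rel=1e-6)

    def test_zero_peaks_flat_baseline(self):
        spec = synth_raman([], baseline=(3.5,), noise_sd=0.0)
        assert np.allclose(spec.intensity, 3.5)

    def test_temperature_series_band_gated_by_onset(self):
        series = synth_raman_series(onset_C=36.0, noise_sd=0.0, seed=0)
        lo = series[30.0].window(1660, 1700)
        hi = series[40.0].window(1660, 1700)
        assert hi.intensity.max() > lo.intensity.max() + 50.0
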