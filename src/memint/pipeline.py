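"""Configuration-driven orchestration of all analysis stages.

A :class:`PipelineConfig` (YAML-loadable, pydantic-validated) selects
stages and parameters; :func:`run_pipeline` executes them in dependency
order and writes per-stage outputs plus a JSON report. The bundled demo
contrasts amide/ester/hexyl synthetic systems — hydrogen-bond counts,
per-arm interaction energies, g(r) first peaks and polymer/PG-lipid
density colocalization — on generator-posed configurations, so the
contrast is a smoke test of the machinery, not evidence about real
polymers.
"""

from __future__ import annotations

import json
import logging
from pathlib import Path

import numpy as np
import yaml
from pydantic import BaseModel, Field, ValidationError

from . import binding_thermo, synthetic_systems, vibrational_spectra
from .hbond_analysis import summarize_hbonds
from .interaction_energetics import decompose_interaction
from .membrane_organization import (
    density_colocalization,
    number_density_2d,
    radial_distribution,
    select_beads,
)
from .molecular_model import MoleculeKind, Trajectory

logger = logging.getLogger(__name__)

__all__ = ["PipelineConfig", "validate_config", "run_pipeline"]


class HBondBlock(BaseModel):
    d_max: float = 4.0
    a_max: float = 60.0


class RDFBlock(BaseModel):
    r_max: float = 12.0
    dr: float = 0.1


class EnergyBlock(BaseModel):
    cutoff: float = 12.0
    switch_on: float = 10.0


class MDStage(BaseModel):
    kinds: list[str] = Field(default_factory=lambda: ["amide", "ester", "hexyl"])
    hbond: HBondBlock = Field(default_factory=HBondBlock)
    rdf: RDFBlock = Field(default_factory=RDFBlock)
    energy: EnergyBlock = Field(default_factory=EnergyBlock)
    # ~one grid cell per lipid: the natural resolution for per-molecule maps
    density_grid_spacing: float = 8.0


class ITCStage(BaseModel):
    n_injections: int = 40
    Ka_per_M: float = 1e6
    dH_kcal_per_mol: float = 2.5
    n_sites: float = 1.0
    noise_sd_ucal: float = 0.0


class GPStage(BaseModel):
    i440: float = 600.0
    i490: float = 400.0
    noise_sd: float = 0.0


class RamanStage(BaseModel):
    # brackets the softened PO2- doublet while excluding the flank of the
    # likewise-softened 1129 cm-1 C-C mode
    doublet_window: tuple[float, float] = (1078.0, 1114.0)
    softening_cm1: float = -4.0
    onset_C: float = 36.0


class PipelineConfig(BaseModel):
    seed: int = 0
    outdir: str = "memint_out"
    log_level: str = "INFO"
    structure: str | None = None  # optional input paths; synthetic if absent
    chemistry_table: str | None = None
    md: MDStage | None = Field(default_factory=MDStage)
    itc: ITCStage | None = Field(default_factory=ITCStage)
    gp: GPStage | None = Field(default_factory=GPStage)
    raman: RamanStage | None = Field(default_factory=RamanStage)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        return cls.model_validate(data)


def validate_config(config) -> list[str]:
    """Return the list of problems; empty iff run_pipeline would start."""
    problems: list[str] = []
    if not isinstance(config, PipelineConfig):
        try:
            config = PipelineConfig.model_validate(config)
        except ValidationError as exc:
            return [str(e["loc"]) + ": " + e["msg"] for e in exc.errors()]
    if config.md is not None:
        if config.md.hbond.d_max <= 0:
            problems.append("md.hbond.d_max: must be positive")
        if config.md.hbond.a_max <= 0:
            problems.append("md.hbond.a_max: must be positive")
        if config.md.rdf.dr <= 0 or config.md.rdf.r_max <= config.md.rdf.dr:
            problems.append("md.rdf: need 0 < dr < r_max")
        if config.md.energy.switch_on >= config.md.energy.cutoff:
            problems.append("md.energy: switch_on must be < cutoff")
        if config.md.density_grid_spacing <= 0:
            problems.append("md.density_grid_spacing: must be positive")
        unknown = set(config.md.kinds) - {"amide", "ester", "hexyl"}
        if unknown:
            problems.append(f"md.kinds: unknown kinds {sorted(unknown)}")
    if config.itc is not None:
        if config.itc.Ka_per_M <= 0:
            problems.append("itc.Ka_per_M: must be positive")
        if config.itc.n_injections < 6:
            problems.append("itc.n_injections: need at least 6")
    for name in ("structure", "chemistry_table"):
        path = getattr(config, name)
        if path is not None and not Path(path).exists():
            problems.append(f"{name}: path {path!r} does not exist")
    return problems


def _md_stage(config: PipelineConfig, outdir: Path) -> dict:
    md = config.md
    results: dict = {}
    for kind in md.kinds:
        system = synthetic_systems.build_demo_pose(kind, seed=config.seed)
        topology, frame = system.topology, system.frame
        traj = Trajectory(topology, [frame])
        summary = summarize_hbonds(
            traj, d_max=md.hbond.d_max, a_max=md.hbond.a_max
        )
        energy = decompose_interaction(
            traj, cutoff=md.energy.cutoff, switch_on=md.energy.switch_on
        )
        former = {"amide": "ND", "ester": "OE", "hexyl": "C1"}[kind]
        formers = topology.indices_where(
            lambda a, nm=former: a.molecule_kind is MoleculeKind.POLYMER
            and a.name == nm
        )
        acceptors = topology.indices_where(
            lambda a: a.molecule_kind in (MoleculeKind.POPE, MoleculeKind.POPG)
            and a.name in ("OP1", "OP2")
        )
        rdf = radial_distribution(
            frame, topology, formers, acceptors, r_max=md.rdf.r_max, dr=md.rdf.dr
        )
        peak_pos, peak_height = rdf.first_peak()
        poly_map = number_density_2d(
            frame,
            topology,
            select_beads(topology, MoleculeKind.POLYMER, "CB"),
            grid_spacing=md.density_grid_spacing,
        )
        popg_map = number_density_2d(
            frame,
            topology,
            select_beads(topology, MoleculeKind.POPG, "P"),
            leaflet="upper",
            grid_spacing=md.density_grid_spacing,
        )
        coloc = density_colocalization(poly_map, popg_map)
        results[kind] = {
            "hbonds_mean_per_frame": summary.mean_per_frame,
            "participating_sidearms": len(summary.participating_sidearms),
            "electrostatic_kcal_mol": energy.electrostatic,
            "vdw_kcal_mol": energy.vdw,
            "per_arm_vdw_kcal_mol": energy.per_arm_vdw,
            "per_arm_electrostatic_kcal_mol": energy.per_arm_electrostatic,
            "n_sequestered": energy.n_sequestered_mean,
            "rdf_first_peak_A": peak_pos,
            "rdf_first_peak_height": peak_height,
            "polymer_popg_colocalization": coloc,
        }
    if {"amide", "ester"} <= set(results):
        results["contrast"] = {
            "amide_more_hbonds_than_ester": bool(
                results["amide"]["hbonds_mean_per_frame"]
                > results["ester"]["hbonds_mean_per_frame"]
            ),
            "amide_vdw_per_arm_more_negative": bool(
                (results["amide"]["per_arm_vdw_kcal_mol"] or 0)
                < (results["ester"]["per_arm_vdw_kcal_mol"] or 0)
            ),
            "amide_higher_colocalization": bool(
                results["amide"]["polymer_popg_colocalization"]
                > results["ester"]["polymer_popg_colocalization"]
            ),
        }
    return results


def _itc_stage(config: PipelineConfig, outdir: Path) -> dict:
    itc = config.itc
    iso = synthetic_systems.simulate_itc(
        n_inj=itc.n_injections,
        n_sites=itc.n_sites,
        Ka_per_M=itc.Ka_per_M,
        dH_kcal_per_mol=itc.dH_kcal_per_mol,
        noise_sd_ucal=itc.noise_sd_ucal,
        seed=config.seed,
    )
    iso.to_csv(outdir / "itc_isotherm.csv")
    params = binding_thermo.fit_one_site(iso)
    return {
        "true": {"Ka_per_M": itc.Ka_per_M, "dH_kcal_per_mol": itc.dH_kcal_per_mol},
        "fitted": {
            "n_sites": params.n_sites,
            "Ka_per_M": params.Ka_per_M,
            "dH_kcal_per_mol": params.dH_kcal_per_mol,
            "dG_kcal_per_mol": params.dG_kcal_per_mol,
            "dS_cal_per_mol_K": params.dS_cal_per_mol_K,
            "saturation_fraction": params.diagnostics["saturation_fraction"],
        },
    }


def _gp_stage(config: PipelineConfig, outdir: Path) -> dict:
    gp = config.gp
    spec = synthetic_systems.synth_emission(
        gp.i440, gp.i490, noise_sd=gp.noise_sd, seed=config.seed
    )
    spec.to_csv(outdir / "emission.csv")
    return {"generalized_polarization": binding_thermo.laurdan_gp(spec)}


def _raman_stage(config: PipelineConfig, outdir: Path) -> dict:
    rm = config.raman
    shift = rm.softening_cm1
    ref = synthetic_systems.synth_raman(
        [(1064.0, 8.0, 90.0), (1100.0, 6.0, 100.0), (1129.0, 8.0, 70.0)],
        noise_sd=1.0,
        seed=config.seed,
    )
    treated = synthetic_systems.synth_raman(
        [
            (1064.0 + shift, 8.0, 90.0),
            (1096.0 + shift, 6.0, 60.0),
            (1100.0 + shift, 6.0, 40.0),
            (1129.0 + shift, 8.0, 70.0),
        ],
        noise_sd=1.0,
        seed=config.seed + 1,
    )
    ref.to_csv(outdir / "raman_ref.csv")
    treated.to_csv(outdir / "raman_treated.csv")
    ref_c = vibrational_spectra.baseline_correct(ref, window=(1000.0, 1180.0))
    tr_c = vibrational_spectra.baseline_correct(treated, window=(1000.0, 1180.0))
    splitting = vibrational_spectra.detect_splitting(
        ref_c, tr_c, window=rm.doublet_window
    )
    shift_1064 = vibrational_spectra.mode_shift(ref_c, tr_c, 1064.0, half_window=12)
    series = synthetic_systems.synth_raman_series(
        onset_C=rm.onset_C, seed=config.seed
    )
    emergence = vibrational_spectra.band_emergence(series)
    return {
        "splitting": {k: v for k, v in splitting.items()},
        "mode_shift_1064_cm1": shift_1064,
        "band_emergence": {
            "transition_temperature_C": emergence.transition_temperature,
            "sigmoid_midpoint_C": emergence.sigmoid_midpoint,
        },
    }


def run_pipeline(config: PipelineConfig | dict | str | Path) -> dict:
    """Execute the configured stages; returns (and writes) the run report.

    Stage failures are recorded in the report and later stages still run
    (stages are independent); the report's ``ok`` flag is False if any
    stage failed.
    """
    if isinstance(config, (str, Path)):
        config = PipelineConfig.from_yaml(config)
    elif isinstance(config, dict):
        config = PipelineConfig.model_validate(config)
    problems = validate_config(config)
    if problems:
        raise ValueError("invalid config: " + "; ".join(problems))
    logging.basicConfig(level=getattr(logging, config.log_level.upper(), 20))
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    report: dict = {"seed": config.seed, "stages": {}, "ok": True}
    stages = [
        ("md", _md_stage, config.md),
        ("itc", _itc_stage, config.itc),
        ("gp", _gp_stage, config.gp),
        ("raman", _raman_stage, config.raman),
    ]
    for name, fn, block in stages:
        if block is None:
            continue
        logger.info("running stage %s", name)
        try:
            report["stages"][name] = fn(config, outdir)
        except Exception as exc:  # noqa: BLE001 - report and continue
            logger.error("stage %s failed: %s", name, exc)
            report["stages"][name] = {"error": str(exc)}
            report["ok"] = False
    with open(outdir / "report.json", "w") as fh:
        json.dump(report, fh, indent=2, sort_keys=True, default=_json_default)
        fh.write("\n")
    return report


def _json_default(obj):
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    raise TypeError(f"not JSON serializable: {type(obj)}")
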