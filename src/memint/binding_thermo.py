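"""ITC one-set-of-sites binding model and Laurdan generalized polarization.

The calorimetric experiment modelled here is a reverse titration: lipid
vesicles (titrant, in the syringe) are injected into a dilute polymer
solution (binding-site species, in the cell). Injection heats follow the
standard single-class independent-sites isotherm, with perfusion-cell
bookkeeping: every injection displaces an equal volume of well-mixed cell
contents, so cell species dilute by exp(-ΔV/V0) at cumulative injected
volume ΔV.

Fitted association constants convert to free energies on the
mole-fraction standard state,

    ΔG = -RT ln(55.5 Ka) = ΔH - TΔS,

with R = 1.986 cal/(mol·K) and 55.5 M the molar concentration of water.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.optimize import least_squares

from .constants import (
    LAURDAN_BLUE_NM,
    LAURDAN_RED_NM,
    R_GAS_CAL,
    T_PHYSIOLOGICAL,
    WATER_MOLARITY,
)
from .spectrum import Spectrum

__all__ = [
    "ITCIsotherm",
    "ThermoParams",
    "FitError",
    "one_site_heats",
    "fit_one_site",
    "derive_thermo",
    "enthalpy_entropy_to_dg",
    "saturation_fraction",
    "laurdan_gp",
]

#: MicroCal VP-ITC class cell volume, mL
DEFAULT_CELL_VOLUME_ML = 1.4285


class FitError(RuntimeError):
    """Nonlinear fit failed to converge or is degenerate."""


@dataclass
class ITCIsotherm:
    """Per-injection heats with the cell/syringe geometry that produced them.

    Concentrations are molar (mM); the cell species is the polymer
    (binding sites), the syringe titrant is lipid.
    """

    injection_volumes_uL: np.ndarray
    heats_ucal: np.ndarray
    cell_volume_mL: float = DEFAULT_CELL_VOLUME_ML
    cell_conc_mM: float = 1.0 / 30.0  # lipid:polymer 30:1 at 1 mM lipid
    syringe_conc_mM: float = 1.0
    temperature_K: float = T_PHYSIOLOGICAL
    buffer_control_ucal: np.ndarray | None = None
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.injection_volumes_uL = np.asarray(self.injection_volumes_uL, dtype=float)
        self.heats_ucal = np.asarray(self.heats_ucal, dtype=float)
        if self.injection_volumes_uL.shape != self.heats_ucal.shape:
            raise ValueError("injection volumes and heats must have equal length")
        if self.cell_volume_mL <= 0 or self.temperature_K <= 0:
            raise ValueError("cell volume and temperature must be positive")
        if self.buffer_control_ucal is not None:
            self.buffer_control_ucal = np.asarray(self.buffer_control_ucal, float)
            if self.buffer_control_ucal.shape != self.heats_ucal.shape:
                raise ValueError("buffer control length mismatch")

    @property
    def n_injections(self) -> int:
        return len(self.heats_ucal)

    def corrected_heats(self) -> np.ndarray:
        """Heats with the buffer (dilution) control subtracted, if provided."""
        if self.buffer_control_ucal is not None:
            return self.heats_ucal - self.buffer_control_ucal
        return self.heats_ucal

    def molar_ratio(self) -> np.ndarray:
        """Cumulative titrant : cell-species molar ratio per injection."""
        dv = np.cumsum(self.injection_volumes_uL) * 1e-3  # mL
        f = np.exp(-dv / self.cell_volume_mL)
        xt = self.syringe_conc_mM * (1.0 - f)
        mt = self.cell_conc_mM * f
        return xt / mt

    def to_csv(self, path: str | Path) -> None:
        pd.DataFrame(
            {
                "injection": np.arange(1, self.n_injections + 1),
                "volume_uL": self.injection_volumes_uL,
                "heat_ucal": self.heats_ucal,
            }
        ).to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path: str | Path, **geometry) -> "ITCIsotherm":
        df = pd.read_csv(path)
        return cls(
            injection_volumes_uL=df["volume_uL"].to_numpy(),
            heats_ucal=df["heat_ucal"].to_numpy(),
            **geometry,
        )


@dataclass
class ThermoParams:
    """One-site binding thermodynamics; ΔG/ΔS derive from Ka and ΔH."""

    n_sites: float
    Ka_per_M: float
    dH_kcal_per_mol: float
    dG_kcal_per_mol: float
    dS_cal_per_mol_K: float
    temperature_K: float = T_PHYSIOLOGICAL
    diagnostics: dict = field(default_factory=dict)

    @classmethod
    def from_fit(cls, n, Ka, dH, T, diagnostics=None) -> "ThermoParams":
        dG, dS = derive_thermo(Ka, dH, T)
        return cls(n, Ka, dH, dG, dS, T, diagnostics or {})


def derive_thermo(Ka_per_M: float, dH_kcal_per_mol: float, T_K: float):
    """ΔG (kcal/mol) and ΔS (cal/(mol·K)) from Ka and ΔH.

    ΔG = -RT ln(55.5 Ka); ΔS = (ΔH - ΔG)/T. Unit conversions are
    explicit: R is in cal/(mol·K), ΔG and ΔH in kcal/mol.
    """
    if Ka_per_M <= 0:
        raise ValueError(f"Ka must be positive, got {Ka_per_M}")
    dG_cal = -R_GAS_CAL * T_K * np.log(WATER_MOLARITY * Ka_per_M)
    dG = dG_cal / 1000.0
    dS = (dH_kcal_per_mol - dG) * 1000.0 / T_K
    return float(dG), float(dS)


def enthalpy_entropy_to_dg(
    dH_kcal_per_mol: float, dS_cal_per_mol_K: float, T_K: float = T_PHYSIOLOGICAL
) -> float:
    """ΔG = ΔH - TΔS in kcal/mol (ΔS given in cal/(mol·K))."""
    return float(dH_kcal_per_mol - T_K * dS_cal_per_mol_K / 1000.0)


def _bound_concentration(n, Ka, Mt, Xt):
    """Bound-titrant concentration from the one-site mass balance.

    Solves  B = n*Mt*Ka*(Xt-B)... i.e. the quadratic
    B^2 - B*(Xt + n*Mt + 1/Ka) + n*Mt*Xt = 0, taking the physical root
    (0 <= B <= min(Xt, n*Mt)).
    """
    s = Xt + n * Mt + 1.0 / Ka
    disc = s * s - 4.0 * n * Mt * Xt
    disc = np.maximum(disc, 0.0)  # exact math gives disc >= (1/Ka)^2 > 0
    return 0.5 * (s - np.sqrt(disc))


def one_site_heats(
    n_sites: float,
    Ka_per_M: float,
    dH_kcal_per_mol: float,
    injection_volumes_uL: np.ndarray,
    cell_volume_mL: float = DEFAULT_CELL_VOLUME_ML,
    cell_conc_mM: float = 1.0 / 30.0,
    syringe_conc_mM: float = 1.0,
) -> np.ndarray:
    """Forward model: per-injection heats (μcal) for one set of sites.

    Cell contents dilute continuously: after cumulative injected volume
    ΔV the cell species is M0·exp(-ΔV/V0) and the accumulated titrant is
    X0·(1-exp(-ΔV/V0)). The observed heat of injection i is the change in
    cell heat content plus the heat carried out with displaced liquid,

        q_i = Q_i - Q_{i-1} + (v_i/V0)·(Q_i + Q_{i-1})/2,

    with Q = ΔH·V0·[bound complex].
    """
    if Ka_per_M <= 0:
        raise ValueError("Ka must be positive")
    if cell_conc_mM <= 0 or syringe_conc_mM <= 0:
        raise ValueError("concentrations must be positive")
    v = np.asarray(injection_volumes_uL, dtype=float) * 1e-3  # mL
    V0 = cell_volume_mL
    dv = np.cumsum(v)
    f = np.exp(-dv / V0)
    Mt = cell_conc_mM * 1e-3 * f  # M
    Xt = syringe_conc_mM * 1e-3 * (1.0 - f)  # M
    B = _bound_concentration(n_sites, Ka_per_M, Mt, Xt)  # M
    # heat content of the cell, kcal -> ucal (1 kcal = 1e9 ucal)
    Q = dH_kcal_per_mol * (V0 * 1e-3) * B * 1e9
    Qprev = np.concatenate([[0.0], Q[:-1]])
    q = Q - Qprev + (v / V0) * (Q + Qprev) / 2.0
    return q


def fit_one_site(
    isotherm: ITCIsotherm,
    init: ThermoParams | None = None,
    exclude_first: bool = True,
    fit_offset: bool = False,
) -> ThermoParams:
    """Least-squares fit of (n, Ka, ΔH) to an injection-heat series.

    The buffer control, if attached to the isotherm, is subtracted before
    fitting. The first (priming) injection is excluded by default. Ka is
    optimized on a log scale with positivity enforced; ΔG and ΔS derive
    from the fitted Ka and ΔH.
    """
    heats = isotherm.corrected_heats()
    vols = isotherm.injection_volumes_uL
    mask = np.ones(len(heats), dtype=bool)
    if exclude_first and len(heats) > 1:
        mask[0] = False
    if mask.sum() < 5:
        raise FitError("need at least 5 informative injections")

    scale = np.max(np.abs(heats[mask]))
    if scale == 0:
        raise FitError("all heats are zero; nothing to fit")
    if np.std(heats[mask]) / scale < 1e-3:
        warnings.warn(
            "injection heats are essentially constant (pure dilution?); "
            "Ka is unidentifiable",
            stacklevel=2,
        )

    def forward(n, Ka, dH, offset):
        return (
            one_site_heats(
                n,
                Ka,
                dH,
                vols,
                isotherm.cell_volume_mL,
                isotherm.cell_conc_mM,
                isotherm.syringe_conc_mM,
            )
            + offset
        )

    # initial guesses: total heat fixes n*dH; inflection position fixes n
    if init is not None:
        x0 = [init.n_sites, np.log10(init.Ka_per_M), init.dH_kcal_per_mol]
    else:
        total = float(np.sum(heats[mask]))
        cell_moles = isotherm.cell_conc_mM * 1e-3 * isotherm.cell_volume_mL * 1e-3
        dh0 = total / 1e9 / max(cell_moles, 1e-30)  # assumes n ~ 1
        if dh0 == 0:
            dh0 = 1.0
        x0 = [1.0, 6.0, dh0]
    if fit_offset:
        x0 = list(x0) + [0.0]

    def residuals(x):
        n, logKa, dH = x[0], x[1], x[2]
        offset = x[3] if fit_offset else 0.0
        model = forward(n, 10.0**logKa, dH, offset)
        return (model[mask] - heats[mask]) / scale

    lower = [1e-6, -3.0, -np.inf] + ([-np.inf] if fit_offset else [])
    upper = [1e6, 15.0, np.inf] + ([np.inf] if fit_offset else [])
    result = least_squares(
        residuals, x0, bounds=(lower, upper), xtol=1e-15, ftol=1e-15, gtol=1e-15
    )
    if not result.success:
        raise FitError(f"one-site fit did not converge: {result.message}")
    n, logKa, dH = result.x[:3]
    Ka = float(10.0**logKa)
    resid_norm = float(np.linalg.norm(result.fun * scale))
    try:
        jtj = result.jac.T @ result.jac
        dof = max(len(result.fun) - len(result.x), 1)
        cov = np.linalg.inv(jtj) * 2 * result.cost / dof
    except np.linalg.LinAlgError:
        cov = None
    diagnostics = {
        "residual_norm_ucal": resid_norm,
        "covariance": cov,
        "n_injections_used": int(mask.sum()),
        "offset_ucal": float(result.x[3]) if fit_offset else 0.0,
    }
    params = ThermoParams.from_fit(
        float(n), Ka, float(dH), isotherm.temperature_K, diagnostics
    )
    params.diagnostics["saturation_fraction"] = saturation_fraction(params, isotherm)
    return params


def saturation_fraction(params: ThermoParams, isotherm: ITCIsotherm) -> float:
    """Fractional occupancy of binding sites after the final injection.

    Values below ~0.9 flag an incomplete titration (the interaction did
    not run to saturation within the injection schedule).
    """
    dv = np.sum(isotherm.injection_volumes_uL) * 1e-3
    f = np.exp(-dv / isotherm.cell_volume_mL)
    Mt = isotherm.cell_conc_mM * 1e-3 * f
    Xt = isotherm.syringe_conc_mM * 1e-3 * (1.0 - f)
    B = _bound_concentration(params.n_sites, params.Ka_per_M, Mt, Xt)
    return float(B / (params.n_sites * Mt))


def laurdan_gp(spectrum: Spectrum) -> float:
    """Generalized polarization GP = (I440 - I490)/(I440 + I490).

    Intensities are read off the emission spectrum by linear
    interpolation at 440 and 490 nm. GP lies in [-1, 1] for non-negative
    intensities; lower GP means a more hydrated, fluid bilayer.
    """
    if spectrum.axis_kind != "wavelength_nm":
        raise ValueError("Laurdan GP needs an emission spectrum in nm")
    i440 = spectrum.interp(LAURDAN_BLUE_NM)
    i490 = spectrum.interp(LAURDAN_RED_NM)
    if np.min(spectrum.intensity) < 0:
        warnings.warn(
            "spectrum has negative intensities (baseline problem?)", stacklevel=2
        )
    denom = i440 + i490
    if denom == 0:
        raise ValueError("I440 + I490 = 0; GP undefined")
    return float((i440 - i490) / denom)
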