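"""Shared spectrum container for fluorescence and Raman data.

A :class:`Spectrum` is a strictly-increasing axis (wavelength in nm or
wavenumber in cm⁻¹) with intensities in arbitrary units, round-trippable
through two-column CSV.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = ["Spectrum"]

_AXIS_KINDS = ("wavelength_nm", "wavenumber_cm1")


@dataclass
class Spectrum:
    axis: np.ndarray
    intensity: np.ndarray
    axis_kind: str = "wavenumber_cm1"
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.axis = np.asarray(self.axis, dtype=float)
        self.intensity = np.asarray(self.intensity, dtype=float)
        if self.axis.shape != self.intensity.shape or self.axis.ndim != 1:
            raise ValueError("axis and intensity must be equal-length 1-D arrays")
        if np.any(np.diff(self.axis) <= 0):
            raise ValueError("axis must be strictly increasing")
        if self.axis_kind not in _AXIS_KINDS:
            raise ValueError(f"axis_kind must be one of {_AXIS_KINDS}")

    def __len__(self) -> int:
        return len(self.axis)

    def interp(self, x: float) -> float:
        """Linearly interpolated intensity at axis value x."""
        lo, hi = self.axis[0], self.axis[-1]
        if not (lo <= x <= hi):
            raise ValueError(f"{x} outside spectrum range [{lo}, {hi}]")
        return float(np.interp(x, self.axis, self.intensity))

    def window(self, lo: float, hi: float) -> "Spectrum":
        """Sub-spectrum restricted to axis values in [lo, hi]."""
        mask = (self.axis >= lo) & (self.axis <= hi)
        if not np.any(mask):
            raise ValueError(f"window [{lo}, {hi}] contains no points")
        return Spectrum(
            self.axis[mask], self.intensity[mask], self.axis_kind, dict(self.metadata)
        )

    def to_csv(self, path: str | Path) -> None:
        col = "wavelength_nm" if self.axis_kind == "wavelength_nm" else "wavenumber_cm1"
        pd.DataFrame({col: self.axis, "intensity": self.intensity}).to_csv(
            path, index=False
        )

    @classmethod
    def from_csv(cls, path: str | Path) -> "Spectrum":
        df = pd.read_csv(path)
        if df.shape[1] < 2:
            raise ValueError(f"{path}: expected two columns (axis, intensity)")
        axis_col = df.columns[0]
        kind = (
            "wavelength_nm"
            if "wave" in axis_col and "length" in axis_col
            else ("wavelength_nm" if "nm" in axis_col else "wavenumber_cm1")
        )
        return cls(df.iloc[:, 0].to_numpy(), df.iloc[:, 1].to_numpy(), kind)
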