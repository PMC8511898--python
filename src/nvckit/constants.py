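"""Default optical constants for hemoglobin spectroscopy.

Extinction coefficients follow the standard compiled hemoglobin spectra
(Prahl compilation, cm^-1 M^-1); mean optical path lengths are Monte-Carlo
derived, literature-order values for green/blue illumination of cortex.
All values are user-overridable through :class:`OpticalConstants` or a YAML
config — hemoglobin outputs stay α-scaled (dimensionless) unless a constants
table is supplied, so absolute numbers here only matter when molar units are
requested.

530 nm is (near-)isosbestic: HbO2 and HbR absorb almost equally, so
single-wavelength reflectance there tracks total hemoglobin.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = ["WavelengthConstants", "OpticalConstants", "DEFAULT_CONSTANTS"]


@dataclass(frozen=True)
class WavelengthConstants:
    """Per-wavelength extinction coefficients and mean path length."""

    epsilon_hbo2: float  # cm^-1 M^-1
    epsilon_hbr: float   # cm^-1 M^-1
    path_length_cm: float


@dataclass
class OpticalConstants:
    """Table wavelength (nm) -> :class:`WavelengthConstants`."""

    table: dict[float, WavelengthConstants] = field(default_factory=dict)

    def __contains__(self, wavelength_nm: float) -> bool:
        return float(wavelength_nm) in self.table

    def __getitem__(self, wavelength_nm: float) -> WavelengthConstants:
        return self.table[float(wavelength_nm)]

    def alpha(self, wavelength_nm: float) -> float:
        """α(λ) = ½(ε_HbO2 + ε_HbR)·χ — the Beer-Lambert proportionality
        constant for total hemoglobin at an isosbestic wavelength."""
        c = self[wavelength_nm]
        return 0.5 * (c.epsilon_hbo2 + c.epsilon_hbr) * c.path_length_cm

    def unmix_matrix(self, wavelength_a: float, wavelength_b: float) -> np.ndarray:
        """2x2 system matrix mapping (ΔHbO2, ΔHbR) in M to −ln(R/R0) at the
        two wavelengths: rows are χ(λ)·[ε_HbO2(λ), ε_HbR(λ)]."""
        a, b = self[wavelength_a], self[wavelength_b]
        return np.array(
            [
                [a.path_length_cm * a.epsilon_hbo2, a.path_length_cm * a.epsilon_hbr],
                [b.path_length_cm * b.epsilon_hbo2, b.path_length_cm * b.epsilon_hbr],
            ]
        )


#: Default table: 530 nm (isosbestic green) and 460 nm (blue) channels.
DEFAULT_CONSTANTS = OpticalConstants(
    table={
        530.0: WavelengthConstants(epsilon_hbo2=39956.8, epsilon_hbr=39036.7,
                                   path_length_cm=0.057),
        460.0: WavelengthConstants(epsilon_hbo2=33209.2, epsilon_hbr=14550.0,
                                   path_length_cm=0.021),
    }
)
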