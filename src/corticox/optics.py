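"""Beer-Lambert transmittance of excitation light through a surface vessel.

A deliberately scattering-free estimate: with hemoglobin as the only
absorber, mu_a = ln(10) * C * (SaO2 * eps_HbO2 + (1 - SaO2) * eps_Hb) and
T = exp(-mu_a * L). Because scattering only lengthens photon paths, this is
an upper bound on transmission.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .errors import ParameterError

__all__ = [
    "ChromophoreSpectrum",
    "VesselOpticsParams",
    "absorption_coefficient",
    "transmittance",
    "vessel_transmittance",
]

# Molar extinction coefficients, M^-1 cm^-1, hemoglobin tetramer basis
# (64,500 g/mol), from the standard tabulated compendium of oxy-/deoxy-
# hemoglobin spectra (Prahl compilation of van Assendelft / Gratzer data),
# linearly interpolated from the bracketing table entries to the two laser
# lines used here. 445 nm sits on the steep red flank of the Soret band, so
# this entry is sensitive to the table's wavelength gridding; override via
# ChromophoreSpectrum.from_csv when a different compendium is preferred.
_BUNDLED_EXTINCTIONS: dict[float, tuple[float, float]] = {
    # wavelength_nm: (eps_hbo2, eps_hb)
    445.0: (82698.0, 258286.0),
    637.0: (546.0, 4659.0),
}

LN10 = math.log(10.0)


@dataclass
class ChromophoreSpectrum:
    """Hemoglobin extinction table: wavelength -> (eps_HbO2, eps_Hb)."""

    entries: dict[float, tuple[float, float]]

    def __post_init__(self) -> None:
        for wl, (e1, e2) in self.entries.items():
            if wl <= 0 or e1 <= 0 or e2 <= 0:
                raise ParameterError("wavelengths and extinctions must be positive")

    @classmethod
    def bundled(cls) -> "ChromophoreSpectrum":
        """The compendium values shipped with the package (445 and 637 nm)."""
        return cls(entries=dict(_BUNDLED_EXTINCTIONS))

    @classmethod
    def from_csv(cls, path: str | Path) -> "ChromophoreSpectrum":
        """Load an override table with columns wavelength_nm, eps_hbo2, eps_hb."""
        df = pd.read_csv(path)
        required = {"wavelength_nm", "eps_hbo2", "eps_hb"}
        if not required.issubset(df.columns):
            raise ParameterError(f"extinction CSV must have columns {sorted(required)}")
        entries = {
            float(r.wavelength_nm): (float(r.eps_hbo2), float(r.eps_hb))
            for r in df.itertuples()
        }
        if len(entries) != len(df):
            raise ParameterError("duplicate wavelengths in extinction CSV")
        return cls(entries=entries)

    def lookup(self, wavelength: float) -> tuple[float, float]:
        try:
            return self.entries[float(wavelength)]
        except KeyError:
            raise ParameterError(
                f"no extinction entry at {wavelength} nm (available: "
                f"{sorted(self.entries)}); interpolation is deliberately not done"
            ) from None


@dataclass
class VesselOpticsParams:
    """Absorber concentration, saturation and path length of the vessel model."""

    hb_concentration: float = 2.3e-3  # mol/L, whole-blood tetramer
    sao2: float = 0.95  # arterial O2 saturation fraction
    path_length: float = 100e-4  # cm (100 um)

    def __post_init__(self) -> None:
        if not (0.0 <= self.sao2 <= 1.0):
            raise ParameterError("sao2 must lie in [0, 1]")
        if self.hb_concentration < 0 or self.path_length < 0:
            raise ParameterError("concentration and path length must be non-negative")


def absorption_coefficient(
    spectrum: ChromophoreSpectrum, params: VesselOpticsParams, wavelength: float
) -> float:
    """Hemoglobin absorption coefficient mu_a (cm^-1) at one wavelength.

    mu_a = ln(10) * C * (SaO2 * eps_HbO2 + (1 - SaO2) * eps_Hb). The
    wavelength must be present in the spectrum; no silent interpolation.
    """
    eps_hbo2, eps_hb = spectrum.lookup(wavelength)
    eps_mix = params.sao2 * eps_hbo2 + (1.0 - params.sao2) * eps_hb
    return LN10 * params.hb_concentration * eps_mix


def transmittance(mu_a: float, path_length: float) -> float:
    """Beer-Lambert transmitted fraction T = exp(-mu_a * L)."""
    if mu_a < 0 or path_length < 0:
        raise ParameterError("mu_a and path_length must be non-negative")
    return math.exp(-mu_a * path_length)


def vessel_transmittance(
    wavelength: float,
    params: VesselOpticsParams | None = None,
    spectrum: ChromophoreSpectrum | None = None,
) -> float:
    """Transmitted fraction through the vessel model at one wavelength."""
    params = params or VesselOpticsParams()
    spectrum = spectrum or ChromophoreSpectrum.bundled()
    mu_a = absorption_coefficient(spectrum, params, wavelength)
    return transmittance(mu_a, params.path_length)
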