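"""SERS substrate quality metrics: enhancement factor and band-intensity
relative standard deviation (uniformity across replicate positions).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .exceptions import DomainError, InputError
from .io import SpectrumSet


@dataclass
class EFInputs:
    """Signal intensities (counts) and reporter concentrations (mol/L) of the
    enhanced (SERS) and unenhanced (normal Raman) measurements."""

    i_sers: float
    c_sers: float
    i_rs: float
    c_rs: float

    def __post_init__(self) -> None:
        for name in ("i_sers", "c_sers", "i_rs", "c_rs"):
            if getattr(self, name) <= 0:
                raise DomainError(f"{name} must be strictly positive")


def enhancement_factor(inputs: EFInputs) -> float:
    """EF = (I_SERS / C_SERS) / (I_RS / C_RS), the concentration-normalized
    intensity ratio of the substrate."""
    return (inputs.i_sers / inputs.c_sers) / (inputs.i_rs / inputs.c_rs)


def rsd(values: np.ndarray) -> float:
    """Relative standard deviation in percent: 100 * sample SD (n-1) / mean."""
    values = np.asarray(values, float)
    if values.size < 2:
        raise InputError("rsd needs at least 2 values")
    mean = values.mean()
    if mean == 0:
        raise DomainError("rsd undefined for zero mean")
    return float(100.0 * values.std(ddof=1) / mean)


def band_intensity(
    spectra: SpectrumSet, wavenumber: float, halfwidth: float = 5.0
) -> np.ndarray:
    """Per-spectrum peak intensity: the maximum within ``wavenumber`` +/-
    ``halfwidth`` cm^-1 (applied after preprocessing)."""
    mask = np.abs(spectra.axis - wavenumber) <= halfwidth
    if not mask.any():
        raise InputError(f"no axis points within {halfwidth} cm^-1 of {wavenumber}")
    return spectra.matrix[:, mask].max(axis=1)


def uniformity_rsd(
    spectra: SpectrumSet, wavenumber: float, halfwidth: float = 5.0
) -> float:
    """RSD (%) of the band intensity across replicate spectra."""
    return rsd(band_intensity(spectra, wavenumber, halfwidth))
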