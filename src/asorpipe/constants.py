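"""Physical constants and the ion valence registry."""

from __future__ import annotations

from .errors import UnknownIonError

GAS_CONSTANT = 8.31446261815324  # J mol^-1 K^-1
FARADAY = 96485.33212  # C mol^-1
ZERO_CELSIUS_K = 273.15

#: Integer valences of the ion species the package knows about.  Concentrations
#: everywhere are in mM; activities are taken equal to concentrations (the
#: equimolar-replacement designs this package targets make activity
#: coefficients cancel to first order).
ION_VALENCE: dict[str, int] = {
    "Na": 1,
    "K": 1,
    "Cs": 1,
    "Li": 1,
    "NMDG": 1,
    "H": 1,
    "Mg": 2,
    "Ca": 2,
    "Cl": -1,
    "Br": -1,
    "I": -1,
    "F": -1,
    "NO3": -1,
    "SCN": -1,
    "gluconate": -1,
    "HSO4": -1,
    "HCO3": -1,
    "OH": -1,
    "SO4": -2,
    "citrate": -3,
}


def ion_valence(ion: str) -> int:
    try:
        return ION_VALENCE[ion]
    except KeyError:
        raise UnknownIonError(
            f"unknown ion species {ion!r}; known: {sorted(ION_VALENCE)}"
        ) from None


def thermal_voltage_mv(temperature_c: float) -> float:
    """RT/F in millivolts at the given temperature (°C)."""
    return 1e3 * GAS_CONSTANT * (ZERO_CELSIUS_K + temperature_c) / FARADAY
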