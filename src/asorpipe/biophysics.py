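"""Constant-field (GHK) flux, Nernst potentials and proton-activation gating.

These primitives are shared between the channel simulator and the analysis
layer.  Currents are expressed per unit permeability in arbitrary units
(valence² × concentration scale); a conductance-scale factor converts them to
pA where needed.  Only zero-current voltages and current *ratios* are ever
interpreted quantitatively, so the absolute scale is immaterial.
"""

from __future__ import annotations

from typing import Mapping, Optional, Tuple

import numpy as np
from scipy.optimize import brentq

from .constants import ion_valence, thermal_voltage_mv
from .errors import NoRootError, SolutionError
from .solutions import SolutionSpec

__all__ = [
    "ghk_current",
    "total_ghk_current",
    "ghk_reversal",
    "nernst_potential",
    "nernst_potential_ph",
    "hill_activation",
    "gating_steady_state",
]


def ghk_current(v_mv, z: int, c_in: float, c_out: float, temperature_c: float = 20.0):
    """Constant-field current carried by one ion species, per unit permeability.

    Implements I ∝ z²·u·(c_in − c_out·e^(−u)) / (1 − e^(−u)) with
    u = zFV/RT; outward current is positive.  Vectorized over ``v_mv``.
    The removable singularity at V = 0 is replaced by its series limit
    (c_in − c_out) + u·(c_in + c_out)/2.
    """
    v = np.asarray(v_mv, dtype=float)
    u = z * v / thermal_voltage_mv(temperature_c)
    small = np.abs(u) < 1e-8
    u_safe = np.where(small, 1.0, u)
    g = np.where(
        small,
        (c_in - c_out) + 0.5 * u * (c_in + c_out),
        u_safe * (c_in - c_out * np.exp(-u_safe)) / (-np.expm1(-u_safe)),
    )
    out = z * g
    return out if out.ndim else float(out)


def total_ghk_current(
    v_mv,
    permeabilities: Mapping[str, float],
    pipette: SolutionSpec,
    bath: SolutionSpec,
    temperature_c: float = 20.0,
):
    """Sum of per-ion GHK currents weighted by relative permeability.

    ``pipette`` supplies intracellular, ``bath`` extracellular concentrations.
    Raises :class:`SolutionError` if no permeant ion is present anywhere.
    """
    total = np.zeros_like(np.asarray(v_mv, dtype=float))
    seen = 0.0
    for ion, perm in permeabilities.items():
        if perm < 0:
            raise SolutionError(f"negative permeability for {ion}")
        z = ion_valence(ion)
        c_in, c_out = pipette.conc(ion), bath.conc(ion)
        seen += perm * (c_in + c_out)
        total = total + perm * ghk_current(v_mv, z, c_in, c_out, temperature_c)
    if seen == 0:
        raise SolutionError("no permeant ion present in either solution")
    return total if total.ndim else float(total)


def ghk_reversal(
    permeabilities: Mapping[str, float],
    pipette: SolutionSpec,
    bath: SolutionSpec,
    temperature_c: float = 20.0,
    bracket_mv: Tuple[float, float] = (-200.0, 200.0),
) -> float:
    """Zero-current voltage (mV) of the summed GHK flux, by bracketed root search.

    The summed constant-field current is strictly increasing in V, so the root
    on the bracket is unique when it exists.
    """

    def f(v):
        return total_ghk_current(v, permeabilities, pipette, bath, temperature_c)

    lo, hi = bracket_mv
    flo, fhi = f(lo), f(hi)
    if flo == 0.0:
        return float(lo)
    if fhi == 0.0:
        return float(hi)
    if np.sign(flo) == np.sign(fhi):
        raise NoRootError(
            f"GHK current does not change sign on [{lo}, {hi}] mV "
            f"(I({lo})={flo:.3g}, I({hi})={fhi:.3g})"
        )
    return float(brentq(f, lo, hi, xtol=1e-10, rtol=1e-14))


def nernst_potential(
    z: int, activity_out: float, activity_in: float, temperature_c: float = 20.0
) -> float:
    """Equilibrium potential E = (RT/zF)·ln(out/in) in mV."""
    if activity_out <= 0 or activity_in <= 0:
        raise SolutionError("activities must be positive for a Nernst potential")
    if z == 0:
        raise SolutionError("Nernst potential undefined for a neutral species")
    return thermal_voltage_mv(temperature_c) / z * float(np.log(activity_out / activity_in))


def nernst_potential_ph(ph_out: float, ph_in: float, temperature_c: float = 20.0) -> float:
    """Proton equilibrium potential from extracellular and intracellular pH."""
    return nernst_potential(1, 10.0 ** (-ph_out), 10.0 ** (-ph_in), temperature_c)


def hill_activation(
    ph,
    ph50: float,
    n_h: float,
    inactivation: Optional[Tuple[float, float]] = None,
):
    """Proton-activation gate a(pH) = 1 / (1 + 10^(n_h·(pH − pH50))).

    Monotone decreasing in pH; equals 1/2 at pH = pH50.  With
    ``inactivation=(ph_i, n_i)`` the gate is multiplied by
    1 / (1 + 10^(n_i·(ph_i − pH))), producing the biphasic decline of
    current at very acidic pH.
    """
    ph = np.asarray(ph, dtype=float)
    a = 1.0 / (1.0 + 10.0 ** (n_h * (ph - ph50)))
    if inactivation is not None:
        ph_i, n_i = inactivation
        a = a / (1.0 + 10.0 ** (n_i * (ph_i - ph)))
    return a if a.ndim else float(a)


def gating_steady_state(v_mv, v_half_mv: float = 40.0, v_slope_mv: float = 25.0):
    """Boltzmann steady state of the depolarization-activated gate."""
    v = np.asarray(v_mv, dtype=float)
    r = 1.0 / (1.0 + np.exp(-(v - v_half_mv) / v_slope_mv))
    return r if r.ndim else float(r)
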