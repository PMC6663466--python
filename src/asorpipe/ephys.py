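"""Quantitative analysis of whole-cell recordings.

Covers: reversal-potential extraction from ramp I/V relations (zero-current
crossing with optional background subtraction and boxcar smoothing), liquid
junction potential correction, Nernst and multi-ion GHK reversal voltages,
bi-ionic permeability ratios, Hill fits of the proton-activation curve
(pH50), current densities and percent inhibition.

Conventions fixed here and exercised by the tests:

* LJP correction: ``corrected = measured - LJP`` (command potentials
  overestimate the membrane potential by the junction potential of the
  bath/pipette pair).
* Temperature defaults to 20 °C.
* Activities are taken equal to concentrations.
* Bi-ionic permeability ratios are computed for monovalent anions only; for
  divalents the reversal-potential shift is reported as-is.
"""

from __future__ import annotations

import dataclasses
import math
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy.optimize import least_squares

# Re-exported physics primitives (part of this module's public surface).
from .biophysics import (  # noqa: F401
    ghk_current,
    ghk_reversal,
    nernst_potential,
    nernst_potential_ph,
    total_ghk_current,
)
from .constants import ion_valence, thermal_voltage_mv
from .errors import DivalentIonError, InsufficientDataError
from .solutions import SolutionSpec  # noqa: F401  (convenience import)

__all__ = [
    "IVCurve",
    "ErevEstimate",
    "extract_erev",
    "correct_ljp",
    "permeability_ratio_biionic",
    "HillPHActivation",
    "HillFitResult",
    "fit_ph_activation",
    "current_density",
    "percent_inhibition",
    "current_ratio",
    "nernst_potential",
    "nernst_potential_ph",
    "ghk_reversal",
]


# --------------------------------------------------------------------------- I/V


@dataclasses.dataclass
class IVCurve:
    """Ramp-derived current-voltage relation on a monotone voltage grid."""

    voltage_mv: np.ndarray
    current_pa: np.ndarray
    capacitance_pf: Optional[float] = None

    def __post_init__(self) -> None:
        self.voltage_mv = np.asarray(self.voltage_mv, dtype=float)
        self.current_pa = np.asarray(self.current_pa, dtype=float)
        if self.voltage_mv.shape != self.current_pa.shape or self.voltage_mv.ndim != 1:
            raise ValueError("voltage and current must be equal-length 1-D arrays")
        dv = np.diff(self.voltage_mv)
        if not (np.all(dv > 0) or np.all(dv < 0)):
            raise ValueError("voltage grid must be strictly monotone")

    @classmethod
    def from_ramp_sweep(cls, sweep: pd.DataFrame, sweep_id: Optional[int] = None,
                        capacitance_pf: Optional[float] = None) -> "IVCurve":
        """Extract the ramp segment (longest strictly monotone voltage run)
        from a sweep table with columns time_s, voltage_mV, current_pA."""
        df = sweep
        if sweep_id is not None and "sweep" in df.columns:
            df = df[df["sweep"] == sweep_id]
        df = df.sort_values("time_s")
        v = df["voltage_mV"].to_numpy(dtype=float)
        i = df["current_pA"].to_numpy(dtype=float)
        rising = np.diff(v) > 0
        if not rising.any():
            raise ValueError("no rising voltage segment in sweep")
        # longest run of consecutive rising steps
        best_len, best_start, run_start = 0, 0, 0
        for k in range(len(rising) + 1):
            if k == len(rising) or not rising[k]:
                if k - run_start > best_len:
                    best_len, best_start = k - run_start, run_start
                run_start = k + 1
        sl = slice(best_start, best_start + best_len + 1)
        return cls(v[sl], i[sl], capacitance_pf=capacitance_pf)


@dataclasses.dataclass
class ErevEstimate:
    """Reversal potential: the voltage at which the current crosses zero."""

    erev_mv: float
    crossing_found: bool
    ljp_applied_mv: float = 0.0

    @property
    def erev_corrected_mv(self) -> float:
        return self.erev_mv - self.ljp_applied_mv

    def correct(self, ljp_mv: float) -> "ErevEstimate":
        return dataclasses.replace(self, ljp_applied_mv=ljp_mv)


def _boxcar(y: np.ndarray, n: int) -> np.ndarray:
    if n is None or n <= 1:
        return y
    kernel = np.ones(n)
    num = np.convolve(y, kernel, mode="same")
    den = np.convolve(np.ones_like(y), kernel, mode="same")
    return num / den


def extract_erev(
    iv: IVCurve,
    background: Optional[IVCurve] = None,
    smooth_pts: Optional[int] = 5,
    previous_mv: Optional[float] = None,
) -> ErevEstimate:
    """Zero-current voltage of an I/V relation by linear interpolation.

    The background curve (e.g. the pH 7.4 current of the same cell) is
    subtracted pointwise if given; a centered boxcar of ``smooth_pts`` samples
    (edge-truncated) smooths the current before crossing detection.  With
    several crossings the one nearest ``previous_mv`` (or 0 mV) is chosen.
    Returns ``crossing_found=False`` with NaN when the current never changes
    sign.
    """
    v = iv.voltage_mv
    i = iv.current_pa
    if background is not None:
        if background.voltage_mv.shape != v.shape or np.any(
            np.abs(background.voltage_mv - v) > 1e-6 * (1 + np.abs(v))
        ):
            raise ValueError("background curve must share the voltage grid")
        i = i - background.current_pa
    i = _boxcar(i, smooth_pts)

    crossings = []
    for k in range(len(v) - 1):
        a, b = i[k], i[k + 1]
        if a == 0.0:
            crossings.append(float(v[k]))
        elif a * b < 0:
            crossings.append(float(v[k] - a * (v[k + 1] - v[k]) / (b - a)))
    if i[-1] == 0.0:
        crossings.append(float(v[-1]))
    if not crossings:
        return ErevEstimate(erev_mv=math.nan, crossing_found=False)
    target = 0.0 if previous_mv is None else previous_mv
    erev = min(crossings, key=lambda c: abs(c - target))
    return ErevEstimate(erev_mv=erev, crossing_found=True)


def correct_ljp(erev_mv: float, ljp_mv: float) -> float:
    """Liquid-junction-potential correction: corrected = measured − LJP."""
    return erev_mv - ljp_mv


def permeability_ratio_biionic(
    delta_erev_mv: float,
    x_out_mm: float,
    cl_out_control_mm: float,
    temperature_c: float = 20.0,
    valence: int = -1,
) -> float:
    """P_X/P_Cl from the reversal-potential shift under anion substitution.

    ΔErev = Erev(X bath) − Erev(Cl bath), both LJP-corrected.  For a
    monovalent anion X replacing Cl as the dominant external anion,

        P_X / P_Cl = (cl_out / x_out) * exp(−F·ΔErev / (R·T)).

    Divalents raise :class:`DivalentIonError`: report ΔErev instead.
    """
    if valence != -1:
        raise DivalentIonError(
            "bi-ionic permeability ratio is defined for monovalent anions only; "
            "report the reversal-potential shift for divalents"
        )
    if x_out_mm <= 0 or cl_out_control_mm <= 0:
        raise ValueError("concentrations must be positive")
    vt = thermal_voltage_mv(temperature_c)
    return (cl_out_control_mm / x_out_mm) * math.exp(-delta_erev_mv / vt)


# ------------------------------------------------------------------- Hill fitting


@dataclasses.dataclass
class HillFitResult:
    """Fitted proton-activation curve I(pH) = I_max / (1 + 10^(n_h·(pH−pH50))).

    With the optional inactivation term the model is multiplied by
    1 / (1 + 10^(n_i·(pH_i − pH))).  ``bse`` holds asymptotic standard errors
    in the same order as ``params``; ``resid_norm`` is the residual 2-norm.
    """

    ph50: float
    n_h: float
    i_max: float
    ph_i: Optional[float]
    n_i: Optional[float]
    resid_norm: float
    converged: bool
    bse: Optional[np.ndarray] = None
    n_obs: int = 0

    @property
    def params(self) -> dict:
        out = {"i_max": self.i_max, "ph50": self.ph50, "n_h": self.n_h}
        if self.ph_i is not None:
            out.update({"ph_i": self.ph_i, "n_i": self.n_i})
        return out

    def predict(self, ph):
        ph = np.asarray(ph, dtype=float)
        y = self.i_max / (1.0 + 10.0 ** (self.n_h * (ph - self.ph50)))
        if self.ph_i is not None:
            y = y / (1.0 + 10.0 ** (self.n_i * (self.ph_i - ph)))
        return y if y.ndim else float(y)

    def summary(self) -> str:
        lines = [
            "Hill pH-activation fit",
            "-" * 40,
            f"observations: {self.n_obs}    converged: {self.converged}",
            f"residual norm: {self.resid_norm:.4g}",
        ]
        names = list(self.params)
        for k, name in enumerate(names):
            se = f" +/- {self.bse[k]:.3g}" if self.bse is not None else ""
            lines.append(f"  {name:>6s} = {self.params[name]:.4g}{se}")
        return "\n".join(lines)


class HillPHActivation:
    """Least-squares model of current vs extracellular pH at fixed voltage.

    The half-activation point pH50 is initialized from the interpolated
    half-maximum crossing, the Hill slope at 3 protons, and I_max at the
    largest-magnitude current; bounds are n_h ∈ [0.5, 10] and pH50 within the
    data range ± 1 pH unit.
    """

    def __init__(self, ph: Sequence[float], current: Sequence[float]):
        self.ph = np.asarray(ph, dtype=float)
        self.current = np.asarray(current, dtype=float)
        if self.ph.shape != self.current.shape or self.ph.ndim != 1:
            raise ValueError("ph and current must be equal-length 1-D arrays")

    @classmethod
    def from_dataframe(
        cls,
        df: pd.DataFrame,
        voltage_mv: float = 80.0,
        ph_col: str = "ph",
        current_col: str = "current_pA",
    ) -> "HillPHActivation":
        """Build from a per-cell current table, selecting one test voltage."""
        if "voltage_mV" in df.columns:
            df = df[np.isclose(df["voltage_mV"], voltage_mv)]
        return cls(df[ph_col].to_numpy(), df[current_col].to_numpy())

    def _initial_ph50(self) -> float:
        order = np.argsort(self.ph)
        ph, cur = self.ph[order], np.abs(self.current[order])
        # mean per distinct pH for a clean half-max crossing
        uph = np.unique(ph)
        mean = np.array([cur[ph == u].mean() for u in uph])
        half = mean.max() / 2.0
        above = mean >= half
        if above.all() or not above.any():
            return float(uph.mean())
        # walking toward alkaline pH, first point that has dropped below half-max
        k = int(np.argmax(~above))
        if k == 0:
            return float(uph[0])
        lo, hi = k - 1, k
        if mean[lo] == mean[hi]:
            return float(uph[lo])
        frac = (mean[lo] - half) / (mean[lo] - mean[hi])
        return float(uph[lo] + frac * (uph[hi] - uph[lo]))

    def fit(self, with_inactivation: bool = False) -> HillFitResult:
        ph, cur = self.ph, self.current
        n_distinct = np.unique(ph).size
        need = 6 if with_inactivation else 4
        if n_distinct < need:
            raise InsufficientDataError(
                f"need >= {need} distinct pH values, got {n_distinct}"
            )
        scale = np.abs(cur).max()
        if scale == 0 or np.ptp(cur) <= 1e-12 * max(scale, 1.0):
            # no transition to fit
            return HillFitResult(
                ph50=self._initial_ph50(), n_h=3.0,
                i_max=float(cur[np.argmax(np.abs(cur))]) if scale else 0.0,
                ph_i=None, n_i=None,
                resid_norm=float(np.linalg.norm(cur - cur.mean())),
                converged=False, n_obs=cur.size,
            )
        i0 = float(cur[np.argmax(np.abs(cur))])
        ph50_0 = float(np.clip(self._initial_ph50(), ph.min() - 1, ph.max() + 1))

        if with_inactivation:
            x0 = np.array([i0, ph50_0, 3.0, ph.min() - 0.5, 3.0])
            lb = [-10 * scale, ph.min() - 1, 0.5, ph.min() - 2, 0.5]
            ub = [10 * scale, ph.max() + 1, 10.0, ph.max() + 1, 10.0]

            def resid(p):
                i_max, ph50, n_h, ph_i, n_i = p
                y = i_max / (1 + 10 ** (n_h * (ph - ph50)))
                y = y / (1 + 10 ** (n_i * (ph_i - ph)))
                return y - cur
        else:
            x0 = np.array([i0, ph50_0, 3.0])
            lb = [-10 * scale, ph.min() - 1, 0.5]
            ub = [10 * scale, ph.max() + 1, 10.0]

            def resid(p):
                i_max, ph50, n_h = p
                return i_max / (1 + 10 ** (n_h * (ph - ph50))) - cur

        sol = least_squares(resid, x0, bounds=(lb, ub), xtol=1e-14, ftol=1e-14)
        converged = bool(sol.status > 0)
        # asymptotic covariance from the Jacobian
        bse = None
        dof = cur.size - sol.x.size
        if dof > 0:
            try:
                jtj_inv = np.linalg.pinv(sol.jac.T @ sol.jac)
                s2 = 2 * sol.cost / dof
                bse = np.sqrt(np.diag(s2 * jtj_inv))
            except np.linalg.LinAlgError:
                bse = None
        p = sol.x
        return HillFitResult(
            ph50=float(p[1]),
            n_h=float(p[2]),
            i_max=float(p[0]),
            ph_i=float(p[3]) if with_inactivation else None,
            n_i=float(p[4]) if with_inactivation else None,
            resid_norm=float(np.sqrt(2 * sol.cost)),
            converged=converged,
            bse=bse,
            n_obs=cur.size,
        )


def fit_ph_activation(
    ph: Sequence[float], currents: Sequence[float], with_inactivation: bool = False
) -> HillFitResult:
    """Functional wrapper over :class:`HillPHActivation`."""
    return HillPHActivation(ph, currents).fit(with_inactivation=with_inactivation)


# ------------------------------------------------------------------- scalar ops


def current_density(current_pa: float, capacitance_pf: float) -> float:
    """Current normalized to membrane capacitance (pA/pF)."""
    if capacitance_pf <= 0:
        raise ValueError("capacitance must be positive")
    return current_pa / capacitance_pf


def percent_inhibition(i_control: float, i_drug: float) -> float:
    """100·(1 − I_drug/I_control); negative values indicate potentiation."""
    if i_control == 0:
        raise ValueError("control current must be non-zero")
    return 100.0 * (1.0 - i_drug / i_control)


def current_ratio(i_after: float, i_control: float) -> float:
    """I_after / I_control, the read-out for cysteine-modification effects."""
    if i_control == 0:
        raise ValueError("control current must be non-zero")
    return i_after / i_control
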