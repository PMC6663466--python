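"""Model-based whole-cell recordings of an acid-activated anion channel.

The channel current is

    I(V, t, pH) = g_max * a(pH) * r(V, t) * sum_ions P_ion * GHK(V, c_in, c_out)

with a Hill proton-activation gate a(pH) (optionally biphasic, declining
again at very acidic pH), and a depolarization-activated gate r relaxing
first-order (time constant ~100 ms) toward a Boltzmann steady state, which
produces the channel's outward rectification.  The zero-current voltage of a
noise-free ramp therefore equals the GHK reversal voltage of the permeability
set — the property the reversal-potential analysis is tested against.
"""

from __future__ import annotations

import dataclasses
from typing import Dict, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from ..biophysics import gating_steady_state, hill_activation, total_ghk_current
from ..constants import ion_valence
from ..errors import SolutionError
from ..solutions import SolutionSpec

__all__ = ["ChannelModel", "simulate_iv_recording", "simulate_ph_series"]


@dataclasses.dataclass
class ChannelModel:
    """Biophysical parameters of the simulated channel.

    ``permeabilities`` are relative to Cl⁻ (P_Cl = 1 by convention);
    ``g_max`` sets the overall current scale (pA per unit GHK flux);
    ``ph50``/``n_h`` parameterize proton activation; ``inactivation``
    optionally adds the current decline below pH ~5 as (ph_i, n_i);
    ``gating_tau_ms`` and the Boltzmann (v_half, v_slope) describe the
    ~100 ms depolarization-dependent gating.
    """

    permeabilities: Dict[str, float] = dataclasses.field(
        default_factory=lambda: {"Cl": 1.0}
    )
    g_max: float = 10.0
    ph50: float = 5.3
    n_h: float = 3.0
    inactivation: Optional[Tuple[float, float]] = None
    gating_tau_ms: float = 100.0
    v_half_mv: float = 40.0
    v_slope_mv: float = 25.0

    def __post_init__(self) -> None:
        for ion, p in self.permeabilities.items():
            if p < 0:
                raise SolutionError(f"negative permeability for {ion}")
        if self.g_max <= 0 or self.n_h <= 0 or self.gating_tau_ms <= 0:
            raise ValueError("g_max, n_h and gating_tau_ms must be positive")

    def activation(self, ph):
        return hill_activation(ph, self.ph50, self.n_h, self.inactivation)

    def r_inf(self, v_mv):
        return gating_steady_state(v_mv, self.v_half_mv, self.v_slope_mv)


def _check_ions(
    channel: ChannelModel, pipette: SolutionSpec, bath: SolutionSpec
) -> None:
    for ion in channel.permeabilities:
        ion_valence(ion)  # unknown species fail before composition checks
        if ion not in pipette.composition and ion not in bath.composition:
            raise SolutionError(
                f"permeant ion {ion!r} present in neither pipette nor bath"
            )


def _ramp_protocol(dt_ms: float) -> Tuple[np.ndarray, np.ndarray]:
    """100 ms at -80 mV, then a 500 ms ramp from -80 to +80 mV."""
    t = np.arange(0.0, 600.0 + dt_ms / 2, dt_ms)
    v = np.where(t <= 100.0, -80.0, -80.0 + (t - 100.0) * 160.0 / 500.0)
    return t, v


def _step_protocol(dt_ms: float) -> Sequence[Tuple[np.ndarray, np.ndarray]]:
    """1 s steps from -80 to +80 mV in 20 mV increments, flanked by 0.5 s at -80."""
    sweeps = []
    for v_step in np.arange(-80.0, 80.0 + 1e-9, 20.0):
        t = np.arange(0.0, 2000.0 + dt_ms / 2, dt_ms)
        v = np.full_like(t, -80.0)
        v[(t > 500.0) & (t <= 1500.0)] = v_step
        sweeps.append((t, v))
    return sweeps


def _integrate_sweep(
    channel: ChannelModel,
    pipette: SolutionSpec,
    bath: SolutionSpec,
    t_ms: np.ndarray,
    v_mv: np.ndarray,
    temperature_c: float,
) -> np.ndarray:
    """Current along one sweep with first-order gating relaxation."""
    a = channel.activation(bath.ph)
    r_inf = channel.r_inf(v_mv)
    r = np.empty_like(r_inf)
    r[0] = r_inf[0]
    decay = np.exp(-np.diff(t_ms) / channel.gating_tau_ms)
    for i in range(1, t_ms.size):
        r[i] = r_inf[i] + (r[i - 1] - r_inf[i]) * decay[i - 1]
    flux = total_ghk_current(
        v_mv, channel.permeabilities, pipette, bath, temperature_c
    )
    return channel.g_max * a * r * flux


def simulate_iv_recording(
    channel: ChannelModel,
    pipette: SolutionSpec,
    bath: SolutionSpec,
    protocol: str = "ramp",
    temperature_c: float = 20.0,
    dt_ms: float = 0.5,
    noise_sd_pa: float = 0.0,
    seed: Optional[int] = None,
) -> pd.DataFrame:
    """Whole-cell sweep table (sweep, time_s, voltage_mV, current_pA).

    ``protocol`` is ``"ramp"`` (one sweep) or ``"steps"`` (one sweep per test
    voltage).  Optional Gaussian current noise with SD ``noise_sd_pa``.
    """
    _check_ions(channel, pipette, bath)
    rng = np.random.default_rng(seed)
    if protocol == "ramp":
        sweeps = [_ramp_protocol(dt_ms)]
    elif protocol == "steps":
        sweeps = list(_step_protocol(dt_ms))
    else:
        raise ValueError(f"unknown protocol {protocol!r}")
    parts = []
    for i, (t, v) in enumerate(sweeps, start=1):
        current = _integrate_sweep(channel, pipette, bath, t, v, temperature_c)
        if noise_sd_pa > 0:
            current = current + rng.normal(0.0, noise_sd_pa, size=current.size)
        parts.append(
            pd.DataFrame(
                {
                    "sweep": i,
                    "time_s": t / 1e3,
                    "voltage_mV": v,
                    "current_pA": current,
                }
            )
        )
    return pd.concat(parts, ignore_index=True)


def simulate_ph_series(
    channel: ChannelModel,
    pipette: SolutionSpec,
    bath_template: SolutionSpec,
    ph_list: Sequence[float],
    temperature_c: float = 20.0,
    noise_cv: float = 0.0,
    n_cells: int = 1,
    seed: Optional[int] = None,
) -> pd.DataFrame:
    """Per-cell steady-state currents at ±80 mV across extracellular pH values.

    Noise is multiplicative log-normal (mean one, coefficient of variation
    ``noise_cv``) drawn independently per cell × pH × voltage.  Columns:
    cell, ph, voltage_mV, current_pA.
    """
    if len(ph_list) == 0:
        raise ValueError("ph_list must be non-empty")
    _check_ions(channel, pipette, bath_template)
    rng = np.random.default_rng(seed)
    sigma = np.sqrt(np.log1p(noise_cv**2))
    rows = []
    for cell in range(1, n_cells + 1):
        for ph in ph_list:
            bath = bath_template.with_ph(ph)
            a = channel.activation(ph)
            for v in (80.0, -80.0):
                flux = total_ghk_current(
                    v, channel.permeabilities, pipette, bath, temperature_c
                )
                i = channel.g_max * a * channel.r_inf(v) * flux
                if noise_cv > 0:
                    i *= np.exp(rng.normal(-0.5 * sigma**2, sigma))
                rows.append(
                    {"cell": cell, "ph": float(ph), "voltage_mV": v, "current_pA": i}
                )
    return pd.DataFrame(rows)
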