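"""Synthetic fluorescence-quench screen generator.

Emulates a 384-well halide-influx assay: a halide-sensitive GFP reporter is
quenched by iodide entering through an acid- and depolarization-activated
anion channel.  Iodide entry follows a saturating exponential,

    [I](t) = i_ss * (1 - exp(-k * (t - t_add)))   for t >= t_add,

and fluorescence follows a Stern-Volmer-like hyperbola,

    F(t) = bg + (f0 - bg) / (1 + [I](t) / ki_app).

Gene knockdown scales the entry rate, k = k0 * (1 - effect).  Control wells
reproduce the assay's control conditions: omitting iodide leaves the trace
flat; omitting the depolarizing peptide or acidic pH leaves residual quench
(configurable rate factors); reporter-free mock wells report background
fluorescence and serve as the normalization background.

Nuisance structure: a multiplicative per-well optical gain (lognormal), an
additive per-plate offset, and fractional Gaussian read noise per sample.
Replicates share the gene->well layout and redraw all noise.
"""

from __future__ import annotations

import dataclasses
import math
from typing import Dict, Iterable, Mapping, Optional, Tuple

import numpy as np
import pandas as pd

from ..datasets import (
    CONTROL_TYPES,
    PLATE_SHAPES,
    PlateTraces,
    ScreenDataSet,
    well_names,
)
from ..errors import LayoutCapacityError
from ..traces import KineticTrace

__all__ = [
    "ScreenDesign",
    "QuenchModel",
    "GeneEffect",
    "generate_layout",
    "simulate_well_trace",
    "simulate_screen",
]

DEFAULT_CONTROLS: Dict[str, int] = {
    "no_fmrf": 4,
    "no_iodide": 4,
    "neutral_ph": 4,
    "untransfected_mock": 4,
}


@dataclasses.dataclass
class ScreenDesign:
    """Layout of a pooled-siRNA screen: genes, plates, controls, replicates.

    One candidate well carries one gene's pooled siRNAs; the assignment is
    identical across replicates (replicates are re-runs of the same plates).
    """

    n_genes: int
    sirnas_per_gene: int = 4
    wells_per_plate: int = 384
    n_replicates: int = 3
    controls_per_plate: Optional[Dict[str, int]] = None
    gene_ids: Optional[Tuple[str, ...]] = None
    seed: int = 0

    def __post_init__(self) -> None:
        if self.controls_per_plate is None:
            self.controls_per_plate = dict(DEFAULT_CONTROLS)
        unknown = set(self.controls_per_plate) - set(CONTROL_TYPES)
        if unknown:
            raise ValueError(f"unknown control types {sorted(unknown)}")
        if self.wells_per_plate not in PLATE_SHAPES:
            raise ValueError(
                f"unsupported plate size {self.wells_per_plate}; "
                f"supported: {sorted(PLATE_SHAPES)}"
            )
        if self.n_genes < 0 or self.n_replicates < 1:
            raise ValueError("n_genes >= 0 and n_replicates >= 1 required")
        if self.candidate_capacity <= 0:
            raise LayoutCapacityError("controls leave no candidate wells on a plate")
        if self.gene_ids is None:
            self.gene_ids = tuple(f"GENE{i}" for i in range(1, self.n_genes + 1))
        elif len(self.gene_ids) != self.n_genes:
            raise ValueError("gene_ids length must equal n_genes")

    @property
    def n_controls(self) -> int:
        return sum(self.controls_per_plate.values())

    @property
    def candidate_capacity(self) -> int:
        return self.wells_per_plate - self.n_controls

    @property
    def n_plates(self) -> int:
        return max(1, math.ceil(self.n_genes / self.candidate_capacity))


@dataclasses.dataclass
class QuenchModel:
    """Parameters of the quench law and the plate nuisance model.

    Units: fluorescence in a.u., times in s, iodide in mM, rates in 1/s.
    ``ki_app`` is the reporter's apparent iodide half-quench constant; its
    true value for the reporter is not established, so it is a configurable
    placeholder.  ``k0`` sets the wild-type quench rate; the default places
    the steep phase of the quench inside the 20-100 s slope-search window
    (most of the fluorescence loss within ~2 min of addition).
    """

    f0: float = 1000.0
    bg: float = 100.0
    k0: float = 0.010
    ki_app: float = 30.0
    i_ss: float = 100.0
    t_add: float = 10.0
    duration: float = 300.0
    dt: float = 1.0
    noise_cv: float = 0.02
    well_gain_sd: float = 0.08
    plate_shift_sd: float = 15.0
    no_fmrf_factor: float = 0.25
    neutral_ph_factor: float = 0.1

    def __post_init__(self) -> None:
        if not (self.f0 > self.bg >= 0):
            raise ValueError("need f0 > bg >= 0")
        for name in ("k0", "ki_app", "i_ss", "dt", "duration"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        for name in ("noise_cv", "well_gain_sd", "plate_shift_sd"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")
        if not (0 <= self.t_add < self.duration):
            raise ValueError("t_add must lie inside the recording")
        for name in ("no_fmrf_factor", "neutral_ph_factor"):
            if not (0 <= getattr(self, name) < 1):
                raise ValueError(f"{name} must be in [0, 1)")

    @property
    def time_s(self) -> np.ndarray:
        n = int(round(self.duration / self.dt)) + 1
        return np.arange(n) * self.dt

    def clean_trace(self, k: np.ndarray) -> np.ndarray:
        """Noise-free fluorescence for quench rate(s) ``k`` (vectorized)."""
        t = self.time_s
        k = np.atleast_1d(np.asarray(k, dtype=float))
        dt_post = np.clip(t[None, :] - self.t_add, 0.0, None)
        iodide = self.i_ss * (-np.expm1(-k[:, None] * dt_post))
        return self.bg + (self.f0 - self.bg) / (1.0 + iodide / self.ki_app)


@dataclasses.dataclass
class GeneEffect:
    """Knockdown effect of one gene's siRNA pool.

    ``effect`` is the fraction in [0, 1] by which the channel-dependent quench
    rate is reduced (k = k0 * (1 - effect)); ``off_target_sd`` adds a pool-
    specific Gaussian perturbation, fixed across replicates.
    """

    gene_id: str
    effect: float
    off_target_sd: float = 0.0

    def __post_init__(self) -> None:
        if not (0.0 <= self.effect <= 1.0):
            raise ValueError("effect must be in [0, 1]")
        if self.off_target_sd < 0:
            raise ValueError("off_target_sd must be non-negative")


def generate_layout(design: ScreenDesign) -> pd.DataFrame:
    """Assign genes and controls to wells; identical across replicates.

    Returns the long layout frame (replicate, plate, well, well_type,
    gene_id).  Deterministic for a given ``design.seed``: control positions
    are drawn per plate and the gene order is a seeded permutation.
    """
    rng = np.random.default_rng(design.seed)
    rows, cols = PLATE_SHAPES[design.wells_per_plate]
    names = well_names(rows, cols)
    order = rng.permutation(design.n_genes)
    genes = [design.gene_ids[i] for i in order]
    capacity = design.candidate_capacity * design.n_plates
    if design.n_genes > capacity:
        raise LayoutCapacityError(
            f"{design.n_genes} genes exceed {capacity} candidate wells"
        )
    frames = []
    cursor = 0
    for p in range(design.n_plates):
        plate = f"P{p + 1:02d}"
        ctrl_positions = rng.choice(
            design.wells_per_plate, size=design.n_controls, replace=False
        )
        well_type = np.array(["candidate"] * design.wells_per_plate, dtype=object)
        pos = 0
        for ctype in sorted(design.controls_per_plate):
            cnt = design.controls_per_plate[ctype]
            well_type[ctrl_positions[pos : pos + cnt]] = ctype
            pos += cnt
        gene_col = np.array([None] * design.wells_per_plate, dtype=object)
        for w in range(design.wells_per_plate):
            if well_type[w] == "candidate":
                if cursor < design.n_genes:
                    gene_col[w] = genes[cursor]
                    cursor += 1
                else:
                    well_type[w] = "empty"
        frames.append(
            pd.DataFrame(
                {
                    "plate": plate,
                    "well": names,
                    "well_type": well_type,
                    "gene_id": gene_col,
                }
            )
        )
    one = pd.concat(frames, ignore_index=True)
    reps = []
    for rep in range(1, design.n_replicates + 1):
        df = one.copy()
        df.insert(0, "replicate", rep)
        reps.append(df)
    return pd.concat(reps, ignore_index=True)


def _condition_rates(
    model: QuenchModel, well_type: np.ndarray, effect: np.ndarray
) -> np.ndarray:
    """Quench rate per well given its condition and knockdown effect."""
    k = model.k0 * (1.0 - effect)
    k = np.where(well_type == "no_fmrf", model.k0 * model.no_fmrf_factor, k)
    k = np.where(well_type == "neutral_ph", model.k0 * model.neutral_ph_factor, k)
    # no_iodide / mock / empty handled as overrides of the clean trace
    return k


def simulate_well_trace(
    model: QuenchModel,
    effect: float = 0.0,
    condition: str = "candidate",
    rng: Optional[np.random.Generator] = None,
) -> KineticTrace:
    """One well's trace under the given condition and knockdown effect.

    ``condition`` is ``candidate`` or one of the control types.  Without an
    ``rng`` the trace is noise-free (gain 1, no offset).
    """
    if not (0.0 <= effect <= 1.0):
        raise ValueError("effect must be in [0, 1]")
    wt = np.array([condition], dtype=object)
    k = _condition_rates(model, wt, np.array([effect]))
    f = model.clean_trace(k)[0]
    if condition == "no_iodide":
        f = np.full_like(f, model.f0)
    elif condition == "untransfected_mock":
        f = np.full_like(f, model.bg)
    if rng is not None:
        gain = np.exp(rng.normal(0.0, model.well_gain_sd))
        f = gain * f * (1.0 + model.noise_cv * rng.standard_normal(f.size))
        f = np.clip(f, 0.0, None)
    return KineticTrace(
        time_s=model.time_s,
        fluorescence=f,
        addition_time_s=model.t_add,
        condition=condition,
    )


def simulate_screen(
    design: ScreenDesign,
    model: Optional[QuenchModel] = None,
    effects: Optional[Iterable[GeneEffect] | Mapping[str, float]] = None,
    seed: Optional[int] = None,
) -> Tuple[ScreenDataSet, dict]:
    """Simulate the full screen: all plates, replicates and noise sources.

    Returns the data set and a ground-truth dictionary (design, model,
    per-gene effects, seed) suitable for a JSON sidecar.  Reproducible for a
    fixed seed; replicates share the layout and redraw gains, plate offsets
    and read noise.
    """
    model = model or QuenchModel()
    seed = design.seed if seed is None else seed
    if effects is None:
        effect_list: list[GeneEffect] = []
    elif isinstance(effects, Mapping):
        effect_list = [GeneEffect(g, e) for g, e in effects.items()]
    else:
        effect_list = list(effects)
    known = set(design.gene_ids)
    for ge in effect_list:
        if ge.gene_id not in known:
            raise LayoutCapacityError(f"planted gene {ge.gene_id!r} not in the library")

    layout = generate_layout(design)
    rng = np.random.default_rng(seed)

    base_effect = {ge.gene_id: ge.effect for ge in effect_list}
    pool_sd = {ge.gene_id: ge.off_target_sd for ge in effect_list}
    # pool-specific off-target perturbation, fixed across replicates
    gene_effect = {}
    for gid in design.gene_ids:
        e = base_effect.get(gid, 0.0)
        sd = pool_sd.get(gid, 0.0)
        if sd > 0:
            e = float(np.clip(e + rng.normal(0.0, sd), 0.0, 1.0))
        gene_effect[gid] = e

    plates: Dict[Tuple[int, str], PlateTraces] = {}
    t = model.time_s
    for rep in range(1, design.n_replicates + 1):
        rep_layout = layout[layout["replicate"] == rep]
        for plate, lay in rep_layout.groupby("plate", sort=True):
            wt = lay["well_type"].to_numpy()
            gid = lay["gene_id"].to_numpy()
            eff = np.array(
                [gene_effect.get(g, 0.0) if g is not None else 0.0 for g in gid]
            )
            k = _condition_rates(model, wt, eff)
            f = model.clean_trace(k)
            f[wt == "no_iodide"] = model.f0
            f[(wt == "untransfected_mock") | (wt == "empty")] = model.bg
            gain = np.exp(rng.normal(0.0, model.well_gain_sd, size=(len(lay), 1)))
            shift = rng.normal(0.0, model.plate_shift_sd)
            noise = 1.0 + model.noise_cv * rng.standard_normal(f.shape)
            f = np.clip(gain * f * noise + shift, 0.0, None)
            plates[(rep, str(plate))] = PlateTraces(
                time_s=t,
                fluorescence=f,
                wells=lay[["well", "well_type", "gene_id"]].reset_index(drop=True),
                addition_time_s=model.t_add,
            )

    truth = {
        "seed": int(seed),
        "design": {
            k: (dict(v) if isinstance(v, dict) else v)
            for k, v in dataclasses.asdict(design).items()
            if k != "gene_ids"
        },
        "model": dataclasses.asdict(model),
        "effects": {g: e for g, e in gene_effect.items() if e != 0.0},
    }
    return ScreenDataSet(plates), truth
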