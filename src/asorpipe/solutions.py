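"""Ionic solutions for whole-cell recordings.

A :class:`SolutionSpec` couples an ionic composition (mM) with a pH and,
optionally, the liquid junction potential (LJP) measured for that bath against
the reference pipette solution.  The shipped recipe file
(``data/solutions.yaml``) contains the standard pipette and bath solutions used
for acid-activated chloride current recordings, with free-ion totals already
summed over the salts (e.g. the CsCl pipette carries 160 mM Cl⁻: 150 from CsCl
plus 10 from 5 mM MgCl₂).
"""

from __future__ import annotations

import dataclasses
from importlib import resources
from typing import Mapping, Optional

import yaml

from .constants import ion_valence
from .errors import SolutionError


@dataclasses.dataclass(frozen=True)
class SolutionSpec:
    """Ionic composition and pH of a pipette or bath solution.

    Parameters
    ----------
    name : str
        Identifier used in outputs and LJP tables.
    composition : mapping
        Free ion concentrations in mM, keyed by species name.  Every species
        must be in the valence registry.
    ph : float
        Solution pH, in (0, 14).
    temperature_c : float, default 20
        Recording temperature in °C.
    measured_ljp_mv : float, optional
        Experimentally measured liquid junction potential of this bath against
        the reference pipette, in mV.
    """

    name: str
    composition: Mapping[str, float]
    ph: float
    temperature_c: float = 20.0
    measured_ljp_mv: Optional[float] = None

    def __post_init__(self) -> None:
        for ion, conc in self.composition.items():
            ion_valence(ion)  # raises UnknownIonError
            if conc < 0:
                raise SolutionError(f"negative concentration for {ion}: {conc} mM")
        if not (0.0 < self.ph < 14.0):
            raise SolutionError(f"pH {self.ph} outside (0, 14)")
        object.__setattr__(self, "composition", dict(self.composition))

    def conc(self, ion: str) -> float:
        """Concentration of ``ion`` in mM (0 if absent)."""
        return float(self.composition.get(ion, 0.0))

    def with_ph(self, ph: float) -> "SolutionSpec":
        """Copy of this solution at a different pH (buffer swap assumed)."""
        return dataclasses.replace(self, ph=ph, name=f"{self.name}@pH{ph:g}")


def load_recipes() -> dict[str, SolutionSpec]:
    """Load the shipped solution recipes keyed by their conventional names."""
    text = resources.files("asorpipe").joinpath("data/solutions.yaml").read_text()
    raw = yaml.safe_load(text)
    out = {}
    for name, spec in raw.items():
        out[name] = SolutionSpec(
            name=name,
            composition=spec["composition"],
            ph=float(spec["ph"]),
            measured_ljp_mv=spec.get("measured_ljp_mv"),
        )
    return out
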