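"""In-memory containers for screen plates.

A :class:`PlateTraces` holds one plate's wells as a (wells × time) fluorescence
matrix plus a layout frame; a :class:`ScreenDataSet` collects plates across
replicates.  The analysis layer works on the matrices directly (vectorized);
the CSV round trip uses the long formats

    traces: replicate,plate,well,time_s,fluorescence
    layout: replicate,plate,well,well_type,gene_id
"""

from __future__ import annotations

import dataclasses
from typing import Dict, Iterator, Optional, Tuple

import numpy as np
import pandas as pd

from .errors import MismatchError, TableFormatError
from .traces import KineticTrace

TRACE_COLUMNS = ["replicate", "plate", "well", "time_s", "fluorescence"]
LAYOUT_COLUMNS = ["replicate", "plate", "well", "well_type", "gene_id"]

#: Well categories.  ``candidate`` wells carry library siRNA pools and enter
#: the plate statistics; the four control types mirror the assay's control
#: conditions; ``untransfected_mock`` wells carry no reporter and provide the
#: background fluorescence; ``empty`` wells are unused positions.
WELL_TYPES = (
    "candidate",
    "no_fmrf",
    "no_iodide",
    "neutral_ph",
    "untransfected_mock",
    "empty",
)

CONTROL_TYPES = ("no_fmrf", "no_iodide", "neutral_ph", "untransfected_mock")


@dataclasses.dataclass
class PlateTraces:
    """One plate: shared time grid, fluorescence matrix, per-well layout."""

    time_s: np.ndarray
    fluorescence: np.ndarray  # shape (n_wells, n_times)
    wells: pd.DataFrame  # columns: well, well_type, gene_id
    addition_time_s: float = 10.0

    def __post_init__(self) -> None:
        self.time_s = np.asarray(self.time_s, dtype=float)
        self.fluorescence = np.asarray(self.fluorescence, dtype=float)
        if self.fluorescence.shape != (len(self.wells), self.time_s.size):
            raise MismatchError(
                f"fluorescence matrix {self.fluorescence.shape} does not match "
                f"{len(self.wells)} wells x {self.time_s.size} samples"
            )

    def trace(self, well: str) -> KineticTrace:
        rows = np.flatnonzero(self.wells["well"].to_numpy() == well)
        if rows.size != 1:
            raise MismatchError(f"well {well!r} not present exactly once")
        row = int(rows[0])
        return KineticTrace(
            time_s=self.time_s,
            fluorescence=self.fluorescence[row],
            addition_time_s=self.addition_time_s,
            well=well,
            condition=str(self.wells["well_type"].iloc[row]),
        )


class ScreenDataSet:
    """Plates of kinetic traces keyed by (replicate, plate id)."""

    def __init__(self, plates: Dict[Tuple[int, str], PlateTraces]):
        self.plates = dict(plates)

    def __len__(self) -> int:
        return len(self.plates)

    @property
    def replicates(self) -> list[int]:
        return sorted({rep for rep, _ in self.plates})

    def iter_plates(self) -> Iterator[Tuple[int, str, PlateTraces]]:
        for (rep, plate) in sorted(self.plates):
            yield rep, plate, self.plates[(rep, plate)]

    # ---- long-format interchange -------------------------------------------------

    def trace_frame(self) -> pd.DataFrame:
        parts = []
        for rep, plate, pt in self.iter_plates():
            n_w, n_t = pt.fluorescence.shape
            parts.append(
                pd.DataFrame(
                    {
                        "replicate": rep,
                        "plate": plate,
                        "well": np.repeat(pt.wells["well"].to_numpy(), n_t),
                        "time_s": np.tile(pt.time_s, n_w),
                        "fluorescence": pt.fluorescence.ravel(),
                    }
                )
            )
        if not parts:
            return pd.DataFrame(columns=TRACE_COLUMNS)
        return pd.concat(parts, ignore_index=True)

    def layout_frame(self) -> pd.DataFrame:
        parts = []
        for rep, plate, pt in self.iter_plates():
            df = pt.wells[["well", "well_type", "gene_id"]].copy()
            df.insert(0, "plate", plate)
            df.insert(0, "replicate", rep)
            parts.append(df)
        if not parts:
            return pd.DataFrame(columns=LAYOUT_COLUMNS)
        return pd.concat(parts, ignore_index=True)

    def to_csv(self, traces_path, layout_path) -> None:
        self.trace_frame().to_csv(traces_path, index=False, float_format="%.4f")
        self.layout_frame().to_csv(layout_path, index=False)

    @classmethod
    def from_frames(
        cls,
        traces: pd.DataFrame,
        layout: pd.DataFrame,
        addition_time_s: float = 10.0,
    ) -> "ScreenDataSet":
        missing = [c for c in TRACE_COLUMNS if c not in traces.columns]
        if missing:
            raise TableFormatError(f"trace table is missing columns {missing}")
        missing = [c for c in LAYOUT_COLUMNS if c not in layout.columns]
        if missing:
            raise TableFormatError(f"layout table is missing columns {missing}")
        plates: Dict[Tuple[int, str], PlateTraces] = {}
        layout_groups = {
            (int(key[0]), str(key[1])): df
            for key, df in layout.groupby(["replicate", "plate"], sort=True)
        }
        for key, df in traces.groupby(["replicate", "plate"], sort=True):
            rep, plate = int(key[0]), str(key[1])
            lay = layout_groups.get((rep, plate))
            if lay is None:
                raise MismatchError(f"no layout for replicate {rep} plate {plate}")
            dup = df.duplicated(subset=["well", "time_s"])
            if dup.any():
                first = df.index[dup][0]
                raise TableFormatError(
                    f"duplicate (well, time) sample at input row {first} "
                    f"(replicate {rep}, plate {plate})"
                )
            pivot = df.pivot_table(
                index="well", columns="time_s", values="fluorescence", sort=True
            )
            lay = lay.set_index("well")
            missing_wells = set(pivot.index) - set(lay.index)
            if missing_wells:
                raise MismatchError(
                    f"wells {sorted(missing_wells)} in traces but not in layout "
                    f"(replicate {rep}, plate {plate})"
                )
            order = [w for w in lay.index if w in set(pivot.index)]
            mat = pivot.loc[order].to_numpy()
            if np.isnan(mat).any():
                raise TableFormatError(
                    f"ragged time grid on replicate {rep} plate {plate}"
                )
            wells = pd.DataFrame(
                {
                    "well": order,
                    "well_type": lay.loc[order, "well_type"].to_numpy(),
                    "gene_id": lay.loc[order, "gene_id"].to_numpy(),
                }
            )
            plates[(rep, plate)] = PlateTraces(
                time_s=pivot.columns.to_numpy(dtype=float),
                fluorescence=mat,
                wells=wells,
                addition_time_s=addition_time_s,
            )
        return cls(plates)

    @classmethod
    def from_csv(
        cls, traces_path, layout_path, addition_time_s: float = 10.0
    ) -> "ScreenDataSet":
        traces = pd.read_csv(traces_path)
        layout = pd.read_csv(layout_path)
        return cls.from_frames(traces, layout, addition_time_s=addition_time_s)


def well_names(n_rows: int, n_cols: int) -> list[str]:
    """Row-letter + column-number well addresses (A1 ... P24 for 384)."""
    letters = [chr(ord("A") + i) for i in range(n_rows)]
    return [f"{r}{c}" for r in letters for c in range(1, n_cols + 1)]


PLATE_SHAPES = {96: (8, 12), 384: (16, 24), 1536: (32, 48)}
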