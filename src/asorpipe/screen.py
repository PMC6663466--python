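"""Plate-wise robust standardization, replicate aggregation and hit ranking.

The per-well statistic xi (the normalized maximal quench slope, negative for
quenching wells) is standardized within each plate as

    Z_i = (x_i - median(x)) / MAD(x)

over the plate's *candidate* wells only, with the raw (unscaled) median
absolute deviation.  A second Z-score computed from the pre-addition baseline
fluorescence proxies cell number; genes whose median baseline Z falls below a
threshold (default -0.5) are removed before ranking.  The median of the
replicate Z-scores ranks the surviving genes.

Sign chain for the default ``loss_of_signal`` direction: knockdown of a
channel required for quenching moves the (negative) slope toward zero, i.e.
*raises* xi above the plate median, so hits carry large positive Z and rank 1
is the gene with the largest median Z.
"""

from __future__ import annotations

import dataclasses
import warnings
from typing import Dict, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy.stats import median_abs_deviation

from .datasets import CONTROL_TYPES, ScreenDataSet
from .errors import DegenerateDispersionError, MismatchError
from .traces import sliding_window_slopes

__all__ = [
    "robust_plate_z",
    "baseline_viability_z",
    "aggregate_and_rank",
    "run_screen_analysis",
    "ScreenAnalysis",
    "ScreenResults",
]

MAD_CONSISTENCY = 1.4826022185056018  # 1/Phi^-1(3/4), used only when scaled=True


def robust_plate_z(values, scaled: bool = False) -> np.ndarray:
    """Plate-wise robust Z-scores (x - median) / MAD for candidate wells.

    ``values`` are one plate's candidate-well statistics.  The MAD is the bare
    median absolute deviation; ``scaled=True`` applies the Gaussian
    consistency factor 1.4826.  NaN entries (invalid wells) are excluded from
    the location/dispersion estimates and propagate as NaN Z-scores.
    Raises :class:`DegenerateDispersionError` when the MAD is zero.
    """
    x = np.asarray(values, dtype=float)
    finite = x[np.isfinite(x)]
    if finite.size < 2:
        raise DegenerateDispersionError(
            f"need at least 2 valid candidate wells, got {finite.size}"
        )
    center = float(np.median(finite))
    mad = float(median_abs_deviation(finite, scale=1.0))
    if mad == 0.0:
        raise DegenerateDispersionError("plate MAD is zero; Z-scores undefined")
    if scaled:
        mad *= MAD_CONSISTENCY
    return (x - center) / mad


def baseline_viability_z(baseline_means, scaled: bool = False) -> np.ndarray:
    """Robust Z of per-well baseline fluorescence (cell-number proxy).

    Identical contract to :func:`robust_plate_z`, applied to the pre-addition
    baseline means of one plate's candidate wells.
    """
    return robust_plate_z(baseline_means, scaled=scaled)


def aggregate_and_rank(
    scores: pd.DataFrame,
    viability_threshold: float = -0.5,
    min_replicates: int = 2,
    direction: str = "loss_of_signal",
) -> pd.DataFrame:
    """Median replicate Z per gene, viability filter, and hit ranking.

    Parameters
    ----------
    scores : DataFrame
        Long per-replicate table with columns ``gene_id``, ``replicate``,
        ``z`` and ``baseline_z`` (NaN where a well was invalid).
    viability_threshold : float
        Genes with median baseline Z strictly below this are excluded.
    min_replicates : int
        Minimum number of valid (finite) replicate Z-scores required.
    direction : {"loss_of_signal", "gain_of_signal"}
        ``loss_of_signal`` ranks descending in median Z (reduced quenching on
        top); ``gain_of_signal`` ranks ascending.

    Returns a gene table with per-replicate Z columns, medians, the viability
    flag and 1-based ranks (ranks form a permutation of 1..n_viable; ties are
    broken by lexicographic gene_id).
    """
    if len(scores) == 0:
        raise ValueError("empty score table")
    if direction not in ("loss_of_signal", "gain_of_signal"):
        raise ValueError(f"unknown direction {direction!r}")
    required = {"gene_id", "replicate", "z", "baseline_z"}
    missing = required - set(scores.columns)
    if missing:
        raise ValueError(f"score table is missing columns {sorted(missing)}")

    wide_z = scores.pivot_table(
        index="gene_id", columns="replicate", values="z", aggfunc="first", dropna=False
    )
    wide_b = scores.pivot_table(
        index="gene_id", columns="replicate", values="baseline_z",
        aggfunc="first", dropna=False,
    )
    reps = list(wide_z.columns)
    table = pd.DataFrame(index=wide_z.index)
    for rep in reps:
        table[f"z_rep{rep}"] = wide_z[rep]
        table[f"baseline_z_rep{rep}"] = wide_b[rep]
    table["n_valid"] = np.isfinite(wide_z.to_numpy()).sum(axis=1)
    with warnings.catch_warnings():
        warnings.filterwarnings("ignore", "All-NaN slice", RuntimeWarning)
        table["median_z"] = np.nanmedian(wide_z.to_numpy(), axis=1)
        table["median_baseline_z"] = np.nanmedian(wide_b.to_numpy(), axis=1)
    table["viable"] = (
        (table["n_valid"] >= min_replicates)
        & ~(table["median_baseline_z"] < viability_threshold)
    )

    table = table.reset_index()
    ascending = direction == "gain_of_signal"
    ranked = table[table["viable"]].sort_values(
        ["median_z", "gene_id"], ascending=[ascending, True], kind="mergesort"
    )
    table["rank"] = pd.Series(pd.NA, index=table.index, dtype="Int64")
    table.loc[ranked.index, "rank"] = np.arange(1, len(ranked) + 1)
    order = table["rank"].astype("float").fillna(np.inf)
    table = (
        table.assign(_o=order)
        .sort_values(["_o", "gene_id"], kind="mergesort")
        .drop(columns="_o")
        .reset_index(drop=True)
    )
    cols = (
        ["gene_id"]
        + [f"z_rep{r}" for r in reps]
        + ["median_z"]
        + [f"baseline_z_rep{r}" for r in reps]
        + ["median_baseline_z", "n_valid", "viable", "rank"]
    )
    return table[cols]


@dataclasses.dataclass
class ScreenResults:
    """Fitted screen analysis: ranked genes, per-well statistics, plate QC."""

    gene_table: pd.DataFrame
    well_table: pd.DataFrame
    plate_qc: pd.DataFrame
    params: dict

    def top(self, n: int = 10) -> pd.DataFrame:
        """The n best-ranked viable genes."""
        return self.gene_table[self.gene_table["viable"]].head(n)

    def rank_of(self, gene_id: str):
        row = self.gene_table.loc[self.gene_table["gene_id"] == gene_id, "rank"]
        return None if row.empty or pd.isna(row.iloc[0]) else int(row.iloc[0])

    def summary(self) -> str:
        qc = self.plate_qc
        lines = [
            "Quench-screen analysis",
            "=" * 54,
            f"replicates: {self.well_table['replicate'].nunique()}"
            f"   plates/replicate: {qc.groupby('replicate').size().max()}",
            f"genes ranked: {int(self.gene_table['viable'].sum())}"
            f" of {len(self.gene_table)}"
            f" (viability filter at median baseline Z < "
            f"{self.params['viability_threshold']:g})",
            f"degenerate plates: {int(qc['degenerate'].sum())}"
            f"   invalid wells: {int(qc['n_invalid'].sum())}",
            "",
            "top genes (median replicate Z of normalized quench slope):",
        ]
        for _, row in self.top(10).iterrows():
            lines.append(
                f"  rank {int(row['rank']):>4d}  {row['gene_id']:<16s}"
                f" median_z={row['median_z']:+7.2f}"
                f"  baseline_z={row['median_baseline_z']:+6.2f}"
            )
        return "\n".join(lines)


class ScreenAnalysis:
    """Full screen pipeline as a fittable model over a :class:`ScreenDataSet`.

    fit() runs, per replicate and plate: maximal-window slope extraction,
    background normalization, robust plate Z-scores for slope and baseline,
    then aggregates replicates per gene and ranks hits.
    """

    def __init__(
        self,
        data: ScreenDataSet,
        n_pts: int = 10,
        t_lo_s: float = 20.0,
        t_hi_s: float = 100.0,
        viability_threshold: float = -0.5,
        min_replicates: int = 2,
        direction: str = "loss_of_signal",
        scaled_mad: bool = False,
        background_well_type: str = "untransfected_mock",
    ):
        self.data = data
        self.params = dict(
            n_pts=n_pts,
            t_lo_s=t_lo_s,
            t_hi_s=t_hi_s,
            viability_threshold=viability_threshold,
            min_replicates=min_replicates,
            direction=direction,
            scaled_mad=scaled_mad,
            background_well_type=background_well_type,
        )

    @classmethod
    def from_csv(cls, traces_path, layout_path, **params) -> "ScreenAnalysis":
        return cls(ScreenDataSet.from_csv(traces_path, layout_path), **params)

    # -- stage 1: per-well statistics ---------------------------------------------

    def _well_stats(self) -> pd.DataFrame:
        p = self.params
        rows = []
        for rep, plate, pt in self.data.iter_plates():
            wells = pt.wells
            baseline_mask = pt.time_s < pt.addition_time_s
            if not baseline_mask.any():
                raise MismatchError(f"plate {plate}: no pre-addition samples")
            baseline = pt.fluorescence[:, baseline_mask].mean(axis=1)
            starts, slopes = sliding_window_slopes(
                pt.time_s, pt.fluorescence, p["n_pts"], p["t_lo_s"], p["t_hi_s"]
            )
            win = np.argmin(slopes, axis=1)
            raw = slopes[np.arange(len(win)), win]
            types = wells["well_type"].to_numpy()
            bg_rows = types == p["background_well_type"]
            if not bg_rows.any():
                raise MismatchError(
                    f"replicate {rep} plate {plate}: no "
                    f"{p['background_well_type']!r} background wells"
                )
            bg_mean = float(pt.fluorescence[bg_rows].mean())
            denom = baseline - bg_mean
            valid = denom > 0
            norm = np.where(valid, raw / np.where(valid, denom, 1.0), np.nan)
            rows.append(
                pd.DataFrame(
                    {
                        "replicate": rep,
                        "plate": plate,
                        "well": wells["well"].to_numpy(),
                        "well_type": types,
                        "gene_id": wells["gene_id"].to_numpy(),
                        "raw_slope": raw,
                        "window_start_s": starts[win],
                        "baseline_mean": baseline,
                        "background_mean": bg_mean,
                        "normalized_slope": norm,
                        "valid": valid,
                    }
                )
            )
        return pd.concat(rows, ignore_index=True)

    # -- stage 2: plate standardization --------------------------------------------

    def _plate_z(self, well_table: pd.DataFrame) -> Tuple[pd.DataFrame, pd.DataFrame]:
        p = self.params
        well_table = well_table.copy()
        well_table["z"] = np.nan
        well_table["baseline_z"] = np.nan
        qc_rows = []
        for (rep, plate), idx in well_table.groupby(["replicate", "plate"]).groups.items():
            sub = well_table.loc[idx]
            cand = sub["well_type"] == "candidate"
            x = np.where(sub["valid"], sub["normalized_slope"], np.nan)
            b = sub["baseline_mean"].to_numpy(dtype=float)
            degenerate = False
            median = mad = np.nan
            try:
                x_cand = x[cand.to_numpy()]
                z_all = _z_against(x, x_cand, p["scaled_mad"])
                bz_all = _z_against(b, b[cand.to_numpy()], p["scaled_mad"])
                median = float(np.nanmedian(x_cand))
                finite = x_cand[np.isfinite(x_cand)]
                mad = float(median_abs_deviation(finite, scale=1.0))
            except DegenerateDispersionError:
                degenerate = True
                z_all = np.full(len(sub), np.nan)
                bz_all = np.full(len(sub), np.nan)
            # control wells receive QC-only Z against candidate statistics
            well_table.loc[idx, "z"] = z_all
            well_table.loc[idx, "baseline_z"] = bz_all
            qc_rows.append(
                {
                    "replicate": rep,
                    "plate": plate,
                    "n_candidate": int(cand.sum()),
                    "median_normalized_slope": median,
                    "mad_normalized_slope": mad,
                    "n_invalid": int((~sub["valid"][cand]).sum()),
                    "degenerate": degenerate,
                }
            )
        # Z of candidate wells only is the screen statistic; controls keep
        # their QC value but never enter ranking.
        mask = ~well_table["well_type"].isin(["candidate"] + list(CONTROL_TYPES))
        well_table.loc[mask, ["z", "baseline_z"]] = np.nan
        return well_table, pd.DataFrame(qc_rows)

    # -- public fit ----------------------------------------------------------------

    def fit(self) -> ScreenResults:
        well_table = self._well_stats()
        well_table, qc = self._plate_z(well_table)
        cand = well_table[well_table["well_type"] == "candidate"].copy()
        cand = cand.dropna(subset=["gene_id"])
        scores = cand.rename(columns={})[
            ["gene_id", "replicate", "z", "baseline_z"]
        ]
        gene_table = aggregate_and_rank(
            scores,
            viability_threshold=self.params["viability_threshold"],
            min_replicates=self.params["min_replicates"],
            direction=self.params["direction"],
        )
        return ScreenResults(
            gene_table=gene_table,
            well_table=well_table,
            plate_qc=qc,
            params=dict(self.params),
        )


def _z_against(x: np.ndarray, reference: np.ndarray, scaled: bool) -> np.ndarray:
    """Z-scores of ``x`` against the median/MAD of ``reference``."""
    finite = reference[np.isfinite(reference)]
    if finite.size < 2:
        raise DegenerateDispersionError("fewer than 2 valid candidate wells")
    center = float(np.median(finite))
    mad = float(median_abs_deviation(finite, scale=1.0))
    if mad == 0.0:
        raise DegenerateDispersionError("zero MAD")
    if scaled:
        mad *= MAD_CONSISTENCY
    return (np.asarray(x, dtype=float) - center) / mad


def run_screen_analysis(
    data: ScreenDataSet | None = None,
    traces_path=None,
    layout_path=None,
    **params,
) -> ScreenResults:
    """Convenience wrapper: build a :class:`ScreenAnalysis` and fit it.

    Provide either an in-memory ``data`` set or the two CSV paths.
    """
    if data is None:
        if traces_path is None or layout_path is None:
            raise ValueError("need either data or traces_path + layout_path")
        model = ScreenAnalysis.from_csv(traces_path, layout_path, **params)
    else:
        model = ScreenAnalysis(data, **params)
    return model.fit()
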