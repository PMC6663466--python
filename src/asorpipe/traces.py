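"""Per-well kinetic trace statistics.

The screen's read-out for a well is the *maximal quench slope*: the most
negative ordinary-least-squares slope over all windows of ``n_pts`` consecutive
samples lying fully inside a search interval (default 20–100 s, 10 points at
1 Hz).  The slope is normalized by the well's pre-addition baseline minus the
mean fluorescence of reporter-free background wells, which makes the statistic
invariant to optical gain and offset.
"""

from __future__ import annotations

import dataclasses
import math
from typing import Iterable, Optional, Sequence

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view

from .errors import (
    DegenerateWindowError,
    WindowRangeError,
    ZeroReferenceError,
)

__all__ = [
    "KineticTrace",
    "SlopeResult",
    "max_window_slope",
    "normalized_quench_slope",
    "normalize_timecourse",
    "sliding_window_slopes",
]

_GRID_RTOL = 1e-9


@dataclasses.dataclass
class KineticTrace:
    """One well's fluorescence timecourse on a uniform time grid.

    ``addition_time_s`` marks reagent addition; samples strictly before it form
    the baseline window.
    """

    time_s: np.ndarray
    fluorescence: np.ndarray
    addition_time_s: float = 10.0
    well: Optional[str] = None
    condition: Optional[str] = None

    def __post_init__(self) -> None:
        self.time_s = np.asarray(self.time_s, dtype=float)
        self.fluorescence = np.asarray(self.fluorescence, dtype=float)
        if self.time_s.ndim != 1 or self.time_s.shape != self.fluorescence.shape:
            raise ValueError("time_s and fluorescence must be equal-length 1-D arrays")
        if self.time_s.size < 2:
            raise ValueError("a trace needs at least two samples")
        steps = np.diff(self.time_s)
        if np.any(steps <= 0):
            raise ValueError("times must be strictly increasing")
        dt = steps[0]
        if np.any(np.abs(steps - dt) > _GRID_RTOL * max(abs(dt), 1.0)):
            raise ValueError("times must lie on a uniform grid")
        if not np.all(np.isfinite(self.fluorescence)):
            raise ValueError("fluorescence must be finite")

    @property
    def dt(self) -> float:
        return float(self.time_s[1] - self.time_s[0])

    def baseline_mean(self) -> float:
        """Mean fluorescence of all samples strictly before reagent addition."""
        mask = self.time_s < self.addition_time_s
        if not mask.any():
            raise WindowRangeError("no samples before addition_time_s")
        return float(self.fluorescence[mask].mean())


@dataclasses.dataclass
class SlopeResult:
    """Outcome of the maximal-slope search for one well.

    ``raw_slope`` is the signed OLS slope of the winning window (negative for
    quenching wells); ``quench_rate`` is its negation.  ``normalized_slope`` is
    raw_slope divided by (baseline − background) and is the statistic that
    enters the plate Z-score; it is NaN when the well is invalid.
    """

    raw_slope: float
    quench_rate: float
    window_start_s: float
    baseline_mean: float
    normalized_slope: float = math.nan
    background_mean: float = math.nan
    valid: bool = True


def _window_weights(n_pts: int, dt: float) -> np.ndarray:
    offsets = np.arange(n_pts, dtype=float) * dt
    centered = offsets - offsets.mean()
    return centered / np.dot(centered, centered)


def sliding_window_slopes(
    time_s: np.ndarray,
    values: np.ndarray,
    n_pts: int = 10,
    t_lo_s: float = 20.0,
    t_hi_s: float = 100.0,
):
    """OLS slopes of every full window of ``n_pts`` samples inside [t_lo, t_hi].

    ``values`` may be 1-D (one trace) or 2-D (wells × time, vectorized over
    wells).  Returns ``(window_start_times, slopes)`` with slopes of shape
    ``values.shape[:-1] + (n_windows,)``.
    """
    time_s = np.asarray(time_s, dtype=float)
    values = np.asarray(values, dtype=float)
    if n_pts < 2:
        raise ValueError("n_pts must be at least 2")
    if t_hi_s <= t_lo_s:
        raise ValueError("t_hi_s must exceed t_lo_s")
    eps = _GRID_RTOL * max(1.0, abs(t_hi_s))
    if time_s[0] > t_lo_s + eps or time_s[-1] < t_hi_s - eps:
        raise WindowRangeError(
            f"trace spans [{time_s[0]:g}, {time_s[-1]:g}] s, "
            f"does not cover [{t_lo_s:g}, {t_hi_s:g}] s"
        )
    inside = np.flatnonzero((time_s >= t_lo_s - eps) & (time_s <= t_hi_s + eps))
    if inside.size < n_pts:
        raise DegenerateWindowError(
            f"only {inside.size} samples inside [{t_lo_s:g}, {t_hi_s:g}] s; "
            f"need {n_pts} for one window"
        )
    dt = float(time_s[1] - time_s[0])
    seg = values[..., inside[0] : inside[-1] + 1]
    windows = sliding_window_view(seg, n_pts, axis=-1)
    # Center each window so a constant trace yields exactly zero slope.
    centered = windows - windows.mean(axis=-1, keepdims=True)
    slopes = centered @ _window_weights(n_pts, dt)
    starts = time_s[inside[0] : inside[-1] - n_pts + 2]
    return starts, slopes


def max_window_slope(
    trace: KineticTrace,
    n_pts: int = 10,
    t_lo_s: float = 20.0,
    t_hi_s: float = 100.0,
) -> SlopeResult:
    """Steepest-quench window: the most negative sliding-window OLS slope.

    Ties are broken toward the earliest window.  The returned
    ``normalized_slope`` is NaN; use :func:`normalized_quench_slope` for the
    full statistic.
    """
    starts, slopes = sliding_window_slopes(
        trace.time_s, trace.fluorescence, n_pts, t_lo_s, t_hi_s
    )
    i = int(np.argmin(slopes))
    raw = float(slopes[i])
    return SlopeResult(
        raw_slope=raw,
        quench_rate=-raw,
        window_start_s=float(starts[i]),
        baseline_mean=trace.baseline_mean(),
    )


def _background_mean(background_traces: Iterable[KineticTrace]) -> float:
    values = [t.fluorescence for t in background_traces]
    if not values:
        raise ValueError("background_traces must be non-empty")
    return float(np.concatenate(values).mean())


def normalized_quench_slope(
    trace: KineticTrace,
    background_traces: Sequence[KineticTrace],
    n_pts: int = 10,
    t_lo_s: float = 20.0,
    t_hi_s: float = 100.0,
    baseline_only: bool = False,
) -> SlopeResult:
    """Maximal window slope normalized to (baseline − background).

    The denominator is the well's pre-addition baseline mean minus the mean
    fluorescence of the background wells over their full traces.  A
    non-positive denominator flags the well invalid (normalized slope NaN)
    rather than emitting ±inf.  With ``baseline_only=True`` (and an empty
    background set) the raw slope is divided by the baseline mean alone.
    """
    res = max_window_slope(trace, n_pts, t_lo_s, t_hi_s)
    if baseline_only:
        if background_traces:
            raise ValueError("baseline_only normalization takes no background traces")
        bg = 0.0
    else:
        bg = _background_mean(background_traces)
    denom = res.baseline_mean - bg
    res.background_mean = bg
    if denom <= 0:
        res.valid = False
        res.normalized_slope = math.nan
    else:
        res.normalized_slope = res.raw_slope / denom
    return res


def normalize_timecourse(
    trace: KineticTrace,
    background_traces: Sequence[KineticTrace],
    t_ref_s: float = 0.0,
) -> KineticTrace:
    """Background-subtract pointwise and scale to 1 at the reference time.

    output(t) = (F(t) − mean_bg(t)) / (F(t_ref) − mean_bg(t_ref)).  All traces
    must share the time grid of ``trace``.
    """
    bg = np.zeros_like(trace.fluorescence)
    if background_traces:
        for b in background_traces:
            if b.time_s.shape != trace.time_s.shape or np.any(
                np.abs(b.time_s - trace.time_s) > _GRID_RTOL * (1 + np.abs(trace.time_s))
            ):
                raise ValueError("background traces must share the trace's time grid")
        bg = np.mean([b.fluorescence for b in background_traces], axis=0)
    corrected = trace.fluorescence - bg
    i_ref = int(np.argmin(np.abs(trace.time_s - t_ref_s)))
    if abs(trace.time_s[i_ref] - t_ref_s) > trace.dt / 2 + _GRID_RTOL:
        raise WindowRangeError(f"t_ref {t_ref_s:g} s outside the trace")
    ref = corrected[i_ref]
    if ref == 0:
        raise ZeroReferenceError("corrected fluorescence is zero at the reference time")
    return KineticTrace(
        time_s=trace.time_s.copy(),
        fluorescence=corrected / ref,
        addition_time_s=trace.addition_time_s,
        well=trace.well,
        condition=trace.condition,
    )
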