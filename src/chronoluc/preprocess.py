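"""Trace normalization and detrending conventions.

The detrend convention divides each point by the centered 24 h moving
average of the trace, turning counts into unitless ratios that oscillate
around 1. Reference-point normalization rescales each well so the sample
just before a chosen time (e.g. a light pulse) reads 100.
"""

from __future__ import annotations

from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .errors import AnalysisError
from .traceset import DetrendedTraceSet, TraceSet

_EDGE_TOL = 1e-9


def moving_average_window(
    time_h: np.ndarray, values: np.ndarray, window_h: float
) -> tuple[np.ndarray, np.ndarray]:
    """Centered moving average over all samples within +-window_h/2, inclusive.

    Returns ``(averages, edge_mask)`` where the mask marks points whose
    window was truncated by the record edge (computed from the available
    asymmetric window).
    """
    half = window_h / 2.0
    lo = np.searchsorted(time_h, time_h - half, side="left")
    hi = np.searchsorted(time_h, time_h + half, side="right")
    avg = np.empty_like(values, dtype=float)
    for i in range(time_h.size):
        avg[i] = np.mean(values[lo[i] : hi[i]])
    edge = (time_h - half < time_h[0] - _EDGE_TOL) | (
        time_h + half > time_h[-1] + _EDGE_TOL
    )
    return avg, edge


def centered_smooth(time_h: np.ndarray, values: np.ndarray, span_h: float) -> np.ndarray:
    """Centered moving-average smoother of span ``span_h`` (shrinks at edges)."""
    if span_h <= 0:
        return values.astype(float)
    avg, _ = moving_average_window(time_h, values, span_h)
    return avg


def detrend_moving_average(ts: TraceSet, window_h: float = 24.0) -> DetrendedTraceSet:
    """Divide each well by its centered ``window_h`` moving average.

    Wells containing missing values are skipped (silent interpolation would
    bias downstream minimum statistics) and listed in ``skipped_wells`` of
    the result. Counts must be strictly positive; the grid must resolve the
    window (spacing <= window_h / 4).
    """
    t = ts.time_h
    if t.size < 2:
        raise AnalysisError("detrending needs at least two time points")
    max_step = float(np.max(np.diff(t)))
    if max_step > window_h / 4.0:
        raise AnalysisError(
            f"grid spacing {max_step} h too coarse for a {window_h} h window "
            f"(need <= {window_h / 4.0} h)"
        )
    kept: dict = {}
    masks: dict = {}
    skipped = []
    for well in ts.wells:
        y = ts.well(well)
        if np.isnan(y).any():
            skipped.append(well)
            continue
        if (y <= 0).any():
            bad = int(np.argmax(y <= 0))
            raise AnalysisError(
                f"nonpositive counts in well {well!r} at t={t[bad]} h; "
                "ratio detrending requires positive counts"
            )
        avg, edge = moving_average_window(t, y, window_h)
        kept[well] = y / avg
        masks[well] = edge
    counts = pd.DataFrame(kept, index=t)
    mask = pd.DataFrame(masks, index=t)
    meta = ts.meta.loc[list(counts.columns)]
    return DetrendedTraceSet(
        t.copy(), counts, meta.copy(), edge_mask=mask, skipped_wells=tuple(skipped)
    )


def normalize_at_time(
    ts: TraceSet, t_ref_h: float, value: float = 100.0
) -> tuple[TraceSet, list]:
    """Scale each well so its last sample at or before ``t_ref_h`` equals ``value``.

    Returns the rescaled TraceSet and the list of wells skipped because the
    reference sample was missing or zero. Idempotent.
    """
    t = ts.time_h
    if t.size == 0 or t_ref_h < t[0] - _EDGE_TOL or t_ref_h > t[-1] + _EDGE_TOL:
        raise AnalysisError(f"reference time {t_ref_h} h outside the grid span")
    idx = int(np.searchsorted(t, t_ref_h + _EDGE_TOL, side="left")) - 1
    if idx < 0:
        raise AnalysisError(f"no grid sample at or before {t_ref_h} h")
    kept = {}
    skipped = []
    for well in ts.wells:
        y = ts.well(well)
        ref = y[idx]
        if not np.isfinite(ref) or ref == 0:
            skipped.append(well)
            continue
        kept[well] = y * (value / ref)
    counts = pd.DataFrame(kept, index=t)
    out = TraceSet(t.copy(), counts, ts.meta.loc[list(counts.columns)].copy())
    return out, skipped


def normalize_to_kth_peak(
    ts: TraceSet,
    k: int = 3,
    group_keys: Sequence[str] = ("strain_label",),
    analysis_start_h: float = 0.0,
    smoothing_h: float = 3.0,
    min_separation_h: float = 16.0,
    value: float = 100.0,
) -> tuple[TraceSet, list]:
    """Per replicate group, set the group-average k-th peak height to ``value``.

    Peaks are detected on the replicate-mean trace (smoothed peak picking
    from :mod:`chronoluc.rhythm`). Groups with fewer than ``k`` peaks are
    skipped and reported.
    """
    from .rhythm import find_trace_peaks  # deferred: rhythm imports this module

    if k < 1:
        raise AnalysisError("k must be >= 1")
    t = ts.time_h
    kept = {}
    skipped_groups = []
    order = []
    for key, group in ts.groupby_meta(list(group_keys)):
        mean_trace = group.counts.mean(axis=1).to_numpy()
        peaks = find_trace_peaks(
            t,
            mean_trace,
            analysis_start_h=analysis_start_h,
            smoothing_h=smoothing_h,
            min_separation_h=min_separation_h,
        )
        if len(peaks) < k:
            skipped_groups.append(key)
            continue
        # smoothing only locates the peak; the height that is set to `value`
        # is the raw replicate-mean level at the nearest grid sample
        i_peak = int(np.argmin(np.abs(t - peaks[k - 1].time_h)))
        height = float(mean_trace[i_peak])
        if height <= 0:
            skipped_groups.append(key)
            continue
        factor = value / height
        for well in group.wells:
            kept[well] = group.well(well) * factor
            order.append(well)
    ordered = [w for w in ts.wells if w in kept]
    counts = pd.DataFrame({w: kept[w] for w in ordered}, index=t)
    out = TraceSet(t.copy(), counts, ts.meta.loc[ordered].copy())
    return out, skipped_groups


def aggregate_replicates(ts: TraceSet, group_keys: Sequence[str]) -> pd.DataFrame:
    """Per-group, per-timepoint mean and sample SD (n-1 denominator).

    Returns a long frame with the group keys, ``time_h``, ``mean``, ``sd``,
    ``n`` and a ``singleton`` flag; groups of one well report SD 0.
    Missing values are excluded pointwise (``n`` varies along the trace).
    """
    if ts.n_wells == 0:
        raise AnalysisError("cannot aggregate an empty trace set")
    frames = []
    for key, group in ts.groupby_meta(list(group_keys)):
        if not isinstance(key, tuple):
            key = (key,)
        vals = group.counts
        n = vals.notna().sum(axis=1)
        mean = vals.mean(axis=1)
        sd = vals.std(axis=1, ddof=1).where(n > 1, 0.0)
        df = pd.DataFrame(
            {
                "time_h": ts.time_h,
                "mean": mean.to_numpy(),
                "sd": sd.to_numpy(),
                "n": n.to_numpy(),
                "singleton": (n <= 1).to_numpy(),
            }
        )
        for col, val in zip(group_keys, key):
            df.insert(0, col, val)
        frames.append(df)
    return pd.concat(frames, ignore_index=True)
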