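"""Free-running period/phase estimation and phase-shift quantification.

Period and phase come from smoothed peak picking with parabolic sub-grid
refinement: the detrended trace is smoothed with a short centered moving
average, strict local maxima separated by at least a minimum period are
located, and each peak time is refined by a least-squares parabola fitted
over a short window around the peak sample (the wider fit averages down
measurement noise that a three-point parabola would pass straight through
to the peak time). Peaks whose windows are truncated by the record edge are
discarded. The period is the mean spacing of successive peaks; phase is the
time of the first used peak modulo the period. Phase shifts between treated
and control wells are peak-time differences, unwrapped into
``(-period/2, period/2]``, with the advance counted positive.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence, Union

import numpy as np
from scipy.signal import find_peaks

from .errors import AnalysisError
from .preprocess import centered_smooth
from .traceset import TraceSet


@dataclass(frozen=True)
class Peak:
    time_h: float
    height: float


@dataclass(frozen=True)
class PhaseEstimate:
    """Period/phase of one well's rhythm (times in hours)."""

    well_id: str
    period_h: float
    peak_times_h: tuple
    phase_h: float
    n_peaks_used: int
    flags: tuple = ()

    @property
    def ok(self) -> bool:
        return np.isfinite(self.period_h)


@dataclass(frozen=True)
class PhaseShiftResult:
    """Treated-vs-control phase difference; advance is positive."""

    shift_h: float
    per_replicate_h: tuple
    sd_h: float
    n: int
    p_value: float
    period_h: float
    peak_index: int

    @property
    def mean_h(self) -> float:
        return self.shift_h


#: half-width (h) of the local parabola fit refining each peak time
REFINE_HALF_H = 3.0
#: peaks closer than this to either record edge are discarded (their
#: smoothing/refinement windows are truncated and their times biased)
EDGE_EXCLUSION_H = 3.0


def _refine_peak(t: np.ndarray, y: np.ndarray, i: int, half_h: float = REFINE_HALF_H) -> Peak:
    """Sub-grid peak refinement: least-squares parabola around the peak sample.

    All samples within ``half_h`` of the grid peak enter the fit (at minimum
    the peak and its two neighbors). The refined time is the parabola's
    vertex, clamped to the fit window; degenerate (non-concave) fits keep
    the grid sample.
    """
    if i <= 0 or i >= t.size - 1:
        return Peak(float(t[i]), float(y[i]))
    lo = int(np.searchsorted(t, t[i] - half_h, side="left"))
    hi = int(np.searchsorted(t, t[i] + half_h, side="right"))
    lo, hi = min(lo, i - 1), max(hi, i + 2)
    tt = t[lo:hi] - t[i]
    yy = y[lo:hi]
    c2, c1, c0 = np.polyfit(tt, yy, 2)
    if c2 >= 0:  # degenerate / flat: keep the grid sample
        return Peak(float(t[i]), float(y[i]))
    offset = float(np.clip(-c1 / (2.0 * c2), tt[0], tt[-1]))
    height = float(c0 + c1 * offset + c2 * offset * offset)
    return Peak(float(t[i] + offset), height)


def find_trace_peaks(
    time_h: np.ndarray,
    values: np.ndarray,
    analysis_start_h: float = 0.0,
    smoothing_h: float = 3.0,
    min_separation_h: float = 16.0,
    edge_exclusion_h: float = EDGE_EXCLUSION_H,
) -> list[Peak]:
    """Strict local maxima of the smoothed trace, sub-grid refined.

    Peaks closer than ``min_separation_h`` are suppressed (highest wins,
    ties resolved to the earliest time by the left-to-right scan); peaks
    within ``edge_exclusion_h`` of either record edge are discarded because
    their windows are truncated and their times biased.
    """
    t = np.asarray(time_h, dtype=float)
    y = np.asarray(values, dtype=float)
    keep = t >= analysis_start_h
    t, y = t[keep], y[keep]
    if t.size < 3:
        return []
    smooth = centered_smooth(t, y, smoothing_h)
    dt = float(np.median(np.diff(t)))
    distance = max(1, int(np.round(min_separation_h / dt)))
    idx, _ = find_peaks(smooth, distance=distance)
    peaks = [_refine_peak(t, smooth, int(i)) for i in idx]
    lo, hi = t[0] + edge_exclusion_h, t[-1] - edge_exclusion_h
    return [p for p in peaks if lo <= p.time_h <= hi]


def estimate_period_phase(
    dts: TraceSet,
    analysis_start_h: float = 12.0,
    smoothing_h: float = 3.0,
    min_separation_h: float = 16.0,
) -> dict[str, PhaseEstimate]:
    """Per-well period and phase from detrended traces.

    Wells with fewer than two detectable peaks get a flagged, NaN estimate
    rather than an exception. The default analysis window skips the first
    12 h (entrainment transients).
    """
    out: dict[str, PhaseEstimate] = {}
    for well in dts.wells:
        y = dts.well(well)
        if np.isnan(y).any():
            out[well] = PhaseEstimate(well, np.nan, (), np.nan, 0, ("missing_values",))
            continue
        peaks = find_trace_peaks(
            dts.time_h, y, analysis_start_h, smoothing_h, min_separation_h
        )
        times = tuple(p.time_h for p in peaks)
        if len(times) < 2:
            out[well] = PhaseEstimate(well, np.nan, times, np.nan, len(times), ("too_few_peaks",))
            continue
        period = float(np.mean(np.diff(times)))
        phase = float(times[0] % period)
        flags = ()
        if len(times) < 3:
            flags = ("two_peaks_only",)
        out[well] = PhaseEstimate(well, period, times, phase, len(times), flags)
    return out


def _wrap_half_period(shift: float, period: float) -> float:
    """Map a shift onto ``(-period/2, period/2]``."""
    w = shift % period
    if w > period / 2.0:
        w -= period
    return w


def compute_phase_shift(
    treated: Union[dict, Sequence[PhaseEstimate]],
    control: Union[dict, Sequence[PhaseEstimate]],
    peak_index: Optional[int] = None,
) -> PhaseShiftResult:
    """Phase difference between treated and control wells at one peak index.

    ``shift = control peak time - treated peak time`` (an earlier treated
    peak is an advance, counted positive), unwrapped modulo the period into
    ``(-period/2, period/2]``. ``peak_index=None`` uses the latest peak all
    wells share, which sits past post-stimulus transients. Per-replicate
    shifts compare each treated well against the control-group mean peak
    time; the p-value is a pooled-variance two-sample comparison of the
    treated shifts against the control wells' internal deviations.
    """
    t_est = list(treated.values()) if isinstance(treated, dict) else list(treated)
    c_est = list(control.values()) if isinstance(control, dict) else list(control)
    t_est = [e for e in t_est if e.ok]
    c_est = [e for e in c_est if e.ok]
    if not t_est or not c_est:
        raise AnalysisError("phase shift needs at least one usable well per group")
    n_common = min(e.n_peaks_used for e in t_est + c_est)
    if peak_index is None:
        peak_index = n_common - 1
    bad = [e.well_id for e in t_est + c_est if e.n_peaks_used <= peak_index]
    if bad:
        raise AnalysisError(
            f"peak index {peak_index} not available in wells: {sorted(bad)}"
        )
    period = float(np.mean([e.period_h for e in t_est + c_est]))
    control_times = np.array([e.peak_times_h[peak_index] for e in c_est])
    treated_times = np.array([e.peak_times_h[peak_index] for e in t_est])
    control_ref = float(np.mean(control_times))
    shifts = [_wrap_half_period(control_ref - tt, period) for tt in treated_times]
    shifts = np.array(shifts)
    mean = float(np.mean(shifts))
    sd = float(np.std(shifts, ddof=1)) if shifts.size > 1 else 0.0
    control_dev = control_ref - control_times  # zero-shift reference spread
    if shifts.size >= 2 and control_dev.size >= 2:
        from .stats import student_t_test

        _, _, p = student_t_test(shifts, control_dev)
    else:
        p = float("nan")
    return PhaseShiftResult(
        shift_h=mean,
        per_replicate_h=tuple(float(s) for s in shifts),
        sd_h=sd,
        n=int(shifts.size),
        p_value=float(p),
        period_h=period,
        peak_index=int(peak_index),
    )


def reentrainment_call(
    shift: Union[PhaseShiftResult, float], threshold_h: float = 4.5
) -> bool:
    """True iff the mean phase shift strictly exceeds ``threshold_h`` (> 4.5 h)."""
    mean = shift.shift_h if isinstance(shift, PhaseShiftResult) else float(shift)
    return bool(mean > threshold_h)
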