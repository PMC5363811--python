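"""Acute light responses, action spectra, and pathway-subtraction spectra.

The sensitivity statistic is the relative bioluminescence lost after a light
pulse: the trace is scaled so the sample just before the pulse reads 100 and
the sensitivity is ``100 - min`` over a post-pulse search window, clamped at
0. Per-wavelength sensitivities at equal photon flux form an equal-quantum
action spectrum; subtracting a mutant's spectrum from the wild type's (with
negatives clamped to 0) isolates the pathway the mutation removes.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .errors import AnalysisError
from .traceset import TraceSet

_TOL = 1e-9


@dataclass(frozen=True)
class SensitivitySpectrum:
    """Per-wavelength acute-response sensitivities (0-100 scale)."""

    wavelengths_nm: tuple
    sensitivity: tuple  # means, one per wavelength
    sd: tuple
    n: tuple
    per_well: dict  # wavelength -> tuple of per-well sensitivities

    def as_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "wavelength_nm": self.wavelengths_nm,
                "sensitivity": self.sensitivity,
                "sd": self.sd,
                "n": self.n,
            }
        )

    def at(self, wavelength_nm) -> float:
        try:
            i = self.wavelengths_nm.index(wavelength_nm)
        except ValueError:
            raise AnalysisError(
                f"wavelength {wavelength_nm} not in spectrum grid {self.wavelengths_nm}"
            ) from None
        return self.sensitivity[i]


def _pre_pulse_index(time_h: np.ndarray, pulse_start_h: float) -> int:
    idx = int(np.searchsorted(time_h, pulse_start_h + _TOL, side="left")) - 1
    if idx < 0:
        raise AnalysisError(f"no sample at or before the pulse start {pulse_start_h} h")
    return idx


def acute_sensitivity(
    time_h: np.ndarray,
    values: np.ndarray,
    pulse_start_h: float,
    search_window_h: float = 2.0,
) -> float:
    """Relative level lost after a pulse: ``100 - min`` over the search window.

    The trace is referenced to the last sample at or before
    ``pulse_start_h`` (set to 100); the minimum is taken over
    ``(pulse_start_h, pulse_start_h + search_window_h]`` and the result is
    clamped below at 0. Scale-invariant in the raw counts.
    """
    t = np.asarray(time_h, dtype=float)
    y = np.asarray(values, dtype=float)
    if t[-1] + _TOL < pulse_start_h + search_window_h:
        raise AnalysisError(
            f"search window ({pulse_start_h} + {search_window_h} h) extends past "
            f"the record end at {t[-1]} h"
        )
    i_ref = _pre_pulse_index(t, pulse_start_h)
    ref = y[i_ref]
    if not np.isfinite(ref) or ref <= 0:
        raise AnalysisError(
            f"pre-pulse reference at t={t[i_ref]} h is missing or nonpositive"
        )
    in_window = (t > pulse_start_h + _TOL) & (t <= pulse_start_h + search_window_h + _TOL)
    window = y[in_window]
    if window.size < 3:
        raise AnalysisError(
            f"need >= 3 samples in the {search_window_h} h search window, "
            f"got {window.size}"
        )
    if np.isnan(window).any():
        raise AnalysisError("missing values inside the search window")
    rel_min = 100.0 * float(np.min(window)) / ref
    return max(0.0, 100.0 - rel_min)


def acute_response_level(
    time_h: np.ndarray,
    values: np.ndarray,
    lights_on_h: float,
    eval_window_h: float = 6.0,
) -> float:
    """Post-lights-on minimum level relative to the pre-lights-on sample (=100).

    The complement of :func:`acute_sensitivity` without clamping: low values
    mean a strong decline after light on.
    """
    t = np.asarray(time_h, dtype=float)
    y = np.asarray(values, dtype=float)
    if t[-1] + _TOL < lights_on_h + eval_window_h:
        raise AnalysisError(
            f"evaluation window ({lights_on_h} + {eval_window_h} h) extends past "
            f"the record end at {t[-1]} h"
        )
    i_ref = _pre_pulse_index(t, lights_on_h)
    ref = y[i_ref]
    if not np.isfinite(ref) or ref <= 0:
        raise AnalysisError(
            f"pre-lights-on reference at t={t[i_ref]} h is missing or nonpositive"
        )
    in_window = (t > lights_on_h + _TOL) & (t <= lights_on_h + eval_window_h + _TOL)
    window = y[in_window]
    if window.size == 0 or np.isnan(window).any():
        raise AnalysisError("evaluation window is empty or contains missing values")
    return 100.0 * float(np.min(window)) / ref


def complementation_call(level: float) -> bool:
    """True iff the relative level after light on is strictly below 30."""
    return bool(level < 30.0)


def build_action_spectrum(
    ts: TraceSet,
    pulse_start_h: float,
    search_window_h: float = 2.0,
    wavelength_column: str = "wavelength_nm",
) -> SensitivitySpectrum:
    """Assemble per-wavelength sensitivities from a pulse-assay trace set.

    Wells must carry wavelength and irradiance metadata. An equal-quantum
    design has one irradiance across wavelengths; unequal irradiances are
    tolerated with a warning flag in the frame (instrument attenuation, e.g.
    plate lids absorbing near-UV, is the caller's metadata concern).
    """
    if wavelength_column not in ts.meta.columns:
        raise AnalysisError(f"wells lack a {wavelength_column!r} metadata column")
    if ts.meta[wavelength_column].isna().any():
        bad = list(ts.meta.index[ts.meta[wavelength_column].isna()])
        raise AnalysisError(f"wells missing wavelength annotation: {bad}")
    if "irradiance" in ts.meta.columns:
        irr = pd.to_numeric(ts.meta["irradiance"], errors="coerce").dropna()
        lit = irr[irr > 0]
        if lit.nunique() > 1:
            import warnings

            warnings.warn(
                "irradiance differs across wells; this is not an equal-quantum design",
                stacklevel=2,
            )
    wavelengths = []
    means, sds, ns = [], [], []
    per_well: dict = {}
    groups = ts.meta.groupby(wavelength_column, sort=False)
    # numeric wavelengths ascending, labels (e.g. "dark") last
    keys = sorted(
        groups.groups, key=lambda w: (isinstance(w, str), w if not isinstance(w, str) else 0)
    )
    for lam in keys:
        ids = list(groups.groups[lam])
        vals = [
            acute_sensitivity(ts.time_h, ts.well(w), pulse_start_h, search_window_h)
            for w in ids
        ]
        arr = np.array(vals)
        wavelengths.append(lam)
        means.append(float(arr.mean()))
        sds.append(float(arr.std(ddof=1)) if arr.size > 1 else 0.0)
        ns.append(int(arr.size))
        per_well[lam] = tuple(float(v) for v in vals)
    return SensitivitySpectrum(
        tuple(wavelengths), tuple(means), tuple(sds), tuple(ns), per_well
    )


def pathway_difference_spectrum(
    wt: SensitivitySpectrum, mut: SensitivitySpectrum
) -> SensitivitySpectrum:
    """Wild-type minus mutant sensitivity, negatives clamped to 0.

    The remainder estimates the action spectrum of the pathway the mutant
    lost. SDs combine in independent-error quadrature; n is the pairwise
    minimum.
    """
    if wt.wavelengths_nm != mut.wavelengths_nm:
        raise AnalysisError(
            f"wavelength grids differ: {wt.wavelengths_nm} vs {mut.wavelengths_nm}"
        )
    diff = tuple(max(0.0, a - b) for a, b in zip(wt.sensitivity, mut.sensitivity))
    sd = tuple(float(np.hypot(a, b)) for a, b in zip(wt.sd, mut.sd))
    n = tuple(min(a, b) for a, b in zip(wt.n, mut.n))
    return SensitivitySpectrum(wt.wavelengths_nm, diff, sd, n, {})
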