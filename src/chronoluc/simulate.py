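"""Synthetic clock-reporter traces: reporter kinetics and a resettable oscillator.

Two generative models share one light-input front end:

* ``simulate_roc15_trace`` -- a night-accumulating, light-degradable reporter
  protein. Between regime events the state obeys the linear ODE
  ``dR/dt = sigma_dark * g(t) - (delta_dark + delta_L(t)) * R`` with
  ``g = 1`` in dark and ``g_light`` in light, and a light-induced degradation
  rate ``delta_L = delta_max * h * E / (K_half + E)`` saturating in the
  effective irradiance ``E``.
* ``simulate_circadian_trace`` -- a phase-only circadian oscillator read out
  through a rhythmic reporter. At every dark-to-light transition the phase
  takes a discrete step ``reset_gain * sin(phi - phi_ref) * D`` where ``D``
  is the fraction of the ROC15-like reporter degraded in the 30 min after
  lights-on, tying clock resetting to reporter degradation.

Integration uses fixed-step RK4 (0.01 h internal step) with steps aligned to
every regime boundary. Within a segment the ODE coefficients are constant, so
the RK4 update reduces to an exact affine recurrence, which is evaluated in
closed form (bit-identical to the step-by-step loop, but vectorized).
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .errors import SimulationError
from .regimes import LightRegime, Segment
from .strains import StrainParams, Wavelength
from .traceset import TraceSet

INTERNAL_STEP_H = 0.01
RESET_WINDOW_H = 0.5  # reporter-degradation window defining the reset drive
PHI_REF = np.pi  # PRC reference: stable entrained dawn sits at phase 0


def effective_irradiance(
    strain: StrainParams, wavelength_nm: Wavelength, irradiance: float
) -> float:
    """Pathway-weighted irradiance ``c_csl*A_csl(lam)*I + c_blue*A_blue(lam)*I``.

    ``"white"`` light couples through both pathways at the mean of each
    spectrum's values.
    """
    if irradiance < 0:
        raise SimulationError(f"irradiance must be >= 0, got {irradiance}")
    if irradiance == 0:
        return 0.0
    a_csl = strain.spectrum_csl.action(wavelength_nm)
    a_blue = strain.spectrum_blue.action(wavelength_nm)
    return (strain.c_csl * a_csl + strain.c_blue * a_blue) * irradiance


# -- internal integration ----------------------------------------------------


def _rk4_decay_factor(b: float, h: float) -> float:
    """One-step RK4 multiplier for dR/dt = -b*R: the degree-4 Taylor of e^(-bh)."""
    x = -b * h
    return 1.0 + x + x * x / 2.0 + x ** 3 / 6.0 + x ** 4 / 24.0


def _segment_events(strain: StrainParams, regime: LightRegime) -> list[tuple]:
    """Piecewise-constant intervals: (t0, t1, synth_rate, decay_rate).

    History scaling is frozen at each light segment's start (cumulative light
    hours accrued strictly before the segment). Type-2 style synthesis
    re-activation splits a light segment at ``reactivation_after_h``.
    """
    events = []
    light_hours = 0.0
    for seg in regime.segments:
        if not seg.is_light:
            events.append((seg.start_h, seg.end_h, strain.sigma_dark, strain.delta_dark))
            continue
        E = effective_irradiance(strain, seg.wavelength_nm, seg.irradiance)
        if strain.history_factor > 0:
            sat = min(1.0, light_hours / strain.history_sat_h) if strain.history_sat_h > 0 else 1.0
            h_scale = (1.0 - strain.history_factor) + strain.history_factor * sat
        else:
            h_scale = 1.0
        delta_L = (
            strain.delta_max * h_scale * E / (strain.K_half + E) if E > 0 else 0.0
        )
        decay = strain.delta_dark + delta_L
        synth_low = strain.sigma_dark * strain.g_light
        react = strain.reactivation_after_h
        if react is not None and seg.duration_h > react:
            events.append((seg.start_h, seg.start_h + react, synth_low, decay))
            events.append((seg.start_h + react, seg.end_h, strain.sigma_dark, decay))
        else:
            events.append((seg.start_h, seg.end_h, synth_low, decay))
        light_hours += seg.duration_h
    return events


def _initial_reporter(strain: StrainParams, regime: LightRegime) -> float:
    """Default initial condition: light-adapted steady state.

    Cultures come out of growth light, so the reporter starts at the fixed
    point it would hold under the regime's first light segment (its dark
    fixed point if the regime never turns the lights on).
    """
    for seg in regime.segments:
        if seg.is_light:
            E = effective_irradiance(strain, seg.wavelength_nm, seg.irradiance)
            delta_L = strain.delta_max * E / (strain.K_half + E) if E > 0 else 0.0
            b = strain.delta_dark + delta_L
            a = strain.sigma_dark * strain.g_light
            return a / b if b > 0 else 0.0
    b = strain.delta_dark
    return strain.sigma_dark / b if b > 0 else 0.0


def integrate_reporter(
    strain: StrainParams,
    regime: LightRegime,
    initial_reporter: Optional[float] = None,
    internal_step_h: float = INTERNAL_STEP_H,
) -> tuple[np.ndarray, np.ndarray]:
    """Reporter trajectory on the dense internal grid (event-aligned RK4).

    Returns ``(t_nodes, R_nodes)``; nodes land exactly on every regime
    boundary so sub-grid pulses act through the integrated kinetics.
    """
    R0 = _initial_reporter(strain, regime) if initial_reporter is None else initial_reporter
    if R0 < 0:
        raise SimulationError(f"initial reporter level must be >= 0, got {R0}")
    ts = [np.array([0.0])]
    Rs = [np.array([R0], dtype=float)]
    R = float(R0)
    for t0, t1, a, b in _segment_events(strain, regime):
        n = max(1, int(np.ceil((t1 - t0) / internal_step_h - 1e-9)))
        h = (t1 - t0) / n
        k = np.arange(1, n + 1)
        if b > 0:
            m = _rk4_decay_factor(b, h)
            fp = a / b
            seg_R = fp + (R - fp) * m ** k
        else:
            seg_R = R + a * h * k
        ts.append(t0 + h * k)
        Rs.append(seg_R)
        R = float(seg_R[-1])
    t_nodes = np.concatenate(ts)
    R_nodes = np.concatenate(Rs)
    if not np.all(np.isfinite(R_nodes)):
        raise SimulationError("reporter integration produced non-finite values")
    # RK4's polynomial decay factor is positive for b*h < ~2.8; with the
    # 0.01 h step any decay rate below ~280/h keeps R >= 0. Guard anyway.
    np.clip(R_nodes, 0.0, None, out=R_nodes)
    return t_nodes, R_nodes


def _output_grid(regime: LightRegime, sampling_interval_h: float) -> np.ndarray:
    if sampling_interval_h <= 0:
        raise SimulationError("sampling_interval_h must be positive")
    n = int(np.floor(regime.total_duration_h / sampling_interval_h + 1e-9))
    return np.arange(n + 1) * sampling_interval_h


def _noise(rng: np.random.Generator, n: int, cv: float) -> np.ndarray:
    """Unit-mean multiplicative lognormal noise with coefficient of variation cv."""
    if cv < 0:
        raise SimulationError(f"noise_cv must be >= 0, got {cv}")
    if cv == 0:
        return np.ones(n)
    sigma = np.sqrt(np.log1p(cv * cv))
    return rng.lognormal(mean=-sigma * sigma / 2.0, sigma=sigma, size=n)


def simulate_roc15_trace(
    strain: StrainParams,
    regime: LightRegime,
    sampling_interval_h: float = 0.5,
    noise_cv: float = 0.0,
    background: float = 0.0,
    gain: float = 1.0,
    seed: int = 0,
    initial_reporter: Optional[float] = None,
    rng: Optional[np.random.Generator] = None,
) -> tuple[np.ndarray, np.ndarray]:
    """One well of the light-degradable reporter; returns ``(time_h, counts)``."""
    if background < 0 or gain <= 0:
        raise SimulationError("background must be >= 0 and gain > 0")
    t_nodes, R_nodes = integrate_reporter(strain, regime, initial_reporter)
    grid = _output_grid(regime, sampling_interval_h)
    R = np.interp(grid, t_nodes, R_nodes)
    counts = gain * R + background
    if rng is None:
        rng = np.random.default_rng(np.random.SeedSequence(seed))
    counts = counts * _noise(rng, counts.size, noise_cv)
    return grid, counts


def degraded_fraction_at_lights_on(
    strain: StrainParams,
    regime: LightRegime,
    initial_reporter: Optional[float] = None,
) -> dict[float, float]:
    """Fraction of reporter lost within 30 min of each dark-to-light transition.

    This is the drive term ``D`` coupling reporter degradation to clock
    resetting. Pulses shorter than 30 min contribute through the minimum the
    reporter reaches inside the window.
    """
    t_nodes, R_nodes = integrate_reporter(strain, regime, initial_reporter)
    out = {}
    for t_on in regime.lights_on_times():
        i0 = int(np.searchsorted(t_nodes, t_on - 1e-12))
        r_on = R_nodes[i0]
        i1 = int(np.searchsorted(t_nodes, t_on + RESET_WINDOW_H + 1e-12))
        window = R_nodes[i0 + 1 : max(i0 + 2, i1)]
        if window.size == 0 or r_on <= 0:
            out[t_on] = 0.0
            continue
        out[t_on] = float(max(0.0, (r_on - window.min()) / r_on))
    return out


@dataclass(frozen=True)
class OscillatorState:
    """Phase-only clock state; phase is reported modulo 2*pi."""

    phase_rad: float
    amplitude: float = 1.0

    def __post_init__(self) -> None:
        if self.amplitude < 0:
            raise SimulationError("amplitude must be >= 0")
        object.__setattr__(self, "phase_rad", float(self.phase_rad) % (2 * np.pi))


def simulate_circadian_trace(
    strain: StrainParams,
    regime: LightRegime,
    sampling_interval_h: float = 0.5,
    noise_cv: float = 0.0,
    background: float = 0.0,
    gain: float = 1.0,
    seed: int = 0,
    baseline_counts: float = 1000.0,
    drift_rate_per_h: float = 0.002,
    initial_phase_rad: Optional[float] = None,
    rng: Optional[np.random.Generator] = None,
) -> tuple[np.ndarray, np.ndarray]:
    """One well of the circadian (chloroplast-style) reporter.

    The oscillator free-runs at ``2*pi/tau_h`` and is kicked at every
    dark-to-light transition by ``reset_gain * sin(phi - phi_ref) * D``. With
    the default initialization the first lights-on lands on the PRC's stable
    zero (the entrained-dawn convention), so an unshifted entraining cycle
    applies no net kick. Counts are
    ``gain * B0 * (1 + amp * exp(-damping*t_DD) * cos(phi)) * drift + background``
    with a slow multiplicative drift ``exp(-drift_rate*t)`` included so that
    detrending has something to remove.
    """
    if background < 0 or gain <= 0 or baseline_counts <= 0:
        raise SimulationError("background >= 0, gain > 0 and baseline_counts > 0 required")
    omega = 2 * np.pi / strain.tau_h
    lights_on = regime.lights_on_times()
    if initial_phase_rad is None:
        phi0 = -omega * lights_on[0] if lights_on else 0.0
    else:
        phi0 = float(initial_phase_rad)

    D = degraded_fraction_at_lights_on(strain, regime) if lights_on else {}
    # accumulate discrete phase steps in regime order
    resets: list[tuple[float, float]] = []
    shift_acc = 0.0
    for t_on in lights_on:
        phi_at = phi0 + omega * t_on + shift_acc
        step = strain.reset_gain * np.sin(phi_at - PHI_REF) * D[t_on]
        shift_acc += step
        resets.append((t_on, shift_acc))

    grid = _output_grid(regime, sampling_interval_h)
    shift_at = np.zeros_like(grid)
    for t_on, acc in resets:
        shift_at[grid >= t_on] = acc
    phi = phi0 + omega * grid + shift_at

    dd0 = regime.dd_start_h()
    t_dd = np.clip(grid - dd0, 0.0, None)
    amp_eff = strain.amp * np.exp(-strain.damping_rate * t_dd)
    drift = np.exp(-drift_rate_per_h * grid)
    counts = gain * baseline_counts * (1.0 + amp_eff * np.cos(phi)) * drift + background
    if not np.all(np.isfinite(counts)):
        raise SimulationError("circadian trace produced non-finite values")
    if rng is None:
        rng = np.random.default_rng(np.random.SeedSequence(seed))
    counts = counts * _noise(rng, counts.size, noise_cv)
    return grid, counts


# -- plate-level simulation --------------------------------------------------


@dataclass(frozen=True)
class WellSpec:
    well_id: str
    strain: StrainParams
    regime: LightRegime
    replicate_index: int = 0
    genotype_class: Optional[str] = None
    regime_id: str = ""


@dataclass(frozen=True)
class PlateDesign:
    """A set of wells simulated on one shared sampling grid."""

    wells: tuple
    sampling_interval_h: float = 0.5
    noise_cv: float = 0.0
    background_counts: float = 0.0
    gain: float = 1.0
    seed: int = 0

    def __post_init__(self) -> None:
        object.__setattr__(self, "wells", tuple(self.wells))
        if self.sampling_interval_h <= 0:
            raise SimulationError("sampling_interval_h must be positive")
        if self.noise_cv < 0 or self.background_counts < 0 or self.gain <= 0:
            raise SimulationError("invalid noise/background/gain")
        ids = [w.well_id for w in self.wells]
        dups = sorted({i for i in ids if ids.count(i) > 1})
        if dups:
            raise SimulationError(f"duplicate well_id(s): {dups}")
        durations = {round(w.regime.total_duration_h, 9) for w in self.wells}
        if len(durations) > 1:
            raise SimulationError(
                f"all wells in a plate must share a regime duration, got {sorted(durations)}"
            )


def _well_rng(seed: int, well_id: str) -> np.random.Generator:
    """Per-well stream keyed on (seed, well_id): insertion-order invariant."""
    key = zlib.crc32(str(well_id).encode("utf-8"))
    return np.random.default_rng(np.random.SeedSequence((int(seed), key)))


def _regime_light_meta(regime: LightRegime) -> tuple:
    """(wavelength, irradiance) metadata summarizing a regime's light."""
    mono = [s for s in regime.segments if s.is_light and not isinstance(s.wavelength_nm, str)]
    if mono:
        return mono[0].wavelength_nm, mono[0].irradiance
    lit = [s for s in regime.segments if s.is_light]
    if lit:
        return "white", lit[0].irradiance
    return "dark", 0.0


def simulate_plate(design: PlateDesign) -> TraceSet:
    """Simulate every well of a design onto one shared grid.

    Reproducible from the design seed; per-well random streams are derived
    from ``(seed, well_id)`` so results do not depend on well order.
    """
    grid = None
    columns: dict[str, np.ndarray] = {}
    meta_rows = []
    for w in design.wells:
        rng = _well_rng(design.seed, w.well_id)
        sim = (
            simulate_circadian_trace
            if w.strain.reporter == "chloroplast"
            else simulate_roc15_trace
        )
        t, counts = sim(
            w.strain,
            w.regime,
            sampling_interval_h=design.sampling_interval_h,
            noise_cv=design.noise_cv,
            background=design.background_counts,
            gain=design.gain,
            rng=rng,
        )
        if grid is None:
            grid = t
        columns[w.well_id] = counts
        lam, irr = _regime_light_meta(w.regime)
        meta_rows.append(
            {
                "well": w.well_id,
                "strain_label": w.strain.name,
                "genotype_class": w.genotype_class or w.strain.name,
                "regime_id": w.regime_id,
                "wavelength_nm": lam,
                "irradiance": irr,
                "replicate_index": w.replicate_index,
            }
        )
    if grid is None:
        grid = np.array([])
    meta = pd.DataFrame(meta_rows).set_index("well") if meta_rows else pd.DataFrame(
        index=pd.Index([], name="well")
    )
    counts_df = pd.DataFrame(columns, index=grid)
    return TraceSet(grid, counts_df, meta)
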