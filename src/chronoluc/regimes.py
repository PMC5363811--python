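"""Light regimes: ordered dark/light segments driving simulation and analysis.

A :class:`LightRegime` is a gap-free, overlap-free tiling of ``[0, T]`` hours
by dark and light segments. Light segments carry a nominal wavelength (nm, or
``"white"``) and an irradiance in umol m-2 s-1; dark segments have irradiance
zero. Times are hours from the start of the recording throughout the package.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Optional, Union

from .errors import RegimeError

Wavelength = Union[int, float, str]  # nm, or the string "white"

DARK = "dark"
LIGHT = "light"

_TOL = 1e-9


@dataclass(frozen=True)
class Segment:
    start_h: float
    end_h: float
    label: str  # "dark" | "light"
    wavelength_nm: Optional[Wavelength] = None
    irradiance: float = 0.0

    def __post_init__(self) -> None:
        if self.label not in (DARK, LIGHT):
            raise RegimeError(f"segment label must be 'dark' or 'light', got {self.label!r}")
        if not self.end_h > self.start_h:
            raise RegimeError(
                f"segment must have start_h < end_h, got [{self.start_h}, {self.end_h}]"
            )
        if self.irradiance < 0:
            raise RegimeError(f"irradiance must be >= 0, got {self.irradiance}")
        if self.label == DARK and self.irradiance != 0:
            raise RegimeError(
                f"dark segment [{self.start_h}, {self.end_h}] must have irradiance 0, "
                f"got {self.irradiance}"
            )
        if self.label == LIGHT and self.wavelength_nm is None:
            raise RegimeError(
                f"light segment [{self.start_h}, {self.end_h}] needs a wavelength "
                "(a number in nm, or 'white')"
            )

    @property
    def duration_h(self) -> float:
        return self.end_h - self.start_h

    @property
    def is_light(self) -> bool:
        return self.label == LIGHT


@dataclass(frozen=True)
class LightRegime:
    """An ordered, validated list of segments tiling ``[0, total_duration_h]``."""

    segments: tuple = field(default_factory=tuple)

    def __post_init__(self) -> None:
        segs = tuple(self.segments)
        if not segs:
            raise RegimeError("a light regime needs at least one segment")
        object.__setattr__(self, "segments", segs)
        if abs(segs[0].start_h) > _TOL:
            raise RegimeError(f"first segment must start at 0 h, got {segs[0].start_h}")
        for prev, nxt in zip(segs, segs[1:]):
            if nxt.start_h - prev.end_h > _TOL:
                raise RegimeError(
                    f"gap between segments: [{prev.start_h}, {prev.end_h}] then "
                    f"[{nxt.start_h}, {nxt.end_h}]"
                )
            if prev.end_h - nxt.start_h > _TOL:
                raise RegimeError(
                    f"overlapping segments: [{prev.start_h}, {prev.end_h}] and "
                    f"[{nxt.start_h}, {nxt.end_h}]"
                )

    @property
    def total_duration_h(self) -> float:
        return self.segments[-1].end_h

    def segment_at(self, t_h: float) -> Segment:
        """Segment containing time ``t_h`` (right-open intervals; the final
        segment is closed on the right)."""
        if t_h < -_TOL or t_h - self.total_duration_h > _TOL:
            raise RegimeError(f"time {t_h} h outside regime [0, {self.total_duration_h}]")
        for seg in self.segments:
            if t_h < seg.end_h - _TOL:
                return seg
        return self.segments[-1]

    def lights_on_times(self) -> list[float]:
        """Times of every dark-to-light transition, in hours."""
        out = []
        for prev, nxt in zip(self.segments, self.segments[1:]):
            if prev.label == DARK and nxt.label == LIGHT:
                out.append(nxt.start_h)
        if self.segments[0].is_light:
            # a regime that opens in light has no observable transition at 0
            pass
        return out

    def dd_start_h(self) -> float:
        """Start of the final stretch of constant darkness (0 if never lit)."""
        last_light_end = 0.0
        for seg in self.segments:
            if seg.is_light:
                last_light_end = seg.end_h
        return last_light_end


def constant_darkness(duration_h: float) -> LightRegime:
    return LightRegime((Segment(0.0, float(duration_h), DARK),))


def cycles(
    dark_h: float,
    light_h: float,
    n_cycles: int,
    wavelength: Wavelength = "white",
    irradiance: float = 1.0,
    dd_h: float = 0.0,
) -> LightRegime:
    """``n_cycles`` of dark/light (dark first), optionally followed by DD."""
    segs: list[Segment] = []
    t = 0.0
    for _ in range(n_cycles):
        segs.append(Segment(t, t + dark_h, DARK))
        t += dark_h
        segs.append(Segment(t, t + light_h, LIGHT, wavelength, irradiance))
        t += light_h
    if dd_h > 0:
        segs.append(Segment(t, t + dd_h, DARK))
    return LightRegime(tuple(segs))


def screen_regime(
    dark_h: float = 6.0,
    light_h: float = 18.0,
    wavelength: Wavelength = "white",
    irradiance: float = 1.0,
) -> LightRegime:
    """The two-cycle dark/light screening schedule (6 h dark / 18 h light)."""
    return cycles(dark_h, light_h, 2, wavelength, irradiance)


def pulse_protocol(
    dark_adapt_h: float,
    pulse_h: float,
    wavelength: Wavelength,
    irradiance: float,
    post_dark_h: float,
) -> LightRegime:
    """Dark adaptation, a short light pulse, then darkness.

    Used for acute-response assays (e.g. 3 h dark, a 5 min monochromatic
    pulse, 3 h dark).
    """
    t1 = float(dark_adapt_h)
    t2 = t1 + float(pulse_h)
    return LightRegime(
        (
            Segment(0.0, t1, DARK),
            Segment(t1, t2, LIGHT, wavelength, irradiance),
            Segment(t2, t2 + float(post_dark_h), DARK),
        )
    )


def entrain_pulse_dd(
    entrain_dark_h: float = 12.0,
    entrain_light_h: float = 12.0,
    dd_pulse_at_h: Optional[float] = 34.0,
    pulse_min: float = 5.0,
    wavelength: Wavelength = 660,
    irradiance: float = 2.0,
    dd_total_h: float = 120.0,
    entrain_wavelength: Wavelength = "white",
    entrain_irradiance: float = 1.0,
) -> LightRegime:
    """One dark/light entrainment cycle, release into DD, optional light pulse.

    ``dd_pulse_at_h`` counts hours into DD; ``None`` gives the dark control.
    """
    segs = [
        Segment(0.0, entrain_dark_h, DARK),
        Segment(
            entrain_dark_h,
            entrain_dark_h + entrain_light_h,
            LIGHT,
            entrain_wavelength,
            entrain_irradiance,
        ),
    ]
    dd0 = entrain_dark_h + entrain_light_h
    dd_end = dd0 + dd_total_h
    if dd_pulse_at_h is None:
        segs.append(Segment(dd0, dd_end, DARK))
    else:
        p0 = dd0 + dd_pulse_at_h
        p1 = p0 + pulse_min / 60.0
        if p1 >= dd_end:
            raise RegimeError("pulse extends past the end of the DD window")
        segs.append(Segment(dd0, p0, DARK))
        segs.append(Segment(p0, p1, LIGHT, wavelength, irradiance))
        segs.append(Segment(p1, dd_end, DARK))
    return LightRegime(tuple(segs))


def reentrainment_protocol(
    advance_h: float = 5.0,
    n_shifted_cycles: int = 2,
    wavelength: Optional[Wavelength] = 660,
    irradiance: float = 2.0,
    dd_h: float = 120.0,
    entrain_dark_h: float = 12.0,
    entrain_light_h: float = 12.0,
    entrain_irradiance: float = 1.0,
) -> LightRegime:
    """Entrainment cycle (white), then phase-advanced LD cycles, then DD.

    ``wavelength=None`` gives the dark control: the shifted cycles are
    replaced by darkness of the same total length, so control and treated
    regimes share the grid.
    """
    segs = [
        Segment(0.0, entrain_dark_h, DARK),
        Segment(entrain_dark_h, entrain_dark_h + entrain_light_h, LIGHT, "white", entrain_irradiance),
    ]
    t = entrain_dark_h + entrain_light_h
    period = entrain_dark_h + entrain_light_h
    # the first shifted dawn comes `advance_h` earlier than the native dawn
    first_dark = entrain_dark_h - advance_h
    if first_dark <= 0:
        raise RegimeError("advance_h must be smaller than the entraining dark phase")
    shifted_len = first_dark + entrain_light_h + (n_shifted_cycles - 1) * period
    if wavelength is None:
        segs.append(Segment(t, t + shifted_len + dd_h, DARK))
        return LightRegime(tuple(segs))
    segs.append(Segment(t, t + first_dark, DARK))
    t += first_dark
    for i in range(n_shifted_cycles):
        segs.append(Segment(t, t + entrain_light_h, LIGHT, wavelength, irradiance))
        t += entrain_light_h
        if i < n_shifted_cycles - 1:
            segs.append(Segment(t, t + entrain_dark_h, DARK))
            t += entrain_dark_h
    segs.append(Segment(t, t + dd_h, DARK))
    return LightRegime(tuple(segs))
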