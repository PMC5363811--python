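"""Generative strain parameters: light-input pathways and reporter kinetics.

The simulator assumes two wavelength-selective input pathways feeding
light-induced degradation of a night-accumulating reporter protein:

* a red/violet-dominated pathway (the "CSL-like" pathway, knocked out in the
  ``csl`` preset), and
* a blue-peaked pathway.

The effective irradiance a strain sees at wavelength ``lam`` and photon flux
``I`` is ``E = c_csl * A_csl(lam) * I + c_blue * A_blue(lam) * I`` where the
``A`` are relative action values in [0, 1] and the ``c`` are coupling
coefficients. All preset numbers below are calibration choices of this
package, not measured values.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Mapping, Union

from .errors import SimulationError

Wavelength = Union[int, float, str]

#: default monochromatic wavelength grid (nm)
DEFAULT_WAVELENGTHS = (360, 410, 460, 510, 660, 710, 760)


@dataclass(frozen=True)
class PathwaySpectrum:
    """Relative action of one input pathway on a fixed wavelength grid.

    A non-null spectrum is normalized so its maximum is 1; the all-zero
    spectrum is allowed and models a knocked-out pathway.
    """

    relative_action: Mapping[float, float]

    def __post_init__(self) -> None:
        ra = {float(k): float(v) for k, v in self.relative_action.items()}
        if not ra:
            raise SimulationError("a pathway spectrum needs at least one wavelength")
        if any(v < 0 for v in ra.values()):
            raise SimulationError("relative action values must be >= 0")
        top = max(ra.values())
        if top > 0 and abs(top - 1.0) > 1e-9:
            raise SimulationError(
                f"a non-null pathway spectrum must have maximum 1, got {top}"
            )
        object.__setattr__(self, "relative_action", ra)

    @property
    def wavelengths_nm(self) -> tuple:
        return tuple(sorted(self.relative_action))

    @property
    def is_null(self) -> bool:
        return all(v == 0 for v in self.relative_action.values())

    def action(self, wavelength: Wavelength) -> float:
        """Relative action at a wavelength; ``"white"`` averages the grid."""
        if isinstance(wavelength, str):
            if wavelength != "white":
                raise SimulationError(f"unknown wavelength label {wavelength!r}")
            vals = list(self.relative_action.values())
            return sum(vals) / len(vals)
        lam = float(wavelength)
        try:
            return self.relative_action[lam]
        except KeyError:
            known = ", ".join(str(int(w)) for w in self.wavelengths_nm)
            raise SimulationError(
                f"wavelength {wavelength} nm not on the pathway grid ({known})"
            ) from None


# invented calibration spectra (shapes chosen to mimic the observed
# red/violet-dominated vs blue-peaked sensitivity patterns)
CSL_PATHWAY = PathwaySpectrum(
    {360: 0.55, 410: 0.80, 460: 0.05, 510: 0.35, 660: 1.00, 710: 0.05, 760: 0.0}
)
BLUE_PATHWAY = PathwaySpectrum(
    {360: 0.25, 410: 0.30, 460: 1.00, 510: 0.55, 660: 0.0, 710: 0.0, 760: 0.0}
)
NULL_PATHWAY = PathwaySpectrum({w: 0.0 for w in DEFAULT_WAVELENGTHS})


@dataclass(frozen=True)
class StrainParams:
    """Generative parameters of one genotype.

    Rates are per hour; ``sigma_dark`` is in count-equivalents per hour.
    ``g_light`` multiplies synthesis under light (transcript downregulation);
    ``reactivation_after_h`` optionally restores full synthesis after that
    many hours of continuous light (the Type-2 archetype). ``history_factor``
    scales light-induced degradation by prior light exposure: 0 means the
    response is unconditional, 1 means it is absent until the culture has
    accumulated ``history_sat_h`` light-hours.
    """

    name: str
    sigma_dark: float = 100.0
    g_light: float = 0.2
    delta_dark: float = 0.15
    delta_max: float = 25.0
    K_half: float = 1.0
    c_csl: float = 1.0
    c_blue: float = 0.5
    spectrum_csl: PathwaySpectrum = CSL_PATHWAY
    spectrum_blue: PathwaySpectrum = BLUE_PATHWAY
    reset_gain: float = 1.2
    tau_h: float = 24.0
    amp: float = 0.5
    damping_rate: float = 0.003
    history_factor: float = 0.0
    history_sat_h: float = 12.0
    reactivation_after_h: float | None = None
    reporter: str = "roc15"  # "roc15" (nuclear fusion) or "chloroplast"

    def __post_init__(self) -> None:
        for attr in (
            "sigma_dark",
            "delta_dark",
            "delta_max",
            "K_half",
            "c_csl",
            "c_blue",
            "reset_gain",
            "tau_h",
            "damping_rate",
            "history_sat_h",
        ):
            if getattr(self, attr) < 0:
                raise SimulationError(f"{attr} must be >= 0, got {getattr(self, attr)}")
        for attr in ("g_light", "amp", "history_factor"):
            v = getattr(self, attr)
            if not 0.0 <= v <= 1.0:
                raise SimulationError(f"{attr} must be in [0, 1], got {v}")
        if self.tau_h == 0:
            raise SimulationError("tau_h must be positive")
        if self.reporter not in ("roc15", "chloroplast"):
            raise SimulationError(f"unknown reporter kind {self.reporter!r}")

    def with_(self, **changes) -> "StrainParams":
        return replace(self, **changes)


def _wt(**kw) -> StrainParams:
    return StrainParams(name=kw.pop("name", "WT"), **kw)


#: versioned registry of genotype presets. All numbers are invented
#: calibration choices that reproduce the qualitative archetype behaviors;
#: none are measured values.
PRESET_VERSION = "1"

PRESETS: dict[str, StrainParams] = {
    # wild type: both pathways coupled
    "WT": _wt(),
    # csl: red/violet pathway knocked out, blue pathway mildly sensitized
    "csl": _wt(name="csl", c_csl=0.0, c_blue=0.6, spectrum_csl=NULL_PATHWAY),
    # roc114-like: no light-induced degradation at all
    "roc114": _wt(name="roc114", delta_max=0.0),
    # Type 1 archetype: synthesis not shut off by light, degradation weak
    "type1": _wt(name="type1", g_light=1.0, delta_max=2.0),
    # Type 2 archetype: synthesis re-activates after 6 h of continuous light
    "type2": _wt(name="type2", reactivation_after_h=6.0),
    # Type 3 archetype (b19/b20-like): acute response conditional on prior
    # light exposure -- absent in the first cycle, full in the second
    "type3": _wt(name="type3", history_factor=1.0),
    # chloroplast circadian-reporter versions (same input pathways)
    "WT-cbr": _wt(name="WT-cbr", reporter="chloroplast"),
    "csl-cbr": _wt(
        name="csl-cbr",
        c_csl=0.0,
        c_blue=0.6,
        spectrum_csl=NULL_PATHWAY,
        reporter="chloroplast",
    ),
}


def get_preset(name: str) -> StrainParams:
    try:
        return PRESETS[name]
    except KeyError:
        known = ", ".join(sorted(PRESETS))
        raise SimulationError(f"unknown strain preset {name!r} (known: {known})") from None
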