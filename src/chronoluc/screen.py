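"""Forward-screen feature extraction and phenotype classification.

Under the two-cycle dark/light screening regime, each well is summarized by
per-cycle acute drops at lights-on, a dark-accumulation ratio, and a midday
rebound ratio, then classified into mutant archetypes:

* Type 3 -- no or very weak acute response at lights-on (checked first; a
  cycle-2 response much stronger than cycle 1 sets the conditional flag);
* Type 1 -- insufficient decline at lights-on, levels staying high in light;
* Type 2 -- normal acute response but failure to keep levels low through the
  mid-to-late day phase;
* WT-like otherwise.

The published screen typed hits qualitatively; every numeric threshold here
is an explicit, configurable calibration artifact, echoed verbatim in each
call's provenance so downstream tables are self-describing.
"""

from __future__ import annotations

from dataclasses import dataclass, asdict, field
from typing import Sequence

import numpy as np
import pandas as pd

from .errors import AnalysisError
from .photoresponse import acute_sensitivity
from .preprocess import centered_smooth
from .regimes import LightRegime
from .traceset import TraceSet


@dataclass(frozen=True)
class ScreenThresholds:
    """Classifier cut-offs (calibrated once against the simulator archetypes)."""

    type3_drop_max: float = 20.0  # cycle-1 acute drop below this = "no response"
    type1_drop_max: float = 60.0  # cycle-1 acute drop below this = "insufficient"
    type2_rebound_min: float = 2.0  # midday rebound ratio above this = Type 2
    conditional_margin: float = 15.0  # cycle2 - cycle1 drop margin for the flag
    acute_window_h: float = 1.0  # search window for the lights-on drop
    smoothing_h: float = 0.5  # pre-smoothing span for feature extraction


@dataclass(frozen=True)
class ScreenFeatures:
    well_id: str
    acute_drop_cycle1: float
    acute_drop_cycle2: float
    dark_accumulation_ratio: float
    midday_rebound_ratio: float


@dataclass(frozen=True)
class ScreenCall:
    well_id: str
    phenotype: str  # WT-like | Type1 | Type2 | Type3
    features: ScreenFeatures
    conditional_flag: bool
    thresholds: ScreenThresholds

    def as_record(self) -> dict:
        rec = {"well": self.well_id, "class": self.phenotype, "conditional": self.conditional_flag}
        rec.update({k: v for k, v in asdict(self.features).items() if k != "well_id"})
        rec.update({f"threshold_{k}": v for k, v in asdict(self.thresholds).items()})
        return rec


def _two_cycle_transitions(regime: LightRegime) -> tuple:
    ons = regime.lights_on_times()
    if len(ons) != 2:
        raise AnalysisError(
            f"screening regime must have exactly two dark->light transitions, got {len(ons)}"
        )
    return tuple(ons)


def extract_screen_features(
    time_h: np.ndarray,
    values: np.ndarray,
    regime: LightRegime,
    well_id: str = "",
    acute_window_h: float = 1.0,
    smoothing_h: float = 0.5,
) -> ScreenFeatures:
    """Per-well screen features under a two-cycle dark/light regime.

    * acute drop per cycle: :func:`~chronoluc.photoresponse.acute_sensitivity`
      at each lights-on;
    * dark accumulation ratio: level at the end of the first dark phase over
      the level at its start;
    * midday rebound ratio, per light phase: mean level over the second half
      of the phase divided by the minimum over its first 2 h, averaged over
      the two cycles.

    The trace is lightly smoothed (centered moving average, ``smoothing_h``)
    before the features are read off: the single pre-dawn reference sample
    would otherwise pass its full measurement noise into every ratio.
    """
    t = np.asarray(time_h, dtype=float)
    y = np.asarray(values, dtype=float)
    if np.isnan(y).any():
        raise AnalysisError(f"well {well_id!r} has missing values")
    if smoothing_h > 0:
        y = centered_smooth(t, y, smoothing_h)
    on1, on2 = _two_cycle_transitions(regime)
    drop1 = acute_sensitivity(t, y, on1, acute_window_h)
    drop2 = acute_sensitivity(t, y, on2, acute_window_h)

    first_dark = next(s for s in regime.segments if not s.is_light)
    i_start = int(np.searchsorted(t, first_dark.start_h - 1e-9, side="left"))
    i_end = int(np.searchsorted(t, first_dark.end_h + 1e-9, side="right")) - 1
    start_level = y[min(i_start, t.size - 1)]
    end_level = y[max(0, min(i_end, t.size - 1))]
    dark_ratio = float(end_level / start_level) if start_level > 0 else np.inf

    rebounds = []
    for seg in regime.segments:
        if not seg.is_light:
            continue
        half = seg.start_h + seg.duration_h / 2.0
        early = (t > seg.start_h + 1e-9) & (t <= min(seg.start_h + 2.0, seg.end_h) + 1e-9)
        late = (t >= half - 1e-9) & (t <= seg.end_h + 1e-9)
        if not early.any() or not late.any():
            raise AnalysisError(f"light phase [{seg.start_h}, {seg.end_h}] unsampled")
        floor = float(np.min(y[early]))
        rebounds.append(float(np.mean(y[late])) / floor if floor > 0 else np.inf)
    rebound = float(np.mean(rebounds)) if rebounds else np.nan

    feats = ScreenFeatures(well_id, drop1, drop2, dark_ratio, rebound)
    for name, v in asdict(feats).items():
        if name != "well_id" and not np.isfinite(v):
            raise AnalysisError(f"non-finite screen feature {name} in well {well_id!r}")
    return feats


def classify_phenotype(
    features: ScreenFeatures, thresholds: ScreenThresholds = ScreenThresholds()
) -> ScreenCall:
    """Rule cascade Type3 -> Type1 -> Type2 -> WT-like.

    Absence of the acute response is the most specific phenotype, so it is
    checked first; the conditional flag marks responses that appear only
    after light exposure (cycle 2 much stronger than cycle 1).
    """
    th = thresholds
    f = features
    if f.acute_drop_cycle1 < th.type3_drop_max:
        conditional = bool(
            (f.acute_drop_cycle2 - f.acute_drop_cycle1) > th.conditional_margin
        )
        return ScreenCall(f.well_id, "Type3", f, conditional, th)
    if f.acute_drop_cycle1 < th.type1_drop_max:
        return ScreenCall(f.well_id, "Type1", f, False, th)
    if f.midday_rebound_ratio > th.type2_rebound_min:
        return ScreenCall(f.well_id, "Type2", f, False, th)
    return ScreenCall(f.well_id, "WT-like", f, False, th)


def screen_plate(
    ts: TraceSet,
    regime: LightRegime,
    thresholds: ScreenThresholds = ScreenThresholds(),
) -> pd.DataFrame:
    """Classify every well of a screening plate; returns one row per well."""
    records = []
    for well in ts.wells:
        feats = extract_screen_features(
            ts.time_h, ts.well(well), regime, well_id=well,
            acute_window_h=thresholds.acute_window_h,
            smoothing_h=thresholds.smoothing_h,
        )
        records.append(classify_phenotype(feats, thresholds).as_record())
    return pd.DataFrame(records)


def complementation_rate(calls: Sequence[bool]) -> tuple[int, float]:
    """Count of positive calls and their fraction of all calls."""
    calls = list(calls)
    if not calls:
        raise AnalysisError("complementation_rate needs at least one call")
    count = sum(bool(c) for c in calls)
    return count, count / len(calls)
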