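"""Reading and writing trace sets and light-regime configuration files.

Traces are stored exclusively as long (tidy) CSV with required columns
``well``, ``time_h``, ``counts`` and any number of metadata columns. Regimes
are YAML (or JSON, a YAML subset) documents::

    segments:
      - {start_h: 0, end_h: 6, label: dark}
      - {start_h: 6, end_h: 24, label: light, wavelength_nm: white, irradiance: 1.0}

Times are decimal hours from the start of the recording; no clock times.
"""

from __future__ import annotations

import os
from typing import Union

import pandas as pd
import yaml

from .errors import RegimeError, SchemaError
from .regimes import LightRegime, Segment
from .traceset import TraceSet


def read_traceset(path: Union[str, os.PathLike]) -> TraceSet:
    """Read a long-format CSV into a validated :class:`TraceSet`.

    Rows with non-numeric counts become flagged missing values; times are
    sorted and de-duplicated per well. Wells must share one time grid.
    """
    df = pd.read_csv(path, dtype={"well": str})
    return TraceSet.from_long(df)


def write_traceset(ts: TraceSet, path: Union[str, os.PathLike]) -> None:
    """Write a TraceSet as long CSV (stable column order, NaN -> empty field)."""
    ts.to_long().to_csv(path, index=False)


def _segment_from_mapping(d: dict, i: int) -> Segment:
    if not isinstance(d, dict):
        raise RegimeError(f"segment {i} is not a mapping: {d!r}")
    try:
        start = float(d["start_h"])
        end = float(d["end_h"])
        label = str(d["label"])
    except KeyError as e:
        raise RegimeError(f"segment {i} is missing required key {e.args[0]!r}") from None
    lam = d.get("wavelength_nm")
    if isinstance(lam, str) and lam != "white":
        raise RegimeError(
            f"segment {i}: wavelength_nm must be a number or 'white', got {lam!r}"
        )
    irr = float(d.get("irradiance", 0.0))
    return Segment(start, end, label, lam, irr)


def read_regime(path: Union[str, os.PathLike]) -> LightRegime:
    """Read and validate a light-regime configuration (YAML or JSON)."""
    with open(path) as fh:
        doc = yaml.safe_load(fh)
    if not isinstance(doc, dict) or "segments" not in doc:
        raise RegimeError(f"{path}: regime file needs a top-level 'segments' list")
    raw = doc["segments"]
    if not isinstance(raw, list) or not raw:
        raise RegimeError(f"{path}: 'segments' must be a non-empty list")
    segments = [_segment_from_mapping(d, i) for i, d in enumerate(raw)]
    regime = LightRegime(tuple(segments))
    if "total_duration_h" in doc:
        stated = float(doc["total_duration_h"])
        if abs(stated - regime.total_duration_h) > 1e-9:
            raise RegimeError(
                f"{path}: stated total_duration_h {stated} != segment span "
                f"{regime.total_duration_h}"
            )
    return regime


def write_regime(regime: LightRegime, path: Union[str, os.PathLike]) -> None:
    doc = {
        "total_duration_h": regime.total_duration_h,
        "segments": [
            {
                "start_h": s.start_h,
                "end_h": s.end_h,
                "label": s.label,
                **(
                    {"wavelength_nm": s.wavelength_nm, "irradiance": s.irradiance}
                    if s.is_light
                    else {}
                ),
            }
            for s in regime.segments
        ],
    }
    with open(path, "w") as fh:
        yaml.safe_dump(doc, fh, sort_keys=False)
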