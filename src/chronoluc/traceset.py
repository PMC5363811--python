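"""The TraceSet container: a shared time grid plus per-well counts and metadata.

Counts live in a wide pandas DataFrame (rows = time points, columns = wells);
missing measurements are NaN. Well metadata is a second DataFrame indexed by
well id. The long (tidy) CSV serialization lives in :mod:`chronoluc.io`.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Optional, Sequence

import numpy as np
import pandas as pd

from .errors import AlignmentError, SchemaError

#: metadata columns written first, in this order, when serializing
META_COLUMNS = (
    "strain_label",
    "genotype_class",
    "regime_id",
    "wavelength_nm",
    "irradiance",
    "replicate_index",
)


@dataclass
class TraceSet:
    """Per-well bioluminescence time series on a common grid.

    Parameters
    ----------
    time_h
        Strictly increasing time grid in hours from the start of recording.
    counts
        Wide frame, one column per well, aligned to ``time_h``. Values are
        nonnegative counts or NaN for missing measurements.
    meta
        One row per well (index = well id). Arbitrary extra columns are kept.
    """

    time_h: np.ndarray
    counts: pd.DataFrame
    meta: pd.DataFrame

    def __post_init__(self) -> None:
        self.time_h = np.asarray(self.time_h, dtype=float)
        if self.time_h.ndim != 1:
            raise SchemaError("time_h must be one-dimensional")
        if self.time_h.size and np.any(np.diff(self.time_h) <= 0):
            raise SchemaError("time_h must be strictly increasing")
        if len(self.counts) != self.time_h.size:
            raise AlignmentError(
                f"counts has {len(self.counts)} rows but the grid has "
                f"{self.time_h.size} points"
            )
        if self.counts.columns.duplicated().any():
            dups = self.counts.columns[self.counts.columns.duplicated()].tolist()
            raise SchemaError(f"duplicate well ids: {dups}")
        with np.errstate(invalid="ignore"):
            if (self.counts.to_numpy(dtype=float) < 0).any():
                raise SchemaError("counts must be >= 0 or missing (NaN)")
        missing_meta = [w for w in self.counts.columns if w not in self.meta.index]
        if missing_meta:
            # tolerate absent metadata by creating empty rows
            add = pd.DataFrame(index=pd.Index(missing_meta, name=self.meta.index.name))
            self.meta = pd.concat([self.meta, add])
        self.meta = self.meta.loc[list(self.counts.columns)]
        self.counts.index = pd.Index(self.time_h, name="time_h")

    # -- basic introspection -------------------------------------------------

    @property
    def wells(self) -> list:
        return list(self.counts.columns)

    @property
    def n_wells(self) -> int:
        return self.counts.shape[1]

    def __len__(self) -> int:
        return self.time_h.size

    def well(self, well_id) -> np.ndarray:
        """Counts of one well as a float array aligned to ``time_h``."""
        return self.counts[well_id].to_numpy(dtype=float)

    def has_missing(self, well_id) -> bool:
        return bool(self.counts[well_id].isna().any())

    # -- manipulation --------------------------------------------------------

    def select(self, wells: Optional[Iterable] = None, **meta_filters) -> "TraceSet":
        """Subset by explicit well ids and/or metadata equality filters."""
        keep = pd.Series(True, index=self.meta.index)
        if wells is not None:
            keep &= self.meta.index.isin(list(wells))
        for col, val in meta_filters.items():
            if col not in self.meta.columns:
                raise SchemaError(f"no metadata column {col!r}")
            keep &= self.meta[col] == val
        ids = list(self.meta.index[keep])
        return type(self)(
            self.time_h.copy(), self.counts[ids].copy(), self.meta.loc[ids].copy()
        )

    def with_counts(self, counts: pd.DataFrame) -> "TraceSet":
        return type(self)(self.time_h.copy(), counts, self.meta.copy())

    def groupby_meta(self, keys: Sequence[str]):
        """Yield ``(group_key, TraceSet)`` pairs grouped on metadata columns."""
        for col in keys:
            if col not in self.meta.columns:
                raise SchemaError(f"no metadata column {col!r}")
        for key, sub in self.meta.groupby(list(keys), dropna=False, sort=True):
            ids = list(sub.index)
            yield key, self.select(wells=ids)

    # -- conversion ----------------------------------------------------------

    def to_long(self) -> pd.DataFrame:
        """Long (tidy) frame: well, time_h, counts, then metadata columns."""
        meta_cols = [c for c in META_COLUMNS if c in self.meta.columns]
        extra = [c for c in self.meta.columns if c not in META_COLUMNS]
        records = []
        for well in self.wells:
            df = pd.DataFrame(
                {"well": well, "time_h": self.time_h, "counts": self.well(well)}
            )
            for c in meta_cols + extra:
                df[c] = self.meta.at[well, c]
            records.append(df)
        if not records:
            return pd.DataFrame(columns=["well", "time_h", "counts", *meta_cols, *extra])
        return pd.concat(records, ignore_index=True)

    @classmethod
    def from_long(cls, df: pd.DataFrame) -> "TraceSet":
        """Build from a long frame (columns ``well``, ``time_h``, ``counts``).

        Times are sorted and de-duplicated per well (last record wins);
        non-numeric counts become missing values. Wells must share one grid.
        """
        required = {"well", "time_h", "counts"}
        missing = sorted(required - set(df.columns))
        if missing:
            raise SchemaError(f"missing required column(s): {missing}")
        if df.empty:
            meta = pd.DataFrame(index=pd.Index([], name="well"))
            return cls(np.array([]), pd.DataFrame(), meta)
        df = df.copy()
        df["time_h"] = pd.to_numeric(df["time_h"], errors="raise")
        df["counts"] = pd.to_numeric(df["counts"], errors="coerce")
        df = df.sort_values(["well", "time_h"]).drop_duplicates(
            ["well", "time_h"], keep="last"
        )
        wide = df.pivot(index="time_h", columns="well", values="counts")
        # wells whose grids disagree show up as NaN blocks exactly where the
        # other grid has points; detect rows a well never measured
        grids = df.groupby("well")["time_h"].apply(lambda s: tuple(s.to_numpy()))
        ref_well = grids.index[0]
        bad = [w for w in grids.index if grids[w] != grids[ref_well]]
        if bad:
            raise AlignmentError(
                f"wells {bad} are not on the same time grid as {ref_well!r}"
            )
        meta_cols = [c for c in df.columns if c not in ("well", "time_h", "counts")]
        meta = (
            df.groupby("well")[meta_cols].first()
            if meta_cols
            else pd.DataFrame(index=grids.index)
        )
        meta.index.name = "well"
        # preserve first-appearance well order
        order = list(dict.fromkeys(df["well"]))
        wide = wide[order]
        return cls(wide.index.to_numpy(dtype=float), wide, meta.loc[order])


@dataclass
class DetrendedTraceSet(TraceSet):
    """A TraceSet of unitless ratios plus an edge mask.

    ``edge_mask`` is True where the centered moving-average window was
    truncated by the record edge (the value was computed from the available
    asymmetric window). ``skipped_wells`` lists wells dropped because a
    required window contained missing values.
    """

    edge_mask: pd.DataFrame = None
    skipped_wells: tuple = ()

    def __post_init__(self) -> None:
        super().__post_init__()
        if self.edge_mask is None:
            self.edge_mask = pd.DataFrame(
                False, index=self.counts.index, columns=self.counts.columns
            )

    @property
    def values(self) -> pd.DataFrame:
        """Alias: detrended values are ratios, not raw counts."""
        return self.counts
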