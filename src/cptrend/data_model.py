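"""Quarterly panel data container and calendar/time-index conversion.

Consumption panels are long-format tables with one record per (country,
quarter): the value is a consumption rate in DDD (defined daily doses) per
1000 inhabitants per day.  The integer time index counts quarters from a
configurable calendar origin (time index 1 = the origin quarter; the
default origin is 1997 Q1).  Panels may be unbalanced: a missing quarter is
simply an absent record, never a sentinel value.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import pandas as pd

logger = logging.getLogger(__name__)

__all__ = [
    "CalendarQuarter",
    "PanelDataset",
    "DEFAULT_ORIGIN",
    "time_index_to_quarter",
    "quarter_to_time_index",
    "load_panel",
    "write_panel",
]


@dataclass(frozen=True, order=True)
class CalendarQuarter:
    """A calendar quarter, e.g. ``CalendarQuarter(2004, 1)`` for 2004 Q1."""

    year: int
    quarter: int

    def __post_init__(self) -> None:
        if self.quarter not in (1, 2, 3, 4):
            raise ValueError(f"quarter must be in 1..4, got {self.quarter}")

    def __str__(self) -> str:
        return f"{self.year} Q{self.quarter}"


DEFAULT_ORIGIN = CalendarQuarter(1997, 1)


def time_index_to_quarter(t: float, origin: CalendarQuarter = DEFAULT_ORIGIN) -> CalendarQuarter:
    """Map a (possibly fractional) time index to its calendar quarter.

    A fractional index such as an estimated change-point location 44.529
    falls *within* quarter ``floor(t)``, so the floor convention is used:
    with the default origin, 44.529 maps to 2007 Q4, not 2008 Q1.

    Parameters
    ----------
    t : float
        Time index, ``t >= 1``; index 1 is the origin quarter.
    origin : CalendarQuarter
        Calendar anchor of time index 1.
    """
    if not math.isfinite(t) or t < 1:
        raise ValueError(f"time index must be finite and >= 1, got {t}")
    k = math.floor(t)
    offset = (origin.quarter - 1) + (k - 1)
    return CalendarQuarter(origin.year + offset // 4, offset % 4 + 1)


def quarter_to_time_index(q: CalendarQuarter, origin: CalendarQuarter = DEFAULT_ORIGIN) -> int:
    """Integer time index of calendar quarter ``q``; exact inverse of
    :func:`time_index_to_quarter` on integer indices."""
    t = (q.year - origin.year) * 4 + (q.quarter - origin.quarter) + 1
    if t < 1:
        raise ValueError(f"{q} is earlier than the origin {origin}")
    return t


@dataclass
class PanelDataset:
    """Unbalanced long-format panel of quarterly consumption values.

    Parameters
    ----------
    frame : pandas.DataFrame
        Columns ``country`` (str), ``time`` (int, >= 1) and ``value``
        (float, finite and >= 0).  No duplicate (country, time) pairs.
    origin : CalendarQuarter
        Calendar quarter corresponding to time index 1.

    An empty frame is allowed (used by prior-recovery checks where the
    likelihood is identically one).  ``allow_negative=True`` relaxes the
    non-negativity check; the Gaussian simulator uses it so that rare
    negative draws are retained rather than truncated (truncation would
    bias parameter-recovery experiments).
    """

    frame: pd.DataFrame
    origin: CalendarQuarter = field(default=DEFAULT_ORIGIN)
    allow_negative: bool = False

    def __post_init__(self) -> None:
        required = {"country", "time", "value"}
        missing = required - set(self.frame.columns)
        if missing:
            raise ValueError(f"panel frame missing columns: {sorted(missing)}")
        df = self.frame.loc[:, ["country", "time", "value"]].copy()
        df["country"] = df["country"].astype(str)
        df["time"] = df["time"].astype(int)
        df["value"] = df["value"].astype(float)
        if len(df):
            dup = df.duplicated(subset=["country", "time"], keep=False)
            if dup.any():
                first = df.loc[dup, ["country", "time"]].iloc[0]
                raise ValueError(
                    "duplicate (country, time) pair: "
                    f"({first['country']!r}, {first['time']})"
                )
            if (df["time"] < 1).any():
                bad = df.loc[df["time"] < 1].iloc[0]
                raise ValueError(f"time index < 1 for country {bad['country']!r}")
            if not df["value"].map(math.isfinite).all():
                raise ValueError("non-finite consumption value in panel")
            if not self.allow_negative and (df["value"] < 0).any():
                bad = df.loc[df["value"] < 0].iloc[0]
                raise ValueError(
                    f"negative consumption value {bad['value']} for "
                    f"country {bad['country']!r} at time {bad['time']}"
                )
        self.frame = df.sort_values(["country", "time"], kind="mergesort").reset_index(drop=True)

    # -- basic descriptors -------------------------------------------------

    @property
    def countries(self) -> list[str]:
        """Distinct country ids, sorted; defines the index i = 1..N."""
        return sorted(self.frame["country"].unique())

    @property
    def n_countries(self) -> int:
        return self.frame["country"].nunique()

    @property
    def country_index(self) -> dict[str, int]:
        """Mapping country id -> 0-based position in :attr:`countries`."""
        return {c: i for i, c in enumerate(self.countries)}

    @property
    def n_obs(self) -> int:
        return len(self.frame)

    @property
    def t_max(self) -> int | None:
        """Largest observed time index, or None for an empty panel."""
        return int(self.frame["time"].max()) if len(self.frame) else None

    def __len__(self) -> int:
        return len(self.frame)

    def quarter_of(self, t: float) -> CalendarQuarter:
        return time_index_to_quarter(t, self.origin)


def load_panel(
    path, origin: CalendarQuarter = DEFAULT_ORIGIN, allow_negative: bool = False
) -> PanelDataset:
    """Read a long-format CSV panel.

    Accepts either ``country,year,quarter,value`` (calendar columns are
    converted to time indices relative to ``origin``) or
    ``country,time,value`` with precomputed indices.  Rows with a missing
    value are dropped and counted in a log message.  Negative values are
    rejected unless ``allow_negative`` (set it when re-loading synthetic
    Gaussian panels, which may contain rare negative draws).
    """
    df = pd.read_csv(path)
    cols = set(df.columns)
    if {"country", "year", "quarter", "value"} <= cols:
        n_before = len(df)
        df = df.dropna(subset=["value"])
        if len(df) < n_before:
            logger.info("load_panel: dropped %d rows with missing value", n_before - len(df))
        times = [
            quarter_to_time_index(CalendarQuarter(int(y), int(q)), origin)
            for y, q in zip(df["year"], df["quarter"])
        ]
        out = pd.DataFrame({"country": df["country"], "time": times, "value": df["value"]})
    elif {"country", "time", "value"} <= cols:
        n_before = len(df)
        df = df.dropna(subset=["value"])
        if len(df) < n_before:
            logger.info("load_panel: dropped %d rows with missing value", n_before - len(df))
        out = df.loc[:, ["country", "time", "value"]]
    else:
        raise ValueError(
            "expected columns country,year,quarter,value or country,time,value; "
            f"got {sorted(cols)}"
        )
    return PanelDataset(out, origin=origin, allow_negative=allow_negative)


def write_panel(data: PanelDataset, path) -> None:
    """Write the panel back as ``country,time,value`` CSV (UTF-8, '.')."""
    data.frame.to_csv(path, index=False)
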