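"""Plate-luminometer recordings and protocol schedules.

Everything downstream works in one coordinate system: decimal hours since the
start of the recording.  The protocol schedule — not the series — carries the
zeitgeber anchoring (which recording hour corresponds to ZT0), so Zeitgeber
Time is always a derived quantity.

Recordings are exchanged as plain CSV in either a long layout
(``time_h,well,value[,group,n_worms,is_blank]``) or a wide layout
(``time_h,<well>,<well>,...``); schedules as JSON.  Proprietary luminometer
export formats are out of scope: users convert to CSV first.
"""

from __future__ import annotations

import enum
import json
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd

__all__ = [
    "Regime",
    "TimeSeries",
    "WellMeta",
    "Epoch",
    "ProtocolSchedule",
    "PlateRecording",
    "read_plate_csv",
    "write_plate_csv",
    "read_schedule_json",
    "write_schedule_json",
    "recording_time_to_zt",
]

_TOL = 1e-9


class Regime(str, enum.Enum):
    """Zeitgeber state of an epoch: driven cycles or constant conditions."""

    CYCLIC = "CYCLIC"
    FREE_RUN = "FREE_RUN"


@dataclass
class TimeSeries:
    """One well's luminescence counts on a strictly increasing hour grid.

    Parameters
    ----------
    times
        Hours since the start of the recording, strictly increasing.
    values
        Luminescence counts (arbitrary relative light units).  Missing
        readings are stored as NaN and dropped point-wise by each analysis
        operation; they are never interpolated.
    nominal_interval
        Nominal sampling interval in hours (0.5 for the 30-min integrations
        of plate luminometers).
    """

    times: np.ndarray
    values: np.ndarray
    nominal_interval: float = 0.5

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.values = np.asarray(self.values, dtype=float)
        if self.times.ndim != 1 or self.values.ndim != 1:
            raise ValueError("times and values must be one-dimensional")
        if self.times.size != self.values.size:
            raise ValueError(
                f"times ({self.times.size}) and values ({self.values.size}) "
                "must have the same length"
            )
        if self.times.size > 1 and not np.all(np.diff(self.times) > 0):
            raise ValueError("times must be strictly increasing")
        if not self.nominal_interval > 0:
            raise ValueError("nominal_interval must be positive")

    def __len__(self) -> int:
        return self.times.size

    @property
    def span_h(self) -> float:
        """Total span (last minus first timestamp) in hours."""
        if len(self) == 0:
            return 0.0
        return float(self.times[-1] - self.times[0])

    def finite(self) -> tuple[np.ndarray, np.ndarray]:
        """Return (times, values) with missing points removed."""
        ok = np.isfinite(self.values)
        return self.times[ok], self.values[ok]

    def n_finite(self) -> int:
        return int(np.isfinite(self.values).sum())

    def window(self, start_h: float, end_h: float) -> "TimeSeries":
        """Sub-series with ``start_h <= t <= end_h`` (inclusive, tolerant)."""
        keep = (self.times >= start_h - _TOL) & (self.times <= end_h + _TOL)
        return TimeSeries(self.times[keep], self.values[keep], self.nominal_interval)

    def with_values(self, values: np.ndarray) -> "TimeSeries":
        return TimeSeries(self.times.copy(), np.asarray(values, dtype=float), self.nominal_interval)


@dataclass
class WellMeta:
    """Identity and grouping of a single well."""

    well_id: str
    plate_id: str = ""
    group: str = ""
    n_worms: int = 0
    is_blank: bool = False

    def __post_init__(self) -> None:
        if self.n_worms < 0:
            raise ValueError("n_worms must be >= 0")


@dataclass
class Epoch:
    """A contiguous stretch of the protocol with one zeitgeber state."""

    start_h: float
    end_h: float
    regime: Regime
    zeitgeber_period: float = 24.0
    lights_on_zt: float = 0.0
    lights_off_zt: float = 12.0

    def __post_init__(self) -> None:
        self.regime = Regime(self.regime)
        if not self.start_h < self.end_h:
            raise ValueError("epoch start_h must be < end_h")
        if not self.zeitgeber_period > 0:
            raise ValueError("zeitgeber_period must be positive")
        if not (0 <= self.lights_on_zt < self.lights_off_zt <= self.zeitgeber_period):
            raise ValueError("need 0 <= lights_on_zt < lights_off_zt <= zeitgeber_period")

    @property
    def span_h(self) -> float:
        return self.end_h - self.start_h


@dataclass
class ProtocolSchedule:
    """Ordered, contiguous epochs plus the recording time of ZT0.

    ``zt0_recording_offset`` is the recording hour corresponding to ZT0 of
    the first zeitgeber cycle (lights-on / cold-phase onset).
    """

    zt0_recording_offset: float = 0.0
    epochs: list[Epoch] = field(default_factory=list)

    def __post_init__(self) -> None:
        if not self.epochs:
            raise ValueError("schedule needs at least one epoch")
        for a, b in zip(self.epochs, self.epochs[1:]):
            if b.start_h < a.end_h - _TOL:
                raise ValueError("epochs must be ordered and non-overlapping")
            if b.start_h > a.end_h + _TOL:
                raise ValueError("epochs must cover a contiguous span")

    @property
    def start_h(self) -> float:
        return self.epochs[0].start_h

    @property
    def end_h(self) -> float:
        return self.epochs[-1].end_h

    @property
    def zeitgeber_period(self) -> float:
        return self.epochs[0].zeitgeber_period

    def cyclic_epochs(self) -> list[Epoch]:
        return [e for e in self.epochs if e.regime is Regime.CYCLIC]

    def free_run_epochs(self) -> list[Epoch]:
        return [e for e in self.epochs if e.regime is Regime.FREE_RUN]

    def epoch_at(self, t: float) -> Epoch:
        for e in self.epochs:
            if e.start_h - _TOL <= t <= e.end_h + _TOL:
                return e
        raise ValueError(f"time {t} h is outside the schedule span")


@dataclass
class PlateRecording:
    """All wells of one plate run plus their metadata and protocol."""

    series: dict[str, TimeSeries]
    meta: dict[str, WellMeta]
    schedule: ProtocolSchedule

    def __post_init__(self) -> None:
        missing = set(self.series) - set(self.meta)
        if missing:
            raise ValueError(f"series without metadata: {sorted(missing)}")
        intervals = {ts.nominal_interval for ts in self.series.values()}
        if len(intervals) > 1:
            raise ValueError("all series must share the same nominal_interval")

    def analysis_wells(self) -> list[str]:
        """Well ids that enter rhythm analysis (blanks excluded)."""
        return [w for w in self.series if not self.meta[w].is_blank]


def recording_time_to_zt(t: float | np.ndarray, schedule: ProtocolSchedule) -> float | np.ndarray:
    """Map recording hours to Zeitgeber Time in ``[0, zeitgeber_period)``.

    ZT = (t - zt0_recording_offset) mod zeitgeber_period.  During free-run
    epochs this is *projected* ZT (the zeitgeber no longer runs); it is used
    only for phase anchoring and plotting.
    """
    zt = np.mod(np.asarray(t, dtype=float) - schedule.zt0_recording_offset,
                schedule.zeitgeber_period)
    zt = np.where(zt >= schedule.zeitgeber_period, 0.0, zt)  # -eps % c == c in floats
    if np.isscalar(t) or np.ndim(t) == 0:
        return float(zt)
    return zt


# ---------------------------------------------------------------------------
# CSV / JSON I/O

_LONG_REQUIRED = {"time_h", "well", "value"}
_LAYOUT_HELP = (
    "accepted layouts: long CSV with header columns time_h,well,value"
    "[,group,n_worms,is_blank], or wide CSV with first column time_h and one "
    "column per well"
)


def _parse_bool(x) -> bool:
    if isinstance(x, str):
        return x.strip().lower() in {"1", "true", "yes"}
    return bool(int(x)) if not isinstance(x, bool) else x


def read_plate_csv(path: str | Path, schedule: ProtocolSchedule) -> PlateRecording:
    """Read a plate recording from CSV (long or wide layout, auto-detected).

    Non-numeric value cells (e.g. ``NA``) become missing points (NaN); the
    series length is unchanged.  Duplicate (time, well) pairs are an error.
    """
    df = pd.read_csv(path, dtype=str, keep_default_na=False)
    cols = [c.strip() for c in df.columns]
    df.columns = cols
    if _LONG_REQUIRED.issubset(cols):
        return _read_long(df, schedule)
    if cols and cols[0] == "time_h" and len(cols) >= 2:
        return _read_wide(df, schedule)
    raise ValueError(f"unknown CSV header layout {cols!r}; {_LAYOUT_HELP}")


def _to_float_or_nan(s: pd.Series) -> np.ndarray:
    # float() is correctly rounded (pd.to_numeric's fast parser is not),
    # which the bit-exact CSV roundtrip contract relies on.
    def conv(x) -> float:
        try:
            return float(x)
        except (TypeError, ValueError):
            return math.nan

    return np.array([conv(x) for x in s], dtype=float)


def _infer_interval(times: np.ndarray) -> float:
    if times.size > 1:
        return float(np.median(np.diff(times)))
    return 0.5


def _read_long(df: pd.DataFrame, schedule: ProtocolSchedule) -> PlateRecording:
    times_all = _to_float_or_nan(df["time_h"])
    if np.isnan(times_all).any():
        bad = df.loc[np.isnan(times_all), "time_h"].iloc[0]
        raise ValueError(f"non-numeric time_h value {bad!r}")
    dup = df.assign(_t=times_all).duplicated(subset=["well", "_t"])
    if dup.any():
        row = df.loc[dup.idxmax()]
        raise ValueError(
            f"duplicate (time, well) pair: time_h={row['time_h']}, well={row['well']}"
        )
    series: dict[str, TimeSeries] = {}
    meta: dict[str, WellMeta] = {}
    order = df["well"].drop_duplicates().tolist()
    values_all = _to_float_or_nan(df["value"])
    for well in order:
        sel = (df["well"] == well).to_numpy()
        t = times_all[sel]
        v = values_all[sel]
        idx = np.argsort(t, kind="stable")
        t, v = t[idx], v[idx]
        series[well] = TimeSeries(t, v, _infer_interval(t))
        first = df.loc[sel].iloc[0]
        meta[well] = WellMeta(
            well_id=well,
            group=str(first["group"]) if "group" in df.columns else "",
            n_worms=int(float(first["n_worms"])) if "n_worms" in df.columns and first["n_worms"] != "" else 0,
            is_blank=_parse_bool(first["is_blank"]) if "is_blank" in df.columns and first["is_blank"] != "" else False,
        )
    return PlateRecording(series, meta, schedule)


def _read_wide(df: pd.DataFrame, schedule: ProtocolSchedule) -> PlateRecording:
    t = _to_float_or_nan(df["time_h"])
    if np.isnan(t).any():
        raise ValueError("non-numeric time_h value in wide CSV")
    if pd.Series(t).duplicated().any():
        dup_t = pd.Series(t)[pd.Series(t).duplicated()].iloc[0]
        raise ValueError(f"duplicate (time, well) pair: time_h={dup_t} duplicated for every well")
    idx = np.argsort(t, kind="stable")
    series: dict[str, TimeSeries] = {}
    meta: dict[str, WellMeta] = {}
    interval = _infer_interval(t[idx])
    for well in df.columns[1:]:
        v = _to_float_or_nan(df[well])
        series[well] = TimeSeries(t[idx], v[idx], interval)
        meta[well] = WellMeta(well_id=well)
    return PlateRecording(series, meta, schedule)


def write_plate_csv(rec: PlateRecording, path: str | Path) -> None:
    """Write a recording as long CSV; roundtrips bit-exactly via shortest-repr floats."""
    rows = []
    for well, ts in rec.series.items():
        m = rec.meta[well]
        for t, v in zip(ts.times, ts.values):
            rows.append(
                {
                    "time_h": t,
                    "well": well,
                    "value": v,
                    "group": m.group,
                    "n_worms": m.n_worms,
                    "is_blank": int(m.is_blank),
                }
            )
    df = pd.DataFrame(rows, columns=["time_h", "well", "value", "group", "n_worms", "is_blank"])
    df.to_csv(path, index=False, na_rep="NA")


def schedule_to_dict(schedule: ProtocolSchedule) -> dict:
    return {
        "zt0_recording_offset": schedule.zt0_recording_offset,
        "epochs": [
            {
                "start_h": e.start_h,
                "end_h": e.end_h,
                "regime": e.regime.value,
                "zeitgeber_period": e.zeitgeber_period,
                "lights_on_zt": e.lights_on_zt,
                "lights_off_zt": e.lights_off_zt,
            }
            for e in schedule.epochs
        ],
    }


def schedule_from_dict(d: Mapping) -> ProtocolSchedule:
    return ProtocolSchedule(
        zt0_recording_offset=float(d.get("zt0_recording_offset", 0.0)),
        epochs=[
            Epoch(
                start_h=float(e["start_h"]),
                end_h=float(e["end_h"]),
                regime=Regime(e["regime"]),
                zeitgeber_period=float(e.get("zeitgeber_period", 24.0)),
                lights_on_zt=float(e.get("lights_on_zt", 0.0)),
                lights_off_zt=float(e.get("lights_off_zt", 12.0)),
            )
            for e in d["epochs"]
        ],
    )


def write_schedule_json(schedule: ProtocolSchedule, path: str | Path) -> None:
    Path(path).write_text(json.dumps(schedule_to_dict(schedule), indent=2) + "\n")


def read_schedule_json(path: str | Path) -> ProtocolSchedule:
    return schedule_from_dict(json.loads(Path(path).read_text()))
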