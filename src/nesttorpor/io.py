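"""On-disk formats, time-base alignment, and input validation.

All timestamps are timezone-aware and canonicalised to UTC in memory; the
site timezone lives in configuration and only matters when comparing to sun
times or printing. Readers validate (strictly increasing timestamps, finite
temperatures) and flag gaps but never interpolate — gap policy belongs to
the detection stage, which decides explicitly what to do with holes.
"""

from __future__ import annotations

import dataclasses
import datetime as dt
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "TemperatureTrace",
    "GasTrace",
    "NestRecord",
    "AlignedPair",
    "FormatError",
    "AlignmentError",
    "read_temperature_csv",
    "read_gas_csv",
    "write_temperature_csv",
    "write_gas_csv",
    "align",
    "write_records",
    "read_records",
    "write_events",
    "write_night_scores",
]

logger = logging.getLogger("nesttorpor.io")

FLOAT_FMT = "%.4f"


class FormatError(ValueError):
    """A file violated the expected schema or an invariant (e.g. time order)."""


class AlignmentError(ValueError):
    """Two series cannot be aligned (no temporal overlap)."""


def _validate_index(index: pd.DatetimeIndex, context: str) -> None:
    if len(index) == 0:
        raise FormatError(f"{context}: empty series")
    if index.tz is None:
        raise FormatError(f"{context}: timestamps must be timezone-aware")
    diffs = np.diff(index.asi8)
    bad = np.nonzero(diffs <= 0)[0]
    if bad.size:
        row = int(bad[0]) + 1
        raise FormatError(
            f"{context}: timestamps not strictly increasing at row {row} "
            f"({index[row]!s} follows {index[row - 1]!s})"
        )


def _infer_interval_minutes(index: pd.DatetimeIndex) -> float:
    if len(index) < 2:
        return float("nan")
    return float(np.median(np.diff(index.asi8)) / 60e9)


@dataclass
class TemperatureTrace:
    """A timestamped temperature series from one logger.

    ``series`` is a pandas Series of temperatures (degC) indexed by
    timezone-aware timestamps (UTC internally). ``role`` distinguishes the
    nest logger from the ambient reference at the colony.
    """

    series: pd.Series
    source_id: str
    role: str  # "nest" | "ambient"
    interval: float = field(default=float("nan"))  # minutes
    parse_issues: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.role not in ("nest", "ambient"):
            raise ValueError(f"role must be 'nest' or 'ambient', got {self.role!r}")
        if not isinstance(self.series.index, pd.DatetimeIndex):
            raise FormatError("TemperatureTrace requires a DatetimeIndex")
        _validate_index(self.series.index, f"trace {self.source_id}")
        self.series = self.series.astype(float)
        if self.series.index.tz != dt.timezone.utc:
            self.series = self.series.tz_convert("UTC")
        if np.isnan(self.interval):
            self.interval = _infer_interval_minutes(self.series.index)

    def __len__(self) -> int:
        return len(self.series)

    def gaps(self, factor: float = 1.5) -> pd.DataFrame:
        """Intervals longer than ``factor`` x the nominal spacing (flagged, not filled)."""
        idx = self.series.index
        d = np.diff(idx.asi8) / 60e9
        mask = d > factor * self.interval
        return pd.DataFrame(
            {"after": idx[:-1][mask], "before": idx[1:][mask], "gap_minutes": d[mask]}
        )

    def window(self, start: dt.datetime, end: dt.datetime) -> pd.Series:
        """Samples in the half-open interval [start, end)."""
        return self.series[(self.series.index >= start) & (self.series.index < end)]


@dataclass
class GasTrace:
    """One nest-box night of gas exchange: VO2 (and optionally VCO2).

    ``frame`` has a tz-aware DatetimeIndex and columns ``vo2`` (ml O2/min)
    and optionally ``vco2``. VCO2 may be absent: the torpor analysis uses
    VO2 only.
    """

    frame: pd.DataFrame
    nest_id: str
    session_date: dt.date

    def __post_init__(self) -> None:
        if "vo2" not in self.frame.columns:
            raise FormatError("GasTrace requires a 'vo2' column")
        _validate_index(self.frame.index, f"gas trace {self.nest_id}/{self.session_date}")
        if self.frame.index.tz != dt.timezone.utc:
            self.frame = self.frame.tz_convert("UTC")
        vo2 = self.frame["vo2"].to_numpy(float)
        if np.any(vo2[np.isfinite(vo2)] < 0):
            raise FormatError("vo2 must be >= 0 where present")

    def __len__(self) -> int:
        return len(self.frame)

    @property
    def vo2(self) -> pd.Series:
        return self.frame["vo2"]

    @property
    def has_vco2(self) -> bool:
        return "vco2" in self.frame.columns and self.frame["vco2"].notna().any()

    @property
    def interval(self) -> float:
        return _infer_interval_minutes(self.frame.index)


@dataclass
class NestRecord:
    """Occupancy metadata for one nest."""

    nest_id: str
    n_adults: int = 0
    n_nestlings: int = 0
    nestling_ages: tuple[int, ...] = ()
    total_mass: float | None = None  # grams

    def __post_init__(self) -> None:
        if self.n_adults < 0 or self.n_nestlings < 0:
            raise ValueError("counts must be >= 0")
        if self.total_mass is not None and self.total_mass <= 0:
            raise ValueError("total_mass must be > 0 when present")


# ---------------------------------------------------------------------------
# temperature CSV


def read_temperature_csv(
    path: str | Path,
    dialect: str = "generic",
    role: str | None = None,
    source_id: str | None = None,
    timezone: float = 0.0,
) -> TemperatureTrace:
    """Read a temperature-logger export.

    Dialects
    --------
    ``generic``
        Columns ``timestamp`` (ISO-8601), ``temp_c``, and optionally
        ``source_id`` and ``role``.
    ``ibutton_export``
        A Mission-Results-style export: preamble lines, then a
        ``Date/Time,Unit,Value`` header and rows like
        ``30/06/17 21:35:00,C,23.062``; naive times are localised using
        ``timezone`` (UTC offset in hours).

    Malformed rows are collected into ``trace.parse_issues`` (and logged),
    never dropped silently; structural problems (empty file, non-monotone
    timestamps) raise :class:`FormatError`.
    """
    path = Path(path)
    if dialect == "generic":
        df = pd.read_csv(path)
        if df.empty:
            raise FormatError(f"{path}: empty file")
        required = {"timestamp", "temp_c"}
        if not required <= set(df.columns):
            raise FormatError(f"{path}: missing columns {sorted(required - set(df.columns))}")
        issues: list[str] = []
        ts = pd.to_datetime(df["timestamp"], errors="coerce", utc=True, format="ISO8601")
        temp = pd.to_numeric(df["temp_c"], errors="coerce")
        bad = ts.isna() | temp.isna()
        for i in np.nonzero(bad.to_numpy())[0]:
            issues.append(f"row {i + 2}: unparseable timestamp or temperature")
        df = df.loc[~bad]
        ts = ts[~bad]
        temp = temp[~bad]
        if df.empty:
            raise FormatError(f"{path}: no parseable rows")
        sid = source_id or (str(df["source_id"].iloc[0]) if "source_id" in df else path.stem)
        file_role = role or (str(df["role"].iloc[0]) if "role" in df else "nest")
        series = pd.Series(temp.to_numpy(float), index=pd.DatetimeIndex(ts))
        try:
            trace = TemperatureTrace(series, source_id=sid, role=file_role)
        except FormatError as exc:
            raise FormatError(f"{path}: {exc}") from exc
        trace.parse_issues = issues
        if issues:
            logger.warning("%s: %d malformed rows", path, len(issues))
        logger.info("%s: %d samples, interval %.1f min", path, len(trace), trace.interval)
        return trace

    if dialect == "ibutton_export":
        lines = path.read_text().splitlines()
        if not lines:
            raise FormatError(f"{path}: empty file")
        try:
            start = next(i for i, l in enumerate(lines) if l.startswith("Date/Time")) + 1
        except StopIteration:
            raise FormatError(f"{path}: no 'Date/Time' header found") from None
        tz = dt.timezone(dt.timedelta(hours=timezone))
        stamps: list[dt.datetime] = []
        temps: list[float] = []
        issues = []
        for i, line in enumerate(lines[start:], start=start + 1):
            if not line.strip():
                continue
            parts = line.split(",")
            try:
                stamp = dt.datetime.strptime(parts[0].strip(), "%d/%m/%y %H:%M:%S")
                value = float(parts[2])
            except (ValueError, IndexError):
                issues.append(f"row {i}: unparseable line {line!r}")
                continue
            stamps.append(stamp.replace(tzinfo=tz))
            temps.append(value)
        if not stamps:
            raise FormatError(f"{path}: no parseable rows")
        series = pd.Series(temps, index=pd.DatetimeIndex(stamps))
        try:
            trace = TemperatureTrace(
                series, source_id=source_id or path.stem, role=role or "nest"
            )
        except FormatError as exc:
            raise FormatError(f"{path}: {exc}") from exc
        trace.parse_issues = issues
        return trace

    raise ValueError(f"unknown dialect {dialect!r}")


def write_temperature_csv(trace: TemperatureTrace, path: str | Path) -> None:
    """Write a trace in the generic dialect (ISO-8601 UTC timestamps)."""
    df = pd.DataFrame(
        {
            "timestamp": trace.series.index.strftime("%Y-%m-%dT%H:%M:%S%z"),
            "temp_c": [FLOAT_FMT % v for v in trace.series.to_numpy()],
            "source_id": trace.source_id,
            "role": trace.role,
        }
    )
    df.to_csv(path, index=False)


def read_gas_csv(
    path: str | Path, nest_id: str | None = None, session_date: dt.date | None = None
) -> GasTrace:
    """Read a gas-exchange trace CSV (columns: timestamp, vo2[, vco2])."""
    path = Path(path)
    df = pd.read_csv(path)
    if df.empty:
        raise FormatError(f"{path}: empty file")
    if "timestamp" not in df.columns or "vo2" not in df.columns:
        raise FormatError(f"{path}: need 'timestamp' and 'vo2' columns")
    ts = pd.to_datetime(df["timestamp"], utc=True, format="ISO8601")
    frame = pd.DataFrame(
        {"vo2": pd.to_numeric(df["vo2"]).to_numpy()}, index=pd.DatetimeIndex(ts)
    )
    if "vco2" in df.columns:
        frame["vco2"] = pd.to_numeric(df["vco2"]).to_numpy()
    nid = nest_id or (str(df["nest_id"].iloc[0]) if "nest_id" in df else path.stem)
    if session_date is None:
        session_date = ts.iloc[0].date()
    try:
        return GasTrace(frame, nest_id=nid, session_date=session_date)
    except FormatError as exc:
        raise FormatError(f"{path}: {exc}") from exc


def write_gas_csv(trace: GasTrace, path: str | Path) -> None:
    out = pd.DataFrame(
        {
            "timestamp": trace.frame.index.strftime("%Y-%m-%dT%H:%M:%S%z"),
            "vo2": [FLOAT_FMT % v for v in trace.frame["vo2"].to_numpy()],
        }
    )
    if "vco2" in trace.frame.columns:
        out["vco2"] = [FLOAT_FMT % v for v in trace.frame["vco2"].to_numpy()]
    out["nest_id"] = trace.nest_id
    out.to_csv(path, index=False)


# ---------------------------------------------------------------------------
# alignment


@dataclass
class AlignedPair:
    """Nest samples paired with the nearest-in-time ambient sample.

    ``frame`` is indexed by the nest timestamps and has columns ``t_nest``
    and ``t_a``; every row maps one real nest sample to one real ambient
    sample (nothing is interpolated or fabricated). ``n_unpaired`` counts
    nest samples with no ambient partner within tolerance.
    """

    frame: pd.DataFrame
    n_unpaired: int
    tolerance: float  # minutes

    @property
    def diff(self) -> pd.Series:
        """T_nest - T_a at the paired times."""
        return self.frame["t_nest"] - self.frame["t_a"]


def align(
    nest: TemperatureTrace,
    ambient: TemperatureTrace,
    tolerance: float | None = None,
) -> AlignedPair:
    """Pair each nest sample with the nearest ambient sample in time.

    ``tolerance`` is in minutes and defaults to half the nest sampling
    interval; nest samples without an ambient partner inside the tolerance
    are excluded and counted, never filled in.
    """
    if tolerance is None:
        tolerance = nest.interval / 2.0
    lo = max(nest.series.index[0], ambient.series.index[0])
    hi = min(nest.series.index[-1], ambient.series.index[-1])
    if lo > hi:
        raise AlignmentError(
            f"no temporal overlap between {nest.source_id} and {ambient.source_id}"
        )
    left = pd.DataFrame({"t_nest": nest.series})
    right = pd.DataFrame({"t_a": ambient.series})
    merged = pd.merge_asof(
        left,
        right,
        left_index=True,
        right_index=True,
        direction="nearest",
        tolerance=pd.Timedelta(minutes=tolerance),
    )
    unpaired = int(merged["t_a"].isna().sum())
    return AlignedPair(merged.dropna(subset=["t_a"]), n_unpaired=unpaired, tolerance=tolerance)


# ---------------------------------------------------------------------------
# tabular record IO (events, night scores, ground truth)


def _format_value(v) -> str:
    if v is None:
        return ""
    if isinstance(v, bool) or isinstance(v, np.bool_):
        return "true" if v else "false"
    if isinstance(v, (dt.datetime, pd.Timestamp)):
        return v.strftime("%Y-%m-%dT%H:%M:%S%z")
    if isinstance(v, dt.date):
        return v.isoformat()
    if isinstance(v, float) or isinstance(v, np.floating):
        if np.isnan(v):
            return ""
        return FLOAT_FMT % v
    if isinstance(v, (tuple, list)):
        return ";".join(str(x) for x in v)
    return str(v)


def write_records(records: Sequence, path: str | Path, cls=None) -> None:
    """Write dataclass records as TSV with stable column order (field order).

    Floats are written at fixed precision so outputs diff cleanly; an empty
    record list still produces a header-only file when ``cls`` is given.
    """
    if records:
        cls = type(records[0])
    if cls is None:
        raise ValueError("cls is required to write an empty record list")
    names = [f.name for f in dataclasses.fields(cls)]
    with open(path, "w") as fh:
        fh.write("\t".join(names) + "\n")
        for rec in records:
            row = [_format_value(getattr(rec, n)) for n in names]
            fh.write("\t".join(row) + "\n")


def _parse_value(text: str, typ):
    from typing import get_args, get_origin, Union

    if get_origin(typ) is Union:  # Optional[...]
        args = [a for a in get_args(typ) if a is not type(None)]
        if text == "":
            return None
        typ = args[0]
    if text == "":
        return None
    if typ is bool:
        return text == "true"
    if typ is int:
        return int(text)
    if typ is float:
        return float(text)
    if typ is dt.datetime:
        return dt.datetime.strptime(text, "%Y-%m-%dT%H:%M:%S%z")
    if typ is dt.date:
        return dt.date.fromisoformat(text)
    if get_origin(typ) in (tuple, list):
        inner = get_args(typ)[0] if get_args(typ) else str
        parts = [p for p in text.split(";") if p]
        vals = [_parse_value(p, inner) for p in parts]
        return tuple(vals) if get_origin(typ) is tuple else vals
    return text


def read_records(path: str | Path, cls) -> list:
    """Read back a TSV written by :func:`write_records`."""
    import typing

    hints = typing.get_type_hints(cls)
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
        out = []
        for line in fh:
            cells = line.rstrip("\n").split("\t")
            kwargs = {
                name: _parse_value(cell, hints[name])
                for name, cell in zip(header, cells)
            }
            out.append(cls(**kwargs))
    return out


def write_events(events: Sequence, path: str | Path) -> None:
    """Write DropEvent records as TSV (header always present)."""
    from .tnest import DropEvent

    write_records(events, path, cls=DropEvent)


def write_night_scores(scores: Sequence, path: str | Path) -> None:
    """Write NightScore records as TSV (header always present)."""
    from .mr import NightScore

    write_records(scores, path, cls=NightScore)
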