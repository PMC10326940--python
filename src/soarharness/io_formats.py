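"""CSV dialects, configuration, and wind-table annotation.

The pipeline exchanges four plain-CSV tables, loosely modelled on Movebank
exports: GPS fixes (timestamp, lon, lat, height a.s.l.), tri-axial
accelerometry (timestamp, ax, ay, az in g), a session log (one row per
release-to-return flight) and an hourly wind table (U/V components in m/s).
Timestamps are UTC ISO-8601 with millisecond precision throughout; a
``column_map`` argument renames arbitrary source columns onto the canonical
names so real-world exports can be read without preprocessing.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, asdict
from datetime import date as _date

import numpy as np
import pandas as pd
import yaml

from .acc_features import AccStream
from .gps_kinematics import GpsTrack, haversine_m

__all__ = [
    "FormatError",
    "ConfigurationError",
    "SessionRecord",
    "WindRecord",
    "PipelineConfig",
    "read_gps_csv",
    "write_gps_csv",
    "read_acc_csv",
    "write_acc_csv",
    "read_sessions_csv",
    "write_sessions_csv",
    "read_wind_csv",
    "write_wind_csv",
    "annotate_wind",
    "load_config",
    "save_config",
]

logger = logging.getLogger("soarharness")

TIME_FORMAT = "%Y-%m-%dT%H:%M:%S.%f"

HARNESS_TYPES = ("backpack", "leg-loop")


class FormatError(ValueError):
    """A file does not match the expected CSV dialect."""


class ConfigurationError(ValueError):
    """Invalid or insufficient configuration for an operation."""


@dataclass(frozen=True)
class SessionRecord:
    """One release-to-return flight of one individual."""

    session_id: str
    individual_id: str
    species: str
    harness: str
    date: _date
    start_time: pd.Timestamp
    end_time: pd.Timestamp
    device_id: str = ""

    def __post_init__(self) -> None:
        if self.harness not in HARNESS_TYPES:
            raise ValueError(f"harness must be one of {HARNESS_TYPES}, got {self.harness!r}")
        if not self.start_time < self.end_time:
            raise ValueError(f"session {self.session_id}: start_time must precede end_time")

    @property
    def meta(self) -> dict:
        """Identity fields propagated onto tracks, segments and summaries."""
        return {
            "session_id": self.session_id,
            "individual_id": self.individual_id,
            "species": self.species,
            "harness": self.harness,
            "date": self.date,
        }


@dataclass(frozen=True)
class WindRecord:
    """Hourly wind vector at a location/height; U eastward, V northward (m/s)."""

    time: pd.Timestamp
    lon: float
    lat: float
    height: float
    u: float
    v: float

    def __post_init__(self) -> None:
        if not (np.isfinite(self.u) and np.isfinite(self.v)):
            raise ValueError("wind components must be finite")

    @property
    def speed(self) -> float:
        return float(np.hypot(self.u, self.v))


@dataclass
class PipelineConfig:
    """Tunable parameters of the processing pipeline (YAML-serialisable)."""

    static_window_s: float = 0.5      # running-mean window for static acceleration
    vspeed_smooth_s: int = 15         # vertical-speed smoothing window
    min_fixes: int = 5                # minimum run length kept as a segment
    speed_threshold: float = 4.0      # m/s split between low- and high-speed segments
    glide_vspeed_max: float = -0.2    # m/s; gliding segments must sink faster than this
    activity_min_separation: float = 0.1  # g; VeDBA cluster gap below which all is passive
    kmeans_scope: str = "session"     # cluster per session (the alternative: "pooled")
    seed: int = 0


def _apply_column_map(df: pd.DataFrame, column_map: dict | None, required: tuple, path) -> pd.DataFrame:
    if column_map:
        df = df.rename(columns={src: dst for dst, src in column_map.items()})
    for col in required:
        if col not in df.columns:
            raise FormatError(f"{path}: missing required column '{col}'")
    return df


def _parse_times(df: pd.DataFrame, path) -> pd.DataFrame:
    df = df.copy()
    df["time"] = pd.to_datetime(df.pop("timestamp"), utc=True, format="ISO8601")
    if not df["time"].is_monotonic_increasing:
        warnings.warn(f"{path}: non-monotonic timestamps; reordering", stacklevel=3)
        df = df.sort_values("time", kind="stable")
    dup = df["time"].duplicated(keep="first")
    if dup.any():
        df = df.loc[~dup]
    return df.reset_index(drop=True)


def _estimate_rate(times: pd.Series) -> float:
    if len(times) < 2:
        return float("nan")
    gap = float(np.median(np.diff(times.astype("int64").to_numpy()))) / 1e9
    return 1.0 / gap


def read_gps_csv(path, column_map: dict | None = None) -> GpsTrack:
    """Read a GPS-fix CSV into a time-ordered, deduplicated :class:`GpsTrack`.

    ``column_map`` maps canonical names (timestamp, lon, lat, height) to the
    source file's column names. Duplicate timestamps collapse to the first
    occurrence; out-of-order fixes are reordered with a warning.
    """
    df = pd.read_csv(path)
    df = _apply_column_map(df, column_map, ("timestamp", "lon", "lat", "height"), path)
    df = _parse_times(df, path)
    rate = _estimate_rate(df["time"])
    # snap to the nominal 1 or 4 Hz when within 10%
    for nominal in (1.0, 4.0):
        if np.isfinite(rate) and abs(rate - nominal) <= 0.1 * nominal:
            rate = nominal
    logger.info("read_gps_csv: %s -> %d fixes at %.3g Hz", path, len(df), rate)
    keep = ["time", "lon", "lat", "height"]
    extra = [c for c in df.columns if c not in keep]
    return GpsTrack(df[keep + extra], rate)


def write_gps_csv(track: GpsTrack, path) -> None:
    df = track.data.copy()
    df.insert(0, "timestamp", df.pop("time").dt.strftime(TIME_FORMAT).str[:-3])
    df.to_csv(path, index=False)


def read_acc_csv(path, column_map: dict | None = None, declared_rate: float | None = None) -> AccStream:
    """Read a tri-axial accelerometry CSV into an :class:`AccStream`.

    The sampling rate is estimated from the median inter-sample gap; the
    stream is marked 25 Hz when that gap is within 10% of 40 ms. If a
    ``declared_rate`` deviates from the estimate by more than 10% a warning
    is issued and the estimated rate is used.
    """
    df = pd.read_csv(path)
    df = _apply_column_map(df, column_map, ("timestamp", "ax", "ay", "az"), path)
    df = _parse_times(df, path)
    rate = _estimate_rate(df["time"])
    if np.isfinite(rate) and abs(1.0 / rate - 0.040) <= 0.004:
        rate = 25.0
    if declared_rate is not None and np.isfinite(rate) and abs(rate - declared_rate) > 0.1 * declared_rate:
        warnings.warn(
            f"{path}: estimated rate {rate:.3g} Hz deviates from declared "
            f"{declared_rate:.3g} Hz; proceeding with the estimate",
            stacklevel=2,
        )
    logger.info("read_acc_csv: %s -> %d samples at %.3g Hz", path, len(df), rate)
    return AccStream(df[["time", "ax", "ay", "az"]], rate)


def write_acc_csv(stream: AccStream, path) -> None:
    df = stream.data[["time", "ax", "ay", "az"]].copy()
    df.insert(0, "timestamp", df.pop("time").dt.strftime(TIME_FORMAT).str[:-3])
    df.to_csv(path, index=False)


def read_sessions_csv(path) -> list[SessionRecord]:
    """Read the session log (one row per flight session)."""
    df = pd.read_csv(path)
    required = ("session_id", "individual_id", "species", "harness", "date", "start_time", "end_time")
    for col in required:
        if col not in df.columns:
            raise FormatError(f"{path}: missing required column '{col}'")
    records = []
    for row in df.itertuples(index=False):
        records.append(
            SessionRecord(
                session_id=str(row.session_id),
                individual_id=str(row.individual_id),
                species=str(row.species),
                harness=str(row.harness),
                date=pd.Timestamp(row.date).date(),
                start_time=pd.Timestamp(row.start_time, tz="UTC")
                if pd.Timestamp(row.start_time).tzinfo is None
                else pd.Timestamp(row.start_time),
                end_time=pd.Timestamp(row.end_time, tz="UTC")
                if pd.Timestamp(row.end_time).tzinfo is None
                else pd.Timestamp(row.end_time),
                device_id=str(getattr(row, "device_id", "")),
            )
        )
    ids = [(r.individual_id, r.session_id) for r in records]
    if len(set(ids)) != len(ids):
        raise FormatError(f"{path}: duplicate (individual_id, session_id) pairs")
    logger.info("read_sessions_csv: %s -> %d sessions", path, len(records))
    return records


def write_sessions_csv(records: list[SessionRecord], path) -> None:
    df = pd.DataFrame([asdict(r) for r in records])
    df["start_time"] = pd.to_datetime(df["start_time"], utc=True).dt.strftime(TIME_FORMAT).str[:-3]
    df["end_time"] = pd.to_datetime(df["end_time"], utc=True).dt.strftime(TIME_FORMAT).str[:-3]
    df.to_csv(path, index=False)


def read_wind_csv(path) -> pd.DataFrame:
    """Read the wind table: time, lon, lat, height, u, v."""
    df = pd.read_csv(path)
    for col in ("timestamp", "lon", "lat", "height", "u", "v"):
        if col not in df.columns:
            raise FormatError(f"{path}: missing required column '{col}'")
    df = _parse_times(df, path)
    return df[["time", "lon", "lat", "height", "u", "v"]]


def write_wind_csv(wind: pd.DataFrame, path) -> None:
    df = wind.copy()
    df.insert(0, "timestamp", df.pop("time").dt.strftime(TIME_FORMAT).str[:-3])
    df.to_csv(path, index=False)


def annotate_wind(centroids: pd.DataFrame, wind: pd.DataFrame) -> pd.DataFrame:
    """Pair each segment centroid with its nearest wind record.

    Nearness is lexicographic: minimal absolute time difference first, then
    minimal 3-D distance (great-circle horizontal plus height difference,
    combined in quadrature); remaining ties resolve to the earliest record.
    Returns one wind row per centroid, in input order.

    Parameters
    ----------
    centroids : DataFrame with columns time, lon, lat, height.
    wind : DataFrame as returned by :func:`read_wind_csv`; must be non-empty.
    """
    if len(wind) == 0:
        raise ConfigurationError("wind table is empty")
    wt = wind.reset_index(drop=True)
    wtimes = wt["time"].astype("int64").to_numpy() / 1e9
    order_rows = []
    for row in centroids.itertuples(index=False):
        t = pd.Timestamp(row.time).value / 1e9
        dt = np.abs(wtimes - t)
        cand = np.flatnonzero(dt == dt.min())
        if len(cand) > 1:
            dh = haversine_m(row.lon, row.lat, wt.loc[cand, "lon"], wt.loc[cand, "lat"])
            dz = wt.loc[cand, "height"].to_numpy(dtype=float) - float(row.height)
            dist = np.hypot(dh, dz)
            cand = cand[np.flatnonzero(dist == dist.min())]
        if len(cand) > 1:  # final tie-break: earliest record
            cand = cand[np.argsort(wtimes[cand], kind="stable")[:1]]
        order_rows.append(int(cand[0]))
    return wt.iloc[order_rows].reset_index(drop=True)


def load_config(path) -> PipelineConfig:
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    known = {f for f in PipelineConfig.__dataclass_fields__}
    unknown = set(raw) - known
    if unknown:
        raise ConfigurationError(f"{path}: unknown config keys {sorted(unknown)}")
    return PipelineConfig(**raw)


def save_config(config: PipelineConfig, path) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(asdict(config), fh, sort_keys=False)
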