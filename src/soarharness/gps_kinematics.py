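"""Per-fix GPS kinematics and the soaring/gliding split.

Tracks are reduced to 1 Hz, forward-difference step metrics are computed on
a spherical earth, vertical speed is smoothed with a 15 s centred running
mean, and a two-cluster split of the smoothed vertical speed separates
soaring (climbing in rising air, positive centre) from gliding (descending
between thermals, negative centre).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .acc_features import DegenerateInputError, kmeans_1d

__all__ = [
    "GpsTrack",
    "haversine_m",
    "initial_bearing_rad",
    "subsample_to_1hz",
    "step_metrics",
    "smooth_vertical_speed",
    "classify_soar_glide",
]

EARTH_RADIUS_M = 6_371_000.0

#: smoothing window (seconds) applied to vertical speed before clustering
VSPEED_SMOOTH_S = 15


@dataclass
class GpsTrack:
    """Timestamped GPS fixes for one flight session.

    ``data`` has one row per fix with at least ``time, lon, lat, height``
    (decimal degrees, metres a.s.l.); the functions in this module add
    ``step_length, horiz_speed, vert_speed, vert_speed_smooth, movement``.
    ``meta`` carries session identity (session_id, individual_id, species,
    harness, date) inherited by every downstream table.
    """

    data: pd.DataFrame
    rate: float
    meta: dict = field(default_factory=dict)

    def __len__(self) -> int:
        return len(self.data)


def haversine_m(lon1, lat1, lon2, lat2) -> np.ndarray:
    """Great-circle distance in metres on a sphere of radius 6371 km."""
    lon1, lat1, lon2, lat2 = (np.radians(np.asarray(a, dtype=float)) for a in (lon1, lat1, lon2, lat2))
    dlat = lat2 - lat1
    dlon = lon2 - lon1
    h = np.sin(dlat / 2.0) ** 2 + np.cos(lat1) * np.cos(lat2) * np.sin(dlon / 2.0) ** 2
    return 2.0 * EARTH_RADIUS_M * np.arcsin(np.sqrt(np.clip(h, 0.0, 1.0)))


def initial_bearing_rad(lon1, lat1, lon2, lat2) -> float:
    """Initial great-circle bearing from point 1 to point 2.

    Radians clockwise from north. Undefined (NaN) for zero displacement.
    """
    if lon1 == lon2 and lat1 == lat2:
        return float("nan")
    lam1, phi1, lam2, phi2 = map(np.radians, (lon1, lat1, lon2, lat2))
    y = np.sin(lam2 - lam1) * np.cos(phi2)
    x = np.cos(phi1) * np.sin(phi2) - np.sin(phi1) * np.cos(phi2) * np.cos(lam2 - lam1)
    return float(np.arctan2(y, x) % (2.0 * np.pi))


def subsample_to_1hz(track: GpsTrack) -> GpsTrack:
    """Reduce a track to one fix per whole second (the first within each).

    A 1 Hz track passes through unchanged apart from index renumbering.
    """
    df = track.data
    second = df["time"].dt.floor("s")
    keep = ~second.duplicated(keep="first")
    out = df.loc[keep].reset_index(drop=True)
    return GpsTrack(out, 1.0, dict(track.meta))


def step_metrics(track: GpsTrack) -> GpsTrack:
    """Forward-difference step length, horizontal and vertical speed.

    Each fix carries the metrics of the step to the *next* fix; the last
    fix carries missing values. Fixes with a non-positive time step
    (duplicate or out-of-order timestamps) are dropped with a warning.
    """
    df = track.data.reset_index(drop=True)
    if len(df) < 2:
        raise ValueError("need at least 2 fixes to compute step metrics")
    t = df["time"].astype("int64").to_numpy() / 1e9
    dt = np.diff(t)
    bad = dt <= 0
    if bad.any():
        warnings.warn(f"dropping {int(bad.sum())} fixes with non-positive time step", stacklevel=2)
        keep = np.concatenate(([True], dt > 0))
        df = df.loc[keep].reset_index(drop=True)
        t = df["time"].astype("int64").to_numpy() / 1e9
        dt = np.diff(t)

    lon = df["lon"].to_numpy(dtype=float)
    lat = df["lat"].to_numpy(dtype=float)
    h = df["height"].to_numpy(dtype=float)
    step = haversine_m(lon[:-1], lat[:-1], lon[1:], lat[1:])
    df["step_length"] = np.append(step, np.nan)
    df["horiz_speed"] = np.append(step / dt, np.nan)
    df["vert_speed"] = np.append(np.diff(h) / dt, np.nan)
    return GpsTrack(df, track.rate, dict(track.meta))


def smooth_vertical_speed(track: GpsTrack, window: int = VSPEED_SMOOTH_S) -> GpsTrack:
    """Centred running mean of vertical speed over ``window`` seconds.

    At 1 Hz the window is ``window`` samples (forced odd), truncated at the
    track boundaries; missing values (e.g. the last fix) are ignored within
    each window rather than propagated.
    """
    df = track.data.copy()
    w = int(window)
    if w % 2 == 0:
        w -= 1
    w = max(w, 1)
    df["vert_speed_smooth"] = (
        df["vert_speed"].rolling(window=w, center=True, min_periods=1).mean()
    )
    return GpsTrack(df, track.rate, dict(track.meta))


def classify_soar_glide(track: GpsTrack, seed: int | None = None) -> GpsTrack:
    """Split fixes into soaring and gliding on smoothed vertical speed.

    Exact 1-D k-means with k=2 per flight session; the higher-centre
    cluster is soaring, the lower gliding. Degenerate input (all smoothed
    values identical, e.g. a monotone climb with no variation) leaves every
    fix unclassified with a warning.
    """
    df = track.data.copy()
    valid = df["vert_speed_smooth"].notna()
    df["movement"] = pd.Series(pd.NA, index=df.index, dtype="object")
    values = df.loc[valid, "vert_speed_smooth"].to_numpy(dtype=float)
    try:
        labels, _ = kmeans_1d(values, seed=seed)
    except DegenerateInputError:
        warnings.warn("degenerate smoothed vertical speed; fixes left unclassified", stacklevel=2)
        return GpsTrack(df, track.rate, dict(track.meta))
    df.loc[valid, "movement"] = np.where(labels == 1, "soaring", "gliding")
    return GpsTrack(df, track.rate, dict(track.meta))
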