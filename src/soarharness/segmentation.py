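"""Behavioural segments and per-segment flight parameters.

The per-second activity label (active/passive, from VeDBA) and the per-fix
movement label (soaring/gliding, from smoothed vertical speed) are crossed
into four behaviour classes. Maximal runs of consecutive fixes sharing a
class become behavioural segments; runs shorter than five fixes are
discarded. Each segment is summarised by its mean vertical and horizontal
speed, maximum height a.s.l., mean VeDBA, glide ratio (gliding only) and —
after wind annotation — airspeed via the wind triangle.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd

from .gps_kinematics import GpsTrack, initial_bearing_rad
from .io_formats import annotate_wind

__all__ = [
    "combine_classes",
    "build_segments",
    "glide_ratio",
    "airspeed_from_wind",
    "annotate_segments_wind",
    "filter_high_speed",
    "filter_glide_validity",
]

logger = logging.getLogger("soarharness")

MIN_FIXES = 5
SPEED_THRESHOLD = 4.0       # m/s: separates stationary/perched from flight segments
GLIDE_VSPEED_MAX = -0.2     # m/s: gliding segments must sink faster than this

#: columns of the segment table (the analysis dataset)
SEGMENT_COLUMNS = [
    "segment_id", "session_id", "individual_id", "species", "harness", "date",
    "behaviour", "n_fixes", "start", "end",
    "mean_vert_speed", "mean_horiz_speed", "max_height", "mean_vedba",
    "distance", "glide_ratio",
    "centroid_time", "centroid_lon", "centroid_lat", "centroid_height",
    "bearing", "hour_centred",
]


def combine_classes(track: GpsTrack) -> GpsTrack:
    """Cross activity (active/passive) with movement (soaring/gliding).

    Fixes missing either label get no behaviour class and are excluded from
    segmentation (they break runs).
    """
    df = track.data.copy()
    both = df["activity"].notna() & df["movement"].notna()
    behaviour = pd.Series(pd.NA, index=df.index, dtype="object")
    behaviour[both] = df.loc[both, "activity"].astype(str) + "_" + df.loc[both, "movement"].astype(str)
    df["behaviour"] = behaviour
    return GpsTrack(df, track.rate, dict(track.meta))


def glide_ratio(horizontal_distance: float, height_drop: float) -> float:
    """Horizontal distance covered per unit of height dropped.

    Defined only for a positive drop; otherwise NaN (the segment is then
    excluded from glide-ratio analyses).
    """
    if not height_drop > 0:
        return float("nan")
    return float(horizontal_distance) / float(height_drop)


def build_segments(track: GpsTrack, min_fixes: int = MIN_FIXES) -> pd.DataFrame:
    """Turn a classified track into the per-segment analysis table.

    Maximal runs of identical behaviour class become segments; runs of
    fewer than ``min_fixes`` consecutive fixes are discarded. Step-based
    parameters (mean speeds, distance, glide ratio) aggregate the
    ``n_fixes − 1`` steps internal to the segment, so on a constant-rate
    glide the glide ratio equals |horizontal rate / vertical rate| exactly.
    The segment centroid is the mean fix position at the midpoint time;
    ``hour_centred`` is the centroid's UTC hour minus 12.
    """
    df = track.data.reset_index(drop=True)
    meta = track.meta
    beh = df["behaviour"]
    # run-length encode; missing classes break runs and are never segments
    key = beh.fillna("__none__")
    run_id = (key != key.shift()).cumsum()

    rows = []
    k = 0
    for _, idx in df.groupby(run_id, sort=False).groups.items():
        sub = df.loc[idx]
        behaviour = sub["behaviour"].iloc[0]
        if pd.isna(behaviour) or len(sub) < min_fixes:
            continue
        k += 1
        t = sub["time"]
        h = sub["height"].to_numpy(dtype=float)
        dt_total = (t.iloc[-1] - t.iloc[0]).total_seconds()
        inner_steps = sub["step_length"].to_numpy(dtype=float)[:-1]
        distance = float(np.nansum(inner_steps))
        mean_horiz = distance / dt_total if dt_total > 0 else float("nan")
        mean_vert = (h[-1] - h[0]) / dt_total if dt_total > 0 else float("nan")
        is_glide = str(behaviour).endswith("gliding")
        gr = glide_ratio(distance, h[0] - h[-1]) if is_glide else float("nan")
        centroid_time = t.iloc[0] + (t.iloc[-1] - t.iloc[0]) / 2
        hour = centroid_time.hour + centroid_time.minute / 60 + centroid_time.second / 3600
        brg = initial_bearing_rad(
            float(sub["lon"].iloc[0]), float(sub["lat"].iloc[0]),
            float(sub["lon"].iloc[-1]), float(sub["lat"].iloc[-1]),
        )
        rows.append(
            {
                "segment_id": f"{meta.get('session_id', 'na')}-{k:04d}",
                "session_id": meta.get("session_id"),
                "individual_id": meta.get("individual_id"),
                "species": meta.get("species"),
                "harness": meta.get("harness"),
                "date": meta.get("date"),
                "behaviour": behaviour,
                "n_fixes": len(sub),
                "start": t.iloc[0],
                "end": t.iloc[-1],
                "mean_vert_speed": mean_vert,
                "mean_horiz_speed": mean_horiz,
                "max_height": float(np.max(h)),
                "mean_vedba": float(sub["vedba"].mean()) if "vedba" in sub else float("nan"),
                "distance": distance,
                "glide_ratio": gr,
                "centroid_time": centroid_time,
                "centroid_lon": float(sub["lon"].mean()),
                "centroid_lat": float(sub["lat"].mean()),
                "centroid_height": float(np.mean(h)),
                "bearing": brg,
                "hour_centred": hour - 12.0,
            }
        )
    return pd.DataFrame(rows, columns=SEGMENT_COLUMNS)


def airspeed_from_wind(ground_speed: float, bearing_rad: float, u: float, v: float) -> float:
    """Airspeed from the wind triangle.

    The wind is projected onto the travel direction (wind support ``ws``)
    and its perpendicular (crosswind ``cw``); the air vector is the ground
    vector minus the wind, giving ``sqrt((vg − ws)² + cw²)``. Bearing is in
    radians clockwise from north; undefined bearing gives NaN.
    """
    if not np.isfinite(bearing_rad):
        return float("nan")
    ws = u * np.sin(bearing_rad) + v * np.cos(bearing_rad)
    cw = u * np.cos(bearing_rad) - v * np.sin(bearing_rad)
    return float(np.hypot(ground_speed - ws, cw))


def annotate_segments_wind(segments: pd.DataFrame, wind: pd.DataFrame) -> pd.DataFrame:
    """Attach the nearest wind record to each segment and compute airspeed.

    The segment centroid (time, lon, lat, height) is matched to the wind
    table by closest time, then closest 3-D position; ``wind_u``/``wind_v``
    and ``airspeed`` columns are added.
    """
    out = segments.copy()
    if len(out) == 0:
        out["wind_u"] = out["wind_v"] = out["airspeed"] = np.nan
        return out
    centroids = out[["centroid_time", "centroid_lon", "centroid_lat", "centroid_height"]].rename(
        columns={"centroid_time": "time", "centroid_lon": "lon",
                 "centroid_lat": "lat", "centroid_height": "height"}
    )
    matched = annotate_wind(centroids, wind)
    out["wind_u"] = matched["u"].to_numpy()
    out["wind_v"] = matched["v"].to_numpy()
    out["airspeed"] = [
        airspeed_from_wind(g, b, u, v)
        for g, b, u, v in zip(out["mean_horiz_speed"], out["bearing"], out["wind_u"], out["wind_v"])
    ]
    return out


def filter_high_speed(segments: pd.DataFrame, threshold: float = SPEED_THRESHOLD) -> pd.DataFrame:
    """Keep segments with mean horizontal speed above ``threshold`` (m/s).

    Very-low-speed segments occur around the release point and cannot be
    attributed to a flight behaviour; the dropped count is logged.
    """
    keep = segments["mean_horiz_speed"] > threshold
    n_dropped = int((~keep).sum())
    logger.info("filter_high_speed: dropped %d of %d segments (<= %g m/s)",
                n_dropped, len(segments), threshold)
    return segments.loc[keep].reset_index(drop=True)


def filter_glide_validity(segments: pd.DataFrame, vspeed_max: float = GLIDE_VSPEED_MAX):
    """Restrict gliding segments to those actually sinking.

    Keeps gliding segments with mean vertical speed below ``vspeed_max``
    (default −0.2 m/s): near-level 'glides' produce unrealistically high
    glide ratios. Returns ``(kept, n_excluded)`` where the excluded count
    covers gliding segments that failed the threshold.
    """
    is_glide = segments["behaviour"].astype(str).str.endswith("gliding")
    keep = is_glide & (segments["mean_vert_speed"] < vspeed_max)
    n_excluded = int((is_glide & ~keep).sum())
    logger.info("filter_glide_validity: excluded %d of %d gliding segments",
                n_excluded, int(is_glide.sum()))
    return segments.loc[keep].reset_index(drop=True), n_excluded
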