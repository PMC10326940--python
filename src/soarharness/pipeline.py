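"""End-to-end orchestration: raw streams -> segments and session summaries.

Thin glue over the module surface: decompose accelerometry and classify
activity per second, derive GPS kinematics and classify movement per fix,
join the two label streams on whole seconds, cross them into behaviour
classes, build the segment table, annotate wind and airspeed, and apply
the speed filter.
"""

from __future__ import annotations

import logging

import pandas as pd

from . import acc_features, gps_kinematics, segmentation, session_metrics
from .acc_features import AccStream
from .gps_kinematics import GpsTrack
from .io_formats import PipelineConfig

__all__ = ["process_session", "process_study"]

logger = logging.getLogger("soarharness")


def process_session(gps: GpsTrack, acc: AccStream,
                    config: PipelineConfig | None = None):
    """Run the full per-session pipeline.

    Returns ``(track, segments, session_summary)``: the classified 1 Hz
    track, the per-segment table (speed-filtered, without wind annotation)
    and the whole-session summary.
    """
    config = config or PipelineConfig()

    acc = acc_features.decompose(acc, window=config.static_window_s)
    seconds = acc_features.per_second_summary(acc)
    seconds = acc_features.classify_activity(
        seconds, seed=config.seed, min_separation=config.activity_min_separation
    )

    track = gps_kinematics.subsample_to_1hz(gps)
    track = gps_kinematics.step_metrics(track)
    track = gps_kinematics.smooth_vertical_speed(track, window=config.vspeed_smooth_s)
    track = gps_kinematics.classify_soar_glide(track, seed=config.seed)

    # join activity and per-second VeDBA onto the GPS fix of the same second
    df = track.data.copy()
    df["second"] = df["time"].dt.floor("s")
    df = df.merge(seconds.rename(columns={"mean_vedba": "vedba"}), on="second", how="left")
    df = df.drop(columns=["second"])
    track = GpsTrack(df, track.rate, dict(track.meta))

    track = segmentation.combine_classes(track)
    segments = segmentation.build_segments(track, min_fixes=config.min_fixes)
    segments = segmentation.filter_high_speed(segments, threshold=config.speed_threshold)
    summary = session_metrics.summarize_session(track)
    logger.info("process_session %s: %d fixes -> %d segments",
                track.meta.get("session_id"), len(track), len(segments))
    return track, segments, summary


def process_study(sessions, wind: pd.DataFrame | None = None,
                  config: PipelineConfig | None = None):
    """Process many sessions into pooled segment and session tables.

    ``sessions`` yields ``(GpsTrack, AccStream)`` pairs (session identity
    travels in the track metadata). When a wind table is given, segments
    are annotated with the nearest wind record and airspeed.
    """
    seg_tables, summaries = [], []
    for gps, acc in sessions:
        _, segments, summary = process_session(gps, acc, config)
        seg_tables.append(segments)
        summaries.append(summary)
    segments = pd.concat(seg_tables, ignore_index=True) if seg_tables else pd.DataFrame()
    if wind is not None and len(segments):
        segments = segmentation.annotate_segments_wind(segments, wind)
    sessions_df = session_metrics.sessions_table(summaries)
    return segments, sessions_df
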