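"""End-to-end session runner: frames + radar in, alarm timeline + events out.

Ties the stages together for one bed: depth-to-height transform,
background subtraction and blob segmentation, time masking, tracking,
radar respiration estimates, presence fusion, posture classification, the
alarm state machine and event extraction.  Works identically on simulator
output (in memory) and on frame directories read from disk.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable

import numpy as np

from .geometry import (
    CrossingEvent,
    DepthFrame,
    SensorConfig,
    ZoneLabel,
    ZoneMap,
    depth_to_height,
)
from .pipeline import (
    BackgroundModel,
    SubjectObservation,
    Track,
    Tracker,
    apply_time_mask,
    label_zones,
    segment_blobs,
)
from .posture import (
    AlarmFrame,
    AlarmStateMachine,
    ClassifierThresholds,
    EventRecord,
    PostureHistory,
    PostureState,
    classify_posture,
    extract_events,
    resident_tracks,
)
from .respiration import RadarTrace, fuse_presence, sliding_estimates


@dataclass
class SessionResult:
    """Everything one monitored session produces."""

    tracks: list[Track]
    timeline: list[AlarmFrame]
    events: list[EventRecord]
    fused_presence: list[tuple[float, bool]]
    resident_ids: list[int] = field(default_factory=list)


def run_session(
    frames: Iterable[DepthFrame],
    radar: RadarTrace | None,
    zones: ZoneMap,
    config: SensorConfig,
    background: BackgroundModel,
    thresholds: ClassifierThresholds | None = None,
    persistence_window: float = 120.0,
) -> SessionResult:
    """Run the full monitoring pipeline over one frame sequence.

    ``frames`` must be time-ordered.  ``radar`` may be None (depth-only
    presence).  The returned timeline has one resolved posture/alarm state
    per frame for the bed's resident track.
    """
    th = thresholds or ClassifierThresholds()
    tracker = Tracker()
    depth_presence: list[tuple[float, bool]] = []
    prev_hm = None
    for frame in frames:
        hm = depth_to_height(frame, config)
        obs = segment_blobs(hm, background, config=config, previous_heights=prev_hm)
        label_zones(obs, zones)
        tracker.step(obs, frame.timestamp)
        depth_presence.append(
            (frame.timestamp, any(o.zone == ZoneLabel.BED for o in obs))
        )
        prev_hm = hm

    apply_time_mask(tracker.tracks, persistence_window)

    resp = sliding_estimates(radar) if radar is not None else []
    fused = fuse_presence(depth_presence, resp)
    fused_map = {round(t, 3): p for t, p in fused}

    residents = resident_tracks(tracker.tracks, th)
    resident_ids = [t.track_id for t in residents]
    primary = max(residents, key=lambda t: t.time_in_zone(ZoneLabel.BED), default=None)

    # per-frame lookup of the resident's observation and zone crossings
    obs_at: dict[float, SubjectObservation] = {}
    crossings_at: dict[float, list[CrossingEvent]] = {}
    if primary is not None:
        prev_obs = None
        for o in primary.observations:
            key = round(o.frame_timestamp, 3)
            if not o.stationary:
                obs_at[key] = o
            if prev_obs is not None and o.zone != prev_obs.zone:
                crossings_at.setdefault(key, []).append(
                    CrossingEvent(o.frame_timestamp, prev_obs.zone, o.zone)
                )
            prev_obs = o

    machine = AlarmStateMachine(zones, th)
    history = PostureHistory()
    timeline: list[AlarmFrame] = []
    for t, _ in depth_presence:
        key = round(t, 3)
        obs = obs_at.get(key)
        presence = fused_map.get(key, False)
        posture = classify_posture(obs, zones, th, history, bed_presence=presence)
        near_edge = zones.near_bed_edge(*obs.centroid) if obs is not None else False
        alarm = machine.step(
            t,
            posture,
            obs.zone if obs is not None else None,
            crossings_at.get(key, []),
            presence,
            track_id=primary.track_id if primary is not None else None,
            near_bed_edge=near_edge,
        )
        timeline.append(
            AlarmFrame(
                timestamp=t,
                posture=posture,
                alarm=alarm,
                track_id=primary.track_id if primary is not None else None,
                zone=obs.zone if obs is not None else None,
            )
        )

    events = extract_events(timeline, tracker.tracks, th)
    return SessionResult(
        tracks=tracker.tracks,
        timeline=timeline,
        events=events,
        fused_presence=fused,
        resident_ids=resident_ids,
    )
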