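"""Threshold decision-tree posture states, alarm escalation and events.

Posture is classified per frame from where the blob centroid sits in the
virtual fence and how high the blob rises above the bed surface or the
floor.  The alarm escalates GREEN -> YELLOW (lingering at the bed edge or
standing by the bed) -> RED (the tracked resident crosses from the leave
zone into the boundary zone).  RED latches until the resident returns to
the bed or an operator resets it; GREY marks a bed both channels agree is
empty.  Maximal RED episodes become bed-exit events, labelled assisted
when a second, non-bed-originating track is concurrently in the room.
"""

from __future__ import annotations

import enum
import logging
from dataclasses import dataclass, field

import numpy as np

from .geometry import CrossingEvent, ZoneLabel, ZoneMap
from .pipeline import SubjectObservation, Track

logger = logging.getLogger(__name__)


class PostureState(enum.Enum):
    SLEEPING = "SLEEPING"
    LYING = "LYING"
    SITTING = "SITTING"
    SITTING_ON_EDGE = "SITTING_ON_EDGE"
    STANDING = "STANDING"
    BED_EXITING = "BED_EXITING"
    EMPTY = "EMPTY"
    OTHER = "OTHER"


class AlarmLevel(enum.Enum):
    GREEN = "GREEN"
    YELLOW = "YELLOW"
    RED = "RED"
    GREY = "GREY"


@dataclass(frozen=True)
class ClassifierThresholds:
    """Tunable decision-tree constants.

    All heights are mm; rises are measured above the bed surface.  The
    defaults are anthropometric: a lying torso stays within ~0.4 m of the
    mattress, a seated torso within ~0.75 m, and an adult standing crown is
    above 1.1 m from the floor even for the shortest residents monitored.
    """

    lying_max_rise: float = 400.0
    sitting_max_rise: float = 750.0
    standing_min_height: float = 1100.0
    sleep_motion_max: float = 10.0
    sleep_min_duration: float = 60.0
    yellow_debounce: float = 2.0
    merge_gap: float = 30.0
    assistance_window: float = 30.0
    #: cumulative seconds in the bed zone before a track counts as the resident
    resident_min_bed_time: float = 1.0

    def __post_init__(self) -> None:
        if not 0 < self.lying_max_rise < self.sitting_max_rise:
            raise ValueError("need 0 < lying_max_rise < sitting_max_rise")
        for name in ("standing_min_height", "yellow_debounce", "merge_gap"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")


@dataclass
class PostureHistory:
    """Rolling per-track context the stateless classifier needs."""

    still_since: float | None = None  # start of the current low-motion run
    last_states: list[PostureState] = field(default_factory=list)
    prev_boundary_distance: float | None = None


def classify_posture(
    obs: SubjectObservation | None,
    zones: ZoneMap,
    th: ClassifierThresholds,
    history: PostureHistory,
    bed_presence: bool = True,
) -> PostureState:
    """One step of the decision tree; updates ``history`` in place.

    With no observation the state is EMPTY once the fused presence channel
    agrees the bed is empty, OTHER while presence persists (e.g. a subject
    under a thick blanket whom only the radar sees).
    """
    if obs is None:
        state = PostureState.OTHER if bed_presence else PostureState.EMPTY
        history.last_states.append(state)
        history.still_since = None
        return state

    t = obs.frame_timestamp
    rise = obs.max_height - zones.bed_surface_height

    if obs.zone == ZoneLabel.BED:
        if rise <= th.lying_max_rise:
            moving = not np.isnan(obs.motion_index) and obs.motion_index > th.sleep_motion_max
            if moving:
                history.still_since = None
            elif history.still_since is None:
                history.still_since = t
            if (
                history.still_since is not None
                and t - history.still_since >= th.sleep_min_duration
            ):
                state = PostureState.SLEEPING
            else:
                state = PostureState.LYING
        elif rise <= th.sitting_max_rise:
            history.still_since = None
            if zones.near_bed_edge(*obs.centroid):
                state = PostureState.SITTING_ON_EDGE
            else:
                state = PostureState.SITTING
        elif obs.max_height >= th.standing_min_height:
            history.still_since = None
            state = PostureState.STANDING
        else:
            history.still_since = None
            state = PostureState.OTHER
    elif obs.zone == ZoneLabel.LEAVE:
        history.still_since = None
        # heading outward? compare distance to the boundary-zone rim
        d = zones.leave_zone.exterior.distance(_point(obs.centroid))
        prev = history.prev_boundary_distance
        history.prev_boundary_distance = d
        if prev is not None and d < prev - 1e-9:
            state = PostureState.BED_EXITING
        else:
            state = PostureState.STANDING
    elif obs.zone == ZoneLabel.BOUNDARY:
        history.still_since = None
        state = PostureState.BED_EXITING
    else:
        history.still_since = None
        state = PostureState.OTHER

    if obs.zone != ZoneLabel.LEAVE:
        history.prev_boundary_distance = None
    history.last_states.append(state)
    return state


def _point(xy):
    from shapely.geometry import Point

    return Point(xy[0], xy[1])


# --------------------------------------------------------------------------
# alarm state machine
# --------------------------------------------------------------------------


@dataclass
class AlarmFrame:
    """Per-frame resolved state for one bed."""

    timestamp: float
    posture: PostureState
    alarm: AlarmLevel
    track_id: int | None = None
    zone: ZoneLabel | None = None


class AlarmStateMachine:
    """GREEN / YELLOW / RED / GREY escalation for one bed.

    YELLOW requires the edge condition (sitting on the edge, or standing
    within the edge band of the bed) to persist for ``yellow_debounce``
    seconds, so brief oscillations across the bed rim never alert.  RED
    fires at a LEAVE->BOUNDARY crossing of the resident track and latches
    until the resident's centroid is back in the bed zone (or `reset` is
    called).  GREY requires fused presence to be negative with no RED
    latched.
    """

    def __init__(self, zones: ZoneMap, th: ClassifierThresholds):
        self.zones = zones
        self.th = th
        self.red_latched = False
        self.red_track: int | None = None
        self._yellow_since: float | None = None

    def reset(self) -> None:
        """Operator reset: clears a latched RED."""
        self.red_latched = False
        self.red_track = None

    def step(
        self,
        timestamp: float,
        posture: PostureState,
        zone: ZoneLabel | None,
        crossings: list[CrossingEvent],
        presence: bool,
        track_id: int | None = None,
        near_bed_edge: bool = False,
    ) -> AlarmLevel:
        for ev in crossings:
            if ev.from_zone == ZoneLabel.LEAVE and ev.to_zone == ZoneLabel.BOUNDARY:
                self.red_latched = True
                self.red_track = track_id
        if self.red_latched and zone == ZoneLabel.BED and track_id == self.red_track:
            self.reset()  # resident returned to bed

        if self.red_latched:
            self._yellow_since = None
            return AlarmLevel.RED

        edge_condition = posture == PostureState.SITTING_ON_EDGE or (
            posture == PostureState.STANDING and near_bed_edge
        )
        if edge_condition:
            if self._yellow_since is None:
                self._yellow_since = timestamp
            if timestamp - self._yellow_since >= self.th.yellow_debounce:
                return AlarmLevel.YELLOW
            return AlarmLevel.GREEN
        self._yellow_since = None

        if not presence and posture in (PostureState.EMPTY, PostureState.OTHER):
            return AlarmLevel.GREY
        if posture == PostureState.BED_EXITING:
            # outward motion without a crossing yet: pre-alert at yellow
            return AlarmLevel.YELLOW
        return AlarmLevel.GREEN


def update_alarm(
    sequence: list[tuple[float, PostureState, ZoneLabel | None, list[CrossingEvent], bool]],
    zones: ZoneMap,
    th: ClassifierThresholds,
) -> list[AlarmLevel]:
    """Run the state machine over a contiguous per-frame sequence.

    Each element is ``(timestamp, posture, zone, crossings, presence)``
    for the resident track of one bed.
    """
    machine = AlarmStateMachine(zones, th)
    out = []
    for t, posture, zone, crossings, presence in sequence:
        out.append(machine.step(t, posture, zone, crossings, presence))
    return out


# --------------------------------------------------------------------------
# events
# --------------------------------------------------------------------------


class EventType(enum.Enum):
    BED_EXIT = "BED_EXIT"
    RETURN = "RETURN"


class Assistance(enum.Enum):
    ASSISTED = "ASSISTED"
    NON_ASSISTED = "NON_ASSISTED"


@dataclass
class EventRecord:
    event_type: EventType
    start: float
    end: float
    assistance: Assistance | None
    max_alarm: AlarmLevel
    track_id: int | None = None

    def __post_init__(self) -> None:
        if self.start >= self.end:
            raise ValueError("event start must precede end")

    def to_dict(self) -> dict:
        return {
            "event_type": self.event_type.value,
            "start": round(self.start, 3),
            "end": round(self.end, 3),
            "assistance": self.assistance.value if self.assistance else None,
            "max_alarm": self.max_alarm.value,
            "track_id": self.track_id,
        }


def resident_tracks(tracks: list[Track], th: ClassifierThresholds) -> list[Track]:
    """Tracks that plausibly belong to the monitored resident.

    A track qualifies once it has spent ``resident_min_bed_time`` seconds
    with its centroid in the bed zone.  Caregivers and passers-by enter
    from the door and never dwell in the bed zone, so they never qualify —
    this is what keeps a roommate's pass-through from raising a bed-exit.
    """
    return [
        t for t in tracks if t.time_in_zone(ZoneLabel.BED) >= th.resident_min_bed_time
    ]


def extract_events(
    timeline: list[AlarmFrame],
    tracks: list[Track],
    th: ClassifierThresholds,
) -> list[EventRecord]:
    """Extract bed-exit and return events from an alarm timeline.

    One BED_EXIT per maximal RED episode; episodes separated by less than
    ``merge_gap`` seconds are merged (a pause in the boundary zone is one
    exit, not two).  Assistance is ASSISTED when a second concurrent track
    that did not originate in the bed zone is present within
    ``assistance_window`` seconds of the exit start.
    """
    # maximal RED runs
    episodes: list[tuple[float, float, int | None]] = []
    run_start: float | None = None
    run_track: int | None = None
    last_t: float | None = None
    for fr in timeline:
        if fr.alarm == AlarmLevel.RED:
            if run_start is None:
                run_start = fr.timestamp
                run_track = fr.track_id
            last_t = fr.timestamp
        else:
            if run_start is not None:
                episodes.append((run_start, fr.timestamp, run_track))
                run_start = None
    if run_start is not None and last_t is not None:
        end = timeline[-1].timestamp if timeline else last_t
        episodes.append((run_start, max(end, run_start + 1e-3), run_track))

    # merge close episodes
    merged: list[tuple[float, float, int | None]] = []
    for ep in episodes:
        if merged and ep[0] - merged[-1][1] < th.merge_gap:
            logger.warning("merging RED episodes at %.1f s and %.1f s", merged[-1][0], ep[0])
            merged[-1] = (merged[-1][0], ep[1], merged[-1][2])
        else:
            merged.append(list(ep))  # type: ignore[arg-type]
    residents = {t.track_id for t in resident_tracks(tracks, th)}

    events: list[EventRecord] = []
    for start, end, track_id in merged:
        assisted = _second_track_present(tracks, residents, start, th.assistance_window)
        events.append(
            EventRecord(
                event_type=EventType.BED_EXIT,
                start=start,
                end=end,
                assistance=Assistance.ASSISTED if assisted else Assistance.NON_ASSISTED,
                max_alarm=AlarmLevel.RED,
                track_id=track_id,
            )
        )
        # RETURN: resident back in bed after the episode
        for tr in tracks:
            if tr.track_id != track_id:
                continue
            back = [
                o.frame_timestamp
                for o in tr.observations
                if o.frame_timestamp > end and o.zone == ZoneLabel.BED
            ]
            if back:
                events.append(
                    EventRecord(
                        event_type=EventType.RETURN,
                        start=back[0],
                        end=back[0] + 1e-3,
                        assistance=None,
                        max_alarm=AlarmLevel.GREEN,
                        track_id=track_id,
                    )
                )
    events.sort(key=lambda e: e.start)
    return events


def _second_track_present(
    tracks: list[Track], residents: set[int], exit_start: float, window: float
) -> bool:
    for tr in tracks:
        if tr.track_id in residents or not tr.observations:
            continue
        t0 = tr.observations[0].frame_timestamp
        t1 = tr.observations[-1].frame_timestamp
        if t0 <= exit_start + window and t1 >= exit_start - window:
            return True
    return False
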