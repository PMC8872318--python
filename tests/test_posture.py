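"""Decision-tree posture states, alarm escalation, event extraction."""

import numpy as np
import pytest

from bedwatch.geometry import CrossingEvent, ZoneLabel, detect_crossing
from bedwatch.pipeline import SubjectObservation, Track
from bedwatch.posture import (
    AlarmFrame,
    AlarmLevel,
    AlarmStateMachine,
    Assistance,
    ClassifierThresholds,
    EventRecord,
    EventType,
    PostureHistory,
    PostureState,
    classify_posture,
    extract_events,
    update_alarm,
)

TH = ClassifierThresholds()


def _obs(t, centroid, max_height, motion=3.0, zone=None, zones=None):
    if zone is None:
        zone = zones.assign(*centroid)
    return SubjectObservation(
        frame_timestamp=t,
        centroid=centroid,
        footprint_area=0.3,
        max_height=max_height,
        pixel_count=1000,
        zone=zone,
        motion_index=motion,
    )


class TestClassifyPosture:
    def test_still_lying_becomes_sleeping(self, zones):
        """Low blob, motion 3 mm for 90 s: LYING first, SLEEPING after 60 s."""
        history = PostureHistory()
        states = [
            classify_posture(_obs(t, (0.0, 0.0), zones.bed_surface_height + 300, zones=zones), zones, TH, history)
            for t in np.arange(0.0, 90.0, 1.0)
        ]
        assert states[0] is PostureState.LYING
        assert states[30] is PostureState.LYING
        assert states[61] is PostureState.SLEEPING
        assert states[-1] is PostureState.SLEEPING

    def test_no_blob_empty_after_presence_lost(self, zones):
        assert (
            classify_posture(None, zones, TH, PostureHistory(), bed_presence=False)
            is PostureState.EMPTY
        )

    def test_no_blob_but_radar_presence_is_other(self, zones):
        assert (
            classify_posture(None, zones, TH, PostureHistory(), bed_presence=True)
            is PostureState.OTHER
        )

    def test_boundary_centroid_is_bed_exiting(self, zones):
        obs = _obs(0.0, (0.0, 1200.0), 1600.0, zones=zones)
        assert classify_posture(obs, zones, TH, PostureHistory()) is PostureState.BED_EXITING

    @pytest.mark.parametrize(
        "centroid,rise,expected",
        [
            ((0.0, 0.0), 300.0, PostureState.LYING),
            ((0.0, 0.0), 600.0, PostureState.SITTING),
            ((0.0, 350.0), 600.0, PostureState.SITTING_ON_EDGE),
            ((0.0, 0.0), 1200.0, PostureState.STANDING),
        ],
        ids=["lying", "sitting", "edge", "standing"],
    )
    def test_in_bed_height_tiers(self, zones, centroid, rise, expected):
        obs = _obs(0.0, centroid, zones.bed_surface_height + rise, motion=20.0, zones=zones)
        assert classify_posture(obs, zones, TH, PostureHistory()) is expected


def _walkout_track(zones, fps=10.0):
    """Scripted centroid track BED -> LEAVE -> BOUNDARY at 0.1 s steps."""
    ts, pts = [], []
    for i in range(200):
        t = i / fps
        y = -100.0 + (1400.0 * i / 199.0)  # exits through +y
        ts.append(t)
        pts.append((0.0, y))
    return list(zip(ts, pts))


class TestAlarm:
    def test_lying_all_night_green(self, zones):
        seq = [
            (t, PostureState.LYING, ZoneLabel.BED, [], True) for t in np.arange(0, 60.0, 0.5)
        ]
        assert set(update_alarm(seq, zones, TH)) == {AlarmLevel.GREEN}

    def test_edge_sit_yellow_then_green(self, zones):
        seq = (
            [(t, PostureState.LYING, ZoneLabel.BED, [], True) for t in np.arange(0, 5, 0.5)]
            + [(t, PostureState.SITTING_ON_EDGE, ZoneLabel.BED, [], True) for t in np.arange(5, 10, 0.5)]
            + [(t, PostureState.LYING, ZoneLabel.BED, [], True) for t in np.arange(10, 15, 0.5)]
        )
        levels = update_alarm(seq, zones, TH)
        by_time = dict(zip([s[0] for s in seq], levels))
        assert by_time[5.0] is AlarmLevel.GREEN  # debounce not yet elapsed
        assert by_time[8.0] is AlarmLevel.YELLOW
        assert by_time[12.0] is AlarmLevel.GREEN

    def test_red_at_leave_boundary_crossing_frame(self, zones):
        """RED fires exactly at the LEAVE->BOUNDARY crossing detect_crossing finds."""
        track = _walkout_track(zones)
        crossings = detect_crossing(track, zones)
        red_cross = [
            c for c in crossings
            if c.from_zone is ZoneLabel.LEAVE and c.to_zone is ZoneLabel.BOUNDARY
        ]
        assert len(red_cross) == 1

        machine = AlarmStateMachine(zones, TH)
        labels = [zones.assign(*p) for _, p in track]
        first_red = None
        for i, (t, _) in enumerate(track):
            evs = (
                [CrossingEvent(t, labels[i - 1], labels[i])]
                if i and labels[i] != labels[i - 1]
                else []
            )
            level = machine.step(t, PostureState.BED_EXITING, labels[i], evs, True, track_id=1)
            if level is AlarmLevel.RED and first_red is None:
                first_red = t
        assert first_red == red_cross[0].timestamp

    def test_fast_oscillation_never_yellow(self, zones):
        """Edge states alternating faster than the debounce stay GREEN."""
        seq = []
        for i, t in enumerate(np.arange(0, 20, 0.5)):
            state = PostureState.SITTING_ON_EDGE if i % 3 == 0 else PostureState.SITTING
            seq.append((t, state, ZoneLabel.BED, [], True))
        assert AlarmLevel.YELLOW not in update_alarm(seq, zones, TH)

    def test_no_red_without_leave_boundary_crossing(self, zones):
        """A BED->BOUNDARY jump (no LEAVE->BOUNDARY crossing) never latches RED."""
        seq = [
            (0.0, PostureState.LYING, ZoneLabel.BED, [], True),
            (0.5, PostureState.BED_EXITING, ZoneLabel.BOUNDARY,
             [CrossingEvent(0.5, ZoneLabel.BED, ZoneLabel.BOUNDARY)], True),
            (1.0, PostureState.BED_EXITING, ZoneLabel.BOUNDARY, [], True),
        ]
        assert AlarmLevel.RED not in update_alarm(seq, zones, TH)

    def test_red_latches_until_return_to_bed(self, zones):
        machine = AlarmStateMachine(zones, TH)
        cross = CrossingEvent(1.0, ZoneLabel.LEAVE, ZoneLabel.BOUNDARY)
        assert machine.step(1.0, PostureState.BED_EXITING, ZoneLabel.BOUNDARY, [cross], True, 1) is AlarmLevel.RED
        # still red while away, even lying elsewhere
        assert machine.step(2.0, PostureState.OTHER, ZoneLabel.OUTSIDE, [], False, 1) is AlarmLevel.RED
        # returns to bed: resets
        assert machine.step(3.0, PostureState.LYING, ZoneLabel.BED, [], True, 1) is not AlarmLevel.RED


def _timeline(red_intervals, t_end=100.0, dt=0.5, track_id=1):
    frames = []
    for t in np.arange(0, t_end, dt):
        red = any(a <= t < b for a, b in red_intervals)
        frames.append(
            AlarmFrame(
                timestamp=float(t),
                posture=PostureState.BED_EXITING if red else PostureState.LYING,
                alarm=AlarmLevel.RED if red else AlarmLevel.GREEN,
                track_id=track_id,
            )
        )
    return frames


def _track(track_id, segments):
    """segments: list of (t0, t1, zone, centroid)."""
    obs = []
    for t0, t1, zone, centroid in segments:
        for t in np.arange(t0, t1, 0.5):
            obs.append(
                SubjectObservation(
                    frame_timestamp=float(t),
                    centroid=centroid,
                    footprint_area=0.3,
                    max_height=1000.0,
                    pixel_count=500,
                    zone=zone,
                    motion_index=5.0,
                )
            )
    return Track(track_id, obs, last_update=obs[-1].frame_timestamp if obs else 0.0)


class TestExtractEvents:
    def test_solo_exit_non_assisted(self, zones):
        resident = _track(1, [(0, 40, ZoneLabel.BED, (0.0, 0.0)), (40, 60, ZoneLabel.BOUNDARY, (0.0, 1200.0))])
        events = extract_events(_timeline([(40.0, 60.0)]), [resident], TH)
        exits = [e for e in events if e.event_type is EventType.BED_EXIT]
        assert len(exits) == 1
        assert exits[0].assistance is Assistance.NON_ASSISTED

    def test_caregiver_makes_exit_assisted(self, zones):
        resident = _track(1, [(0, 40, ZoneLabel.BED, (0.0, 0.0)), (40, 60, ZoneLabel.BOUNDARY, (0.0, 1200.0))])
        caregiver = _track(2, [(20, 60, ZoneLabel.LEAVE, (900.0, 700.0))])
        events = extract_events(_timeline([(40.0, 60.0)]), [resident, caregiver], TH)
        exits = [e for e in events if e.event_type is EventType.BED_EXIT]
        assert len(exits) == 1
        assert exits[0].assistance is Assistance.ASSISTED

    def test_pause_in_boundary_merges_to_one_event(self, zones):
        resident = _track(1, [(0, 40, ZoneLabel.BED, (0.0, 0.0)), (40, 80, ZoneLabel.BOUNDARY, (0.0, 1200.0))])
        events = extract_events(_timeline([(40.0, 50.0), (60.0, 80.0)]), [resident], TH)
        exits = [e for e in events if e.event_type is EventType.BED_EXIT]
        assert len(exits) == 1
        assert exits[0].start == 40.0 and exits[0].end == 80.0

    def test_return_event_emitted(self, zones):
        resident = _track(
            1,
            [
                (0, 40, ZoneLabel.BED, (0.0, 0.0)),
                (40, 60, ZoneLabel.BOUNDARY, (0.0, 1200.0)),
                (60, 80, ZoneLabel.BED, (0.0, 0.0)),
            ],
        )
        events = extract_events(_timeline([(40.0, 60.0)]), [resident], TH)
        assert [e.event_type for e in events] == [EventType.BED_EXIT, EventType.RETURN]

    def test_event_record_validates_interval(self):
        with pytest.raises(ValueError):
            EventRecord(EventType.BED_EXIT, 10.0, 10.0, None, AlarmLevel.RED)
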