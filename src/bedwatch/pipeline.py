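"""Foreground segmentation, blob features, time masking and tracking.

The background is a calibration capture of the empty room (median of N
empty frames); it is deliberately non-adaptive so a motionless sleeper is
never absorbed into it.  Long-stationary foreground objects (a parked
wheelchair, a dropped walking aid) are instead suppressed by a *time mask*
that flags blobs whose centroid and surface stop moving for a full
persistence window.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

from .geometry import (
    DepthFrame,
    HeightMap,
    InputError,
    SensorConfig,
    ZoneLabel,
    ZoneMap,
    depth_to_height,
)

logger = logging.getLogger(__name__)

#: Height offset above the background reference for foreground (mm).
DEFAULT_FOREGROUND_THRESHOLD = 100.0
#: Minimum blob footprint kept as a subject observation (m^2).
DEFAULT_MIN_BLOB_AREA = 0.05
#: Greedy association gate at the reference 10 fps frame interval (mm).
DEFAULT_GATE = 500.0
#: A track unmatched for longer than this is closed (s).
TRACK_TIMEOUT = 3.0
#: Time-mask thresholds: centroid drift (mm) and surface motion (mm).
STATIONARY_DRIFT = 100.0
STATIONARY_MOTION = 10.0


@dataclass
class BackgroundModel:
    """Empty-room reference heights (mm) plus the foreground threshold."""

    reference_heights: np.ndarray
    foreground_threshold: float = DEFAULT_FOREGROUND_THRESHOLD

    def __post_init__(self) -> None:
        if self.foreground_threshold <= 0:
            raise InputError("foreground_threshold must be positive")

    @classmethod
    def from_frames(
        cls,
        frames: list[DepthFrame],
        config: SensorConfig,
        foreground_threshold: float = DEFAULT_FOREGROUND_THRESHOLD,
    ) -> "BackgroundModel":
        """Calibrate from empty-room frames (per-pixel median height)."""
        if not frames:
            raise InputError("background calibration needs at least one frame")
        stack = np.stack([depth_to_height(f, config).heights for f in frames])
        return cls(np.median(stack, axis=0), foreground_threshold)


@dataclass
class SubjectObservation:
    """One foreground blob in one frame, with floor-coordinate features."""

    frame_timestamp: float
    centroid: tuple[float, float]  # floor mm
    footprint_area: float  # m^2
    max_height: float  # mm above floor
    pixel_count: int
    zone: ZoneLabel
    motion_index: float  # mean |height change| vs previous frame, mm
    mean_height: float = 0.0
    stationary: bool = False


@dataclass
class Track:
    """Time-ordered observations of one subject (or object)."""

    track_id: int
    observations: list[SubjectObservation] = field(default_factory=list)
    last_update: float = 0.0
    closed: bool = False
    # time-mask bookkeeping
    _anchor: tuple[float, float] | None = None
    _anchor_time: float = 0.0

    @property
    def start_time(self) -> float:
        return self.observations[0].frame_timestamp

    @property
    def centroid(self) -> tuple[float, float]:
        return self.observations[-1].centroid

    def time_in_zone(self, zone: ZoneLabel) -> float:
        """Cumulative observation time spent in ``zone`` (s), frame-count based."""
        if len(self.observations) < 2:
            return 0.0
        dts = np.diff([o.frame_timestamp for o in self.observations])
        flags = np.array([o.zone == zone for o in self.observations[1:]])
        return float(np.sum(dts[flags]))


# --------------------------------------------------------------------------
# silhouettes
# --------------------------------------------------------------------------


def render_silhouette(
    frame: DepthFrame,
    config: SensorConfig,
    background: BackgroundModel | None = None,
) -> np.ndarray:
    """Render the privacy-preserving 8-bit silhouette of a depth frame.

    Foreground pixels are shaded by normalised depth — the closest surface
    maps to 255 and the farthest foreground surface to 64 — so the image
    carries body contour but no facial or clothing detail.  Background and
    invalid pixels are 0.  Without a background model every valid pixel
    closer than the mount height is treated as foreground.
    """
    depth = frame.values.astype(np.float64, copy=False)
    valid = depth > 0
    if background is not None:
        heights = np.where(valid, config.mount_height - depth, 0.0)
        fg = valid & (heights > background.reference_heights + background.foreground_threshold)
    else:
        fg = valid & (depth < config.mount_height)
    out = np.zeros(depth.shape, dtype=np.uint8)
    if not fg.any():
        logger.warning("silhouette render: no foreground at t=%.2f", frame.timestamp)
        return out
    d = depth[fg]
    lo, hi = d.min(), d.max()
    if hi - lo < 1e-9:
        out[fg] = 255
        return out
    # closest -> 255, farthest foreground -> 64
    out[fg] = np.round(255 - (d - lo) / (hi - lo) * (255 - 64)).astype(np.uint8)
    return out


# --------------------------------------------------------------------------
# segmentation
# --------------------------------------------------------------------------

_EIGHT_CONN = np.ones((3, 3), dtype=bool)


def segment_blobs(
    heights: HeightMap,
    background: BackgroundModel,
    min_blob_area: float = DEFAULT_MIN_BLOB_AREA,
    config: SensorConfig | None = None,
    previous_heights: HeightMap | None = None,
) -> list[SubjectObservation]:
    """Segment foreground blobs from a height map and compute features.

    Foreground pixels exceed the background reference by the threshold;
    8-connected components smaller than ``min_blob_area`` (true footprint,
    m^2) are dropped.  Centroid, footprint area and heights are computed in
    floor coordinates so they are independent of where the blob sits in the
    image.  ``motion_index`` is the mean absolute change of the (lightly
    smoothed) height surface against the previous frame over the blob.
    """
    if background is None:
        raise InputError("segment_blobs requires a background model")
    if heights.heights.shape != background.reference_heights.shape:
        raise InputError("height map and background shapes differ")

    fg = heights.valid & (
        heights.heights > background.reference_heights + background.foreground_threshold
    )
    labels, n = ndimage.label(fg, structure=_EIGHT_CONN)
    if n == 0:
        return []

    # gather features over foreground pixels only (a tiny fraction of the frame)
    ys, xs = np.nonzero(fg)
    lab = labels[ys, xs]
    h_fg = heights.heights[ys, xs].astype(np.float64)
    counts = np.bincount(lab, minlength=n + 1)
    sx = np.bincount(lab, weights=heights.floor_x[ys, xs], minlength=n + 1)
    sy = np.bincount(lab, weights=heights.floor_y[ys, xs], minlength=n + 1)
    sh = np.bincount(lab, weights=h_fg, minlength=n + 1)
    # max over the box-smoothed surface: unbiased for plateau interiors,
    # robust against the upward bias of a max over thousands of noisy pixels
    mx = np.zeros(n + 1)
    np.maximum.at(mx, lab, _smoothed(heights)[ys, xs])

    # true per-pixel footprint: pixel solid angle times squared depth
    if config is not None:
        f_u, f_v = config.focal_length
        depth_fg = config.mount_height - h_fg
        areas = np.bincount(
            lab, weights=depth_fg * depth_fg * (1e-6 / (f_u * f_v)), minlength=n + 1
        )
    else:
        areas = None

    # motion index: smoothed height change, ignoring pixels touched by
    # invalid returns in either frame (noise-robust stationarity signal)
    if previous_heights is not None:
        cur_s = _smoothed(heights)
        prev_s = _smoothed(previous_heights)
        clean = ~_dilate3x3(~heights.valid | ~previous_heights.valid)
        clean_fg = clean[ys, xs]
        absdiff_fg = np.abs(cur_s[ys, xs] - prev_s[ys, xs]) * clean_fg
        sm = np.bincount(lab, weights=absdiff_fg, minlength=n + 1)
        cm = np.bincount(lab, weights=clean_fg.astype(np.float64), minlength=n + 1)
    else:
        sm = cm = None

    observations: list[SubjectObservation] = []
    for i in range(1, n + 1):
        cnt = int(counts[i])
        if cnt == 0:
            continue
        area = float(areas[i]) if areas is not None else 0.0
        if areas is not None and area < min_blob_area:
            continue
        if sm is not None:
            motion = float(sm[i] / cm[i]) if cm[i] > 0 else 0.0
        else:
            motion = float("nan")
        observations.append(
            SubjectObservation(
                frame_timestamp=heights.timestamp,
                centroid=(float(sx[i] / cnt), float(sy[i] / cnt)),
                footprint_area=area,
                max_height=float(mx[i]),
                pixel_count=cnt,
                zone=ZoneLabel.OUTSIDE,  # filled by the caller with a ZoneMap
                motion_index=motion,
                mean_height=float(sh[i] / cnt),
            )
        )
    return observations


def _smoothed(hm: HeightMap) -> np.ndarray:
    """3x3 box-smoothed heights, cached on the height map."""
    cached = getattr(hm, "_smoothed_cache", None)
    if cached is None:
        cached = ndimage.uniform_filter(hm.heights, size=3)
        hm._smoothed_cache = cached
    return cached


def _dilate3x3(mask: np.ndarray) -> np.ndarray:
    """Binary dilation with a 3x3 structuring element via shifted ORs."""
    out = mask.copy()
    out[1:, :] |= mask[:-1, :]
    out[:-1, :] |= mask[1:, :]
    m = out.copy()
    out[:, 1:] |= m[:, :-1]
    out[:, :-1] |= m[:, 1:]
    return out


def label_zones(observations: list[SubjectObservation], zones: ZoneMap) -> None:
    """Assign each observation the zone of its centroid, in place."""
    for obs in observations:
        obs.zone = zones.assign(*obs.centroid)


# --------------------------------------------------------------------------
# tracking
# --------------------------------------------------------------------------


class Tracker:
    """Greedy nearest-centroid frame-to-frame association.

    The gate distance defaults to 500 mm per frame at 10 fps and scales
    linearly with the actual frame interval.  Unmatched observations open
    new tracks; tracks unmatched for more than :data:`TRACK_TIMEOUT`
    seconds are closed.  Greedy matching (not optimal assignment) is
    adequate at the one-to-two-person densities this monitor targets.
    """

    def __init__(self, gate: float = DEFAULT_GATE, reference_interval: float = 0.1):
        self.gate = gate
        self.reference_interval = reference_interval
        self.tracks: list[Track] = []
        self._next_id = 1
        self._last_time: float | None = None

    @property
    def open_tracks(self) -> list[Track]:
        return [t for t in self.tracks if not t.closed]

    def step(self, observations: list[SubjectObservation], timestamp: float) -> list[Track]:
        """Associate one frame's observations; returns tracks updated this frame."""
        dt = (
            timestamp - self._last_time
            if self._last_time is not None
            else self.reference_interval
        )
        self._last_time = timestamp
        gate = self.gate * max(dt, self.reference_interval) / self.reference_interval

        open_tracks = self.open_tracks
        pairs: list[tuple[float, int, int]] = []
        for ti, tr in enumerate(open_tracks):
            cx, cy = tr.centroid
            for oi, obs in enumerate(observations):
                d = float(np.hypot(obs.centroid[0] - cx, obs.centroid[1] - cy))
                if d <= gate:
                    pairs.append((d, ti, oi))
        pairs.sort()
        used_t: set[int] = set()
        used_o: set[int] = set()
        updated: list[Track] = []
        for d, ti, oi in pairs:
            if ti in used_t or oi in used_o:
                continue
            used_t.add(ti)
            used_o.add(oi)
            tr = open_tracks[ti]
            tr.observations.append(observations[oi])
            tr.last_update = timestamp
            updated.append(tr)
        for oi, obs in enumerate(observations):
            if oi in used_o:
                continue
            tr = Track(track_id=self._next_id, observations=[obs], last_update=timestamp)
            self._next_id += 1
            self.tracks.append(tr)
            updated.append(tr)
        for tr in self.open_tracks:
            if timestamp - tr.last_update > TRACK_TIMEOUT:
                tr.closed = True
        return updated


def associate_tracks(
    prev_tracks: list[Track],
    new_observations: list[SubjectObservation],
    timestamp: float,
    gate: float = DEFAULT_GATE,
) -> list[Track]:
    """One-shot functional wrapper over :class:`Tracker` for a single frame."""
    tracker = Tracker(gate=gate)
    tracker.tracks = list(prev_tracks)
    tracker._next_id = max((t.track_id for t in prev_tracks), default=0) + 1
    if prev_tracks:
        tracker._last_time = max(t.last_update for t in prev_tracks)
    tracker.step(new_observations, timestamp)
    return tracker.tracks


# --------------------------------------------------------------------------
# time mask
# --------------------------------------------------------------------------


def apply_time_mask(tracks: list[Track], persistence_window: float = 120.0) -> None:
    """Flag long-stationary objects so they are excluded from alarm logic.

    A track whose centroid stays within :data:`STATIONARY_DRIFT` of an
    anchor point and whose ``motion_index`` stays below
    :data:`STATIONARY_MOTION` for the full persistence window is flagged
    stationary from that point on; the flag clears the moment the object
    moves again.  Observations with ``motion_index`` at or above the
    threshold are never suppressed.
    """
    for track in tracks:
        anchor: tuple[float, float] | None = None
        anchor_time = 0.0
        for obs in track.observations:
            moving = (
                not np.isnan(obs.motion_index) and obs.motion_index >= STATIONARY_MOTION
            )
            if anchor is not None:
                drift = float(
                    np.hypot(obs.centroid[0] - anchor[0], obs.centroid[1] - anchor[1])
                )
            else:
                drift = 0.0
            if moving or anchor is None or drift >= STATIONARY_DRIFT:
                anchor = obs.centroid
                anchor_time = obs.frame_timestamp
                obs.stationary = False
            else:
                obs.stationary = obs.frame_timestamp - anchor_time >= persistence_window
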