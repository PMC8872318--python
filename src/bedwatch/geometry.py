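"""Sensor model, depth-to-height transform, monitoring zones and crossings.

A ceiling-mounted time-of-flight depth camera looks straight down at a bed.
Each depth frame stores, per pixel, the perpendicular distance (mm) from the
sensor plane to the first surface below it, so height above the floor is a
subtraction: ``height = mount_height - depth``.  Floor-plane coordinates are
recovered with a pinhole model whose focal lengths come from the field of
view.

Three nested polygonal zones form a virtual fence around the bed: the bed
zone (the mattress), the leave zone (a buffer the resident may occupy) and
the boundary zone (the outer ring whose crossing signals a bed exit).
"""

from __future__ import annotations

import enum
import json
import math
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import shapely
from shapely.geometry import Polygon


class ConfigurationError(ValueError):
    """Invalid sensor or zone configuration."""


class InputError(ValueError):
    """Malformed runtime input (frames, tracks, traces, event lists)."""


# --------------------------------------------------------------------------
# sensor model
# --------------------------------------------------------------------------

from functools import lru_cache


@lru_cache(maxsize=8)
def _pixel_rays_cached(width, height, focal, center):
    f_u, f_v = focal
    c_u, c_v = center
    kx = (np.arange(width, dtype=np.float64) - c_u) / f_u
    ky = (np.arange(height, dtype=np.float64) - c_v) / f_v
    gx, gy = np.meshgrid(kx, ky)
    gx.setflags(write=False)
    gy.setflags(write=False)
    return gx, gy

#: Mount heights outside this band trigger a validation warning (mm).
MOUNT_HEIGHT_BAND = (2300.0, 2700.0)


@dataclass(frozen=True)
class SensorConfig:
    """Ceiling-mounted (nadir) depth sensor geometry.

    Parameters
    ----------
    mount_height:
        Sensor height above the floor, mm.
    image_width, image_height:
        Depth image resolution in pixels.
    horizontal_fov, vertical_fov:
        Full field-of-view angles, degrees.
    frame_rate:
        Sensor frame rate, frames per second.
    principal_point:
        Optical centre (u, v) in pixel coordinates; image centre if omitted.
    """

    mount_height: float = 2500.0
    image_width: int = 512
    image_height: int = 424
    horizontal_fov: float = 70.6
    vertical_fov: float = 60.0
    frame_rate: float = 10.0
    principal_point: tuple[float, float] | None = None

    def __post_init__(self) -> None:
        if self.mount_height <= 0:
            raise ConfigurationError("mount_height must be positive")
        if self.frame_rate <= 0:
            raise ConfigurationError("frame_rate must be positive")
        if self.image_width <= 0 or self.image_height <= 0:
            raise ConfigurationError("image dimensions must be positive")
        lo, hi = MOUNT_HEIGHT_BAND
        if not lo <= self.mount_height <= hi:
            warnings.warn(
                f"mount_height {self.mount_height:.0f} mm outside the "
                f"recommended {lo:.0f}-{hi:.0f} mm band",
                stacklevel=3,
            )

    @property
    def focal_length(self) -> tuple[float, float]:
        """Pinhole focal lengths (f_u, f_v) in pixels, derived from the FOV."""
        f_u = (self.image_width / 2.0) / math.tan(math.radians(self.horizontal_fov) / 2.0)
        f_v = (self.image_height / 2.0) / math.tan(math.radians(self.vertical_fov) / 2.0)
        return f_u, f_v

    @property
    def center(self) -> tuple[float, float]:
        if self.principal_point is not None:
            return self.principal_point
        return ((self.image_width - 1) / 2.0, (self.image_height - 1) / 2.0)

    def pixel_rays(self) -> tuple[np.ndarray, np.ndarray]:
        """Per-pixel ray slopes (kx, ky): floor offset per mm of depth.

        A pixel (u, v) at depth d maps to floor coordinates
        ``x = kx * d``, ``y = ky * d`` with the origin at the sensor nadir,
        x to image-right and y to image-down.  Cached per configuration.
        """
        return _pixel_rays_cached(
            self.image_width, self.image_height, self.focal_length, self.center
        )

    def to_dict(self) -> dict:
        return {
            "mount_height_mm": self.mount_height,
            "image_width": self.image_width,
            "image_height": self.image_height,
            "horizontal_fov_deg": self.horizontal_fov,
            "vertical_fov_deg": self.vertical_fov,
            "frame_rate_hz": self.frame_rate,
            "principal_point": list(self.center),
        }

    @classmethod
    def from_dict(cls, d: dict) -> "SensorConfig":
        pp = d.get("principal_point")
        return cls(
            mount_height=d["mount_height_mm"],
            image_width=d.get("image_width", 512),
            image_height=d.get("image_height", 424),
            horizontal_fov=d.get("horizontal_fov_deg", 70.6),
            vertical_fov=d.get("vertical_fov_deg", 60.0),
            frame_rate=d.get("frame_rate_hz", 10.0),
            principal_point=tuple(pp) if pp is not None else None,
        )


@dataclass
class DepthFrame:
    """One depth image: per-pixel sensor-to-surface distance in mm.

    ``values`` is ``(image_height, image_width)``; 0 marks an invalid pixel
    (no return).  ``timestamp`` is seconds since session start.
    """

    values: np.ndarray
    timestamp: float = 0.0

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values)
        if self.values.ndim != 2:
            raise InputError("depth frame must be a 2-D array")

    @property
    def valid_mask(self) -> np.ndarray:
        return self.values > 0


@dataclass
class HeightMap:
    """Per-pixel height above the floor (mm) plus floor-plane coordinates.

    ``valid`` distinguishes true floor pixels (height 0) from sensor
    dropouts, which carry no height at all.
    """

    heights: np.ndarray
    floor_x: np.ndarray
    floor_y: np.ndarray
    valid: np.ndarray
    timestamp: float = 0.0


def depth_to_height(frame: DepthFrame, config: SensorConfig) -> HeightMap:
    """Transform a depth frame into a height map in floor coordinates.

    Height is ``mount_height - depth`` clipped to ``[0, mount_height]``;
    floor coordinates follow the pinhole projection of :meth:`SensorConfig.
    pixel_rays`.  Invalid (zero-depth) pixels stay invalid.
    """
    expected = (config.image_height, config.image_width)
    if frame.values.shape != expected:
        raise ConfigurationError(
            f"frame shape {frame.values.shape} does not match sensor {expected}"
        )
    depth = frame.values.astype(np.float32, copy=False)
    valid = depth > 0
    heights = np.where(valid, np.clip(config.mount_height - depth, 0.0, config.mount_height), 0.0)
    kx, ky = config.pixel_rays()
    floor_x = np.where(valid, kx * depth, np.nan)
    floor_y = np.where(valid, ky * depth, np.nan)
    return HeightMap(
        heights=heights,
        floor_x=floor_x,
        floor_y=floor_y,
        valid=valid,
        timestamp=frame.timestamp,
    )


# --------------------------------------------------------------------------
# zones
# --------------------------------------------------------------------------


class ZoneLabel(enum.Enum):
    """Exhaustive zone partition; every floor point gets exactly one label."""

    BED = "BED"
    LEAVE = "LEAVE"
    BOUNDARY = "BOUNDARY"
    OUTSIDE = "OUTSIDE"


def _as_polygon(coords, name: str) -> Polygon:
    poly = Polygon(coords) if not isinstance(coords, Polygon) else coords
    if not poly.is_valid or poly.is_empty:
        raise ConfigurationError(f"{name} polygon is invalid or empty")
    return poly


@dataclass
class ZoneMap:
    """Virtual fence: nested bed / leave / boundary polygons (floor mm).

    Nesting precedence resolves overlap: a point inside the bed polygon is
    BED even though it also lies inside leave and boundary.  Points exactly
    on a shared edge take the inner zone — conservative: a subject stays
    "in bed" until clearly out.
    """

    bed_zone: Polygon
    leave_zone: Polygon
    boundary_zone: Polygon
    bed_surface_height: float = 500.0
    edge_band_width: float = 200.0

    def __post_init__(self) -> None:
        self.bed_zone = _as_polygon(self.bed_zone, "bed_zone")
        self.leave_zone = _as_polygon(self.leave_zone, "leave_zone")
        self.boundary_zone = _as_polygon(self.boundary_zone, "boundary_zone")
        if self.edge_band_width <= 0:
            raise ConfigurationError("edge_band_width must be positive")
        if not self.leave_zone.covers(self.bed_zone):
            raise ConfigurationError("bed zone must be nested inside the leave zone")
        if not self.boundary_zone.covers(self.leave_zone):
            raise ConfigurationError("leave zone must be nested inside the boundary zone")

    # -- queries ------------------------------------------------------------

    def assign(self, x: float, y: float) -> ZoneLabel:
        """Label a single floor point (see :func:`assign_zone`)."""
        return assign_zone((x, y), self)

    def assign_many(self, x: np.ndarray, y: np.ndarray) -> np.ndarray:
        """Vectorised zone assignment; returns an object array of ZoneLabel."""
        x = np.asarray(x, dtype=float)
        y = np.asarray(y, dtype=float)
        out = np.full(x.shape, ZoneLabel.OUTSIDE, dtype=object)
        # inclusive point-on-edge tests, inner zone wins
        in_boundary = shapely.intersects_xy(self.boundary_zone, x, y)
        out[in_boundary] = ZoneLabel.BOUNDARY
        in_leave = shapely.intersects_xy(self.leave_zone, x, y)
        out[in_leave] = ZoneLabel.LEAVE
        in_bed = shapely.intersects_xy(self.bed_zone, x, y)
        out[in_bed] = ZoneLabel.BED
        return out

    def near_bed_edge(self, x: float, y: float) -> bool:
        """True when the point is within ``edge_band_width`` of the bed rim."""
        return self.bed_zone.exterior.distance(shapely.Point(x, y)) <= self.edge_band_width

    # -- serialisation --------------------------------------------------------

    def to_dict(self) -> dict:
        return {
            "bed_zone": [list(c) for c in self.bed_zone.exterior.coords[:-1]],
            "leave_zone": [list(c) for c in self.leave_zone.exterior.coords[:-1]],
            "boundary_zone": [list(c) for c in self.boundary_zone.exterior.coords[:-1]],
            "bed_surface_height_mm": self.bed_surface_height,
            "edge_band_width_mm": self.edge_band_width,
        }

    def save(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.to_dict(), indent=2))

    @classmethod
    def from_dict(cls, d: dict) -> "ZoneMap":
        return cls(
            bed_zone=Polygon(d["bed_zone"]),
            leave_zone=Polygon(d["leave_zone"]),
            boundary_zone=Polygon(d["boundary_zone"]),
            bed_surface_height=d.get("bed_surface_height_mm", 500.0),
            edge_band_width=d.get("edge_band_width_mm", 200.0),
        )

    @classmethod
    def load(cls, path: str | Path) -> "ZoneMap":
        return cls.from_dict(json.loads(Path(path).read_text()))


def default_zones(bed_surface_height: float = 500.0) -> ZoneMap:
    """Rectangular three-zone layout for a single bed under the sensor.

    The bed (2.0 m x 0.9 m) is centred at the nadir with its long axis
    along x; the leave zone extends about 0.55 m past the bed toward the
    exit side (+y) and the boundary ring reaches 2.2 m x coverage within
    the sensor footprint of a 2.5 m mount.
    """
    return ZoneMap(
        bed_zone=Polygon([(-1000, -450), (1000, -450), (1000, 450), (-1000, 450)]),
        leave_zone=Polygon([(-1300, -750), (1300, -750), (1300, 1000), (-1300, 1000)]),
        boundary_zone=Polygon([(-1600, -1050), (1600, -1050), (1600, 1350), (-1600, 1350)]),
        bed_surface_height=bed_surface_height,
    )


def assign_zone(point: Sequence[float], zones: ZoneMap) -> ZoneLabel:
    """Map one floor point (x, y) in mm to its zone label.

    Precedence BED > LEAVE > BOUNDARY > OUTSIDE; boundary-inclusive tests
    give shared edges to the inner zone.
    """
    x, y = float(point[0]), float(point[1])
    if shapely.intersects_xy(zones.bed_zone, x, y):
        return ZoneLabel.BED
    if shapely.intersects_xy(zones.leave_zone, x, y):
        return ZoneLabel.LEAVE
    if shapely.intersects_xy(zones.boundary_zone, x, y):
        return ZoneLabel.BOUNDARY
    return ZoneLabel.OUTSIDE


# --------------------------------------------------------------------------
# crossings
# --------------------------------------------------------------------------


@dataclass(frozen=True)
class CrossingEvent:
    """A zone transition on a track; timestamped at the later sample."""

    timestamp: float
    from_zone: ZoneLabel
    to_zone: ZoneLabel


def detect_crossing(
    track: Sequence[tuple[float, Sequence[float]]], zones: ZoneMap
) -> list[CrossingEvent]:
    """Detect zone transitions along a timestamped floor-point track.

    ``track`` is an ordered list of ``(timestamp, (x, y))`` samples with
    strictly increasing timestamps.  Each consecutive pair with differing
    zone labels yields one event stamped at the later sample.
    """
    if len(track) < 2:
        return []
    times = np.array([t for t, _ in track], dtype=float)
    if np.any(np.diff(times) <= 0):
        raise InputError("track timestamps must be strictly increasing")
    pts = np.array([[p[0], p[1]] for _, p in track], dtype=float)
    labels = zones.assign_many(pts[:, 0], pts[:, 1])
    events: list[CrossingEvent] = []
    for i in range(1, len(labels)):
        if labels[i] != labels[i - 1]:
            events.append(CrossingEvent(times[i], labels[i - 1], labels[i]))
    return events
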