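"""File formats: depth-frame directories, JSONL streams, silhouettes.

Depth frames are 16-bit grayscale PNGs (millimetre values, 0 = invalid),
one per frame, named ``frame_%06d.png``, with a JSON sidecar carrying the
sensor configuration and per-frame timestamps.  Observations, alarm
states and events stream as JSONL; silhouettes archive as 8-bit PNG.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Iterator

import imageio.v3 as iio
import numpy as np

from .geometry import DepthFrame, InputError, SensorConfig
from .posture import AlarmFrame, EventRecord

SIDECAR_NAME = "sensor.json"


def write_frames(
    frames,
    config: SensorConfig,
    out_dir: str | Path,
) -> int:
    """Write frames as 16-bit PNGs plus the sensor/timestamp sidecar."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    timestamps = []
    n = 0
    for i, frame in enumerate(frames):
        arr = np.clip(np.round(frame.values), 0, 65535).astype(np.uint16)
        iio.imwrite(out / f"frame_{i:06d}.png", arr)
        timestamps.append(round(float(frame.timestamp), 4))
        n += 1
    sidecar = {"sensor": config.to_dict(), "timestamps": timestamps}
    (out / SIDECAR_NAME).write_text(json.dumps(sidecar))
    return n


def read_frames(frame_dir: str | Path) -> tuple[Iterator[DepthFrame], SensorConfig]:
    """Read a frame directory written by :func:`write_frames`."""
    d = Path(frame_dir)
    sidecar_path = d / SIDECAR_NAME
    if not sidecar_path.exists():
        raise InputError(f"missing sensor sidecar {sidecar_path}")
    sidecar = json.loads(sidecar_path.read_text())
    config = SensorConfig.from_dict(sidecar["sensor"])
    timestamps = sidecar["timestamps"]
    paths = sorted(d.glob("frame_*.png"))
    if len(paths) != len(timestamps):
        raise InputError("frame count does not match sidecar timestamps")

    def _iter():
        for path, t in zip(paths, timestamps):
            yield DepthFrame(values=iio.imread(path).astype(np.float32), timestamp=t)

    return _iter(), config


def write_silhouette(image: np.ndarray, path: str | Path) -> None:
    iio.imwrite(Path(path), image.astype(np.uint8))


def write_events_jsonl(events: list[EventRecord], path: str | Path) -> None:
    with open(path, "w") as fh:
        for ev in events:
            fh.write(json.dumps(ev.to_dict(), sort_keys=True) + "\n")


def read_events_jsonl(path: str | Path) -> list[dict]:
    out = []
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if line:
                out.append(json.loads(line))
    return out


def write_timeline_jsonl(timeline: list[AlarmFrame], path: str | Path, bed: str = "bed1") -> None:
    with open(path, "w") as fh:
        for fr in timeline:
            fh.write(
                json.dumps(
                    {
                        "t": round(fr.timestamp, 3),
                        "bed": bed,
                        "state": fr.posture.value,
                        "alarm": fr.alarm.value,
                    },
                    sort_keys=True,
                )
                + "\n"
            )
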