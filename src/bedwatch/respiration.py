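"""Respiration-rate estimation and presence detection from UWB radar.

An ultra-wideband impulse radar samples chest displacement at a fixed
range bin; the slow-time amplitude trace carries respiration as a
0.1-0.7 Hz modulation (6-42 breaths/min).  The estimator detrends and
band-passes the trace, takes an averaged periodogram (Welch) and reads the
rate off the spectral peak; a peak-to-median in-band SNR gate rejects
breathing-free noise.  Gross body motion (ambulation near the bed) shows
up as broadband energy and sets a separate motion flag.

Presence fuses both channels with the depth camera: the bed is declared
empty only when depth and radar agree it is, and only after a debounce.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import signal

from .geometry import InputError

#: Physiologic respiration band, Hz (6-42 breaths/min).
RESP_BAND = (0.1, 0.7)
#: Peak-over-median in-band power gate, dB.
DEFAULT_SNR_THRESHOLD = 6.0
#: RMS of the high-passed (>0.8 Hz) trace above which gross motion is
#: declared, in trace amplitude units (the simulator's noise floor is ~1).
DEFAULT_MOTION_THRESHOLD = 3.0
#: Minimum analysis window, s.
MIN_WINDOW = 30.0
#: Both channels must be negative this long before the bed is "empty" (s).
DEFAULT_EMPTY_DEBOUNCE = 10.0


@dataclass
class RadarTrace:
    """Slow-time radar amplitude trace (arbitrary units)."""

    sampling_rate: float
    samples: np.ndarray
    window_length: float = MIN_WINDOW

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=float)
        if self.sampling_rate < 2.0:
            raise InputError("slow-time sampling rate must be at least 2 Hz")
        if self.window_length < MIN_WINDOW:
            raise InputError(f"window_length must be >= {MIN_WINDOW} s for rate estimation")

    @property
    def duration(self) -> float:
        return len(self.samples) / self.sampling_rate

    def to_csv(self, path: str | Path) -> None:
        t = np.arange(len(self.samples)) / self.sampling_rate
        pd.DataFrame({"time_s": t, "amplitude": self.samples}).to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path: str | Path, window_length: float = MIN_WINDOW) -> "RadarTrace":
        df = pd.read_csv(path)
        if not {"time_s", "amplitude"} <= set(df.columns):
            raise InputError("radar CSV needs 'time_s' and 'amplitude' columns")
        t = df["time_s"].to_numpy()
        if len(t) < 2:
            raise InputError("radar CSV too short")
        fs = 1.0 / float(np.median(np.diff(t)))
        return cls(sampling_rate=fs, samples=df["amplitude"].to_numpy(), window_length=window_length)


@dataclass
class RespirationEstimate:
    """Breathing rate (breaths/min, None when no credible peak) + flags."""

    breathing_rate: float | None
    spectral_snr: float  # dB
    presence: bool
    motion_flag: bool


def estimate_breathing(
    trace: RadarTrace,
    snr_threshold: float = DEFAULT_SNR_THRESHOLD,
    motion_threshold: float = DEFAULT_MOTION_THRESHOLD,
) -> RespirationEstimate:
    """Estimate the respiration rate and presence from one trace window.

    Pipeline: linear detrend -> 4th-order Butterworth band-pass over
    0.1-0.7 Hz -> Welch periodogram (10 s Hann segments, 50% overlap,
    zero-padded for fine peak localisation).  The rate is the in-band peak
    frequency x 60; it is reported only when the peak clears the
    peak-over-median SNR gate.  The motion flag compares the RMS of the
    >0.8 Hz residual against an absolute threshold calibrated to the
    radar's noise floor, so presence survives amplitude scaling of a
    breathing trace while empty-bed noise stays below the gate.
    """
    fs = trace.sampling_rate
    x = np.asarray(trace.samples, dtype=float)
    if len(x) < int(round(trace.window_length * fs)):
        raise InputError(
            f"trace ({len(x) / fs:.1f} s) shorter than the analysis window "
            f"({trace.window_length:.0f} s)"
        )

    x = signal.detrend(x, type="linear")

    # gross-motion flag from broadband (>0.8 Hz) energy, absolute units
    sos_hp = signal.butter(4, 0.8, btype="highpass", fs=fs, output="sos")
    hp = signal.sosfiltfilt(sos_hp, x)
    motion_flag = bool(np.sqrt(np.mean(hp**2)) > motion_threshold)

    # respiration band
    sos_bp = signal.butter(4, RESP_BAND, btype="bandpass", fs=fs, output="sos")
    bp = signal.sosfiltfilt(sos_bp, x)

    nperseg = min(len(bp), int(round(10.0 * fs)))
    nfft = max(4096, nperseg)
    freqs, psd = signal.welch(
        bp, fs=fs, window="hann", nperseg=nperseg, noverlap=nperseg // 2, nfft=nfft
    )
    band = (freqs >= RESP_BAND[0]) & (freqs <= RESP_BAND[1])
    pf, pp = freqs[band], psd[band]
    peak_idx = int(np.argmax(pp))
    peak_power = pp[peak_idx]
    med = float(np.median(pp))
    snr_db = 10.0 * math.log10(peak_power / med) if med > 0 and peak_power > 0 else -math.inf

    rate: float | None = None
    if snr_db >= snr_threshold:
        # parabolic interpolation around the peak for sub-bin frequency
        f0 = pf[peak_idx]
        if 0 < peak_idx < len(pp) - 1:
            y0, y1, y2 = pp[peak_idx - 1], pp[peak_idx], pp[peak_idx + 1]
            denom = y0 - 2 * y1 + y2
            if denom != 0:
                delta = 0.5 * (y0 - y2) / denom
                f0 = f0 + delta * (pf[1] - pf[0])
        rate = float(f0 * 60.0)

    presence = motion_flag or rate is not None
    return RespirationEstimate(
        breathing_rate=rate, spectral_snr=float(snr_db), presence=presence, motion_flag=motion_flag
    )


def sliding_estimates(
    trace: RadarTrace,
    hop: float = 1.0,
    snr_threshold: float = DEFAULT_SNR_THRESHOLD,
    motion_threshold: float = DEFAULT_MOTION_THRESHOLD,
) -> list[tuple[float, RespirationEstimate]]:
    """Windowed estimates over a long trace: (window end time, estimate).

    For traces shorter than one window the whole trace is used once and
    stamped at its end, so short recordings still yield a presence call.
    """
    fs = trace.sampling_rate
    win = int(round(trace.window_length * fs))
    n = len(trace.samples)
    out: list[tuple[float, RespirationEstimate]] = []
    if n < win:
        if n >= int(round(MIN_WINDOW * fs)):
            sub = RadarTrace(fs, trace.samples, window_length=MIN_WINDOW)
            out.append((n / fs, estimate_breathing(sub, snr_threshold, motion_threshold)))
        return out
    step = max(1, int(round(hop * fs)))
    for end in range(win, n + 1, step):
        sub = RadarTrace(fs, trace.samples[end - win : end], trace.window_length)
        out.append((end / fs, estimate_breathing(sub, snr_threshold, motion_threshold)))
    return out


def fuse_presence(
    depth_presence: list[tuple[float, bool]],
    resp_estimates: list[tuple[float, RespirationEstimate]],
    empty_debounce: float = DEFAULT_EMPTY_DEBOUNCE,
) -> list[tuple[float, bool]]:
    """Fuse depth-camera and radar presence into one in-bed decision.

    At every depth timestamp the nearest radar estimate within 1 s is
    consulted; presence is the OR of the two channels.  "Empty" is declared
    only after both channels have been negative for ``empty_debounce``
    seconds, so a fully covered but breathing subject never empties the
    bed, and neither does a brief segmentation dropout.
    """
    if not depth_presence:
        return []
    resp_times = np.array([t for t, _ in resp_estimates]) if resp_estimates else None
    fused: list[tuple[float, bool]] = []
    negative_since: float | None = None
    for t, depth_here in depth_presence:
        radar_here = False
        if resp_times is not None and len(resp_times):
            j = int(np.argmin(np.abs(resp_times - t)))
            if abs(resp_times[j] - t) <= 1.0:
                radar_here = resp_estimates[j][1].presence
        raw = depth_here or radar_here
        if raw:
            negative_since = None
            fused.append((t, True))
        else:
            if negative_since is None:
                negative_since = t
            fused.append((t, (t - negative_since) < empty_debounce))
    return fused
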