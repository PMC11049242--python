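"""LFP filtering and seizure-like event detection.

Traces are band-pass filtered (zero-phase second-order Butterworth,
corners 0.1 Hz and 1 kHz by default) and an event is every maximal segment
of the filtered signal below the amplitude threshold (−0.3 mV relative to
the filtered zero baseline) lasting strictly more than the minimum
duration (100 ms). The detector is sampling-rate agnostic.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import signal


@dataclass
class LfpRecording:
    """Voltage samples (mV) at a fixed sampling interval (s)."""

    samples: np.ndarray
    sampling_interval: float

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, float)
        if self.samples.ndim != 1:
            raise ValueError("samples must be 1D")
        if self.sampling_interval <= 0:
            raise ValueError("sampling_interval must be > 0")

    @property
    def duration_s(self) -> float:
        return self.samples.size * self.sampling_interval

    @property
    def sampling_rate(self) -> float:
        return 1.0 / self.sampling_interval


@dataclass
class LfpEvent:
    start_s: float
    duration_ms: float
    amplitude_mv: float  # most negative filtered value within the event


def bandpass(
    rec: LfpRecording,
    hp_hz: float = 0.1,
    lp_hz: float = 1000.0,
    order: int = 2,
) -> LfpRecording:
    """Zero-phase Butterworth band-pass; removes any DC offset.

    Forward–backward filtering (``sosfiltfilt``) keeps deflection shapes
    undistorted in phase. Raises when the low-pass corner reaches the
    Nyquist frequency, instructing the caller to resample or lower the
    corner.
    """
    nyq = 0.5 * rec.sampling_rate
    if lp_hz >= nyq:
        raise ValueError(
            f"low-pass corner {lp_hz} Hz ≥ Nyquist {nyq} Hz: resample the "
            "recording or lower lp_hz"
        )
    if not 0 < hp_hz < lp_hz:
        raise ValueError("need 0 < hp_hz < lp_hz")
    sos = signal.butter(
        order, [hp_hz, lp_hz], btype="bandpass", fs=rec.sampling_rate, output="sos"
    )
    return LfpRecording(
        samples=signal.sosfiltfilt(sos, rec.samples),
        sampling_interval=rec.sampling_interval,
    )


def detect_lfp_events(
    rec: LfpRecording,
    amp_mv: float = -0.3,
    min_dur_ms: float = 100.0,
    merge_gap_ms: float = 0.0,
) -> list[LfpEvent]:
    """Downward threshold-crossing events on a filtered recording.

    Maximal contiguous segments with sample < ``amp_mv`` become events
    when their duration strictly exceeds ``min_dur_ms``. Segments closer
    than ``merge_gap_ms`` are merged first (off by default).
    """
    below = rec.samples < amp_mv
    if not below.any():
        return []
    padded = np.concatenate([[False], below, [False]]).astype(np.int8)
    d = np.diff(padded)
    starts = np.flatnonzero(d == 1)
    ends = np.flatnonzero(d == -1)  # exclusive
    dt = rec.sampling_interval
    segs = list(zip(starts, ends))
    if merge_gap_ms > 0:
        merged = [segs[0]]
        gap = merge_gap_ms / 1000.0 / dt
        for s, e in segs[1:]:
            if s - merged[-1][1] < gap:
                merged[-1] = (merged[-1][0], e)
            else:
                merged.append((s, e))
        segs = merged
    events = []
    for s, e in segs:
        dur_ms = (e - s) * dt * 1000.0
        if dur_ms > min_dur_ms:
            events.append(
                LfpEvent(
                    start_s=float(s * dt),
                    duration_ms=float(dur_ms),
                    amplitude_mv=float(rec.samples[s:e].min()),
                )
            )
    return events


def lfp_stats(
    events: list[LfpEvent], duration_s: float
) -> tuple[int, float, float | None]:
    """(count, rate per minute, mean |amplitude| in mV or None)."""
    if duration_s <= 0:
        raise ValueError("duration must be > 0")
    count = len(events)
    rate = count / (duration_s / 60.0)
    mean_amp = (
        float(np.mean([abs(e.amplitude_mv) for e in events])) if events else None
    )
    return count, rate, mean_amp
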