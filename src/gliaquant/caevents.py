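"""ΔF/F₀ computation and calcium event detection.

The normalized fluorescence change of frame t is
``dff(t) = (F(t) − mean(F)) / mean(F)`` with F the per-frame mean gray
value and the baseline F₀ the mean over all frames, so dff is exactly
invariant to any multiplicative gain and sums to zero over the trace.
A calcium event is a maximal run of frames with dff above threshold
(default 0.04).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, replace

import numpy as np
from scipy import ndimage


@dataclass
class FluorescenceTrace:
    """Per-frame mean fluorescence with optional computed ΔF/F₀."""

    frame_times: np.ndarray  # seconds
    raw: np.ndarray          # mean gray value, arbitrary units
    dff: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.frame_times = np.asarray(self.frame_times, float)
        self.raw = np.asarray(self.raw, float)
        if self.frame_times.shape != self.raw.shape:
            raise ValueError("frame_times and raw must have the same length")
        if np.any(self.raw < 0):
            raise ValueError("raw intensities must be ≥ 0")

    @property
    def n_frames(self) -> int:
        return self.raw.size

    @property
    def duration_s(self) -> float:
        return float(self.frame_times[-1] - self.frame_times[0]) if self.n_frames > 1 else 0.0


@dataclass
class CalciumEvent:
    onset_frame: int
    peak_frame: int
    amplitude: float        # peak ΔF/F₀ within the event
    duration_frames: int


def compute_dff(trace: FluorescenceTrace) -> FluorescenceTrace:
    """ΔF/F₀ against the global-mean baseline; errors on an all-zero trace."""
    f0 = float(trace.raw.mean())
    if f0 <= 0:
        raise ValueError("mean fluorescence is zero; cannot normalize")
    return replace(trace, dff=(trace.raw - f0) / f0)


def _running_percentile_baseline(
    raw: np.ndarray, window: int, percentile: float
) -> np.ndarray:
    """Sliding low-percentile baseline with linearly extrapolated edges.

    Plain nearest-padding leaves edge residuals proportional to any
    baseline drift slope over the half window, so the outer half-windows
    are replaced by a straight-line extrapolation of the adjacent valid
    baseline region.
    """
    base = ndimage.percentile_filter(raw, percentile, size=window, mode="nearest")
    h = window // 2
    n = raw.size
    if n > 3 * h > 0:
        t = np.arange(n, dtype=float)
        for sl_fit, sl_fix in (
            (slice(h, min(2 * h + 1, n)), slice(0, h)),
            (slice(max(n - 2 * h - 1, 0), n - h), slice(n - h, n)),
        ):
            coef = np.polyfit(t[sl_fit], base[sl_fit], 1)
            base[sl_fix] = np.polyval(coef, t[sl_fix])
    return base


def correct_drift(
    trace: FluorescenceTrace, window_s: float = 60.0, percentile: float = 10.0
) -> FluorescenceTrace:
    """Remove slow baseline drift, then compute ΔF/F₀.

    A running ``percentile``-th percentile over a ``window_s`` sliding
    window estimates the local background; subtracting it (and restoring
    the mean level) flattens drift while leaving transients — which occupy
    the upper tail of any window — intact. Falls back to the global
    percentile, with a warning, when the window exceeds the trace.
    """
    if trace.n_frames < 2:
        raise ValueError("trace too short for drift correction")
    dt = float(np.median(np.diff(trace.frame_times)))
    window = max(3, int(round(window_s / dt)) | 1)  # odd
    if window > trace.n_frames:
        warnings.warn(
            "drift window longer than trace; using global percentile",
            stacklevel=2,
        )
        base = np.full_like(trace.raw, np.percentile(trace.raw, percentile))
    else:
        base = _running_percentile_baseline(trace.raw, window, percentile)
    corrected = trace.raw - base + float(base.mean())
    corrected = np.clip(corrected, 0.0, None)
    return compute_dff(replace(trace, raw=corrected))


def detect_events(
    trace: FluorescenceTrace,
    threshold: float = 0.04,
    min_separation_frames: int = 1,
) -> list[CalciumEvent]:
    """Maximal runs of frames with dff > threshold, one event per run.

    Runs separated by fewer than ``min_separation_frames`` sub-threshold
    frames are merged. Event amplitude is the run maximum of dff.
    """
    if trace.dff is None:
        raise ValueError("dff not computed; call compute_dff or correct_drift first")
    above = trace.dff > threshold
    if not above.any():
        return []
    padded = np.concatenate([[False], above, [False]]).astype(np.int8)
    d = np.diff(padded)
    starts = np.flatnonzero(d == 1)
    ends = np.flatnonzero(d == -1) - 1
    runs = list(zip(starts, ends))
    merged = [runs[0]]
    for s, e in runs[1:]:
        if s - merged[-1][1] - 1 < min_separation_frames:
            merged[-1] = (merged[-1][0], e)
        else:
            merged.append((s, e))
    events = []
    for s, e in merged:
        seg = trace.dff[s : e + 1]
        events.append(
            CalciumEvent(
                onset_frame=int(s),
                peak_frame=int(s + np.argmax(seg)),
                amplitude=float(seg.max()),
                duration_frames=int(e - s + 1),
            )
        )
    return events


def event_stats(
    events: list[CalciumEvent], recording_duration_s: float
) -> tuple[int, float, float | None]:
    """(count, rate per minute, mean amplitude or None when no events)."""
    if recording_duration_s <= 0:
        raise ValueError("recording duration must be > 0")
    count = len(events)
    rate = count / (recording_duration_s / 60.0)
    mean_amp = float(np.mean([e.amplitude for e in events])) if events else None
    return count, rate, mean_amp
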