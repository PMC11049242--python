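"""Locomotor scoring of larva trajectories.

Each inter-sample step of a centroid trajectory is assigned to one of four
speed states — immobile (below a motion floor), low (< 4 mm/s), medium
(4–8 mm/s) or high (≥ 8 mm/s) — and the summary reports the total distance
swum plus the time spent in each state, overall and per integration bin
(default 60 s). The two printed thresholds separate inactive from small
movements and small from fast bursts; a motion floor distinguishes
genuinely immobile frames from slow drift.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

STATES = ("immobile", "low", "medium", "high")


@dataclass(frozen=True)
class SwimConfig:
    integration_s: float = 60.0
    inactive_threshold: float = 4.0   # mm/s
    high_threshold: float = 8.0       # mm/s
    motion_floor: float = 0.1         # mm/s; below = immobile

    def __post_init__(self) -> None:
        if not 0 < self.inactive_threshold < self.high_threshold:
            raise ValueError("need 0 < inactive_threshold < high_threshold")
        if not 0 <= self.motion_floor < self.inactive_threshold:
            raise ValueError("motion_floor must sit below inactive_threshold")


@dataclass
class TrajectorySummary:
    total_distance: float       # mm
    time_immobile: float        # s
    time_low: float
    time_medium: float
    time_high: float
    per_bin: pd.DataFrame | None = None

    def as_dict(self) -> dict:
        return {
            "total_distance": self.total_distance,
            "time_immobile": self.time_immobile,
            "time_low": self.time_low,
            "time_medium": self.time_medium,
            "time_high": self.time_high,
        }


def _steps(positions: pd.DataFrame):
    t = np.asarray(positions["t_s"], float)
    x = np.asarray(positions["x_mm"], float)
    y = np.asarray(positions["y_mm"], float)
    if t.size < 2:
        raise ValueError("need at least 2 samples")
    dt = np.diff(t)
    if np.any(dt <= 0):
        raise ValueError("times must be strictly increasing")
    dist = np.hypot(np.diff(x), np.diff(y))
    return t, dt, dist


def summarize_trajectory(
    positions: pd.DataFrame, cfg: SwimConfig = SwimConfig()
) -> TrajectorySummary:
    """Score one trajectory (columns ``t_s, x_mm, y_mm``)."""
    t, dt, dist = _steps(positions)
    speed = dist / dt
    state = np.full(speed.size, 2, np.int8)  # medium
    state[speed < cfg.inactive_threshold] = 1
    state[speed < cfg.motion_floor] = 0
    state[speed >= cfg.high_threshold] = 3
    times = [float(dt[state == k].sum()) for k in range(4)]

    bins = np.floor(t[:-1] / cfg.integration_s).astype(int)
    per_bin = (
        pd.DataFrame(
            {
                "bin": bins,
                "distance": dist,
                **{
                    f"time_{name}": np.where(state == k, dt, 0.0)
                    for k, name in enumerate(STATES)
                },
            }
            )
        .groupby("bin")
        .sum()
        .reset_index()
    )
    per_bin["t_start_s"] = per_bin["bin"] * cfg.integration_s
    return TrajectorySummary(
        total_distance=float(dist.sum()),
        time_immobile=times[0],
        time_low=times[1],
        time_medium=times[2],
        time_high=times[3],
        per_bin=per_bin,
    )


def batch_summarize(
    plate: list[pd.DataFrame], cfg: SwimConfig = SwimConfig()
) -> pd.DataFrame:
    """Per-larva rows plus ``mean`` and ``sem`` rows for a plate."""
    if not plate:
        raise ValueError("empty plate")
    rows = []
    for i, traj in enumerate(plate):
        s = summarize_trajectory(traj, cfg)
        rows.append({"larva": i, **s.as_dict()})
    df = pd.DataFrame(rows)
    metrics = [c for c in df.columns if c != "larva"]
    mean = df[metrics].mean()
    sem = df[metrics].std(ddof=1) / np.sqrt(len(df)) if len(df) > 1 else mean * 0.0
    df_mean = pd.DataFrame([{"larva": "mean", **mean.to_dict()}])
    df_sem = pd.DataFrame([{"larva": "sem", **sem.to_dict()}])
    return pd.concat([df, df_mean, df_sem], ignore_index=True)
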