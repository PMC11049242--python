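"""Cell-body tracking and motility metrics.

Centroids are linked frame-to-frame by greedy mutual-nearest-neighbor
assignment with a maximum step length; a track's motility summary reports
the straight-line displacement between its first and last centroid, the
path length (sum of inter-frame steps) and the mean speed
(path length / elapsed time, µm/min). There is no gap closing: a centroid
missing from one frame ends its track.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd


@dataclass
class CellTrack:
    cell_id: int
    times: np.ndarray      # s, strictly increasing
    positions: np.ndarray  # (n, 2 or 3) µm
    complete: bool = False  # spans first through last frame

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, float)
        self.positions = np.atleast_2d(np.asarray(self.positions, float))
        if self.times.size != self.positions.shape[0]:
            raise ValueError("times and positions must align")
        if self.times.size > 1 and np.any(np.diff(self.times) <= 0):
            raise ValueError("times must be strictly increasing")

    @property
    def n_samples(self) -> int:
        return self.times.size


@dataclass
class MotilitySummary:
    displacement: float   # µm, first → last centroid
    path_length: float    # µm, Σ inter-frame steps
    mean_speed: float     # µm/min


def centroids_from_labels(
    label_frames: list[np.ndarray],
    voxel_size: tuple[float, ...] | None = None,
) -> list[np.ndarray]:
    """Per-frame centroid sets from labeled 2D/3D frames of a time-lapse.

    Each frame is an integer label image (0 = background); centroids are
    intensity-free centers of mass in physical units (µm) when
    ``voxel_size`` is given, voxel units otherwise.
    """
    from scipy import ndimage

    out = []
    for frame in label_frames:
        frame = np.asarray(frame)
        ids = np.unique(frame)
        ids = ids[ids > 0]
        if ids.size == 0:
            out.append(np.empty((0, frame.ndim)))
            continue
        cents = np.asarray(ndimage.center_of_mass(frame > 0, frame, ids), float)
        if voxel_size is not None:
            cents = cents * np.asarray(voxel_size, float)
        out.append(cents)
    return out


def link_centroids(
    frames: list[np.ndarray],
    max_step: float = 20.0,
    dt: float = 40.0,
) -> list[CellTrack]:
    """Greedy mutual-nearest-neighbor linking of per-frame centroid sets.

    ``frames[i]`` is an (n_i, d) array of centroids at time ``i*dt``.
    Candidate links are consumed in order of increasing distance (which is
    exactly mutual-nearest-neighbor greediness); links longer than
    ``max_step`` are rejected, so would-be identity swaps end tracks
    instead. Empty frames simply terminate all open tracks.
    """
    if len(frames) < 2:
        raise ValueError("need at least 2 frames")
    frames = [np.atleast_2d(np.asarray(f, float)) if np.size(f) else np.empty((0, 2)) for f in frames]
    n_frames = len(frames)
    tracks: list[dict] = []
    open_tracks: dict[int, int] = {}  # index of centroid in prev frame -> track idx
    for j, c in enumerate(frames[0]):
        tracks.append({"t": [0.0], "p": [c], "start": 0})
        open_tracks[j] = len(tracks) - 1

    for fi in range(1, n_frames):
        prev, cur = frames[fi - 1], frames[fi]
        links: dict[int, int] = {}
        if prev.shape[0] and cur.shape[0] and open_tracks:
            d = np.linalg.norm(prev[:, None, :] - cur[None, :, :], axis=2)
            pairs = sorted(
                ((d[i, j], i, j) for i in range(prev.shape[0]) for j in range(cur.shape[0])),
                key=lambda x: x[0],
            )
            used_i, used_j = set(), set()
            for dist, i, j in pairs:
                if dist > max_step:
                    break
                if i in used_i or j in used_j or i not in open_tracks:
                    continue
                links[j] = open_tracks[i]
                used_i.add(i)
                used_j.add(j)
        new_open: dict[int, int] = {}
        for j, c in enumerate(cur):
            if j in links:
                ti = links[j]
                tracks[ti]["t"].append(fi * dt)
                tracks[ti]["p"].append(c)
            else:
                tracks.append({"t": [fi * dt], "p": [c], "start": fi})
                ti = len(tracks) - 1
            new_open[j] = ti
        open_tracks = new_open

    out = []
    for k, tr in enumerate(tracks):
        n = len(tr["t"])
        complete = tr["start"] == 0 and n == n_frames
        out.append(
            CellTrack(
                cell_id=k,
                times=np.asarray(tr["t"]),
                positions=np.asarray(tr["p"]),
                complete=complete,
            )
        )
    return out


def summarize_track(track: CellTrack) -> MotilitySummary:
    """Displacement, path length and mean speed of one track."""
    if track.n_samples < 2:
        raise ValueError("need at least 2 samples")
    steps = np.linalg.norm(np.diff(track.positions, axis=0), axis=1)
    path = float(steps.sum())
    disp = float(np.linalg.norm(track.positions[-1] - track.positions[0]))
    elapsed_min = (track.times[-1] - track.times[0]) / 60.0
    return MotilitySummary(
        displacement=disp,
        path_length=path,
        mean_speed=path / elapsed_min if elapsed_min > 0 else 0.0,
    )


def summarize_tracks(
    tracks: list[CellTrack], min_span_fraction: float = 0.8, n_frames: int | None = None
) -> pd.DataFrame:
    """Summary table over tracks spanning enough of the recording.

    Short fragments bias speed estimates, so only tracks covering at least
    ``min_span_fraction`` of the frames enter the table (when ``n_frames``
    is known).
    """
    rows = []
    for tr in tracks:
        if tr.n_samples < 2:
            continue
        if n_frames is not None and tr.n_samples < min_span_fraction * n_frames:
            continue
        s = summarize_track(tr)
        rows.append(
            {
                "cell_id": tr.cell_id,
                "n_samples": tr.n_samples,
                "complete": tr.complete,
                "displacement_um": s.displacement,
                "path_length_um": s.path_length,
                "mean_speed_um_min": s.mean_speed,
            }
        )
    return pd.DataFrame(rows)
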