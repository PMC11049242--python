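"""Synthetic input generators with known ground truth.

Every input kind the quantification chain consumes can be generated here
with a seeded random stream and a ground-truth record, so downstream
morphometry, classification, event detection and tracking are verifiable
without any raw imaging data:

* 3D microglia-like shapes (soma ball + tube-like processes) rasterized
  into a :class:`~gliaquant.volume.LabeledVolume`,
* whole-field fluorescence traces with injected calcium transients on a
  noisy drifting baseline,
* LFP voltage traces with injected downward deflections,
* piecewise-constant-speed larva trajectories.

Generators are pure functions of (parameters, seed).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import ndimage
from scipy.spatial.transform import Rotation

from .volume import LabeledVolume

# Effective physical radius of a rasterized process tube (µm at 1 µm
# voxels): the dilation radius plus the half-extent of the seeded voxel.
TUBE_RADIUS_VOX = 1.5
EFFECTIVE_TUBE_RADIUS_UM = 2.0


# ---------------------------------------------------------------------------
# ground-truth records
# ---------------------------------------------------------------------------

@dataclass
class ShapeTruth:
    """Ground truth for one generated microglia-like cell.

    ``process_lengths`` are the arc lengths (µm) of the primary processes,
    measured from the soma surface; secondary branch arcs, when present,
    are recorded in ``secondary_lengths`` after generation.
    """

    soma_radius: float
    n_processes: int
    process_lengths: list[float]
    has_secondary_branches: bool = False
    intended_class: str | None = None
    secondary_lengths: list[float] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.soma_radius <= 0:
            raise ValueError("soma_radius must be > 0")
        if self.n_processes != len(self.process_lengths):
            raise ValueError("n_processes must equal len(process_lengths)")
        if any(l <= 0 for l in self.process_lengths):
            raise ValueError("all process lengths must be > 0")

    @property
    def total_length(self) -> float:
        """Total process arc length (primaries + secondaries), µm."""
        return float(sum(self.process_lengths) + sum(self.secondary_lengths))


@dataclass
class CalciumTruth:
    """Ground truth for one generated fluorescence trace."""

    event_onsets: list[int]
    event_peak_dff: list[float]
    baseline: float = 100.0
    drift_slope: float = 0.0
    noise_sigma: float = 0.0

    def __post_init__(self) -> None:
        if len(self.event_onsets) != len(self.event_peak_dff):
            raise ValueError("event_onsets and event_peak_dff must align")
        if any(np.diff(self.event_onsets) <= 0):
            raise ValueError("event onsets must be strictly increasing")
        if any(a <= 0 for a in self.event_peak_dff):
            raise ValueError("peak ΔF/F₀ amplitudes must be > 0")
        if self.baseline <= 0:
            raise ValueError("baseline must be > 0")


@dataclass
class LfpTruth:
    """Ground truth for one generated LFP trace.

    Amplitudes are the plateau depths in mV (negative = downward).
    """

    event_starts: list[float]
    event_durations_ms: list[float]
    event_amplitudes_mv: list[float]
    noise_sigma_mv: float = 0.0

    def __post_init__(self) -> None:
        n = len(self.event_starts)
        if len(self.event_durations_ms) != n or len(self.event_amplitudes_mv) != n:
            raise ValueError("event fields must have equal length")
        if any(d <= 0 for d in self.event_durations_ms):
            raise ValueError("durations must be > 0")
        order = np.argsort(self.event_starts)
        starts = np.asarray(self.event_starts, float)[order]
        ends = starts + np.asarray(self.event_durations_ms, float)[order] / 1000.0
        if np.any(starts[1:] < ends[:-1]):
            raise ValueError("events must not overlap")


# ---------------------------------------------------------------------------
# 3D microglia shapes
# ---------------------------------------------------------------------------

def _fibonacci_directions(n: int) -> np.ndarray:
    """n quasi-uniform unit vectors (z, y, x) on the sphere."""
    i = np.arange(n) + 0.5
    polar = np.arccos(1.0 - 2.0 * i / n)
    azim = np.pi * (1.0 + 5.0**0.5) * i
    return np.stack(
        [np.cos(polar), np.sin(polar) * np.sin(azim), np.sin(polar) * np.cos(azim)],
        axis=1,
    )


def _unit(v: np.ndarray) -> np.ndarray:
    n = np.linalg.norm(v)
    return v / n if n > 0 else np.array([0.0, 0.0, 1.0])


def _walk(
    rng: np.random.Generator,
    start: np.ndarray,
    direction: np.ndarray,
    length: float,
    step: float,
    jitter: float,
    half_extent: np.ndarray,
) -> tuple[np.ndarray, float]:
    """Persistent random walk; returns (points, realized arc length).

    The walk is clipped when it would leave the physical half-extent of the
    grid, so the realized length is never silently wrong.
    """
    pts = [np.asarray(start, float)]
    d = _unit(np.asarray(direction, float))
    arc = 0.0
    while arc < length - 1e-9:
        s = min(step, length - arc)
        d = _unit(d + jitter * rng.standard_normal(3))
        p = pts[-1] + d * s
        if np.any(np.abs(p) > half_extent):
            break
        pts.append(p)
        arc += s
    return np.asarray(pts), arc


def _rasterize(
    points_phys: list[np.ndarray],
    soma_radius: float,
    voxel_size: tuple[float, float, float],
    half_extent: np.ndarray,
    tube_radius_vox: float,
) -> np.ndarray:
    """Binary volume: soma ball plus tubes of the given voxel radius."""
    vs = np.asarray(voxel_size, float)
    shape = (2 * np.ceil(half_extent / vs) + 1).astype(int)
    center = (shape - 1) // 2
    mask = np.zeros(tuple(shape), bool)

    # soma: physical ball around the grid center
    zz, yy, xx = np.ogrid[: shape[0], : shape[1], : shape[2]]
    d2 = (
        ((zz - center[0]) * vs[0]) ** 2
        + ((yy - center[1]) * vs[1]) ** 2
        + ((xx - center[2]) * vs[2]) ** 2
    )
    mask |= d2 <= soma_radius**2

    if points_phys:
        # densify polylines and seed their voxels
        dense = []
        fine = 0.4 * vs.min()
        for pts in points_phys:
            if len(pts) < 2:
                dense.append(pts)
                continue
            seg = np.linalg.norm(np.diff(pts, axis=0), axis=1)
            nsub = np.maximum(1, np.ceil(seg / fine).astype(int))
            out = [pts[:1]]
            for a, b, k in zip(pts[:-1], pts[1:], nsub):
                t = np.linspace(0, 1, k + 1)[1:, None]
                out.append(a + t * (b - a))
            dense.append(np.vstack(out))
        pts = np.vstack(dense)
        idx = np.round(pts / vs + center).astype(int)
        idx = np.clip(idx, 0, shape - 1)
        seeds = np.zeros(tuple(shape), bool)
        seeds[idx[:, 0], idx[:, 1], idx[:, 2]] = True

        # dilate seeds to a tube within a cropped subgrid
        pad = int(np.ceil(tube_radius_vox)) + 1
        nz = np.argwhere(seeds)
        lo = np.maximum(nz.min(0) - pad, 0)
        hi = np.minimum(nz.max(0) + pad + 1, shape)
        sl = tuple(slice(a, b) for a, b in zip(lo, hi))
        dist = ndimage.distance_transform_edt(~seeds[sl])
        mask[sl] |= dist <= tube_radius_vox
    return mask


def gen_microglia(
    truth: ShapeTruth,
    voxel_size: tuple[float, float, float] = (1.0, 1.0, 1.0),
    seed: int = 0,
    *,
    step_um: float = 1.0,
    jitter: float = 0.12,
    margin_um: float = 4.0,
    tube_radius_vox: float = TUBE_RADIUS_VOX,
) -> tuple[LabeledVolume, ShapeTruth]:
    """Rasterize one soma-plus-processes cell into a binary volume.

    Processes are persistent random walks launched from quasi-uniform,
    randomly rotated directions on the soma surface, rasterized as tubes of
    ``tube_radius_vox`` voxels. When ``truth.has_secondary_branches`` each
    primary longer than 10 µm spawns one secondary branch (0.4× its length)
    halfway along. Returns the volume and the *realized* truth: lengths are
    re-measured on the generated polylines (walks clipped at the grid edge
    shorten their recorded length).
    """
    vs = np.asarray(voxel_size, float)
    if np.any(vs <= 0):
        raise ValueError("voxel sizes must be > 0")
    rng = np.random.default_rng(seed)

    lmax = max(truth.process_lengths, default=0.0)
    reach = truth.soma_radius + lmax * (1.3 if truth.has_secondary_branches else 1.05)
    half_extent = np.full(3, reach + margin_um)

    dirs = _fibonacci_directions(max(truth.n_processes, 1))
    rot = Rotation.from_quat(_unit(rng.standard_normal(4)))
    dirs = rot.apply(dirs)

    polylines: list[np.ndarray] = []
    primary_lengths: list[float] = []
    secondary_lengths: list[float] = []
    for i in range(truth.n_processes):
        d = dirs[i]
        start = d * truth.soma_radius
        pts, arc = _walk(rng, start, d, truth.process_lengths[i], step_um, jitter, half_extent)
        polylines.append(pts)
        primary_lengths.append(arc)
        if truth.has_secondary_branches and arc > 10.0 and len(pts) > 3:
            j = len(pts) // 2
            base_dir = _unit(pts[j] - pts[j - 1])
            # rotate ~50° away from the parent course
            perp = _unit(np.cross(base_dir, rng.standard_normal(3)))
            d2 = _unit(np.cos(np.deg2rad(50)) * base_dir + np.sin(np.deg2rad(50)) * perp)
            pts2, arc2 = _walk(rng, pts[j], d2, 0.4 * arc, step_um, jitter, half_extent)
            if arc2 > 0:
                polylines.append(pts2)
                secondary_lengths.append(arc2)

    mask = _rasterize(polylines, truth.soma_radius, voxel_size, half_extent, tube_radius_vox)
    realized = ShapeTruth(
        soma_radius=truth.soma_radius,
        n_processes=truth.n_processes,
        process_lengths=primary_lengths if truth.n_processes else [],
        has_secondary_branches=truth.has_secondary_branches,
        intended_class=truth.intended_class,
        secondary_lengths=secondary_lengths,
    )
    vol = LabeledVolume(mask.astype(np.uint8), tuple(vs))
    return vol, realized


def truth_morphology(truth: ShapeTruth, tube_radius_um: float = EFFECTIVE_TUBE_RADIUS_UM):
    """Analytic (S, NP, TL, A, V) for the idealized ball-plus-cylinders shape.

    Junction overlaps and end caps are ignored; this is the truth-level
    morphology used to check that class-conditional generator parameters
    satisfy their intended classification criteria by construction.
    """
    from .morpho3d import CellMorphology

    r = truth.soma_radius
    rt = tube_radius_um
    tl = truth.total_length
    v = 4.0 / 3.0 * np.pi * r**3 + np.pi * rt**2 * tl
    a = 4.0 * np.pi * r**2 + 2.0 * np.pi * rt * tl
    s = np.pi ** (1.0 / 3.0) * (6.0 * v) ** (2.0 / 3.0) / a
    np_ = truth.n_processes
    return CellMorphology(
        sphericity=float(s),
        n_processes=np_,
        total_length=float(tl),
        mean_length=float(tl / np_) if np_ else 0.0,
        surface_area=float(a),
        volume=float(v),
        ramification_index=(
            (np_ + len(truth.secondary_lengths)) / np_ if np_ else 0.0
        ),
        sholl=[],
    )


#: class-conditional parameter ranges; each intended class satisfies its
#: classification criteria by construction (see docs/methods.md)
_CLASS_PARAMS = {
    "amoeboid": dict(soma=(4.0, 6.0), np=(0, 2), secondary=False),
    "transitional": dict(soma=(4.0, 5.5), np=(4, 6), secondary=True, tl=(100.0, 130.0)),
    "branched": dict(soma=(4.0, 5.5), np=(8, 10), secondary=True, length=(20.0, 30.0)),
}


def sample_truth(intended_class: str, rng: np.random.Generator) -> ShapeTruth:
    """Draw one ShapeTruth from the class-conditional parameter ranges."""
    p = _CLASS_PARAMS[intended_class]
    soma = rng.uniform(*p["soma"])
    n = int(rng.integers(p["np"][0], p["np"][1] + 1))
    if intended_class == "amoeboid":
        lengths = list(rng.uniform(6.0, 10.0, size=n))
    elif intended_class == "branched":
        lengths = list(rng.uniform(*p["length"], size=n))
    else:  # transitional: hit a total-length window incl. 0.4× secondaries
        tl_target = rng.uniform(*p["tl"])
        base = tl_target / (n * 1.4)
        lengths = list(base * rng.uniform(0.9, 1.1, size=n))
    return ShapeTruth(
        soma_radius=float(soma),
        n_processes=n,
        process_lengths=[float(l) for l in lengths],
        has_secondary_branches=bool(p["secondary"]) and n > 0,
        intended_class=intended_class,
    )


def gen_population(
    mix: dict[str, float],
    n: int,
    seed: int = 0,
    voxel_size: tuple[float, float, float] = (1.0, 1.0, 1.0),
) -> list[tuple[LabeledVolume, ShapeTruth]]:
    """Generate ``n`` cells with intended classes drawn from ``mix``.

    ``mix`` maps class labels (branched/amoeboid/transitional) to
    proportions that must be non-negative and sum to 1.
    """
    if n <= 0:
        raise ValueError("n must be > 0")
    labels = list(mix)
    probs = np.asarray([mix[k] for k in labels], float)
    if np.any(probs < 0) or abs(probs.sum() - 1.0) > 1e-6:
        raise ValueError("mix proportions must be ≥ 0 and sum to 1")
    unknown = set(labels) - set(_CLASS_PARAMS)
    if unknown:
        raise ValueError(f"unknown class labels: {sorted(unknown)}")
    rng = np.random.default_rng(seed)
    drawn = rng.choice(labels, size=n, p=probs)
    seeds = rng.integers(0, 2**31 - 1, size=n)
    out = []
    for cls, s in zip(drawn, seeds):
        truth = sample_truth(str(cls), rng)
        out.append(gen_microglia(truth, voxel_size=voxel_size, seed=int(s)))
    return out


# ---------------------------------------------------------------------------
# calcium traces
# ---------------------------------------------------------------------------

def gen_calcium_trace(
    n_frames: int,
    truth: CalciumTruth,
    seed: int = 0,
    *,
    tau_frames: float = 10.0,
    frame_interval_s: float = 0.4,
):
    """Raw fluorescence trace: baseline + linear drift + noise + transients.

    Transients rise instantly at their onset frame and decay exponentially
    (time constant ``tau_frames``); each peak amplitude is expressed as
    ΔF/F₀ relative to the noiseless local baseline at its onset, so the
    intended peak ΔF/F₀ survives any drift. Overlapping transients sum.
    Returns ``(FluorescenceTrace, CalciumTruth)``.
    """
    from .caevents import FluorescenceTrace

    if n_frames <= 0:
        raise ValueError("n_frames must be > 0")
    rng = np.random.default_rng(seed)
    t = np.arange(n_frames, dtype=float)
    raw = truth.baseline + truth.drift_slope * t
    for onset, peak in zip(truth.event_onsets, truth.event_peak_dff):
        if onset >= n_frames:
            raise ValueError("event onset beyond trace end")
        local = truth.baseline + truth.drift_slope * onset
        tail = np.arange(n_frames - onset, dtype=float)
        raw[onset:] += peak * local * np.exp(-tail / tau_frames)
    if truth.noise_sigma > 0:
        raw = raw + rng.normal(0.0, truth.noise_sigma, n_frames)
    if np.any(raw < 0):
        warnings.warn("negative intensities clipped to 0", stacklevel=2)
        raw = np.clip(raw, 0.0, None)
    trace = FluorescenceTrace(frame_times=t * frame_interval_s, raw=raw)
    return trace, truth


# ---------------------------------------------------------------------------
# LFP traces
# ---------------------------------------------------------------------------

def gen_lfp(
    duration_s: float,
    sampling_interval_s: float,
    truth: LfpTruth,
    seed: int = 0,
    *,
    edge_ms: float = 5.0,
):
    """Zero-mean noise plus smooth-edged downward deflections.

    Deflections have half-cosine onset/offset ramps (``edge_ms`` each,
    shrunk for very short events) so they pass a band-pass filter without
    ringing dominating. Returns ``(LfpRecording, LfpTruth)``.
    """
    from .lfpevents import LfpRecording

    dt = float(sampling_interval_s)
    n = int(round(duration_s / dt))
    last_end = max(
        (s + d / 1000.0 for s, d in zip(truth.event_starts, truth.event_durations_ms)),
        default=0.0,
    )
    if last_end > duration_s + 1e-9:
        raise ValueError("duration does not cover all events")
    rng = np.random.default_rng(seed)
    x = (
        rng.normal(0.0, truth.noise_sigma_mv, n)
        if truth.noise_sigma_mv > 0
        else np.zeros(n)
    )
    t = np.arange(n) * dt
    for start, dur_ms, amp in zip(
        truth.event_starts, truth.event_durations_ms, truth.event_amplitudes_mv
    ):
        dur = dur_ms / 1000.0
        edge = min(edge_ms / 1000.0, dur / 2.0)
        rel = t - start
        env = np.zeros(n)
        inside = (rel >= 0) & (rel <= dur)
        r = rel[inside]
        e = np.ones_like(r)
        if edge > 0:
            rise = r < edge
            fall = r > dur - edge
            e[rise] = 0.5 * (1 - np.cos(np.pi * r[rise] / edge))
            e[fall] = 0.5 * (1 - np.cos(np.pi * (dur - r[fall]) / edge))
        env[inside] = e
        x = x + amp * env
    return LfpRecording(samples=x, sampling_interval=dt), truth


# ---------------------------------------------------------------------------
# trajectories
# ---------------------------------------------------------------------------

def gen_trajectory(
    segments: list[tuple[float, float]],
    dt_s: float = 1.0,
    seed: int = 0,
    *,
    heading_jitter: float = 0.4,
    start_xy: tuple[float, float] = (0.0, 0.0),
) -> pd.DataFrame:
    """Piecewise-constant-speed 2D trajectory with random heading changes.

    ``segments`` is a list of ``(duration_s, speed_mm_s)``; each step moves
    exactly ``speed × dt`` mm (durations should be multiples of ``dt`` for
    exact totals). Returns a DataFrame with columns ``t_s, x_mm, y_mm``.
    """
    if not segments:
        raise ValueError("segments must be non-empty")
    if dt_s <= 0:
        raise ValueError("dt must be > 0")
    if any(v < 0 for _, v in segments):
        raise ValueError("speeds must be ≥ 0")
    rng = np.random.default_rng(seed)
    heading = rng.uniform(0, 2 * np.pi)
    xs = [start_xy[0]]
    ys = [start_xy[1]]
    ts = [0.0]
    for dur, speed in segments:
        for _ in range(int(round(dur / dt_s))):
            heading += heading_jitter * rng.standard_normal()
            xs.append(xs[-1] + speed * dt_s * np.cos(heading))
            ys.append(ys[-1] + speed * dt_s * np.sin(heading))
            ts.append(ts[-1] + dt_s)
    return pd.DataFrame({"t_s": ts, "x_mm": xs, "y_mm": ys})
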