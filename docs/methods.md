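# Methods

This note documents the models, algorithms, parameter choices and known
limitations behind `gliaquant`. The package quantifies four read-outs of a
larval-zebrafish epilepsy study design: microglial morphology and
activation state in 3D confocal stacks, microglial cell-body motility in
time-lapse stacks, neuronal hyperactivity via whole-field GCaMP ΔF/F₀ and
via tectal local field potentials (LFP), and seizure-like locomotor
behavior of freely swimming larvae.

## 3D morphometry (`morpho3d`)

A cell is a 26-connected set of voxels in a `LabeledVolume` with physical
voxel sizes (z, y, x) in µm. Per cell we compute:

* **Volume** V — voxel count × voxel volume (µm³).
* **Surface area** A — area of the marching-cubes isosurface at level 0.5,
  relaxed with 5 iterations of Humphrey's anti-shrinkage mesh filter
  (α = 0.05, β = 0.7). The raw staircase isosurface of a digitized ball
  overestimates its area by ≈ 9 %, while volumetric Gaussian smoothing or
  Taubin/Laplacian mesh smoothing rounds off flat-faced shapes; the
  Humphrey filter keeps both within a few percent of the closed forms
  (digitized ball ≈ +1 %, digitized cube ≈ −4 %).
* **Sphericity** S = π^(1/3)·(6V)^(2/3)/A (Wadell's definition): 1 for a
  perfect ball, smaller for ramified shapes.
* **Skeleton quantities** — the mask (isotropically resampled to its
  smallest voxel pitch when anisotropic, linear interpolation) is thinned
  to a 1-voxel 3D skeleton. The soma center is the maximum of the
  Euclidean distance transform and the soma radius its value there.
  Skeleton voxels within `soma_radius + 3 µm` of the center are contracted
  into a single soma node: within roughly one process-tube diameter of the
  soma surface, skeleton topology reflects tube fusion rather than true
  branching (the same role the soma region plays in commercial filament
  tracers). The remaining voxels form a junction/terminal graph; terminal
  spurs shorter than 2 µm (`prune_len`) are removed as thinning artifacts.
  * **NP** — number of skeleton edges incident to the soma node (primary
    processes).
  * **TL** — total skeleton arc length outside the soma sphere, with
    soma-incident branches extended radially to the soma surface so the
    contracted shell is not under-counted. **Mean length** = TL/NP.
  * **Ramification index RI** — terminal nodes per primary process: 1 for
    unbranched cells, 2 for one bifurcation per primary, 0 when NP = 0.
    (The metric has no published formula in the protocols this package
    follows; this definition is the natural one with those properties.)
  * **Sholl profile** — for spheres of radius 5, 10, … 100 µm around the
    soma center, the number of skeleton polyline crossings (a branch
    crossing k times counts k; vertices exactly on a sphere are not
    tangencies).

`segment_cells` provides Otsu-threshold + 26-connected labeling with a
minimum size of 50 voxels for intensity stacks; `coexpression_fraction`
scores each cell positive for a second reporter channel when its mean
reporter intensity exceeds an Otsu cutoff computed over all cell voxels
(or, optionally, when a set fraction of its voxels do).

## Activation-state classification (`classify`)

Fixed rule on the four parameters (S, NP, TL, A); V is carried but unused:

* **branched** — at least 3 of: S < 0.5, NP > 7, TL > 140 µm, A > 2400 µm²;
* **amoeboid** — at least 3 of: S > 0.7, NP < 3, TL < 60 µm, A < 1500 µm²;
* **transitional** — everything else.

All comparisons are strict. Because each parameter's branched and amoeboid
intervals are disjoint, at most 4 of the 8 predicates can hold for one
cell, so no cell can reach 3 criteria on both sides: the classes are
mutually exclusive by construction (also verified against a brute-force
oracle on 10⁵ random vectors and on 10⁶ vectors for the exclusivity
property). Custom thresholds can be supplied but must keep the intervals
disjoint.

## Motility (`motility`)

Per-frame centroids are linked by greedy mutual-nearest-neighbor
assignment (candidate links consumed in order of increasing distance),
rejecting links longer than 20 µm; there is no gap closing — at a 40 s
frame interval, identity across a missed detection is unreliable, so a
disappearing cell ends its track. Per track: displacement (straight line,
first → last centroid), path length (sum of steps) and mean speed
(path length / elapsed time, µm/min). Group tables keep only tracks
spanning ≥ 80 % of frames, since short fragments bias speed estimates.

## Calcium events (`caevents`)

ΔF/F₀(t) = (F(t) − mean F)/mean F with F the per-frame mean gray value and
F₀ the whole-trace mean; the definition is exactly gain-invariant and sums
to zero over the trace. Slow drift is removed before normalization by
subtracting a running 10th-percentile baseline (60 s window); the
percentile tracks the inter-event background while transients occupy the
upper tail of any window. The outer half-windows of the baseline are
linearly extrapolated from the adjacent valid region, which reduces an
event-free linear ramp of any slope to numerically zero residual.

An event is a maximal run of frames with ΔF/F₀ > 0.04; its amplitude is
the run maximum. Runs separated by fewer than `min_separation_frames`
sub-threshold frames merge. The default is 1 frame; the synthetic suites
and the pipeline use 3 frames (≈ 1 s) because a decaying transient
re-crossing the threshold through noise is one physiological event, not
several. No minimum duration is imposed.

## LFP events (`lfpevents`)

Recordings are band-pass filtered with a zero-phase (forward–backward)
second-order Butterworth filter, corners 0.1 Hz and 1 kHz; zero-phase
filtering preserves deflection timing and the high-pass removes any DC
offset exactly. An event is a maximal segment of the filtered trace below
−0.3 mV lasting strictly more than 100 ms; its amplitude is the segment
minimum (reported negative). Amplitudes are measured from the filtered
zero baseline (threshold-crossing semantics); a local-baseline mode is not
provided because no protocol detail supports one. Segments closer than
`merge_gap_ms` are merged first (default 0; the synthetic suites use
20 ms, which rejoins noise-fragmented crossings of one deflection — with
σ = 0.05 mV noise a −0.4 mV plateau sits only 2σ below threshold, so
momentary re-crossings are expected). The detector is sampling-rate
agnostic; the filter refuses a low-pass corner at or above Nyquist and
asks the caller to resample or lower it.

## Locomotor scoring (`swim`)

Per-step speed = step length / Δt. Steps are binned as immobile
(< 0.1 mm/s motion floor), low (< 4 mm/s), medium (4–8 mm/s) or high
(≥ 8 mm/s); the summary reports total distance and per-state times,
overall and per 60-s integration bin. The two printed thresholds (4, 8)
are interpreted as mm/s: tracker conventions quote them as distance per
second at one-second re-integration. The motion floor separates "immobile"
from "low speed", which the two thresholds alone cannot; it is
configurable. State times sum to the recording duration exactly (to one
sample interval).

## Statistics (`stats`)

Two-group comparisons: Shapiro–Wilk normality on each group (α = 0.05,
configurable); both normal → unpaired t-test, with Welch's correction when
Levene's test rejects equal variances (α = 0.05); otherwise Mann–Whitney U
(two-sided). Degenerate all-equal input returns p = 1. Factorial designs:
two-way ANOVA with interaction (type-II) plus a Tukey HSD table over the
crossed groups. All tests delegate to scipy.stats and statsmodels; this
module owns only selection and reporting. No multiple-testing correction
is applied across metrics; reports include the number of comparisons made.

## Synthetic data (`synthdata`)

The generators emulate each input kind with exact ground truth:

* **Cells** — a rasterized soma ball plus tube-like processes (persistent
  random walks from quasi-uniform, randomly rotated launch directions;
  tube radius 1.5 voxels — thinner tubes fragment under thinning). Primary
  arc lengths are re-measured on the generated polylines; walks clipped at
  the grid edge shorten their recorded truth. Secondary branches (0.4× the
  primary length, branching ~50° halfway along) model ramification.
  Class-conditional parameter ranges (amoeboid: ≤ 2 processes of 6–10 µm;
  transitional: 4–6 processes, total length targeted at 100–130 µm
  including secondaries; branched: 8–10 processes of 20–30 µm with
  secondaries) satisfy their intended classification criteria by
  construction, verified analytically on the ball-plus-cylinders model.
* **Calcium traces** — baseline + linear drift + Gaussian noise +
  transients with instant rise and exponential decay (τ = 10 frames; the
  detection rule depends only on threshold crossing, so any unimodal shape
  would do). Peak amplitudes are expressed as ΔF/F₀ against the local
  noiseless baseline, so the intended peak survives drift.
* **LFP traces** — zero-mean Gaussian noise plus downward deflections with
  5 ms half-cosine edges (sharp edges ring through the band-pass).
  Default synthetic sampling is 1 kHz–2.5 kHz; the hardware-level 10 µs
  interval is supported but pointless for events lasting ≥ 100 ms.
* **Trajectories** — piecewise-constant speed with random heading changes;
  each step moves exactly speed × dt, so distances and state times have
  closed-form truth.

Every generator is a pure function of (parameters, seed). What the
generators do **not** model: optics (PSF, shot noise, background
gradients), touching/overlapping cells, z-drift, photobleaching beyond a
linear trend, electrode artifacts, and wall-following or burst-and-glide
kinematics of real larvae. Passing recovery tests therefore demonstrates
correctness of the measurement chain, not robustness to every
imaging artifact.

## The synthetic experiment (`pipeline`)

`run_synthetic_experiment` mirrors the study design: two genotypes
(control "wt", condition "kd") × microglia present/depleted. Effect sizes
default to the study's printed group values — amoeboid fraction
10.4 → 29.1 %, calcium events 16.5 → 32.2 /h, LFP events 4.8 → 28.2 /h,
total distance 212 → 355 mm per 30 min, with further worsening in
depleted condition larvae (LFP/calcium ×1.5, distance ×1.19). Cohort
sizes are desk-scale choices that preserve the rates and fractions while
keeping a full two-config, multi-seed study tractable on one CPU:

| arm        | groups | larvae/group | per larva                    |
|------------|--------|--------------|------------------------------|
| morphology | 2 (microglia present only) | 12 | 14 cells, 1 µm voxels |
| calcium    | 4      | 10           | 40 min at 2.5 Hz             |
| LFP        | 4      | 8            | 20 min at 500 Hz, low-pass 200 Hz |
| swim       | 4      | 16           | 30 min at 1 Hz               |

Microglia-depleted groups contain no microglial cells by definition, so
the morphology arm covers the two microglia-present genotypes. The LFP
low-pass is set to 200 Hz because the synthetic signal has no content
above ~50 Hz and the 500 Hz sampling rate caps the usable corner below
250 Hz; the detector itself is rate-agnostic.

The report bundles larva-level tables, the four primary endpoint
comparisons (amoeboid fraction, calcium event rate, LFP event rate, total
distance; condition vs control with microglia present — the study's
figure-level claims), 2×2 ANOVA tables for the physiology/behavior
metrics, and a provenance log of every threshold actually used. Output is
byte-identical across repeated runs with the same config and seed.

## Numerical choices and degenerate inputs

* Connectivity is 26 throughout; thresholds of the classifier and both
  detectors are strict inequalities.
* A mask thinner than one voxel everywhere (or a bare ball) yields a
  degenerate single-node skeleton with NP = 0, not an error.
* An all-zero fluorescence trace raises (F₀ = 0); an empty segmentation
  warns and returns zero cells; empty event lists report a rate of 0 and
  an absent (None) mean amplitude rather than 0.
* Ties: centroid links are consumed in order of (distance, frame order);
  equal-distance candidates resolve by enumeration order.

## Known limitations

* Strongly anisotropic voxels (≥ 2:1) inflate skeleton arc lengths by up
  to ~25 % through resampling staircase meander; process counts and
  classification are unaffected in our tests, but length-based metrics are
  most trustworthy at near-isotropic acquisition.
* The surface-area estimator is accurate to a few percent on convex
  bodies; extremely thin sheets (< 2 voxels) are outside its validated
  range.
* Touching microglia are not split: segmentation assumes separable cells.
* The motility linker is greedy; globally optimal assignment (Hungarian)
  could differ in dense fields, which the 20 µm gate makes rare at the
  study's cell densities.
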