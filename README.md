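# gliaquant

Quantification toolkit for studies of microglia and seizure activity in
larval zebrafish — a genetic epilepsy model (Dravet-syndrome-like *scn1Lab*
loss of function) in which microglial activation state, neuronal
hyperactivity and locomotor seizures are read out together. The package
re-implements the measurement chain of such studies as a tested, reusable
Python library:

* **3D microglia morphometrics** from labeled confocal stacks: volume V,
  surface area A, Wadell sphericity S = π^⅓(6V)^⅔/A, primary process
  count NP, total/mean process length, ramification index (terminals per
  primary), and Sholl profiles from a 3D skeleton.
* **Rule-based activation classification**: *branched* (≥3 of S < 0.5,
  NP > 7, TL > 140 µm, A > 2400 µm²), *amoeboid* (≥3 of S > 0.7, NP < 3,
  TL < 60 µm, A < 1500 µm²), else *transitional*.
* **Cell-body motility**: nearest-neighbor centroid tracking,
  displacement, path length, mean speed.
* **Calcium events**: ΔF/F₀ = (F − F̄)/F̄ on whole-field traces, running
  percentile drift correction, events = excursions above 0.04 ΔF/F₀.
* **LFP events**: zero-phase 0.1 Hz–1 kHz Butterworth band-pass, events =
  downward deflections below −0.3 mV lasting > 100 ms.
* **Locomotor scoring**: total distance and time in
  immobile/low/medium/high speed states (thresholds 4 and 8 mm/s, 60 s
  integration bins).
* **Synthetic data generators** with exact ground truth for every input
  kind, so the whole chain is verifiable without raw imaging data, plus an
  end-to-end synthetic two-genotype experiment with group statistics
  (Shapiro-gated t/Welch/Mann–Whitney, two-way ANOVA + Tukey).

## Worked example

Generate one ramified cell with known ground truth, measure it, and
classify it:

```python
from gliaquant import synthdata, morpho3d, classify

truth = synthdata.ShapeTruth(
    soma_radius=5.0, n_processes=8, process_lengths=[25.0] * 8,
    has_secondary_branches=True,
)
vol, realized = synthdata.gen_microglia(truth, seed=1)
m = morpho3d.measure_cell(vol, cell_id=1)
print(f"NP={m.n_processes}  TL={m.total_length:.0f} µm  "
      f"S={m.sphericity:.2f}  A={m.surface_area:.0f} µm²  RI={m.ramification_index:.2f}")
print(classify.classify_cell(m))
```

```
NP=8  TL=283 µm  S=0.32  A=3438 µm²  RI=1.88
MorphClass(label='branched', n_branched_criteria=4, n_amoeboid_criteria=0)
```

The generator injected 8 primary processes totalling 280 µm of truth
(primaries plus secondary branches); the skeleton recovers all 8 and the
total length within ~1 %. Low sphericity, high process count, length and
area satisfy all four branched criteria, so the cell is classified as
"resting"-type branched microglia.

The same round trip exists for every modality — see `examples/`:

* `examples/morphometry.py` — generate, measure and classify one cell
* `examples/population.py` — classify a 300-cell mixed population and
  recover its composition
* `examples/calcium.py` — detect injected ΔF/F₀ transients on a noisy
  drifting trace
* `examples/lfp.py` — band-pass and detect seizure-like LFP deflections
* `examples/swim.py` — score a piecewise-speed trajectory into speed bins
* `examples/motility.py` — track moving centroids and summarize motility
* `examples/experiment.py` — the full synthetic two-genotype study with
  group statistics

There is also a thin CLI (`gliaquant synth|morpho|classify|motility|
calcium|lfp|swim|stats|run-all`) over CSV/TIFF files; `--help` on any
subcommand shows its options.

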