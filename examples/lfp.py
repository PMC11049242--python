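"""Detect seizure-like LFP events: deflections < −0.3 mV lasting > 100 ms.

Injects ten downward deflections into noise, band-pass filters and
detects; also shows that sub-threshold or too-brief deflections are
rejected.
"""

from gliaquant import lfpevents, synthdata

fs = 2500.0
truth = synthdata.LfpTruth(
    event_starts=[30.0 * k + 10 for k in range(10)],
    event_durations_ms=[250.0] * 10,
    event_amplitudes_mv=[-0.6] * 10,
    noise_sigma_mv=0.05,
)
rec, _ = synthdata.gen_lfp(320.0, 1 / fs, truth, seed=1)

filtered = lfpevents.bandpass(rec, hp_hz=0.1, lp_hz=1000.0)
events = lfpevents.detect_lfp_events(filtered, merge_gap_ms=20.0)
count, rate, mean_amp = lfpevents.lfp_stats(events, rec.duration_s)
print(f"injected 10 deflections; detected {count} events")
print(f"rate {rate:.2f}/min, mean |amplitude| {mean_amp:.2f} mV (injected 0.6 mV)")

# boundary cases: too brief, and too shallow
for amp, dur in ((-0.5, 50.0), (-0.2, 200.0)):
    t = synthdata.LfpTruth([5.0], [dur], [amp])
    r, _ = synthdata.gen_lfp(20.0, 1 / fs, t, seed=0)
    n = len(lfpevents.detect_lfp_events(lfpevents.bandpass(r)))
    print(f"deflection {amp} mV x {dur:.0f} ms -> {n} events (rule requires "
          "< -0.3 mV AND > 100 ms)")
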