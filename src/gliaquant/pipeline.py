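"""End-to-end synthetic experiment orchestration.

``run_synthetic_experiment`` generates a two-genotype (control "wt" vs
condition "kd") × two-microglia-status (present vs depleted) synthetic
study — microglia shapes, calcium traces, LFP traces and swim
trajectories — runs every quantification stage on it, and reports
larva-level tables, the primary group comparisons (amoeboid fraction,
calcium event rate, LFP event rate, total distance; condition vs control
with microglia present, mirroring the study's figure-level endpoints) and
2×2 factorial ANOVAs for the physiology/behavior metrics. Fully
deterministic per (config, seed).

Default effect sizes follow the study's printed group values (amoeboid
fraction 10.4→29.1 %, calcium events 16.5→32.2 /h, LFP events
4.8→28.2 /h, distance 212→355 mm per 30 min); cohort sizes are scaled to
desk-size (see docs/methods.md).
"""

from __future__ import annotations

import copy
import json
import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from . import caevents, classify, lfpevents, morpho3d, swim, synthdata
from .stats import compare_factorial, compare_two_groups

log = logging.getLogger("gliaquant")

GENOTYPES = ("wt", "kd")
MICROGLIA = ("present", "depleted")

DEFAULT_CONFIG: dict = {
    "morphology": {
        "n_larvae": 12,
        "cells_per_larva": 14,
        "voxel_size": [1.0, 1.0, 1.0],
        # class mixes per genotype (study Fig-level proportions)
        "mix_wt": {"branched": 0.278, "amoeboid": 0.104, "transitional": 0.618},
        "mix_kd": {"branched": 0.102, "amoeboid": 0.291, "transitional": 0.607},
    },
    "calcium": {
        "n_larvae": 10,
        "duration_min": 40.0,
        "frame_rate_hz": 2.5,
        "rate_per_hr_wt": 16.5,
        "rate_per_hr_kd": 32.2,
        "depletion_rate_factor": 1.5,  # applies to the condition genotype
        "peak_dff_min": 0.05,
        "noise_sigma_dff": 0.005,
        "drift_per_frame": 0.01,
        "baseline": 100.0,
    },
    "lfp": {
        "n_larvae": 8,
        "duration_min": 20.0,
        "sampling_hz": 500.0,
        "rate_per_hr_wt": 4.8,
        "rate_per_hr_kd": 28.2,
        "depletion_rate_factor": 1.5,
        "noise_sigma_mv": 0.05,
        "hp_hz": 0.1,
        "lp_hz": 200.0,  # generator content is < 50 Hz; keep below Nyquist
        "merge_gap_ms": 20.0,  # rejoin noise-fragmented threshold crossings
    },
    "swim": {
        "n_larvae": 16,
        "duration_min": 30.0,
        "dt_s": 1.0,
        "distance_mm_wt": 212.0,
        "distance_mm_kd": 355.0,
        "distance_sd_mm": 45.0,
        "depletion_distance_factor": 423.0 / 355.0,
    },
    "stats": {"normality_alpha": 0.05, "variance_alpha": 0.05},
}


def zero_effect_config() -> dict:
    """A config whose condition groups equal the control groups."""
    cfg = copy.deepcopy(DEFAULT_CONFIG)
    cfg["morphology"]["mix_kd"] = dict(cfg["morphology"]["mix_wt"])
    cfg["calcium"]["rate_per_hr_kd"] = cfg["calcium"]["rate_per_hr_wt"]
    cfg["calcium"]["depletion_rate_factor"] = 1.0
    cfg["lfp"]["rate_per_hr_kd"] = cfg["lfp"]["rate_per_hr_wt"]
    cfg["lfp"]["depletion_rate_factor"] = 1.0
    cfg["swim"]["distance_mm_kd"] = cfg["swim"]["distance_mm_wt"]
    cfg["swim"]["depletion_distance_factor"] = 1.0
    return cfg


def validate_config(config: dict) -> dict:
    """Merge a partial config over the defaults; reject unknown keys."""
    bad: list[str] = []

    def merge(defaults: dict, user: dict, prefix: str) -> dict:
        out = copy.deepcopy(defaults)
        for k, v in user.items():
            if k not in defaults:
                bad.append(prefix + k)
            elif isinstance(defaults[k], dict) and k not in ("mix_wt", "mix_kd"):
                if not isinstance(v, dict):
                    bad.append(prefix + k)
                else:
                    out[k] = merge(defaults[k], v, prefix + k + ".")
            else:
                out[k] = copy.deepcopy(v)
        return out

    merged = merge(DEFAULT_CONFIG, config or {}, "")
    if bad:
        raise ValueError(f"unknown config keys: {sorted(bad)}")
    return merged


@dataclass
class ExperimentReport:
    """Bundle of larva-level tables, comparisons and provenance."""

    larva_tables: dict[str, pd.DataFrame]
    comparisons: pd.DataFrame
    anova: dict[str, pd.DataFrame]
    thresholds: dict
    config: dict
    seed: int

    def write(self, out_dir: str | Path) -> None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        for name, df in self.larva_tables.items():
            df.to_csv(out / f"larvae_{name}.csv", index=False)
        self.comparisons.to_csv(out / "comparisons.csv", index=False)
        for name, df in self.anova.items():
            df.to_csv(out / f"anova_{name}.csv")
        with open(out / "report.json", "w") as fh:
            json.dump(
                {"seed": self.seed, "thresholds": self.thresholds, "config": self.config},
                fh,
                indent=2,
                sort_keys=True,
            )


# ---------------------------------------------------------------------------
# per-modality synthetic arms
# ---------------------------------------------------------------------------

def _spaced_onsets(rng, n: int, n_frames: int, min_gap: int) -> list[int]:
    if n == 0:
        return []
    lo, hi = min_gap, max(n_frames - min_gap, min_gap + 1)
    for _ in range(200):
        on = np.sort(rng.integers(lo, hi, n))
        if n == 1 or np.all(np.diff(on) >= min_gap):
            return [int(x) for x in on]
    base = np.linspace(lo, hi - 1, n)
    jit = rng.uniform(-0.25, 0.25, n) * min_gap
    on = np.unique((base + jit).astype(int))
    return [int(x) for x in on]


def _morphology_arm(cfg: dict, rng) -> pd.DataFrame:
    rows = []
    mc = cfg["morphology"]
    for geno in GENOTYPES:
        mix = mc[f"mix_{geno}"]
        for larva in range(mc["n_larvae"]):
            seed = int(rng.integers(2**31 - 1))
            cells = synthdata.gen_population(
                mix, mc["cells_per_larva"], seed=seed,
                voxel_size=tuple(mc["voxel_size"]),
            )
            morphs = [morpho3d.measure_cell(vol, 1) for vol, _ in cells]
            pct, _ = classify.classify_population(morphs)
            rows.append(
                {
                    "genotype": geno,
                    "microglia": "present",
                    "larva": larva,
                    "n_cells": len(cells),
                    "amoeboid_fraction_pct": pct[classify.AMOEBOID],
                    "branched_fraction_pct": pct[classify.BRANCHED],
                    "transitional_fraction_pct": pct[classify.TRANSITIONAL],
                }
            )
    return pd.DataFrame(rows)


def _calcium_arm(cfg: dict, rng) -> pd.DataFrame:
    cc = cfg["calcium"]
    n_frames = int(cc["duration_min"] * 60 * cc["frame_rate_hz"])
    duration_s = n_frames / cc["frame_rate_hz"]
    rows = []
    for geno in GENOTYPES:
        for mg in MICROGLIA:
            rate = cc[f"rate_per_hr_{geno}"]
            if mg == "depleted" and geno == "kd":
                rate *= cc["depletion_rate_factor"]
            lam = rate * cc["duration_min"] / 60.0
            for larva in range(cc["n_larvae"]):
                n_ev = int(rng.poisson(lam))
                onsets = _spaced_onsets(rng, n_ev, n_frames, min_gap=40)
                peaks = list(cc["peak_dff_min"] + rng.gamma(2.0, 0.015, len(onsets)))
                truth = synthdata.CalciumTruth(
                    event_onsets=onsets,
                    event_peak_dff=peaks,
                    baseline=cc["baseline"],
                    drift_slope=cc["drift_per_frame"],
                    noise_sigma=cc["noise_sigma_dff"] * cc["baseline"],
                )
                trace, _ = synthdata.gen_calcium_trace(
                    n_frames, truth, seed=int(rng.integers(2**31 - 1)),
                    frame_interval_s=1.0 / cc["frame_rate_hz"],
                )
                trace = caevents.correct_drift(trace)
                # 3-frame debounce: a decaying transient re-crossing the
                # threshold in noise is one event, not several
                events = caevents.detect_events(trace, min_separation_frames=3)
                count, rate_min, mean_amp = caevents.event_stats(events, duration_s)
                rows.append(
                    {
                        "genotype": geno, "microglia": mg, "larva": larva,
                        "n_events_true": len(onsets),
                        "n_events": count,
                        "events_per_min": rate_min,
                        "mean_amplitude_dff": mean_amp,
                    }
                )
    return pd.DataFrame(rows)


def _lfp_arm(cfg: dict, rng) -> pd.DataFrame:
    lc = cfg["lfp"]
    duration_s = lc["duration_min"] * 60.0
    dt = 1.0 / lc["sampling_hz"]
    rows = []
    for geno in GENOTYPES:
        for mg in MICROGLIA:
            rate = lc[f"rate_per_hr_{geno}"]
            if mg == "depleted" and geno == "kd":
                rate *= lc["depletion_rate_factor"]
            lam = rate * lc["duration_min"] / 60.0
            for larva in range(lc["n_larvae"]):
                n_ev = int(rng.poisson(lam))
                starts: list[float] = []
                durs: list[float] = []
                for _ in range(2000):
                    if len(starts) == n_ev:
                        break
                    d = float(rng.uniform(150.0, 500.0))
                    s = float(rng.uniform(2.0, duration_s - 2.0))
                    if all(
                        s + d / 1000 + 1.0 < s2 or s2 + d2 / 1000 + 1.0 < s
                        for s2, d2 in zip(starts, durs)
                    ):
                        starts.append(s)
                        durs.append(d)
                amps = list(-(0.4 + rng.gamma(2.0, 0.1, len(starts))))
                truth = synthdata.LfpTruth(
                    event_starts=starts,
                    event_durations_ms=durs,
                    event_amplitudes_mv=amps,
                    noise_sigma_mv=lc["noise_sigma_mv"],
                )
                rec, _ = synthdata.gen_lfp(
                    duration_s, dt, truth, seed=int(rng.integers(2**31 - 1))
                )
                filt = lfpevents.bandpass(rec, hp_hz=lc["hp_hz"], lp_hz=lc["lp_hz"])
                events = lfpevents.detect_lfp_events(filt, merge_gap_ms=lc["merge_gap_ms"])
                count, rate_min, mean_amp = lfpevents.lfp_stats(events, duration_s)
                rows.append(
                    {
                        "genotype": geno, "microglia": mg, "larva": larva,
                        "n_events_true": len(starts),
                        "n_events": count,
                        "events_per_min": rate_min,
                        "mean_abs_amplitude_mv": mean_amp,
                    }
                )
    return pd.DataFrame(rows)


def _swim_segments(rng, duration_s: float, target_mm: float, dt: float):
    n_bouts = 20
    speeds = rng.uniform(3.0, 9.0, n_bouts)
    t_act = min(target_mm / speeds.mean(), 0.85 * duration_s)
    bout = max(dt, np.round(t_act / n_bouts / dt) * dt)
    speeds = speeds * (target_mm / float((speeds * bout).sum()))
    rest = max(0.0, np.floor((duration_s - n_bouts * bout) / n_bouts / dt) * dt)
    segs: list[tuple[float, float]] = []
    for v in speeds:
        if rest > 0:
            segs.append((rest, 0.0))
        segs.append((float(bout), float(v)))
    rem = duration_s - sum(d for d, _ in segs)
    if rem >= dt:
        segs.append((rem, 0.0))
    return segs


def _swim_arm(cfg: dict, rng) -> pd.DataFrame:
    sc = cfg["swim"]
    duration_s = sc["duration_min"] * 60.0
    swim_cfg = swim.SwimConfig()
    rows = []
    for geno in GENOTYPES:
        for mg in MICROGLIA:
            mean = sc[f"distance_mm_{geno}"]
            if mg == "depleted" and geno == "kd":
                mean *= sc["depletion_distance_factor"]
            for larva in range(sc["n_larvae"]):
                target = float(max(20.0, rng.normal(mean, sc["distance_sd_mm"])))
                segs = _swim_segments(rng, duration_s, target, sc["dt_s"])
                traj = synthdata.gen_trajectory(
                    segs, dt_s=sc["dt_s"], seed=int(rng.integers(2**31 - 1))
                )
                s = swim.summarize_trajectory(traj, swim_cfg)
                rows.append(
                    {
                        "genotype": geno, "microglia": mg, "larva": larva,
                        "target_distance_mm": target,
                        **{f"{k}_{'mm' if k == 'total_distance' else 's'}": v
                           for k, v in s.as_dict().items()},
                    }
                )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# orchestration
# ---------------------------------------------------------------------------

#: (report table, metric column) of the four primary endpoints
PRIMARY_ENDPOINTS = [
    ("morphology", "amoeboid_fraction_pct"),
    ("calcium", "events_per_min"),
    ("lfp", "events_per_min"),
    ("swim", "total_distance_mm"),
]


def run_synthetic_experiment(
    config: dict | None = None,
    seed: int = 0,
    out_dir: str | Path | None = None,
) -> ExperimentReport:
    """Generate, quantify and compare the full synthetic study."""
    cfg = validate_config(config or {})
    sa = cfg["stats"]

    tables = {
        "morphology": _morphology_arm(cfg, np.random.default_rng([seed, 1])),
        "calcium": _calcium_arm(cfg, np.random.default_rng([seed, 2])),
        "lfp": _lfp_arm(cfg, np.random.default_rng([seed, 3])),
        "swim": _swim_arm(cfg, np.random.default_rng([seed, 4])),
    }

    comp_rows = []
    for table, metric in PRIMARY_ENDPOINTS:
        df = tables[table]
        present = df[df["microglia"] == "present"]
        a = present.loc[present["genotype"] == "wt", metric].to_numpy()
        b = present.loc[present["genotype"] == "kd", metric].to_numpy()
        cmp_ = compare_two_groups(
            a, b,
            normality_alpha=sa["normality_alpha"],
            variance_alpha=sa["variance_alpha"],
            metric=f"{table}:{metric}",
            labels=("wt", "kd"),
        )
        comp_rows.append(cmp_.as_row())
    comparisons = pd.DataFrame(comp_rows)

    anova = {}
    for table, metric in PRIMARY_ENDPOINTS[1:]:  # 2×2 designs only
        res = compare_factorial(
            tables[table], value=metric, factor_a="genotype", factor_b="microglia",
            metric=f"{table}:{metric}",
        )
        anova[table] = res.anova

    thresholds = {
        "classifier": classify.DEFAULT_RULE.__dict__,
        "calcium_dff_threshold": 0.04,
        "lfp_amplitude_mv": -0.3,
        "lfp_min_duration_ms": 100.0,
        "lfp_bandpass_hz": [cfg["lfp"]["hp_hz"], cfg["lfp"]["lp_hz"]],
        "swim_thresholds_mm_s": [
            swim.SwimConfig().motion_floor,
            swim.SwimConfig().inactive_threshold,
            swim.SwimConfig().high_threshold,
        ],
    }
    for k, v in thresholds.items():
        log.info("threshold used: %s = %s", k, v)

    report = ExperimentReport(
        larva_tables=tables,
        comparisons=comparisons,
        anova=anova,
        thresholds=thresholds,
        config=cfg,
        seed=seed,
    )
    if out_dir is not None:
        report.write(out_dir)
    return report
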