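"""Reading and writing the pipeline's file formats.

Volumes travel as single-channel 3D TIFF with the voxel size stored in the
ImageJ-style metadata (spacing + x/y resolution), ground truths as JSON
sidecars, and traces/trajectories as headed CSV:

* fluorescence: ``frame,intensity`` (optionally ``t_s``)
* LFP: ``t_s,mV``
* trajectory: ``t_s,x_mm,y_mm``
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile

from .caevents import FluorescenceTrace
from .lfpevents import LfpRecording
from .volume import LabeledVolume


def write_volume(path: str | Path, vol: LabeledVolume) -> None:
    z, y, x = vol.voxel_size
    tifffile.imwrite(
        str(path),
        vol.voxels.astype(np.uint16),
        imagej=True,
        resolution=(1.0 / x, 1.0 / y),
        metadata={"spacing": z, "unit": "um", "axes": "ZYX"},
    )


def read_volume(path: str | Path, voxel_size=None) -> LabeledVolume:
    """Read a 3D TIFF; ``voxel_size`` overrides metadata when given."""
    with tifffile.TiffFile(str(path)) as tf:
        data = tf.asarray()
        if voxel_size is None:
            z = 1.0
            if tf.imagej_metadata and "spacing" in tf.imagej_metadata:
                z = float(tf.imagej_metadata["spacing"])
            page = tf.pages[0]
            xres = page.tags.get("XResolution")
            yres = page.tags.get("YResolution")

            def _res(tag):
                if tag is None:
                    return 1.0
                num, den = tag.value
                return den / num if num else 1.0

            voxel_size = (z, _res(yres), _res(xres))
    if data.ndim == 2:
        data = data[None]
    return LabeledVolume(data, tuple(voxel_size))


def write_truth(path: str | Path, truth) -> None:
    with open(path, "w") as fh:
        json.dump(dataclasses.asdict(truth), fh, indent=2, sort_keys=True)


def write_trace(path: str | Path, trace: FluorescenceTrace) -> None:
    pd.DataFrame(
        {"frame": np.arange(trace.n_frames), "t_s": trace.frame_times,
         "intensity": trace.raw}
    ).to_csv(path, index=False)


def read_trace(path: str | Path) -> FluorescenceTrace:
    df = pd.read_csv(path)
    if "intensity" not in df.columns:
        raise ValueError("trace CSV needs an 'intensity' column")
    times = df["t_s"] if "t_s" in df.columns else df.get("frame", pd.RangeIndex(len(df)))
    return FluorescenceTrace(frame_times=np.asarray(times, float),
                             raw=df["intensity"].to_numpy(float))


def write_lfp(path: str | Path, rec: LfpRecording) -> None:
    t = np.arange(rec.samples.size) * rec.sampling_interval
    pd.DataFrame({"t_s": t, "mV": rec.samples}).to_csv(path, index=False)


def read_lfp(path: str | Path, sampling_interval: float | None = None) -> LfpRecording:
    df = pd.read_csv(path)
    if "mV" not in df.columns:
        raise ValueError("LFP CSV needs a 'mV' column")
    if sampling_interval is None:
        if "t_s" not in df.columns:
            raise ValueError("declare sampling_interval or provide a 't_s' column")
        sampling_interval = float(np.median(np.diff(df["t_s"].to_numpy(float))))
    return LfpRecording(df["mV"].to_numpy(float), sampling_interval)


def read_trajectory(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path)
    missing = {"t_s", "x_mm", "y_mm"} - set(df.columns)
    if missing:
        raise ValueError(f"trajectory CSV lacks columns: {sorted(missing)}")
    return df
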