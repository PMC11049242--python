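"""Labeled 3D volumes with physical voxel sizes.

The substrate of all morphometric operations: an integer voxel grid in
(z, y, x) order where 0 is background and each positive integer labels one
cell, together with the physical voxel size in micrometres.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np


@dataclass
class LabeledVolume:
    """A 3D label image with physical voxel sizes.

    Parameters
    ----------
    voxels
        3D integer array, ``0`` background, ``k > 0`` the id of one cell.
    voxel_size
        Physical voxel extent ``(z, y, x)`` in µm; all entries positive.
    """

    voxels: np.ndarray
    voxel_size: tuple[float, float, float] = (1.0, 1.0, 1.0)

    def __post_init__(self) -> None:
        self.voxels = np.asarray(self.voxels)
        if self.voxels.ndim != 3:
            raise ValueError("voxels must be a 3D array")
        vs = tuple(float(v) for v in self.voxel_size)
        if len(vs) != 3 or any(v <= 0 for v in vs):
            raise ValueError("voxel_size must be three positive values (z, y, x)")
        self.voxel_size = vs

    @property
    def voxel_volume(self) -> float:
        """Volume of one voxel in µm³."""
        z, y, x = self.voxel_size
        return z * y * x

    @property
    def cell_ids(self) -> np.ndarray:
        """Sorted array of cell ids present in the volume."""
        ids = np.unique(self.voxels)
        return ids[ids > 0]

    def mask(self, cell_id: int) -> np.ndarray:
        """Boolean mask of one cell; raises ``KeyError`` for absent ids."""
        m = self.voxels == cell_id
        if not m.any():
            raise KeyError(f"cell id {cell_id} not present in volume")
        return m
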