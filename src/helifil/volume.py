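"""Density volumes and segment stacks, with MRC2014 I/O (via gemmi).

Array conventions: volumes are cubic numpy arrays indexed [z, y, x]
with the helix axis along z through the box centre; segment images are
indexed [row, col] = [z, x] (the filament axis runs along image rows).
On disk, volumes and stacks are MRC2014 mode-2 maps with the voxel
size carried in the cell header; per-segment metadata is a plain-text
tab-separated table.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import gemmi
import numpy as np
import pandas as pd

__all__ = ["DensityVolume", "SegmentStack", "META_COLUMNS"]


def _write_mrc(data: np.ndarray, voxel_size_A: float, path: str | Path) -> None:
    arr = np.ascontiguousarray(np.asarray(data, dtype=np.float32).transpose(2, 1, 0))
    grid = gemmi.FloatGrid(arr)
    nz, ny, nx = data.shape
    grid.set_unit_cell(
        gemmi.UnitCell(nx * voxel_size_A, ny * voxel_size_A, nz * voxel_size_A, 90, 90, 90)
    )
    m = gemmi.Ccp4Map()
    m.grid = grid
    m.update_ccp4_header(2, True)  # mode 2 (float32), refresh statistics
    m.write_ccp4_map(str(path))


def _read_mrc(path: str | Path) -> tuple[np.ndarray, float]:
    m = gemmi.read_ccp4_map(str(path))
    data = np.array(m.grid.array, dtype=np.float32).transpose(2, 1, 0)
    spacing = m.grid.spacing
    return data, float(spacing[0])


@dataclass
class DensityVolume:
    """Cubic voxel grid with a physical voxel size in Angstrom."""

    data: np.ndarray
    voxel_size_A: float
    origin: np.ndarray = field(default_factory=lambda: np.zeros(3))

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=np.float32)
        if self.voxel_size_A <= 0:
            raise ValueError("voxel_size_A must be positive")
        if not np.all(np.isfinite(self.data)):
            raise ValueError("volume contains non-finite values")

    @property
    def shape(self) -> tuple[int, ...]:
        return self.data.shape

    def copy(self) -> "DensityVolume":
        return DensityVolume(self.data.copy(), self.voxel_size_A, np.array(self.origin))

    def write_mrc(self, path: str | Path) -> None:
        _write_mrc(self.data, self.voxel_size_A, path)

    @classmethod
    def read_mrc(cls, path: str | Path) -> "DensityVolume":
        data, vox = _read_mrc(path)
        return cls(data, vox)


META_COLUMNS = [
    "filament_id",
    "azimuth_deg",
    "tilt_deg",
    "inplane_deg",
    "shift_x_px",
    "shift_z_px",
    "defocus_A",
    "class_label",
]


@dataclass
class SegmentStack:
    """Boxed filament segments plus per-segment ground-truth/CTF metadata.

    ``images`` is (n, box, box); ``meta`` has one row per image with the
    columns in :data:`META_COLUMNS`.  ``ctf_flipped`` records whether the
    images have been multiplied by their CTF once (and hence carry CTF^2
    signal weighting that back-projection must divide out).
    """

    images: np.ndarray
    meta: pd.DataFrame
    pixel_size_A: float
    ctf_flipped: bool = False

    def __post_init__(self) -> None:
        self.images = np.asarray(self.images, dtype=np.float32)
        if self.images.ndim != 3 or self.images.shape[1] != self.images.shape[2]:
            raise ValueError("images must be (n, box, box)")
        if len(self.meta) != len(self.images):
            raise ValueError(
                f"metadata length {len(self.meta)} != image count {len(self.images)}"
            )
        if self.pixel_size_A <= 0:
            raise ValueError("pixel_size_A must be positive")

    def __len__(self) -> int:
        return len(self.images)

    @property
    def box_px(self) -> int:
        return self.images.shape[1]

    def subset(self, idx) -> "SegmentStack":
        idx = np.asarray(idx)
        return SegmentStack(
            self.images[idx],
            self.meta.iloc[idx].reset_index(drop=True),
            self.pixel_size_A,
            self.ctf_flipped,
        )

    def write(self, mrc_path: str | Path, meta_path: str | Path) -> None:
        _write_mrc(self.images, self.pixel_size_A, mrc_path)
        self.meta.to_csv(meta_path, sep="\t", index=False)

    @classmethod
    def read(cls, mrc_path: str | Path, meta_path: str | Path, ctf_flipped: bool = False) -> "SegmentStack":
        data, vox = _read_mrc(mrc_path)
        meta = pd.read_csv(meta_path, sep="\t")
        return cls(data, meta, vox, ctf_flipped)
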