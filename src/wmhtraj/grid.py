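"""Regular voxel grids with physical extents.

Phantoms are generated pre-aligned: both the structural and the diffusion grid
cover the same physical field of view and differ only in voxel size, so
resampling between them is a pure grid operation (no registration).
Voxel indices are 0-based; the center of voxel ``i`` along an axis with voxel
size ``v`` sits at physical coordinate ``(i + 0.5) * v``.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np


@dataclass(frozen=True)
class Grid:
    shape: tuple[int, int, int]
    voxel_mm: tuple[float, float, float]

    def __post_init__(self) -> None:
        if len(self.shape) != 3 or any(int(s) <= 0 for s in self.shape):
            raise ValueError(f"grid shape must be 3 positive integers, got {self.shape}")
        if len(self.voxel_mm) != 3 or any(v <= 0 for v in self.voxel_mm):
            raise ValueError(f"voxel sizes must be positive, got {self.voxel_mm}")

    @property
    def extent_mm(self) -> tuple[float, float, float]:
        return tuple(s * v for s, v in zip(self.shape, self.voxel_mm))

    @property
    def voxel_volume_mm3(self) -> float:
        return float(np.prod(self.voxel_mm))

    def centers_mm(self, axis: int) -> np.ndarray:
        """Physical coordinates of voxel centers along one axis."""
        v = self.voxel_mm[axis]
        return (np.arange(self.shape[axis]) + 0.5) * v

    def same_extent(self, other: "Grid", tol_mm: float = 1e-6) -> bool:
        return all(
            abs(a - b) <= tol_mm for a, b in zip(self.extent_mm, other.extent_mm)
        )
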