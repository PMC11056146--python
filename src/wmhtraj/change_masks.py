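"""Four-class longitudinal change masks and structural-space volumetrics.

The four classes follow the two-timepoint intersection logic: stable NAWM is
NAWM at both visits, stable WMH is WMH at both, progressing WMH was NAWM and
became WMH, regressing WMH was WMH and became NAWM. Voxels in none of the
intersections (e.g. WMH that became stroke) belong to no class. Small
clusters (< 5 structural voxels by default, 26-connectivity) are removed
before resampling to the quantitative-map grid but never before the
structural-space volume calculation.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

from wmhtraj.grid import Grid

CLASS_NAMES = ("stable_nawm", "stable_wmh", "progressing_wmh", "regressing_wmh")


@dataclass
class FourClassMasks:
    stable_nawm: np.ndarray
    stable_wmh: np.ndarray
    progressing_wmh: np.ndarray
    regressing_wmh: np.ndarray
    provenance: dict = field(default_factory=dict)

    def as_dict(self) -> dict[str, np.ndarray]:
        return {name: getattr(self, name) for name in CLASS_NAMES}

    def map_masks(self, fn) -> "FourClassMasks":
        return FourClassMasks(
            **{name: fn(getattr(self, name)) for name in CLASS_NAMES},
            provenance=dict(self.provenance),
        )


def change_classes(
    nawm_bl: np.ndarray,
    wmh_bl: np.ndarray,
    nawm_fu: np.ndarray,
    wmh_fu: np.ndarray,
) -> FourClassMasks:
    """Voxelwise intersection logic for the four longitudinal classes."""
    masks = [np.asarray(m, dtype=bool) for m in (nawm_bl, wmh_bl, nawm_fu, wmh_fu)]
    nawm_bl, wmh_bl, nawm_fu, wmh_fu = masks
    if len({m.shape for m in masks}) != 1:
        raise ValueError("all masks must be on one grid")
    if (nawm_bl & wmh_bl).any() or (nawm_fu & wmh_fu).any():
        raise ValueError("NAWM and WMH overlap within a timepoint")
    return FourClassMasks(
        stable_nawm=nawm_bl & nawm_fu,
        stable_wmh=wmh_bl & wmh_fu,
        progressing_wmh=nawm_bl & wmh_fu,
        regressing_wmh=wmh_bl & nawm_fu,
        provenance={"op": "change_classes"},
    )


def _structure(connectivity: int) -> np.ndarray:
    if connectivity == 26:
        return ndimage.generate_binary_structure(3, 3)
    if connectivity == 6:
        return ndimage.generate_binary_structure(3, 1)
    raise ValueError("connectivity must be 6 or 26")


def filter_small_clusters(
    mask: np.ndarray, min_size: int = 5, connectivity: int = 26
) -> np.ndarray:
    """Remove connected components with fewer than ``min_size`` voxels."""
    mask = np.asarray(mask, dtype=bool)
    if min_size <= 1:
        return mask.copy()
    labeled, n = ndimage.label(mask, structure=_structure(connectivity))
    if n == 0:
        return mask.copy()
    counts = np.bincount(labeled.ravel())
    keep = counts >= min_size
    keep[0] = False
    return keep[labeled]


def resample_nn(
    mask: np.ndarray,
    src_grid: Grid,
    dst_grid: Grid,
) -> np.ndarray:
    """Nearest-neighbor resampling between grids sharing a field of view.

    Each destination voxel takes the value of the source voxel whose center is
    nearest to the destination voxel center; ties break toward the lower
    index. Binary input yields binary output.
    """
    mask = np.asarray(mask)
    if mask.shape != tuple(src_grid.shape):
        raise ValueError("mask shape does not match the source grid")
    for a, b in zip(src_grid.extent_mm, dst_grid.extent_mm):
        if abs(a - b) > max(src_grid.voxel_mm + dst_grid.voxel_mm):
            raise ValueError("source and destination fields of view do not overlap")
    idx = []
    for ax in range(3):
        centers = dst_grid.centers_mm(ax)
        coord = centers / src_grid.voxel_mm[ax] - 0.5
        j = np.ceil(coord - 0.5).astype(int)
        idx.append(np.clip(j, 0, src_grid.shape[ax] - 1))
    return mask[np.ix_(*idx)]


def class_volumes(masks: FourClassMasks, voxel_mm: tuple[float, float, float]) -> dict[str, float]:
    """Per-class volumes in mL from pre-filter structural-grid masks."""
    vv = float(np.prod(voxel_mm))
    return {
        name: float(getattr(masks, name).sum()) * vv / 1000.0 for name in CLASS_NAMES
    }
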