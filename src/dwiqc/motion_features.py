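"""Per-volume geometric features and the inter-volume motion trace.

The centre of mass (COM) is the unweighted centroid of the binary mask
voxels mapped through the affine — invariant to diffusion contrast.
FOV-boundary contact is evaluated on all six faces of the grid.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from dwiqc.io_bridge import DiffusionSeries, MaskSeries

__all__ = ["VolumeFeatures", "MotionTrace", "compute_volume_features",
           "compute_all_features", "inter_volume_l2"]


@dataclass
class VolumeFeatures:
    """Geometry and intensity statistics of one volume, within its mask."""

    index: int
    b_value: float
    mask_voxels: int
    brain_volume: float              # mm³ = voxel count × voxel volume
    com_world: np.ndarray            # (3,) mm; NaN when mask empty
    boundary_fraction: float         # in [0, 1]
    slice_mask_counts: np.ndarray    # per-slice in-mask voxel counts
    slice_mean_intensities: np.ndarray  # per-slice mean, NaN where count 0
    volume_mean_intensity: float

    @property
    def empty(self) -> bool:
        return self.mask_voxels == 0


@dataclass
class MotionTrace:
    """Consecutive-volume COM displacements in mm.

    ``l2_mm`` has length t-1; pairs touching an empty-mask volume are
    NaN ("missing").  ``mean_l2_mm`` averages the defined entries.
    """

    l2_mm: np.ndarray
    mean_l2_mm: float = field(init=False)

    def __post_init__(self) -> None:
        self.l2_mm = np.asarray(self.l2_mm, dtype=float)
        defined = self.l2_mm[~np.isnan(self.l2_mm)]
        self.mean_l2_mm = float(defined.mean()) if defined.size else float("nan")

    @property
    def l2_cm(self) -> np.ndarray:
        """The trace in cm, for human-readable summaries."""
        return self.l2_mm / 10.0


def _voxels_to_world(affine: np.ndarray, ijk: np.ndarray) -> np.ndarray:
    """Map (n, 3) voxel indices to world mm through the affine."""
    return ijk @ affine[:3, :3].T + affine[:3, 3]


def compute_volume_features(series: DiffusionSeries, masks: MaskSeries,
                            index: int) -> VolumeFeatures:
    """Extract mask geometry and in-mask intensity statistics for one volume.

    Raises ``ValueError`` ("empty segmentation for volume") when the mask
    has no voxels; callers that must survive empty masks should use
    :func:`compute_all_features`.
    """
    if not (0 <= index < series.n_volumes):
        raise IndexError(f"volume index {index} out of range")
    mask = masks.volume(index).astype(bool)
    n = int(mask.sum())
    if n == 0:
        raise ValueError(f"empty segmentation for volume {index}")

    vol = series.volume(index).astype(float)
    ijk = np.argwhere(mask)
    com = _voxels_to_world(series.affine, ijk.astype(float)).mean(axis=0)

    shape = np.array(series.grid)
    on_face = np.any((ijk == 0) | (ijk == shape - 1), axis=1)
    boundary_fraction = float(on_face.sum()) / n

    ax = series.slice_axis
    n_slices = series.grid[ax]
    other = tuple(a for a in range(3) if a != ax)
    counts = mask.sum(axis=other)
    sums = np.where(mask, vol, 0.0).sum(axis=other)
    with np.errstate(invalid="ignore", divide="ignore"):
        means = np.where(counts > 0, sums / np.maximum(counts, 1), np.nan)

    return VolumeFeatures(
        index=index,
        b_value=float(series.btable.bvals[index]),
        mask_voxels=n,
        brain_volume=n * series.voxel_volume,
        com_world=com,
        boundary_fraction=boundary_fraction,
        slice_mask_counts=counts.astype(int),
        slice_mean_intensities=means,
        volume_mean_intensity=float(vol[mask].mean()),
    )


def _empty_features(series: DiffusionSeries, index: int) -> VolumeFeatures:
    n_slices = series.grid[series.slice_axis]
    return VolumeFeatures(
        index=index,
        b_value=float(series.btable.bvals[index]),
        mask_voxels=0,
        brain_volume=0.0,
        com_world=np.full(3, np.nan),
        boundary_fraction=0.0,
        slice_mask_counts=np.zeros(n_slices, dtype=int),
        slice_mean_intensities=np.full(n_slices, np.nan),
        volume_mean_intensity=float("nan"),
    )


def compute_all_features(series: DiffusionSeries,
                         masks: MaskSeries) -> list[VolumeFeatures]:
    """Features for every volume; empty masks yield placeholder records."""
    if masks.data.shape != series.data.shape:
        raise ValueError("mask/series geometry mismatch")
    out = []
    for t in range(series.n_volumes):
        try:
            out.append(compute_volume_features(series, masks, t))
        except ValueError:
            out.append(_empty_features(series, t))
    return out


def inter_volume_l2(features: list[VolumeFeatures]) -> MotionTrace:
    """Euclidean COM displacement between consecutive volumes (mm)."""
    usable = sum(1 for f in features if not f.empty)
    if usable < 2:
        raise ValueError("trace undefined: fewer than 2 usable volumes")
    l2 = np.full(len(features) - 1, np.nan)
    for i in range(len(features) - 1):
        a, b = features[i], features[i + 1]
        if a.empty or b.empty:
            continue
        l2[i] = float(np.linalg.norm(b.com_world - a.com_world))
    return MotionTrace(l2_mm=l2)
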