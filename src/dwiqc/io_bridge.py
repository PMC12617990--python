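"""On-disk formats and core domain types.

Reads/writes 4D NIfTI series, FSL-dialect bval/bvec tables, JSON QC
reports, TSV re-acquisition manifests and YAML configuration.

Conventions
-----------
* Voxel indices are 0-based; world coordinates (mm) are produced by the
  affine.
* b-vector signs are preserved as read; no antipodal canonicalisation.
* The through-plane (slice) axis defaults to array axis 2 and can be
  overridden.
* Probabilistic masks are binarised at 0.5.
"""

from __future__ import annotations

import dataclasses
import json
import os
from dataclasses import dataclass, field
from typing import Sequence

import nibabel as nib
import numpy as np
import yaml

__all__ = [
    "BTable",
    "DiffusionSeries",
    "MaskSeries",
    "QCConfig",
    "read_series",
    "read_masks",
    "write_series",
    "write_masks",
    "write_reacq_list",
    "read_reacq_list",
    "write_report",
    "read_report",
    "load_config",
    "save_config",
    "write_btable",
]

#: tolerance for accepting/renormalising non-unit b-vectors
BVEC_NORM_TOL = 1e-3


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class BTable:
    """Ordered diffusion table: b-values (s/mm²) and unit directions.

    ``bvals`` has shape (t,); ``bvecs`` has shape (t, 3).  Entries with
    b = 0 carry the zero vector; entries with b > 0 carry unit vectors.
    """

    bvals: np.ndarray
    bvecs: np.ndarray

    def __post_init__(self) -> None:
        bvals = np.asarray(self.bvals, dtype=float)
        bvecs = np.asarray(self.bvecs, dtype=float)
        if bvals.ndim != 1:
            raise ValueError("bvals must be 1-D")
        if bvecs.shape != (bvals.size, 3):
            raise ValueError("bvecs must have shape (len(bvals), 3)")
        if np.any(bvals < 0):
            raise ValueError("b-values must be non-negative")
        norms = np.linalg.norm(bvecs, axis=1)
        nz = bvals > 0
        bad = nz & (np.abs(norms - 1.0) > BVEC_NORM_TOL)
        if np.any(bad):
            raise ValueError(
                f"non-unit b-vector(s) at volume(s) {np.flatnonzero(bad).tolist()}"
            )
        # renormalise small deviations; force zero vector at b=0
        bvecs = bvecs.copy()
        with np.errstate(invalid="ignore"):
            bvecs[nz] = bvecs[nz] / norms[nz, None]
        bvecs[~nz] = 0.0
        object.__setattr__(self, "bvals", bvals)
        object.__setattr__(self, "bvecs", bvecs)

    def __len__(self) -> int:
        return int(self.bvals.size)

    def subset(self, indices: Sequence[int]) -> "BTable":
        idx = np.asarray(indices, dtype=int)
        return BTable(self.bvals[idx], self.bvecs[idx])

    @property
    def unique_bvals(self) -> np.ndarray:
        return np.unique(self.bvals)


@dataclass
class DiffusionSeries:
    """A 4D diffusion-weighted series with geometry and b-table."""

    data: np.ndarray
    affine: np.ndarray
    btable: BTable
    slice_axis: int = 2

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        if self.data.ndim != 4:
            raise ValueError("expects 4D series")
        self.affine = np.asarray(self.affine, dtype=float)
        if self.affine.shape != (4, 4):
            raise ValueError("affine must be 4x4")
        if abs(np.linalg.det(self.affine[:3, :3])) < 1e-12:
            raise ValueError("affine is singular")
        if self.data.shape[3] != len(self.btable):
            raise ValueError("btable/series length mismatch")
        if self.slice_axis not in (0, 1, 2):
            raise ValueError("slice_axis must be 0, 1 or 2")

    @property
    def n_volumes(self) -> int:
        return int(self.data.shape[3])

    @property
    def grid(self) -> tuple[int, int, int]:
        return tuple(int(s) for s in self.data.shape[:3])

    @property
    def voxel_size(self) -> np.ndarray:
        """Voxel edge lengths in mm, derived from the affine."""
        return np.linalg.norm(self.affine[:3, :3], axis=0)

    @property
    def voxel_volume(self) -> float:
        """Volume of one voxel in mm³."""
        return float(abs(np.linalg.det(self.affine[:3, :3])))

    def volume(self, index: int) -> np.ndarray:
        return self.data[..., index]


@dataclass
class MaskSeries:
    """Per-volume binary brain masks on the same grid as the series."""

    data: np.ndarray

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        if self.data.ndim != 4:
            raise ValueError("expects 4D mask series")
        vals = np.unique(self.data)
        if not np.all(np.isin(vals, (0, 1))):
            raise ValueError("mask values must be 0/1")
        self.data = self.data.astype(np.uint8)

    @property
    def n_volumes(self) -> int:
        return int(self.data.shape[3])

    def volume(self, index: int) -> np.ndarray:
        return self.data[..., index]


@dataclass
class QCConfig:
    """Tunable parameters of the QC rules.

    ``alpha``, ``f_offset`` and ``adc_ref`` parametrise the b-value
    dependent volume-change threshold alpha*(1 - exp(-b*adc_ref)) +
    f_offset; ``slice_deficit`` is the relative slice-intensity deficit
    above which a slice counts as dropped out.
    """

    alpha: float = 0.3
    f_offset: float = 0.02
    adc_ref: float = 0.002
    slice_deficit: float = 0.35
    min_mask_voxels_per_slice: int = 5
    boundary_fraction_tol: float = 0.0
    max_iterations: int = 2
    reference_volume_policy: str = "first"

    def __post_init__(self) -> None:
        if self.alpha < 0:
            raise ValueError("alpha must be >= 0")
        if not (0 <= self.f_offset < 1):
            raise ValueError("f_offset must be in [0, 1)")
        if self.adc_ref <= 0:
            raise ValueError("adc_ref must be > 0")
        if not (0 < self.slice_deficit < 1):
            raise ValueError("slice_deficit must be in (0, 1)")
        if self.max_iterations < 0:
            raise ValueError("max_iterations must be >= 0")
        if self.reference_volume_policy not in ("first", "first_clean_b0"):
            raise ValueError(
                "reference_volume_policy must be 'first' or 'first_clean_b0'"
            )

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "QCConfig":
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(d) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**d)


# ---------------------------------------------------------------------------
# bval/bvec (FSL dialect)
# ---------------------------------------------------------------------------

def read_btable(bval_path: str | os.PathLike, bvec_path: str | os.PathLike) -> BTable:
    """Read an FSL-style bval/bvec pair into a validated :class:`BTable`."""
    bvals = np.atleast_1d(np.loadtxt(bval_path, dtype=float, ndmin=1))
    if bvals.ndim != 1:
        raise ValueError("bval file must contain a single row")
    bvecs = np.atleast_2d(np.loadtxt(bvec_path, dtype=float))
    if bvecs.shape == (3, bvals.size):
        bvecs = bvecs.T
    elif bvecs.shape != (bvals.size, 3):
        raise ValueError("bvec file must contain 3 rows matching the bval count")
    return BTable(bvals, bvecs)


def write_btable(btable: BTable, bval_path: str | os.PathLike,
                 bvec_path: str | os.PathLike) -> None:
    """Write a :class:`BTable` as an FSL-style bval/bvec pair."""
    with open(bval_path, "w") as fh:
        fh.write(" ".join(repr(float(b)) for b in btable.bvals) + "\n")
    with open(bvec_path, "w") as fh:
        for row in btable.bvecs.T:  # three rows: x, y, z components
            fh.write(" ".join(repr(float(v)) for v in row) + "\n")


# ---------------------------------------------------------------------------
# NIfTI series / masks
# ---------------------------------------------------------------------------

def read_series(dwi_path: str | os.PathLike, bval_path: str | os.PathLike,
                bvec_path: str | os.PathLike, slice_axis: int = 2) -> DiffusionSeries:
    """Load a 4D NIfTI plus bval/bvec into a validated series.

    Raises ``ValueError`` with "expects 4D series" for 3D input and
    "btable/series length mismatch" when table and series disagree.
    """
    img = nib.load(os.fspath(dwi_path))
    if img.ndim != 4:
        raise ValueError("expects 4D series")
    data = np.asarray(img.dataobj, dtype=np.float64)
    if np.any(data < 0):
        raise ValueError("series intensities must be non-negative")
    btable = read_btable(bval_path, bvec_path)
    if len(btable) != data.shape[3]:
        raise ValueError("btable/series length mismatch")
    return DiffusionSeries(data=data, affine=img.affine, btable=btable,
                           slice_axis=slice_axis)


def write_series(series: DiffusionSeries, dwi_path: str | os.PathLike,
                 bval_path: str | os.PathLike | None = None,
                 bvec_path: str | os.PathLike | None = None) -> None:
    """Write the series back to NIfTI (and optionally its b-table)."""
    img = nib.Nifti1Image(series.data, series.affine)
    img.header.set_data_dtype(np.float64)
    nib.save(img, os.fspath(dwi_path))
    if bval_path is not None and bvec_path is not None:
        write_btable(series.btable, bval_path, bvec_path)


def read_masks(mask_path: str | os.PathLike, series: DiffusionSeries) -> MaskSeries:
    """Load a 4D mask NIfTI aligned to ``series``; binarise at 0.5."""
    img = nib.load(os.fspath(mask_path))
    if img.ndim != 4:
        raise ValueError("mask/series geometry mismatch")
    data = np.asarray(img.dataobj, dtype=np.float64)
    if data.shape != series.data.shape:
        raise ValueError("mask/series geometry mismatch")
    return MaskSeries(data=(data > 0.5).astype(np.uint8))


def write_masks(masks: MaskSeries, affine: np.ndarray,
                mask_path: str | os.PathLike) -> None:
    img = nib.Nifti1Image(masks.data.astype(np.uint8), np.asarray(affine))
    nib.save(img, os.fspath(mask_path))


# ---------------------------------------------------------------------------
# re-acquisition manifest
# ---------------------------------------------------------------------------

_MANIFEST_HEADER = "original_index\tb_value\tgx\tgy\tgz\tpriority_rank"


def write_reacq_list(plan, path: str | os.PathLike,
                     bval_path: str | os.PathLike | None = None,
                     bvec_path: str | os.PathLike | None = None) -> None:
    """Write a re-acquisition plan as a TSV manifest plus bval/bvec pair.

    The manifest has one row per planned volume in acquisition-priority
    order.  An empty plan produces a header-only manifest and empty
    bval/bvec files.
    """
    path = os.fspath(path)
    with open(path, "w") as fh:
        fh.write(_MANIFEST_HEADER + "\n")
        for rank, item in enumerate(plan.items, start=1):
            gx, gy, gz = (repr(float(v)) for v in item.direction)
            fh.write(f"{item.original_index}\t{item.b_value!r}\t"
                     f"{gx}\t{gy}\t{gz}\t{rank}\n")
    if bval_path is None:
        bval_path = os.path.splitext(path)[0] + ".bval"
    if bvec_path is None:
        bvec_path = os.path.splitext(path)[0] + ".bvec"
    if plan.items:
        bt = BTable(np.array([it.b_value for it in plan.items], dtype=float),
                    np.array([it.direction for it in plan.items], dtype=float))
        write_btable(bt, bval_path, bvec_path)
    else:
        open(bval_path, "w").close()
        open(bvec_path, "w").close()


def read_reacq_list(path: str | os.PathLike) -> list[dict]:
    """Read a TSV manifest back into a list of row dicts."""
    rows: list[dict] = []
    with open(path) as fh:
        header = fh.readline().strip().split("\t")
        if header != _MANIFEST_HEADER.split("\t"):
            raise ValueError("unrecognised manifest header")
        for line in fh:
            if not line.strip():
                continue
            idx, b, gx, gy, gz, rank = line.rstrip("\n").split("\t")
            rows.append({
                "original_index": int(idx),
                "b_value": float(b),
                "direction": (float(gx), float(gy), float(gz)),
                "priority_rank": int(rank),
            })
    return rows


# ---------------------------------------------------------------------------
# QC report (JSON)
# ---------------------------------------------------------------------------

def _jsonify(obj):
    if isinstance(obj, (np.floating, float)):
        v = float(obj)
        return None if np.isnan(v) else v
    if isinstance(obj, (np.integer, int)):
        return int(obj)
    if isinstance(obj, np.ndarray):
        return [_jsonify(v) for v in obj.tolist()]
    if isinstance(obj, (list, tuple)):
        return [_jsonify(v) for v in obj]
    if isinstance(obj, dict):
        return {k: _jsonify(v) for k, v in obj.items()}
    return obj


def write_report(report, path: str | os.PathLike) -> None:
    """Serialise a QC report to JSON (schema stable across runs)."""
    from dwiqc import __version__

    doc = {"software_version": __version__, **report.to_dict()}
    with open(os.fspath(path), "w") as fh:
        json.dump(_jsonify(doc), fh, indent=1, sort_keys=True)
        fh.write("\n")


def read_report(path: str | os.PathLike):
    """Deserialise a QC report written by :func:`write_report`."""
    from dwiqc.quality_control import QCReport

    with open(os.fspath(path)) as fh:
        doc = json.load(fh)
    doc.pop("software_version", None)
    return QCReport.from_dict(doc)


# ---------------------------------------------------------------------------
# configuration
# ---------------------------------------------------------------------------

def load_config(path: str | os.PathLike | None) -> QCConfig:
    """Load a YAML config file; ``None`` yields the defaults."""
    if path is None:
        return QCConfig()
    with open(os.fspath(path)) as fh:
        doc = yaml.safe_load(fh) or {}
    return QCConfig.from_dict(doc)


def save_config(config: QCConfig, path: str | os.PathLike) -> None:
    with open(os.fspath(path), "w") as fh:
        yaml.safe_dump(config.to_dict(), fh, sort_keys=True)
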