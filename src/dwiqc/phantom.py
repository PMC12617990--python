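"""Synthetic fetal-brain dMRI phantom with scripted artifact injection.

An ellipsoidal "brain" (biexponential perfusion + diffusion signal per
tissue class, with a high-diffusivity fluid rim of D = 0.002 mm²/s)
is replicated across a multi-b-value acquisition.  Artifacts — slice
dropout, inter-volume shifts, mask-volume drift mimicking segmentation
error, boundary cropping — are injected per volume, and Rician noise is
optionally added.  A ground-truth log records the realised artifact
magnitudes and the volumes expected to be flagged, evaluated with an
independent straight-line reimplementation of the QC rules so the truth
can serve as an oracle.

Determinism: identical config + seed yields bitwise identical output.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

from dwiqc.io_bridge import BTable, DiffusionSeries, MaskSeries, QCConfig

__all__ = ["TissueParams", "ArtifactSpec", "PhantomConfig", "VolumeTruth",
           "PhantomTruth", "make_phantom", "score_detection",
           "DetectionScore", "default_btable"]

#: per-shell diffusion weightings of the default protocol (s/mm²)
DEFAULT_SHELLS = (10.0, 50.0, 80.0, 200.0, 400.0, 600.0, 1000.0)


def default_btable() -> BTable:
    """One b=0 volume plus 7 shells × 3 orthogonal directions (22 volumes)."""
    bvals = [0.0]
    bvecs = [(0.0, 0.0, 0.0)]
    dirs = [(1.0, 0.0, 0.0), (0.0, 1.0, 0.0), (0.0, 0.0, 1.0)]
    for b in DEFAULT_SHELLS:
        for d in dirs:
            bvals.append(b)
            bvecs.append(d)
    return BTable(np.array(bvals), np.array(bvecs))


@dataclass(frozen=True)
class TissueParams:
    """Biexponential signal parameters of one tissue class."""

    S0: float
    ivim_f: float
    D: float        # mm²/s
    Dstar: float    # mm²/s

    def signal(self, b: float) -> float:
        return self.S0 * (self.ivim_f * math.exp(-b * self.Dstar)
                          + (1.0 - self.ivim_f) * math.exp(-b * self.D))


@dataclass(frozen=True)
class ArtifactSpec:
    """One injected artifact on one volume.

    kind ∈ {dropout_slices, com_shift, volume_drift, crop_shift}.
    Parameters by kind: ``slices`` + ``attenuation`` (dropout_slices),
    ``shift_mm`` (com_shift / crop_shift), ``rel_change`` (volume_drift).
    """

    kind: str
    volume: int
    slices: tuple[int, ...] = ()
    attenuation: float = 0.0
    shift_mm: tuple[float, float, float] = (0.0, 0.0, 0.0)
    rel_change: float = 0.0

    def __post_init__(self) -> None:
        if self.kind not in ("dropout_slices", "com_shift", "volume_drift",
                             "crop_shift"):
            raise ValueError(f"unknown artifact kind {self.kind!r}")
        if self.kind == "dropout_slices":
            if not self.slices:
                raise ValueError("dropout_slices requires a slice list")
            if not (0.0 <= self.attenuation < 1.0):
                raise ValueError("attenuation must be in [0, 1)")
        if self.kind == "volume_drift" and not (abs(self.rel_change) < 1.0):
            raise ValueError("|rel_change| must be < 1")


@dataclass
class PhantomConfig:
    """Full description of one synthetic acquisition.

    Default grid 64×64×35 at 3 mm isotropic (a 35-slice axial stack at
    desk scale); ``noise_sigma`` is Rician sigma relative to parenchyma
    S0 (0 disables noise; SNR = 1/noise_sigma).
    """

    seed: int
    grid: tuple[int, int, int] = (64, 64, 35)
    voxel_size: tuple[float, float, float] = (3.0, 3.0, 3.0)
    btable: BTable = field(default_factory=default_btable)
    brain_center_mm: tuple[float, float, float] | None = None
    brain_semiaxes_mm: tuple[float, float, float] = (60.0, 66.0, 39.0)
    csf_rim_mm: float = 6.0
    parenchyma: TissueParams = TissueParams(S0=100.0, ivim_f=0.1,
                                            D=0.0012, Dstar=0.05)
    csf: TissueParams = TissueParams(S0=180.0, ivim_f=0.0,
                                     D=0.002, Dstar=0.0)
    noise_sigma: float = 0.0
    artifacts: tuple[ArtifactSpec, ...] = ()
    slice_axis: int = 2

    def __post_init__(self) -> None:
        if self.seed is None:
            raise ValueError("seed is required")
        self.artifacts = tuple(self.artifacts)
        if any(s <= 0 for s in self.brain_semiaxes_mm):
            raise ValueError("semi-axes must be > 0")
        if self.noise_sigma < 0:
            raise ValueError("noise_sigma must be >= 0")
        for a in self.artifacts:
            if not (0 <= a.volume < len(self.btable)):
                raise ValueError(f"artifact targets volume {a.volume} "
                                 f"outside the series")
        fov = np.asarray(self.grid) * np.asarray(self.voxel_size)
        center = (np.asarray(self.brain_center_mm, dtype=float)
                  if self.brain_center_mm is not None else fov / 2.0)
        semi = np.asarray(self.brain_semiaxes_mm)
        wants_crop = any(a.kind == "crop_shift" for a in self.artifacts)
        if not wants_crop and (np.any(center - semi < 0)
                               or np.any(center + semi > fov)):
            raise ValueError("ellipsoid extends outside the grid "
                             "(add a crop_shift artifact if intended)")
        self._center_mm = center

    @property
    def affine(self) -> np.ndarray:
        aff = np.eye(4)
        aff[0, 0], aff[1, 1], aff[2, 2] = self.voxel_size
        return aff


@dataclass
class VolumeTruth:
    """Realised per-volume ground truth."""

    index: int
    artifacts: list[str]
    corrupted_slices: list[int]
    com_mm: tuple[float, float, float]
    mask_volume_mm3: float

    def to_dict(self) -> dict:
        return {"index": self.index, "artifacts": list(self.artifacts),
                "corrupted_slices": list(self.corrupted_slices),
                "com_mm": list(self.com_mm),
                "mask_volume_mm3": self.mask_volume_mm3}


@dataclass
class PhantomTruth:
    """Ground-truth log for scoring detections against the phantom."""

    volumes: list[VolumeTruth]
    expected_red: list[int]

    def to_dict(self) -> dict:
        return {"volumes": [v.to_dict() for v in self.volumes],
                "expected_red": list(self.expected_red)}

    @classmethod
    def from_dict(cls, d: dict) -> "PhantomTruth":
        vols = [VolumeTruth(index=v["index"], artifacts=list(v["artifacts"]),
                            corrupted_slices=list(v["corrupted_slices"]),
                            com_mm=tuple(v["com_mm"]),
                            mask_volume_mm3=v["mask_volume_mm3"])
                for v in d["volumes"]]
        return cls(volumes=vols, expected_red=list(d["expected_red"]))


# ---------------------------------------------------------------------------
# geometry helpers
# ---------------------------------------------------------------------------

def _ellipsoid_fields(config: PhantomConfig) -> tuple[np.ndarray, np.ndarray]:
    """Boolean support of the ellipsoid and of its fluid rim."""
    vx = np.asarray(config.voxel_size)
    axes = [(np.arange(n) * v) for n, v in zip(config.grid, vx)]
    x, y, z = np.meshgrid(*axes, indexing="ij")
    c = config._center_mm
    a = np.asarray(config.brain_semiaxes_mm)
    rho = np.sqrt(((x - c[0]) / a[0]) ** 2 + ((y - c[1]) / a[1]) ** 2
                  + ((z - c[2]) / a[2]) ** 2)
    inside = rho <= 1.0
    rho_rim = 1.0 - config.csf_rim_mm / float(min(a))
    rim = inside & (rho > rho_rim)
    return inside, rim


def _shift_clip(arr: np.ndarray, shift_vox: tuple[int, int, int]) -> np.ndarray:
    """Integer-voxel shift with zero fill (no wrap-around)."""
    out = np.zeros_like(arr)
    src, dst = [], []
    for axis, s in enumerate(shift_vox):
        n = arr.shape[axis]
        if abs(s) >= n:
            return out
        if s >= 0:
            dst.append(slice(s, n))
            src.append(slice(0, n - s))
        else:
            dst.append(slice(0, n + s))
            src.append(slice(-s, n))
    out[tuple(dst)] = arr[tuple(src)]
    return out


def _adjust_mask_count(mask: np.ndarray, target: int) -> np.ndarray:
    """Erode/dilate a binary mask to an exact voxel count, deterministically.

    Whole one-voxel layers are peeled/grown; the final partial layer is
    resolved in C-order (lexicographic) voxel order.
    """
    m = mask.copy()
    count = int(m.sum())
    if target <= 0:
        raise ValueError("target mask count must be positive")
    while count > target:
        er = ndimage.binary_erosion(m)
        layer = np.argwhere(m & ~er)
        if len(layer) == 0:
            raise ValueError("mask erosion exhausted before reaching target")
        if count - len(layer) >= target:
            m = er
            count -= len(layer)
        else:
            for ijk in layer[: count - target]:
                m[tuple(ijk)] = False
            count = target
    while count < target:
        dl = ndimage.binary_dilation(m)
        layer = np.argwhere(dl & ~m)
        if len(layer) == 0:
            raise ValueError("mask dilation saturated before reaching target")
        if count + len(layer) <= target:
            m = dl
            count += len(layer)
        else:
            for ijk in layer[: target - count]:
                m[tuple(ijk)] = True
            count = target
    return m


# ---------------------------------------------------------------------------
# independent (naive) rule evaluation for the truth log
# ---------------------------------------------------------------------------

def _naive_dropout(vol: np.ndarray, mask: np.ndarray, axis: int,
                   cfg: QCConfig) -> list[int]:
    inmask = vol[mask]
    vol_mean = inmask.mean()
    cut = (1.0 - cfg.slice_deficit) * vol_mean
    flagged = []
    for s in range(vol.shape[axis]):
        sl = [slice(None)] * 3
        sl[axis] = s
        msl = mask[tuple(sl)]
        n = int(msl.sum())
        if n < cfg.min_mask_voxels_per_slice:
            continue
        if vol[tuple(sl)][msl].mean() < cut:
            flagged.append(s)
    return flagged


def _naive_expected_red(data: np.ndarray, masks: np.ndarray, bvals: np.ndarray,
                        axis: int, cfg: QCConfig) -> tuple[list[int], dict]:
    """Straight-line re-evaluation of the three rules on noiseless data."""
    t = data.shape[3]
    ref_count = int(masks[..., 0].sum())
    red, slice_log = [], {}
    for i in range(t):
        mask = masks[..., i].astype(bool)
        n = int(mask.sum())
        if n == 0:
            red.append(i)
            slice_log[i] = []
            continue
        dropped = _naive_dropout(data[..., i], mask, axis, cfg)
        slice_log[i] = dropped
        thr = cfg.alpha * (1.0 - math.exp(-bvals[i] * cfg.adc_ref)) + cfg.f_offset
        vol_flag = abs(n - ref_count) / ref_count > thr
        ijk = np.argwhere(mask)
        shape = np.array(data.shape[:3])
        cropped = bool(np.any((ijk == 0) | (ijk == shape - 1)))
        if dropped or vol_flag or cropped:
            red.append(i)
    return red, slice_log


# ---------------------------------------------------------------------------
# generation
# ---------------------------------------------------------------------------

def make_phantom(config: PhantomConfig,
                 qc_config: QCConfig | None = None,
                 ) -> tuple[DiffusionSeries, MaskSeries, PhantomTruth]:
    """Generate the series, per-volume masks and the ground-truth log.

    ``qc_config`` parametrises the rule thresholds used to derive the
    expected red set (defaults used when omitted).
    """
    qc_config = qc_config or QCConfig()
    rng = np.random.default_rng(config.seed)
    inside, rim = _ellipsoid_fields(config)
    parench = inside & ~rim
    vx = np.asarray(config.voxel_size)
    voxel_volume = float(np.prod(vx))

    bvals = config.btable.bvals
    t = len(config.btable)
    by_volume: dict[int, list[ArtifactSpec]] = {}
    for a in config.artifacts:
        by_volume.setdefault(a.volume, []).append(a)

    data = np.zeros(config.grid + (t,), dtype=np.float64)
    mask_data = np.zeros(config.grid + (t,), dtype=np.uint8)

    for i in range(t):
        b = float(bvals[i])
        vol = np.zeros(config.grid, dtype=np.float64)
        vol[parench] = config.parenchyma.signal(b)
        vol[rim] = config.csf.signal(b)
        mask = inside.copy()

        for a in by_volume.get(i, ()):
            if a.kind in ("com_shift", "crop_shift"):
                shift_vox = tuple(int(v) for v in
                                  np.rint(np.asarray(a.shift_mm) / vx))
                vol = _shift_clip(vol, shift_vox)
                mask = _shift_clip(mask, shift_vox)
            elif a.kind == "volume_drift":
                target = int(round(inside.sum() * (1.0 + a.rel_change)))
                mask = _adjust_mask_count(mask, target)
            elif a.kind == "dropout_slices":
                sl = [slice(None)] * 3
                for s in a.slices:
                    sl[config.slice_axis] = s
                    vol[tuple(sl)] *= a.attenuation

        data[..., i] = vol
        mask_data[..., i] = mask.astype(np.uint8)

    expected_red, slice_log = _naive_expected_red(
        data, mask_data, bvals, config.slice_axis, qc_config)

    volumes = []
    for i in range(t):
        m = mask_data[..., i].astype(bool)
        if m.any():
            com = (np.argwhere(m).mean(axis=0) * vx).astype(float)
            com_mm = tuple(float(c) for c in com)
        else:
            com_mm = (float("nan"),) * 3
        volumes.append(VolumeTruth(
            index=i,
            artifacts=[a.kind for a in by_volume.get(i, ())],
            corrupted_slices=slice_log[i],
            com_mm=com_mm,
            mask_volume_mm3=float(m.sum()) * voxel_volume,
        ))
    truth = PhantomTruth(volumes=volumes, expected_red=expected_red)

    if config.noise_sigma > 0:
        sigma = config.noise_sigma * config.parenchyma.S0
        n1 = rng.normal(0.0, sigma, size=data.shape)
        n2 = rng.normal(0.0, sigma, size=data.shape)
        data = np.sqrt((data + n1) ** 2 + n2 ** 2)

    series = DiffusionSeries(data=data, affine=config.affine,
                             btable=config.btable,
                             slice_axis=config.slice_axis)
    return series, MaskSeries(data=mask_data), truth


# ---------------------------------------------------------------------------
# detection scoring
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class DetectionScore:
    """Volume-level confusion counts against the ground-truth red set."""

    tp: int
    fp: int
    tn: int
    fn: int

    @property
    def sensitivity(self) -> float:
        d = self.tp + self.fn
        return self.tp / d if d else float("nan")

    @property
    def specificity(self) -> float:
        d = self.tn + self.fp
        return self.tn / d if d else float("nan")

    @property
    def agreement(self) -> float:
        total = self.tp + self.fp + self.tn + self.fn
        return (self.tp + self.tn) / total if total else float("nan")


def score_detection(report, truth: PhantomTruth) -> DetectionScore:
    """2×2 volume-level counts of report verdicts vs. expected red set."""
    if len(report.verdicts) != len(truth.volumes):
        raise ValueError("report/truth length mismatch")
    expected = set(truth.expected_red)
    tp = fp = tn = fn = 0
    for v in report.verdicts:
        flagged = v.status == "red"
        if v.index in expected:
            tp += flagged
            fn += not flagged
        else:
            fp += flagged
            tn += not flagged
    return DetectionScore(tp=tp, fp=fp, tn=tn, fn=fn)
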