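"""Green/red volume classification and QC report assembly.

Three rules drive the verdict:

* dropout — a slice whose mean in-mask intensity falls more than
  ``slice_deficit`` (default 35%) below the in-mask volume mean;
* volume change — |V - V_ref| / V_ref exceeding the b-value dependent
  threshold alpha*(1 - exp(-b*adc_ref)) + f_offset;
* cropping — mask voxels touching the FOV boundary beyond tolerance.

Both intensity rules are ratio-based, so verdicts are invariant to
global positive intensity scaling.  Comparisons are strict: a deficit of
exactly ``slice_deficit`` or a change exactly at threshold is clean.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from dwiqc.io_bridge import DiffusionSeries, MaskSeries, QCConfig
from dwiqc.motion_features import (
    MotionTrace,
    VolumeFeatures,
    compute_all_features,
    compute_volume_features,
    inter_volume_l2,
)

__all__ = ["VolumeVerdict", "QCReport", "dynamic_threshold",
           "detect_dropout_slices", "classify_volume", "run_qc", "alpha_sweep"]


def dynamic_threshold(b_value: float, config: QCConfig) -> float:
    """b-value dependent relative volume-change threshold.

    ``alpha * (1 - exp(-b * adc_ref)) + f_offset`` — equals ``f_offset``
    at b=0, strictly increasing in b for alpha>0 and bounded above by
    ``alpha + f_offset``.
    """
    if b_value < 0:
        raise ValueError("b-value must be non-negative")
    return config.alpha * (1.0 - math.exp(-b_value * config.adc_ref)) + config.f_offset


def _dropout_from_slice_stats(counts: np.ndarray, means: np.ndarray,
                              volume_mean: float, config: QCConfig) -> list[int]:
    """Slice indices failing the dropout rule, given per-slice stats."""
    out = []
    cut = (1.0 - config.slice_deficit) * volume_mean
    for s, (c, m) in enumerate(zip(counts, means)):
        if c >= config.min_mask_voxels_per_slice and m < cut:
            out.append(s)
    return out


def detect_dropout_slices(series: DiffusionSeries, masks: MaskSeries,
                          index: int, config: QCConfig) -> list[int]:
    """Indices of slices whose in-mask mean intensity is more than
    ``slice_deficit`` below the in-mask volume mean.

    Slices with fewer than ``min_mask_voxels_per_slice`` in-mask voxels
    are exempt (tiny polar caps have unstable means).
    """
    f = compute_volume_features(series, masks, index)
    return _dropout_from_slice_stats(f.slice_mask_counts,
                                     f.slice_mean_intensities,
                                     f.volume_mean_intensity, config)


@dataclass
class VolumeVerdict:
    """Per-volume QC outcome."""

    index: int
    b_value: float
    dropout_slices: list[int]
    volume_change_rel: float         # |V - V_ref| / V_ref; NaN if mask empty
    threshold_b: float
    flag_dropout: bool
    flag_volume: bool
    flag_cropped: bool
    status: str = field(init=False)  # "green" | "red"
    priority_score: float = field(init=False)

    def __post_init__(self) -> None:
        red = self.flag_dropout or self.flag_volume or self.flag_cropped
        self.status = "red" if red else "green"
        score = 0.0
        if red:
            score += len(self.dropout_slices)
            if self.flag_volume:
                vc = self.volume_change_rel
                if np.isnan(vc):
                    score += 1.0  # empty segmentation: unit severity
                else:
                    score += max(0.0, vc - self.threshold_b) / self.threshold_b
            if self.flag_cropped:
                score += 1.0
        self.priority_score = score

    def to_dict(self) -> dict:
        return {
            "index": self.index,
            "b_value": self.b_value,
            "dropout_slices": list(self.dropout_slices),
            "volume_change_rel": self.volume_change_rel,
            "threshold_b": self.threshold_b,
            "flag_dropout": self.flag_dropout,
            "flag_volume": self.flag_volume,
            "flag_cropped": self.flag_cropped,
            "status": self.status,
            "priority_score": self.priority_score,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "VolumeVerdict":
        vc = d["volume_change_rel"]
        return cls(
            index=d["index"], b_value=d["b_value"],
            dropout_slices=list(d["dropout_slices"]),
            volume_change_rel=float("nan") if vc is None else vc,
            threshold_b=d["threshold_b"],
            flag_dropout=d["flag_dropout"], flag_volume=d["flag_volume"],
            flag_cropped=d["flag_cropped"],
        )


@dataclass
class QCReport:
    """One verdict per volume plus the inter-volume motion trace."""

    verdicts: list[VolumeVerdict]
    trace: MotionTrace | None
    reference_index: int
    config_echo: QCConfig

    @property
    def red_indices(self) -> list[int]:
        return [v.index for v in self.verdicts if v.status == "red"]

    @property
    def n_red(self) -> int:
        return len(self.red_indices)

    def to_dict(self) -> dict:
        return {
            "verdicts": [v.to_dict() for v in self.verdicts],
            "l2_trace_mm": None if self.trace is None else list(self.trace.l2_mm),
            "mean_l2_mm": None if self.trace is None else self.trace.mean_l2_mm,
            "reference_index": self.reference_index,
            "config": self.config_echo.to_dict(),
        }

    @classmethod
    def from_dict(cls, d: dict) -> "QCReport":
        trace = None
        if d.get("l2_trace_mm") is not None:
            l2 = [float("nan") if v is None else v for v in d["l2_trace_mm"]]
            trace = MotionTrace(l2_mm=np.asarray(l2))
        return cls(
            verdicts=[VolumeVerdict.from_dict(v) for v in d["verdicts"]],
            trace=trace,
            reference_index=d["reference_index"],
            config_echo=QCConfig.from_dict(d["config"]),
        )


def classify_volume(features: VolumeFeatures, reference: VolumeFeatures,
                    config: QCConfig,
                    dropout_slices: list[int] | None = None) -> VolumeVerdict:
    """Apply the three rules to one volume against the reference volume.

    ``dropout_slices`` may be passed in to avoid recomputation; when
    omitted it is derived from the slice statistics in ``features``.
    An empty-mask volume is red with its features recorded as missing.
    """
    if reference.empty:
        raise ValueError("invalid reference: empty segmentation")
    thr = dynamic_threshold(features.b_value, config)
    if features.empty:
        return VolumeVerdict(
            index=features.index, b_value=features.b_value, dropout_slices=[],
            volume_change_rel=float("nan"), threshold_b=thr,
            flag_dropout=False, flag_volume=True, flag_cropped=False,
        )
    if dropout_slices is None:
        dropout_slices = _dropout_from_slice_stats(
            features.slice_mask_counts, features.slice_mean_intensities,
            features.volume_mean_intensity, config)
    vc = abs(features.brain_volume - reference.brain_volume) / reference.brain_volume
    return VolumeVerdict(
        index=features.index,
        b_value=features.b_value,
        dropout_slices=list(dropout_slices),
        volume_change_rel=vc,
        threshold_b=thr,
        flag_dropout=bool(dropout_slices),
        flag_volume=vc > thr,
        flag_cropped=features.boundary_fraction > config.boundary_fraction_tol,
    )


def _choose_reference(features: list[VolumeFeatures],
                      config: QCConfig) -> int:
    """Pick the reference volume index per ``reference_volume_policy``."""
    non_empty = [f.index for f in features if not f.empty]
    if not non_empty:
        raise ValueError("no usable volumes: all masks empty")
    ref = non_empty[0] if features[0].empty else 0
    if config.reference_volume_policy == "first_clean_b0":
        f0 = features[ref]
        dropped = _dropout_from_slice_stats(
            f0.slice_mask_counts, f0.slice_mean_intensities,
            f0.volume_mean_intensity, config)
        if dropped:
            for f in features:
                if f.empty or f.b_value != 0:
                    continue
                if not _dropout_from_slice_stats(
                        f.slice_mask_counts, f.slice_mean_intensities,
                        f.volume_mean_intensity, config):
                    return f.index
    return ref


def run_qc(series: DiffusionSeries, masks: MaskSeries,
           config: QCConfig | None = None) -> QCReport:
    """Classify every volume and assemble the QC report.

    Deterministic for fixed inputs and config.  Raises when every mask
    is empty.
    """
    config = config or QCConfig()
    if masks.data.shape != series.data.shape:
        raise ValueError("mask/series geometry mismatch")
    features = compute_all_features(series, masks)
    ref_idx = _choose_reference(features, config)
    reference = features[ref_idx]
    verdicts = [classify_volume(f, reference, config) for f in features]
    try:
        trace = inter_volume_l2(features)
    except ValueError:
        trace = None
    return QCReport(verdicts=verdicts, trace=trace,
                    reference_index=ref_idx, config_echo=config)


def alpha_sweep(series: DiffusionSeries, masks: MaskSeries, truth,
                alphas: list[float], config: QCConfig | None = None):
    """Disagreement between flagged volumes and ground truth per alpha.

    Re-runs the full classification for each alpha (only the
    volume-change rule depends on it) and counts volumes whose red/green
    status differs from ``truth.expected_red``.  Returns a list of
    ``(alpha, disagreement_count)`` pairs.
    """
    base = (config or QCConfig()).to_dict()
    if len(truth.volumes) != series.n_volumes:
        raise ValueError("truth/series length mismatch")
    expected = set(truth.expected_red)
    table = []
    for a in alphas:
        cfg = QCConfig.from_dict({**base, "alpha": float(a)})
        report = run_qc(series, masks, cfg)
        flagged = set(report.red_indices)
        table.append((float(a), len(flagged.symmetric_difference(expected))))
    return table
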