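"""Prioritised re-acquisition planning, volume merging and the QC loop.

Priority scoring: dropout-slice count dominates, the relative
volume-change excess over its threshold adds a fractional term, and a
cropping flag adds one unit.  Ties break on acquisition order.  Whole
volumes are replanned, never single directions.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable

import numpy as np

from dwiqc.io_bridge import BTable, DiffusionSeries, MaskSeries, QCConfig
from dwiqc.quality_control import QCReport, run_qc

__all__ = ["PlanItem", "ReacquisitionPlan", "build_plan", "merge",
           "merge_masks", "iterate"]

#: matching tolerance for (b_value, direction) between plan and reacquisition
MATCH_TOL = 1e-3


@dataclass(frozen=True)
class PlanItem:
    original_index: int
    b_value: float
    direction: tuple[float, float, float]
    priority_score: float


@dataclass
class ReacquisitionPlan:
    """Ordered list of volumes to re-acquire (highest priority first)."""

    items: list[PlanItem]
    iteration: int
    cap_reached: bool = False

    def __len__(self) -> int:
        return len(self.items)

    @property
    def indices(self) -> list[int]:
        return [it.original_index for it in self.items]

    def btable(self) -> BTable:
        return BTable(
            np.array([it.b_value for it in self.items], dtype=float),
            np.array([it.direction for it in self.items], dtype=float),
        )


def build_plan(report: QCReport, iteration: int,
               config: QCConfig | None = None,
               btable: BTable | None = None) -> ReacquisitionPlan:
    """Turn a QC report into a prioritised plan for one iteration.

    Every red volume is included, sorted by priority score descending
    (ties by original index ascending).  Beyond ``max_iterations`` the
    plan is empty and carries the cap marker.

    ``btable`` supplies the directions for the planned volumes; when
    omitted, directions are taken as unavailable (zero vectors) — pass
    the series b-table for scanner-ready output.
    """
    if iteration < 1:
        raise ValueError("iteration is 1-based")
    config = config or report.config_echo
    if iteration > config.max_iterations:
        return ReacquisitionPlan(items=[], iteration=iteration, cap_reached=True)
    red = [v for v in report.verdicts if v.status == "red"]
    red.sort(key=lambda v: (-v.priority_score, v.index))
    items = []
    for v in red:
        if btable is not None:
            direction = tuple(float(x) for x in btable.bvecs[v.index])
        else:
            direction = (0.0, 0.0, 0.0)
        items.append(PlanItem(original_index=v.index, b_value=v.b_value,
                              direction=direction,
                              priority_score=v.priority_score))
    return ReacquisitionPlan(items=items, iteration=iteration)


def _check_match(plan: ReacquisitionPlan, reacq: DiffusionSeries) -> None:
    if reacq.n_volumes != len(plan):
        raise ValueError("reacquisition/plan mismatch: wrong volume count")
    for i, item in enumerate(plan.items):
        if abs(reacq.btable.bvals[i] - item.b_value) > MATCH_TOL:
            raise ValueError("reacquisition/plan mismatch: b-value")
        if np.linalg.norm(reacq.btable.bvecs[i] - np.asarray(item.direction)) > MATCH_TOL:
            raise ValueError("reacquisition/plan mismatch: direction")


def merge(series: DiffusionSeries, reacq: DiffusionSeries,
          plan: ReacquisitionPlan) -> DiffusionSeries:
    """Replace planned volumes with their re-acquisitions.

    Re-acquired volumes are matched by plan position and verified
    against (b_value, direction) within tolerance.  All other volumes
    are bitwise unchanged; the b-table is preserved.
    """
    if not plan.items:
        return DiffusionSeries(data=series.data.copy(), affine=series.affine,
                               btable=series.btable, slice_axis=series.slice_axis)
    _check_match(plan, reacq)
    if reacq.data.shape[:3] != series.data.shape[:3]:
        raise ValueError("reacquisition/plan mismatch: grid")
    out = series.data.copy()
    for i, item in enumerate(plan.items):
        out[..., item.original_index] = reacq.data[..., i]
    return DiffusionSeries(data=out, affine=series.affine,
                           btable=series.btable, slice_axis=series.slice_axis)


def merge_masks(masks: MaskSeries, reacq_masks: MaskSeries,
                plan: ReacquisitionPlan) -> MaskSeries:
    """Companion of :func:`merge` for the per-volume mask series."""
    if not plan.items:
        return MaskSeries(data=masks.data.copy())
    if reacq_masks.n_volumes != len(plan):
        raise ValueError("reacquisition/plan mismatch: wrong mask count")
    out = masks.data.copy()
    for i, item in enumerate(plan.items):
        out[..., item.original_index] = reacq_masks.data[..., i]
    return MaskSeries(data=out)


ReacqProvider = Callable[[ReacquisitionPlan], tuple[DiffusionSeries, MaskSeries]]


def iterate(series: DiffusionSeries, masks: MaskSeries,
            reacq_provider: ReacqProvider,
            config: QCConfig | None = None,
            ) -> tuple[DiffusionSeries, list[QCReport], list[ReacquisitionPlan]]:
    """Run the qc → plan → re-acquire → merge loop until clean or capped.

    ``reacq_provider`` plays the scanner: given a plan it returns a
    series and mask series with exactly one volume per plan item, in
    plan order.  Returns the final series, the report history (one
    report per QC pass, including the final one) and the emitted plans.
    """
    config = config or QCConfig()
    reports: list[QCReport] = []
    plans: list[ReacquisitionPlan] = []
    current, current_masks = series, masks
    iteration = 1
    while True:
        report = run_qc(current, current_masks, config)
        reports.append(report)
        if report.n_red == 0 or iteration > config.max_iterations:
            break
        plan = build_plan(report, iteration, config, btable=current.btable)
        plans.append(plan)
        reacq, reacq_masks = reacq_provider(plan)
        current = merge(current, reacq, plan)
        current_masks = merge_masks(current_masks, reacq_masks, plan)
        iteration += 1
    return current, reports, plans
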