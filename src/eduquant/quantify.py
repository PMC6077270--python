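"""Densities, group comparison and the percent-change efficacy statistic.

Per-circle cell counts become a per-section density (mean count divided by
circle area, in cells/mm²); per-group summaries are means over sections,
so each animal/section contributes once regardless of how many circles it
got; the headline statistic is

    percent_change = 100 * (1 - treated_mean / control_mean)

for (a) EdU density in the proliferating area — the tumor-proliferation
readout — and (b) protein density in the protein's own compartment — the
target-efficacy readout. An optional seeded nonparametric bootstrap over
sections gives a percentile 95% interval; no hypothesis test is computed
by default.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .detection import count_in_circle
from .errors import UndefinedComparisonError, ValidationError
from .types import (
    CellDetectionSet,
    CircularRoi,
    CompartmentCall,
    DensityEstimate,
    GroupComparison,
    circle_area_mm2,
)

__all__ = [
    "estimate_density",
    "compare_groups",
    "ExperimentReport",
    "summarize_experiment",
]


def estimate_density(
    detections: CellDetectionSet | np.ndarray,
    rois: list[CircularRoi],
    pixel_size_um: float,
    sample_id: str | None = None,
    channel_role: str | None = None,
) -> DensityEstimate:
    """Cells-per-mm² for one section/channel from k equal-radius circles."""
    if not rois:
        raise ValidationError("need at least one ROI")
    radii = {r.radius_px for r in rois}
    if len(radii) > 1:
        raise ValidationError(f"ROIs must share one radius, got {sorted(radii)}")
    radius = radii.pop()
    if not (radius > 0):
        raise ValidationError("zero-area circle")
    compartments = {r.compartment for r in rois}
    if len(compartments) > 1:
        raise ValidationError("ROIs span multiple compartments")
    if isinstance(detections, CellDetectionSet):
        sample_id = sample_id or detections.section_id
        channel_role = channel_role or detections.channel_role
    counts = [count_in_circle(detections, roi) for roi in rois]
    return DensityEstimate(
        sample_id=sample_id or "",
        compartment=compartments.pop(),
        channel_role=channel_role or "edu",
        counts=counts,
        circle_area_mm2=circle_area_mm2(radius, pixel_size_um),
    )


def _group_mean(estimates: list[DensityEstimate]) -> float:
    return float(np.mean([d.mean_density for d in estimates]))


def compare_groups(
    control: list[DensityEstimate],
    treated: list[DensityEstimate],
    n_boot: int = 0,
    seed: int | None = None,
) -> GroupComparison:
    """Percent change of the treated group mean relative to control.

    Group means are means of per-section densities. A zero control mean
    makes the statistic undefined and raises
    :class:`UndefinedComparisonError` (never a silent NaN). With
    ``n_boot > 0``, sections are resampled with replacement within each
    group and the percentile 2.5/97.5 bounds of the bootstrap percent
    changes are attached.
    """
    if not control or not treated:
        raise ValidationError("both groups must be non-empty")
    channels = {d.channel_role for d in control} | {d.channel_role for d in treated}
    if len(channels) > 1:
        raise ValidationError(f"mixed channel roles in comparison: {channels}")
    compartments = {d.compartment for d in control} | {d.compartment for d in treated}
    if len(compartments) > 1:
        raise ValidationError(f"mixed compartments in comparison: {compartments}")
    c_mean = _group_mean(control)
    t_mean = _group_mean(treated)
    if c_mean == 0:
        raise UndefinedComparisonError(
            "control mean density is zero; percent change undefined"
        )
    pc = 100.0 * (1.0 - t_mean / c_mean)
    ci_low = ci_high = None
    if n_boot > 0:
        rng = np.random.default_rng(seed)
        c_dens = np.array([d.mean_density for d in control])
        t_dens = np.array([d.mean_density for d in treated])
        boots = []
        for _ in range(n_boot):
            cb = c_dens[rng.integers(0, len(c_dens), len(c_dens))].mean()
            tb = t_dens[rng.integers(0, len(t_dens), len(t_dens))].mean()
            if cb > 0:
                boots.append(100.0 * (1.0 - tb / cb))
        if boots:
            ci_low, ci_high = (float(q) for q in np.percentile(boots, [2.5, 97.5]))
    return GroupComparison(
        channel_role=channels.pop(),
        compartment=compartments.pop(),
        control_mean=c_mean,
        treated_mean=t_mean,
        n_control=len(control),
        n_treated=len(treated),
        percent_change=pc,
        ci_low=ci_low,
        ci_high=ci_high,
    )


_SAMPLE_COLUMNS = [
    "sample_id", "group",
    "edu_compartment", "edu_k", "edu_mean_density_mm2",
    "protein_compartment", "protein_k", "protein_mean_density_mm2",
]
_COMPARISON_COLUMNS = [
    "channel", "compartment", "control_mean_mm2", "treated_mean_mm2",
    "n_control", "n_treated", "percent_change", "ci_low", "ci_high",
]
_CALL_COLUMNS = ["target_name", "n_cells", "overlap_fraction", "call"]


@dataclass
class ExperimentReport:
    """Tidy result tables of one experiment run.

    ``samples`` has one row per section with both density readouts;
    ``comparisons`` one row per channel readout; ``calls`` one row per
    target protein.
    """

    samples: pd.DataFrame
    comparisons: pd.DataFrame
    calls: pd.DataFrame
    provenance: dict = field(default_factory=dict)

    def to_csv(self, directory) -> dict[str, str]:
        """Write densities.csv / comparisons.csv / calls.csv with a stable
        row order and float format, returning the paths."""
        import os

        paths = {}
        for name, df in (
            ("densities", self.samples),
            ("comparisons", self.comparisons),
            ("calls", self.calls),
        ):
            path = os.path.join(str(directory), f"{name}.csv")
            df.to_csv(path, index=False, float_format="%.10g", lineterminator="\n")
            paths[name] = path
        return paths


def summarize_experiment(
    calls: list[CompartmentCall],
    densities: list[DensityEstimate],
    comparisons: list[GroupComparison],
    groups: dict[str, str] | None = None,
) -> ExperimentReport:
    """Assemble per-sample densities, compartment calls and group
    comparisons into one report.

    ``groups`` maps sample_id to its group label; omitted samples get an
    empty group. Samples must carry a consistent set of channels: a sample
    with a density for one channel but not the other is a metadata
    mismatch and raises :class:`ValidationError`.
    """
    groups = groups or {}
    by_sample: dict[str, dict[str, DensityEstimate]] = {}
    for d in densities:
        slot = by_sample.setdefault(d.sample_id, {})
        if d.channel_role in slot:
            raise ValidationError(
                f"duplicate density for sample '{d.sample_id}' channel "
                f"'{d.channel_role}'"
            )
        slot[d.channel_role] = d
    channel_sets = {frozenset(v) for v in by_sample.values()}
    if len(channel_sets) > 1:
        raise ValidationError(
            "mismatched sample ids: not all samples have the same channels"
        )
    rows = []
    for sid in sorted(by_sample):
        slot = by_sample[sid]
        row = {"sample_id": sid, "group": groups.get(sid, "")}
        for role in ("edu", "protein"):
            d = slot.get(role)
            row[f"{role}_compartment"] = d.compartment if d else ""
            row[f"{role}_k"] = d.k if d else 0
            row[f"{role}_mean_density_mm2"] = d.mean_density if d else np.nan
        rows.append(row)
    samples = pd.DataFrame(rows, columns=_SAMPLE_COLUMNS)

    comp_rows = [
        {
            "channel": c.channel_role,
            "compartment": c.compartment,
            "control_mean_mm2": c.control_mean,
            "treated_mean_mm2": c.treated_mean,
            "n_control": c.n_control,
            "n_treated": c.n_treated,
            "percent_change": c.percent_change,
            "ci_low": c.ci_low,
            "ci_high": c.ci_high,
        }
        for c in comparisons
    ]
    comp = pd.DataFrame(comp_rows, columns=_COMPARISON_COLUMNS)
    if len(comp):
        comp = comp.sort_values(["channel", "compartment"]).reset_index(drop=True)

    call_rows = [
        {
            "target_name": c.target_name,
            "n_cells": c.n_cells,
            "overlap_fraction": c.overlap_fraction,
            "call": c.call,
        }
        for c in calls
    ]
    calls_df = pd.DataFrame(call_rows, columns=_CALL_COLUMNS)
    if len(calls_df):
        calls_df = calls_df.sort_values("target_name").reset_index(drop=True)
    return ExperimentReport(samples=samples, comparisons=comp, calls=calls_df)
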