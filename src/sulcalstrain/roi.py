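"""Per-impact ROI summary metrics.

For each impact: the whole-brain 90th-percentile strain and strain rate (a
robust per-impact severity scalar that discounts abnormally large values in
poorly shaped elements), arithmetic means within each atlas region, and the
collapse of region means into one sulcal and one gyral mean.  The collapse is
ROI-weighted — each region counts once regardless of its voxel count — with
the voxel-weighted alternative computed alongside for comparison.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .fields import VoxelField
from .geometry import RegionInfo

__all__ = [
    "percentile_90",
    "roi_means",
    "collapse_sulcal_gyral",
    "ClassMeans",
    "ImpactSummary",
    "summarize_impact",
    "summarize_cohort",
    "profile_summary",
]


def percentile_90(fieldv: VoxelField, mask: np.ndarray) -> float:
    """90th percentile of in-mask voxels, linear interpolation convention."""
    mask = np.asarray(mask, bool)
    if mask.shape != fieldv.data.shape:
        raise ValueError("mask shape does not match field")
    vals = np.asarray(fieldv.data)[mask]
    if vals.size == 0:
        raise ValueError("empty mask")
    return float(np.percentile(vals, 90.0, method="linear"))


def roi_means(fieldv: VoxelField, atlas: VoxelField) -> pd.DataFrame:
    """Mean voxel value per atlas label; labels without voxels are absent.

    The background label 0 is never reported.  Returns columns
    ``label, mean, n_voxels``.
    """
    if not fieldv.congruent_with(atlas):
        raise ValueError("atlas and field grids are not congruent")
    labels = np.asarray(atlas.data).ravel()
    vals = np.asarray(fieldv.data).ravel()
    keep = labels != 0
    df = (pd.DataFrame({"label": labels[keep], "value": vals[keep]})
          .groupby("label")["value"]
          .agg(mean="mean", n_voxels="size")
          .reset_index())
    df["label"] = df["label"].astype(int)
    return df


@dataclass(frozen=True)
class ClassMeans:
    """Sulcal/gyral collapse, ROI-weighted (primary) and voxel-weighted."""

    sulcal: float
    gyral: float
    sulcal_voxelweighted: float
    gyral_voxelweighted: float


def collapse_sulcal_gyral(means: pd.DataFrame,
                          region_table: dict[int, RegionInfo]) -> ClassMeans:
    """Unweighted mean over ROI means within the sulcal and gyral classes."""
    cls = means["label"].map(
        lambda lab: region_table.get(int(lab), RegionInfo("?", "other")).cls)
    out = {}
    for c in ("sulcal", "gyral"):
        sub = means[cls == c]
        if sub.empty:
            raise ValueError(f"no {c}-class region present")
        out[c] = float(sub["mean"].mean())
        out[c + "_vw"] = float(np.average(sub["mean"], weights=sub["n_voxels"]))
    return ClassMeans(sulcal=out["sulcal"], gyral=out["gyral"],
                      sulcal_voxelweighted=out["sulcal_vw"],
                      gyral_voxelweighted=out["gyral_vw"])


@dataclass
class ImpactSummary:
    event_id: str
    p90_strain: float
    p90_strain_rate: float
    sulcal_mean_strain: float
    gyral_mean_strain: float
    sulcal_mean_strain_rate: float
    gyral_mean_strain_rate: float
    roi_strain: dict[int, float] = field(default_factory=dict)
    roi_strain_rate: dict[int, float] = field(default_factory=dict)


def summarize_impact(event_id: str,
                     strain: VoxelField, strain_rate: VoxelField,
                     atlas: VoxelField,
                     region_table: dict[int, RegionInfo],
                     brain_mask: np.ndarray) -> ImpactSummary:
    ms = roi_means(strain, atlas)
    mr = roi_means(strain_rate, atlas)
    cs = collapse_sulcal_gyral(ms, region_table)
    cr = collapse_sulcal_gyral(mr, region_table)
    return ImpactSummary(
        event_id=event_id,
        p90_strain=percentile_90(strain, brain_mask),
        p90_strain_rate=percentile_90(strain_rate, brain_mask),
        sulcal_mean_strain=cs.sulcal,
        gyral_mean_strain=cs.gyral,
        sulcal_mean_strain_rate=cr.sulcal,
        gyral_mean_strain_rate=cr.gyral,
        roi_strain=dict(zip(ms["label"], ms["mean"])),
        roi_strain_rate=dict(zip(mr["label"], mr["mean"])),
    )


COHORT_COLUMNS = [
    "event_id", "profile", "event_type", "velocity_class",
    "peak_lin_acc", "peak_lin_vel", "peak_rot_acc", "peak_rot_vel",
    "p90_strain", "p90_strain_rate",
    "sulcal_mean_strain", "gyral_mean_strain",
    "sulcal_mean_strain_rate", "gyral_mean_strain_rate",
]


def summarize_cohort(events, summaries: list[ImpactSummary]) -> pd.DataFrame:
    """One row per impact: profile/kinematics joined with the ROI metrics."""
    by_id = {s.event_id: s for s in summaries}
    rows = []
    for ev in events:
        s = by_id.get(ev.event_id)
        if s is None:
            raise ValueError(f"missing strain summary for event {ev.event_id}")
        row = {
            "event_id": ev.event_id,
            "profile": ev.profile,
            "event_type": ev.event_type,
            "velocity_class": ev.velocity_class,
            **ev.summary.as_dict(),
            "p90_strain": s.p90_strain,
            "p90_strain_rate": s.p90_strain_rate,
            "sulcal_mean_strain": s.sulcal_mean_strain,
            "gyral_mean_strain": s.gyral_mean_strain,
            "sulcal_mean_strain_rate": s.sulcal_mean_strain_rate,
            "gyral_mean_strain_rate": s.gyral_mean_strain_rate,
        }
        rows.append(row)
    return pd.DataFrame(rows, columns=COHORT_COLUMNS)


def profile_summary(table: pd.DataFrame) -> pd.DataFrame:
    """Per-profile mean ± SD of kinematics and deformation metrics.

    Mirrors the layout of a per-profile cohort summary table: one row per
    measure, one mean/sd column pair per profile.
    """
    measures = [c for c in COHORT_COLUMNS[4:] if c in table.columns]
    out = {}
    for prof, grp in table.groupby("profile"):
        out[f"profile{prof}_mean"] = grp[measures].mean()
        out[f"profile{prof}_sd"] = grp[measures].std(ddof=1)
        out[f"profile{prof}_n"] = pd.Series(len(grp), index=measures)
    return pd.DataFrame(out)
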