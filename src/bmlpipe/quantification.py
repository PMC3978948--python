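"""Lesion-definition rules and volumetric measurement.

Candidates from the segmentation stage become bone marrow lesions (BMLs)
only if, after removal of the central excluded slice block, they still
span at least two slices and approach the articular surface within the
distance cap (default 10 mm).  Retained lesions are assigned to one of four
regions (medial/lateral x femur/tibia) and summed into per-region, total,
and index-tibiofemoral-compartment volumes in cm^3.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .segmentation import BoneMask, LesionCandidate, MRVolume

REGIONS = ("medial femur", "lateral femur", "medial tibia", "lateral tibia")


@dataclass(frozen=True)
class BMLCriteria:
    """Operational BML definition."""

    max_surface_dist_mm: float = 10.0
    min_slice_span: int = 2
    central_excluded_slices: int = 9

    def validate(self) -> None:
        if self.max_surface_dist_mm <= 0 or self.min_slice_span <= 0 \
                or self.central_excluded_slices <= 0:
            raise ValueError("criteria values must be positive")


def central_block(slice_count: int, excluded: int = 9) -> range:
    """Indices of the centred excluded slice block.

    For an even slice count the block sits one slice toward index 0.
    """
    excluded = min(excluded, slice_count)
    start = (slice_count - excluded) // 2
    return range(start, start + excluded)


def apply_bml_criteria(cands: list[LesionCandidate], crit: BMLCriteria,
                       slice_count: int) -> list[LesionCandidate]:
    """Filter candidates by the lesion-definition rules (order preserved).

    Voxels inside the central excluded block are deleted first; the slice
    span and minimum surface distance are then recomputed on the surviving
    voxels.  The operation is idempotent and never grows a candidate.
    """
    crit.validate()
    block = central_block(slice_count, crit.central_excluded_slices)
    out: list[LesionCandidate] = []
    for cand in cands:
        keep = ~np.isin(cand.voxels[:, 2], list(block))
        if not keep.any():
            continue
        vox = cand.voxels[keep]
        dists = cand.voxel_dists_mm[keep]
        span = int(np.unique(vox[:, 2]).size)
        min_dist = float(dists.min())
        if min_dist > crit.max_surface_dist_mm or span < crit.min_slice_span:
            continue
        out.append(replace(cand, voxels=vox, voxel_dists_mm=dists,
                           slice_span=span, min_surface_dist_mm=min_dist,
                           centroid_mm=cand.centroid_mm))
    return out


def assign_region(cand: LesionCandidate, bones: BoneMask,
                  spacing_mm=None) -> str:
    """Region label from the containing bone and the medial/lateral split.

    The candidate must lie inside exactly one bone; a centroid exactly on
    the split coordinate is medial.
    """
    idx = tuple(cand.voxels.T)
    containing = [name for name, m in bones.masks.items() if m[idx].any()]
    if len(containing) != 1:
        raise ValueError(
            f"candidate at {cand.centroid_mm} lies in {len(containing)} bones")
    bone = containing[0]
    side = "medial" if cand.centroid_mm[2] <= bones.split_z_mm else "lateral"
    return f"{side} {bone}"


@dataclass
class BMLMeasurement:
    """Per-region BML volumes (cm^3) for one knee-visit."""

    knee_id: str
    visit: str
    region_volumes_cm3: dict[str, float] = field(
        default_factory=lambda: {r: 0.0 for r in REGIONS})

    @property
    def total_cm3(self) -> float:
        return float(sum(self.region_volumes_cm3.values()))

    def compartment_cm3(self, side: str) -> float:
        return (self.region_volumes_cm3[f"{side} femur"]
                + self.region_volumes_cm3[f"{side} tibia"])


def compute_measurement(cands: list[LesionCandidate], vol: MRVolume,
                        knee_id: str = "knee", visit: str = "baseline"
                        ) -> BMLMeasurement:
    """Sum voxel volumes of filtered, region-assigned candidates."""
    meas = BMLMeasurement(knee_id=knee_id, visit=visit)
    for cand in cands:
        if cand.region is None:
            raise ValueError("candidate has no region label; "
                             "run assign_region first")
        meas.region_volumes_cm3[cand.region] += cand.volume_cm3(vol.spacing_mm)
    return meas


def index_compartment(meas: BMLMeasurement, jsn_medial: int,
                      jsn_lateral: int) -> float:
    """Femur+tibia BML volume in the compartment with greater baseline
    joint-space-narrowing grade; ties go medial."""
    for g in (jsn_medial, jsn_lateral):
        if g not in (0, 1, 2, 3):
            raise ValueError(f"JSN grade {g!r} outside 0..3")
    side = "lateral" if jsn_lateral > jsn_medial else "medial"
    return meas.compartment_cm3(side)


def volume_change(baseline: BMLMeasurement, followup: BMLMeasurement,
                  jsn_medial: int = 0, jsn_lateral: int = 0) -> dict:
    """Follow-up minus baseline volumes for the analysed aggregates."""
    if baseline.knee_id != followup.knee_id:
        raise ValueError(
            f"knee id mismatch: {baseline.knee_id!r} vs {followup.knee_id!r}")
    return {
        "total": followup.total_cm3 - baseline.total_cm3,
        "index_compartment": (index_compartment(followup, jsn_medial, jsn_lateral)
                              - index_compartment(baseline, jsn_medial, jsn_lateral)),
        "medial": followup.compartment_cm3("medial") - baseline.compartment_cm3("medial"),
        "lateral": followup.compartment_cm3("lateral") - baseline.compartment_cm3("lateral"),
    }
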