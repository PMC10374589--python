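"""Sphere ROIs from significance maps, bootstrap CIs, and cluster overlap.

Group ROIs are 6 mm spheres centered on each significant cluster's t-peak;
large clusters are split at local maxima separated by at least a minimum
peak distance.  Individual ROIs re-center the sphere on each participant's
own accuracy peak within the group ROI.  Overlapping ROIs with similar
accuracy distributions can be merged.  Overlap reports convert voxel counts
to mm^3 using the 3 mm isotropic voxel volume (27 mm^3) and express the
intersection as a percentage of either cluster.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

from .inference import CONNECTIVITY_26

VOXEL_VOLUME_MM3 = 27.0


@dataclass
class SphereROI:
    name: str
    center_ijk: tuple
    radius_mm: float
    member_voxels: np.ndarray  # boolean volume (sphere ∩ mask)
    level: str = "group"  # "group" | "individual"
    parent: str | None = None
    meta: dict = field(default_factory=dict)

    @property
    def n_voxels(self) -> int:
        return int(self.member_voxels.sum())

    def center_mm(self, voxel_size_mm=(3.0, 3.0, 3.0)) -> tuple:
        return tuple(c * v for c, v in zip(self.center_ijk, voxel_size_mm))


def _sphere_members(shape, center_ijk, radius_mm, voxel_size_mm, mask):
    grids = np.indices(shape).astype(float)
    d2 = np.zeros(shape)
    for ax in range(3):
        d2 += ((grids[ax] - center_ijk[ax]) * voxel_size_mm[ax]) ** 2
    return (d2 <= radius_mm**2) & mask


def _local_maxima(t_map, cluster_mask):
    """Voxels that are >= all 26-neighbors within the cluster."""
    t = np.where(cluster_mask, t_map, -np.inf)
    dil = ndimage.maximum_filter(t, footprint=CONNECTIVITY_26)
    return cluster_mask & (t >= dil)


def define_group_rois(
    t_map,
    sig_mask,
    radius_mm: float = 6.0,
    min_peak_sep_mm: float = 20.0,
    voxel_size_mm=(3.0, 3.0, 3.0),
    brain_mask=None,
    name_prefix: str = "roi",
) -> list:
    """One 6 mm sphere ROI per significant cluster peak.

    Within each 26-connected cluster of ``sig_mask``, local t-map maxima are
    visited in descending t order and accepted greedily when at least
    ``min_peak_sep_mm`` from every already-accepted peak, so a large cluster
    with well-separated peaks yields several ROIs.
    """
    sig_mask = np.asarray(sig_mask, dtype=bool)
    if brain_mask is None:
        brain_mask = np.isfinite(t_map)
    if not sig_mask.any():
        return []
    labels, n_clusters = ndimage.label(sig_mask, structure=CONNECTIVITY_26)
    vs = np.asarray(voxel_size_mm, dtype=float)
    rois = []
    for lab in range(1, n_clusters + 1):
        cluster = labels == lab
        peaks = np.argwhere(_local_maxima(t_map, cluster))
        order = np.argsort([-t_map[tuple(p)] for p in peaks], kind="stable")
        accepted = []
        for idx in order:
            p = peaks[idx]
            if all(
                np.linalg.norm((p - q) * vs) >= min_peak_sep_mm for q in accepted
            ):
                accepted.append(p)
        for j, p in enumerate(accepted):
            suffix = f"c{lab}" if len(accepted) == 1 else f"c{lab}p{j + 1}"
            rois.append(
                SphereROI(
                    name=f"{name_prefix}_{suffix}",
                    center_ijk=tuple(int(v) for v in p),
                    radius_mm=radius_mm,
                    member_voxels=_sphere_members(
                        sig_mask.shape, p, radius_mm, vs, brain_mask
                    ),
                    level="group",
                    meta={"cluster_label": int(lab), "peak_t": float(t_map[tuple(p)])},
                )
            )
    return rois


def individual_peak_roi(
    accuracy_map,
    group_roi: SphereROI,
    radius_mm: float = 6.0,
    voxel_size_mm=(3.0, 3.0, 3.0),
    brain_mask=None,
) -> SphereROI:
    """Sphere around the participant's max-accuracy voxel within a group ROI.

    Ties are broken toward the lowest flat voxel index (deterministic).
    """
    acc = np.asarray(accuracy_map, dtype=float)
    if brain_mask is None:
        brain_mask = np.isfinite(acc)
    members = group_roi.member_voxels
    vals = np.where(members, acc, -np.inf)
    flat = int(np.argmax(vals))  # argmax returns the first (lowest) index on ties
    center = np.unravel_index(flat, acc.shape)
    tie = int(np.sum(vals == vals.ravel()[flat]))
    return SphereROI(
        name=f"{group_roi.name}_indiv",
        center_ijk=tuple(int(v) for v in center),
        radius_mm=radius_mm,
        member_voxels=_sphere_members(acc.shape, center, radius_mm,
                                      np.asarray(voxel_size_mm), brain_mask),
        level="individual",
        parent=group_roi.name,
        meta={"n_tied_peaks": tie},
    )


def merge_overlapping_rois(
    rois,
    accuracy_by_roi: dict,
    mean_tol: float = 2.0,
    var_ratio_tol: float = 2.0,
) -> list:
    """Merge spatially overlapping ROIs with similar accuracy distributions.

    ``accuracy_by_roi`` maps ROI name -> per-participant mean accuracies.
    Two overlapping ROIs merge when |Δmean| <= mean_tol (accuracy points)
    and their variance ratio (larger/smaller) <= var_ratio_tol.  Merging
    iterates to a fixed point; a merged ROI is the union of members with
    concatenated names.
    """
    rois = list(rois)
    acc = {r.name: np.asarray(accuracy_by_roi[r.name], dtype=float) for r in rois}
    changed = True
    while changed:
        changed = False
        for i in range(len(rois)):
            for j in range(i + 1, len(rois)):
                a, b = rois[i], rois[j]
                if not np.any(a.member_voxels & b.member_voxels):
                    continue
                va, vb = acc[a.name].var(ddof=1), acc[b.name].var(ddof=1)
                ratio = np.inf
                if min(va, vb) > 0:
                    ratio = max(va, vb) / min(va, vb)
                elif va == vb:
                    ratio = 1.0
                if (
                    abs(acc[a.name].mean() - acc[b.name].mean()) <= mean_tol
                    and ratio <= var_ratio_tol
                ):
                    merged = SphereROI(
                        name=f"{a.name}+{b.name}",
                        center_ijk=a.center_ijk,
                        radius_mm=a.radius_mm,
                        member_voxels=a.member_voxels | b.member_voxels,
                        level=a.level,
                        parent=a.parent,
                        meta={"merged_from": [a.name, b.name]},
                    )
                    acc[merged.name] = np.mean([acc[a.name], acc[b.name]], axis=0)
                    rois = [r for k, r in enumerate(rois) if k not in (i, j)]
                    rois.append(merged)
                    changed = True
                    break
            if changed:
                break
    return rois


def bootstrap_ci(values, n_boot: int = 1000, level: float = 0.95, rng=None) -> tuple:
    """Percentile bootstrap CI of the mean over resamples with replacement."""
    values = np.asarray(values, dtype=float)
    if values.size < 2:
        raise ValueError("need at least 2 values")
    rng = np.random.default_rng(rng)
    idx = rng.integers(0, values.size, size=(n_boot, values.size))
    means = values[idx].mean(axis=1)
    alpha = (1.0 - level) / 2.0
    return (
        float(np.quantile(means, alpha)),
        float(np.quantile(means, 1.0 - alpha)),
    )


def roi_mean_accuracy(accuracy_map, roi: SphereROI) -> float:
    vals = np.asarray(accuracy_map, dtype=float)[roi.member_voxels]
    return float(np.nanmean(vals))


@dataclass
class OverlapReport:
    name_a: str
    name_b: str
    n_overlap_voxels: int
    overlap_volume_mm3: float
    percent_of_a: float
    percent_of_b: float

    def to_dict(self) -> dict:
        return {
            "pair": [self.name_a, self.name_b],
            "n_overlap_voxels": self.n_overlap_voxels,
            "overlap_volume_mm3": self.overlap_volume_mm3,
            "percent_of_a": self.percent_of_a,
            "percent_of_b": self.percent_of_b,
        }


def overlap_report(
    mask_a,
    mask_b,
    voxel_volume_mm3: float = VOXEL_VOLUME_MM3,
    name_a: str = "A",
    name_b: str = "B",
) -> OverlapReport:
    """Voxel/volume/percentage overlap between two cluster masks."""
    a = np.asarray(mask_a, dtype=bool)
    b = np.asarray(mask_b, dtype=bool)
    if a.shape != b.shape:
        raise ValueError("masks are not in a common space")
    n = int(np.sum(a & b))
    na, nb = int(a.sum()), int(b.sum())
    return OverlapReport(
        name_a=name_a,
        name_b=name_b,
        n_overlap_voxels=n,
        overlap_volume_mm3=float(n * voxel_volume_mm3),
        percent_of_a=100.0 * n / na if na else 0.0,
        percent_of_b=100.0 * n / nb if nb else 0.0,
    )
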