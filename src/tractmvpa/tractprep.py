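"""Probabilistic tract-map post-processing and feature assembly.

Mirrors the standard tractography bookkeeping: streamline visitation
counts are normalized by the waytotal (the number of streamline samples
not rejected by exclusion masks) into per-voxel probabilities, the
probability map is thresholded at a fraction of the 95th percentile of
the positive within-tract values (20 % for the uncinate configuration,
40 % for the superior longitudinal fasciculus control tract), and the
surviving voxels are intersected with the skeleton before per-metric
feature matrices are assembled.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .skeletons import TractSkeleton

__all__ = ["ProbTractMap", "TractMask", "normalize_tract_map",
           "threshold_tract_map", "group_tract_mask", "intersect_with_skeleton",
           "assemble_feature_matrix", "FeatureMatrix",
           "UF_THRESHOLD_FRACTION", "SLF_THRESHOLD_FRACTION"]

UF_THRESHOLD_FRACTION = 0.20
SLF_THRESHOLD_FRACTION = 0.40


@dataclass(frozen=True)
class ProbTractMap:
    """Streamline-sample counts on a voxel grid."""
    counts: np.ndarray          # nonnegative integers, any grid shape
    waytotal: int

    def __post_init__(self):
        counts = np.asarray(self.counts)
        if (counts < 0).any():
            raise ValueError("streamline counts must be non-negative")
        if self.waytotal < counts.max(initial=0):
            raise ValueError("waytotal must be >= the largest voxel count")


@dataclass(frozen=True)
class TractMask:
    """Boolean voxel membership on a grid."""
    mask: np.ndarray

    @property
    def n_voxels(self) -> int:
        return int(np.asarray(self.mask).sum())

    def coords(self) -> np.ndarray:
        """Member coordinates in lexicographic order."""
        return np.argwhere(np.asarray(self.mask))


def normalize_tract_map(tract_map: ProbTractMap) -> np.ndarray:
    """Counts / waytotal, a per-voxel visitation probability in [0, 1]."""
    if tract_map.waytotal <= 0:
        raise ValueError("waytotal must be positive")
    return np.asarray(tract_map.counts, dtype=float) / float(tract_map.waytotal)


def threshold_tract_map(prob_map: np.ndarray, fraction: float = UF_THRESHOLD_FRACTION) -> TractMask:
    """Retain voxels >= fraction * P95 of the positive within-tract values.

    The 95th percentile is computed by linear interpolation between order
    statistics over strictly positive voxels only (background zeros are
    not part of the tract's intensity distribution); ties at the
    threshold are retained.
    """
    prob_map = np.asarray(prob_map, dtype=float)
    if not 0 < fraction <= 1:
        raise ValueError("fraction must lie in (0, 1]")
    positive = prob_map[prob_map > 0]
    if positive.size == 0:
        raise ValueError("tract map has no positive voxels")
    p95 = np.percentile(positive, 95, method="linear")
    return TractMask(mask=prob_map >= fraction * p95)


def group_tract_mask(prob_maps, fraction: float = UF_THRESHOLD_FRACTION,
                     order: str = "average_then_threshold") -> TractMask:
    """Combine per-subject probability maps into one group mask.

    Whether the subject maps are averaged before thresholding or each
    thresholded and then combined by majority is analysis-dependent;
    both orders are offered and neither is asserted as canonical.
    """
    prob_maps = [np.asarray(m, dtype=float) for m in prob_maps]
    if not prob_maps:
        raise ValueError("need at least one subject map")
    if order == "average_then_threshold":
        return threshold_tract_map(np.mean(prob_maps, axis=0), fraction)
    if order == "threshold_then_average":
        votes = np.mean([threshold_tract_map(m, fraction).mask
                         for m in prob_maps], axis=0)
        return TractMask(mask=votes >= 0.5)
    raise ValueError("order must be 'average_then_threshold' or "
                     "'threshold_then_average'")


def intersect_with_skeleton(mask: TractMask, skeleton: TractSkeleton) -> np.ndarray:
    """Skeleton voxel indices whose coordinates fall inside the mask,
    in lexicographic coordinate order."""
    m = np.asarray(mask.mask)
    if m.ndim != 3:
        raise ValueError("mask must be a 3-D volume")
    if np.any(skeleton.voxel_coords.max(axis=0) >= m.shape):
        raise ValueError("mask grid does not cover the skeleton "
                         f"(mask shape {m.shape}, skeleton extent "
                         f"{tuple(skeleton.voxel_coords.max(axis=0) + 1)})")
    inside = m[tuple(skeleton.voxel_coords.T)]
    idx = np.flatnonzero(inside)
    order = np.lexsort(skeleton.voxel_coords[idx].T[::-1])
    idx = idx[order]
    if idx.size == 0:
        warnings.warn("tract mask and skeleton do not overlap", stacklevel=2)
    return idx


@dataclass
class FeatureMatrix:
    """Subjects x voxels matrix of one DTI metric."""
    values: np.ndarray
    subject_ids: list
    voxel_index: np.ndarray
    metric: str

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        self.voxel_index = np.asarray(self.voxel_index, dtype=np.int64)
        if not np.all(np.isfinite(self.values)):
            raise ValueError("feature matrix must be finite")
        if self.values.shape != (len(self.subject_ids), len(self.voxel_index)):
            raise ValueError("feature matrix shape does not match labels")
        if len(set(self.subject_ids)) != len(self.subject_ids):
            raise ValueError("subject ids must be unique")
        if len(np.unique(self.voxel_index)) != len(self.voxel_index):
            raise ValueError("voxel indices must be unique")

    @property
    def n_subjects(self) -> int:
        return self.values.shape[0]

    @property
    def n_voxels(self) -> int:
        return self.values.shape[1]


def assemble_feature_matrix(cohort, voxels, metric: str) -> FeatureMatrix:
    """Extract cohort feature values at the given skeleton voxel indices.

    Row order follows the cohort's subject order; column j is the metric
    at ``voxels[j]``.  No imputation is performed.
    """
    voxels = np.asarray(voxels, dtype=np.int64)
    if voxels.size == 0:
        raise ValueError("empty voxel list; nothing to classify")
    if voxels.min(initial=0) < 0 or voxels.max(initial=0) >= cohort.skeleton.n_voxels:
        raise ValueError("voxel indices outside the skeleton")
    values = cohort.metric(metric)[:, voxels]
    return FeatureMatrix(values=values,
                         subject_ids=[s.id for s in cohort.subjects],
                         voxel_index=voxels, metric=metric)
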