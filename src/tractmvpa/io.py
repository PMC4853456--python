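"""NIfTI and table I/O for skeleton-aligned maps and subject metadata.

Maps and masks are stored as NIfTI-1 volumes on the skeleton's 1-mm
isotropic grid with an RAS+ affine; per-voxel vectors are scattered into
the volume at the skeleton coordinates (background 0) and gathered back
in the skeleton's voxel order.  Subject tables are plain CSV with the
header ``id,group,age,rt_mean,errors,aggression,mania``.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

import nibabel as nib

from .cohort import SubjectRecord
from .skeletons import TractSkeleton
from .spatialmaps import VoxelMap

__all__ = ["write_voxel_map", "read_voxel_map", "write_skeleton_mask",
           "read_subject_table", "write_subject_table"]

SUBJECT_COLUMNS = ["id", "group", "age", "rt_mean", "errors", "aggression", "mania"]
GROUP_ALIASES = {"1": 1, "+1": 1, "athlete": 1, "-1": -1, "control": -1}


def _affine() -> np.ndarray:
    return np.eye(4)  # 1-mm isotropic RAS+


def write_voxel_map(vmap: VoxelMap, path) -> None:
    vol = np.zeros(vmap.skeleton.shape(), dtype=np.float64)
    vol[tuple(vmap.skeleton.voxel_coords.T)] = vmap.values
    nib.save(nib.Nifti1Image(vol, _affine()), str(path))


def write_skeleton_mask(skeleton: TractSkeleton, path) -> None:
    nib.save(nib.Nifti1Image(skeleton.to_mask().astype(np.uint8), _affine()),
             str(path))


def read_voxel_map(path, skeleton: TractSkeleton,
                   semantics: str = "covariance") -> VoxelMap:
    img = nib.load(str(path))
    if not np.allclose(img.affine, _affine()):
        raise ValueError(f"{path}: affine does not match the skeleton grid "
                         "(expected 1-mm RAS+ identity)")
    vol = np.asarray(img.dataobj, dtype=np.float64)
    if np.any(skeleton.voxel_coords.max(axis=0) >= vol.shape):
        raise ValueError(f"{path}: volume does not cover the skeleton")
    values = vol[tuple(skeleton.voxel_coords.T)]
    return VoxelMap(values=values, skeleton=skeleton, semantics=semantics)


def write_subject_table(subjects, path) -> None:
    pd.DataFrame(
        [{c: getattr(s, c) for c in SUBJECT_COLUMNS} for s in subjects]
    ).to_csv(path, index=False)


def read_subject_table(path) -> list:
    """Parse and validate a subject CSV; errors name the offending cell."""
    df = pd.read_csv(path, dtype=str)
    missing = [c for c in SUBJECT_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing columns {missing}")
    records = []
    seen = set()
    for row_no, row in enumerate(df.itertuples(index=False), start=2):
        sid = str(row.id)
        if sid in seen:
            raise ValueError(f"{path} row {row_no}: duplicate id {sid!r}")
        seen.add(sid)
        raw_group = str(row.group).strip().lower()
        if raw_group not in GROUP_ALIASES:
            raise ValueError(f"{path} row {row_no}, column 'group': "
                             f"unknown label {row.group!r}")
        vals = {}
        for col in ("age", "rt_mean", "errors", "aggression", "mania"):
            raw = getattr(row, col)
            try:
                vals[col] = float(raw)
            except (TypeError, ValueError):
                raise ValueError(f"{path} row {row_no}, column {col!r}: "
                                 f"non-numeric value {raw!r}") from None
        records.append(SubjectRecord(
            id=sid, group=GROUP_ALIASES[raw_group], age=vals["age"],
            rt_mean=vals["rt_mean"], errors=int(vals["errors"]),
            aggression=vals["aggression"], mania=vals["mania"]))
    return records
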