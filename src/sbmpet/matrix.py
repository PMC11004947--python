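"""Cohort vectorization: masked volumes -> subjects x voxels matrix, row demeaning.

Column ``j`` of the matrix always corresponds to ``mask.flat_index[j]``.
Only subject (row) means are ever removed — voxel means are kept, which is a
substantive modelling choice for the decomposition, not bookkeeping. Removed
means are retained so the original matrix can be reconstructed exactly.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass, replace
from pathlib import Path
from typing import Sequence

import numpy as np

from .volumes import ParametricVolume, VoxelMask


@dataclass
class SubjectMatrix:
    """Subjects x masked-voxels data matrix with demeaning bookkeeping."""

    data: np.ndarray
    row_means: np.ndarray
    subject_ids: list[str]
    mask: VoxelMask
    demeaned: bool

    def __post_init__(self) -> None:
        n, v = self.data.shape
        if n < 2:
            raise ValueError(f"need at least 2 subjects, got {n}")
        if v < n:
            raise ValueError(f"need at least as many voxels as subjects ({v} < {n})")
        if v != self.mask.n_voxels:
            raise ValueError(
                f"matrix has {v} columns but mask has {self.mask.n_voxels} voxels"
            )
        if len(self.subject_ids) != n:
            raise ValueError("subject_ids length does not match row count")

    @property
    def n_subjects(self) -> int:
        return self.data.shape[0]

    @property
    def n_voxels(self) -> int:
        return self.data.shape[1]


def vectorize_cohort(
    volumes: Sequence[ParametricVolume], mask: VoxelMask
) -> SubjectMatrix:
    """Flatten each subject's masked voxels into one row of an N x V matrix.

    Subjects enter in the order given (manifest order); raises if any volume
    carries non-finite values inside the mask, naming the subject.
    """
    rows = []
    ids = []
    for vol in volumes:
        if vol.grid_shape != mask.grid_shape:
            raise ValueError(
                f"grid mismatch: subject {vol.subject_id!r} has grid "
                f"{vol.grid_shape}, mask has {mask.grid_shape}"
            )
        row = mask.flatten(vol.values)
        bad = np.count_nonzero(~np.isfinite(row))
        if bad:
            raise ValueError(
                f"subject {vol.subject_id!r} has {bad} non-finite voxels inside the mask"
            )
        rows.append(row)
        ids.append(vol.subject_id)
    data = np.asarray(rows, dtype=np.float64)
    return SubjectMatrix(
        data=data,
        row_means=np.zeros(data.shape[0]),
        subject_ids=ids,
        mask=mask,
        demeaned=False,
    )


def demean_rows(m: SubjectMatrix) -> SubjectMatrix:
    """Subtract each subject's mean value; store the removed means."""
    if m.demeaned:
        raise ValueError("matrix is already row-demeaned")
    means = m.data.mean(axis=1)
    return replace(m, data=m.data - means[:, None], row_means=means, demeaned=True)


def unvectorize(m: SubjectMatrix, subject: int | str, fill: float = 0.0) -> ParametricVolume:
    """Restore one subject's row as a 3-D volume (row mean re-added if demeaned)."""
    if isinstance(subject, str):
        idx = m.subject_ids.index(subject)
    else:
        idx = subject
    row = m.data[idx] + (m.row_means[idx] if m.demeaned else 0.0)
    return ParametricVolume(
        values=m.mask.unflatten(row, fill=fill),
        voxel_size_mm=(1.0, 1.0, 1.0),
        subject_id=m.subject_ids[idx],
    )


def mask_hash(mask: VoxelMask) -> str:
    """Stable hash of a mask's support, used to guard matrix caches."""
    h = hashlib.sha256()
    h.update(np.asarray(mask.grid_shape, dtype=np.int64).tobytes())
    h.update(np.packbits(mask.included.ravel(order="C")).tobytes())
    return h.hexdigest()


def save_matrix(m: SubjectMatrix, path: str | Path) -> None:
    """Cache a subject matrix to disk (npz with ids, mask and demeaning state)."""
    np.savez_compressed(
        Path(path),
        data=m.data,
        row_means=m.row_means,
        subject_ids=np.asarray(m.subject_ids),
        mask_included=m.mask.included,
        demeaned=np.asarray(m.demeaned),
        mask_hash=np.asarray(mask_hash(m.mask)),
    )


def load_matrix(path: str | Path) -> SubjectMatrix:
    with np.load(Path(path), allow_pickle=False) as f:
        mask = VoxelMask(included=f["mask_included"])
        stored_hash = str(f["mask_hash"])
        if stored_hash != mask_hash(mask):
            raise ValueError(f"matrix cache {path} is corrupt: mask hash mismatch")
        return SubjectMatrix(
            data=f["data"],
            row_means=f["row_means"],
            subject_ids=[str(s) for s in f["subject_ids"]],
            mask=mask,
            demeaned=bool(f["demeaned"]),
        )
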