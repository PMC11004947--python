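"""Template-space parametric volumes, voxel masks, smoothing, and mask construction.

Volumes are plain 3-D scalar fields on a fixed grid with known voxel spacing,
stored/loaded as NIfTI-1 through nibabel. The :class:`VoxelMask` defines both
the analysis support and the canonical flattening order used everywhere
downstream (C order: last axis fastest), so matrix columns map reproducibly
back to voxels.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import nibabel as nib
import numpy as np
from scipy import ndimage

#: FWHM -> sigma conversion for a Gaussian kernel, 2*sqrt(2*ln 2).
FWHM_TO_SIGMA = 2.0 * np.sqrt(2.0 * np.log(2.0))


@dataclass
class ParametricVolume:
    """One subject's 3-D scalar field (e.g. a BP_ND or DVR map).

    Parameters
    ----------
    values : ndarray
        3-D array of voxel values.
    voxel_size_mm : tuple of float
        Positive voxel edge lengths in mm, one per axis.
    subject_id : str
        Identifier used for error reporting and manifest bookkeeping.
    quantity : {"BP_ND", "DVR", "arbitrary"}
        What the scalar field measures.
    """

    values: np.ndarray
    voxel_size_mm: tuple[float, float, float]
    subject_id: str = ""
    quantity: str = "arbitrary"

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=np.float64)
        if self.values.ndim != 3:
            raise ValueError(
                f"volume for {self.subject_id!r} is not a single 3-D volume "
                f"(got shape {self.values.shape})"
            )
        self.voxel_size_mm = tuple(float(s) for s in self.voxel_size_mm)
        if len(self.voxel_size_mm) != 3 or any(
            not np.isfinite(s) or s <= 0 for s in self.voxel_size_mm
        ):
            raise ValueError(f"invalid voxel spacing {self.voxel_size_mm}")
        if self.quantity not in ("BP_ND", "DVR", "arbitrary"):
            raise ValueError(f"unknown quantity {self.quantity!r}")

    @property
    def grid_shape(self) -> tuple[int, int, int]:
        return self.values.shape  # type: ignore[return-value]

    def with_values(self, values: np.ndarray, quantity: str | None = None) -> "ParametricVolume":
        """Copy of this volume with new values on the same grid."""
        return ParametricVolume(
            values=values,
            voxel_size_mm=self.voxel_size_mm,
            subject_id=self.subject_id,
            quantity=self.quantity if quantity is None else quantity,
        )


@dataclass
class VoxelMask:
    """Boolean analysis support plus the canonical voxel flattening order.

    ``flat_index`` enumerates included voxels in C order (last axis fastest);
    position ``j`` of any flattened vector always refers to the same voxel.
    """

    included: np.ndarray
    flat_index: np.ndarray = field(init=False)

    def __post_init__(self) -> None:
        self.included = np.asarray(self.included, dtype=bool)
        if self.included.ndim != 3:
            raise ValueError("mask must be 3-D")
        self.flat_index = np.flatnonzero(self.included.ravel(order="C"))
        if self.flat_index.size == 0:
            raise ValueError("empty mask: at least one voxel must be included")

    @property
    def grid_shape(self) -> tuple[int, int, int]:
        return self.included.shape  # type: ignore[return-value]

    @property
    def n_voxels(self) -> int:
        return int(self.flat_index.size)

    def flatten(self, values: np.ndarray) -> np.ndarray:
        """Extract masked voxels of a 3-D field as a 1-D vector in flat order."""
        values = np.asarray(values)
        if values.shape != self.included.shape:
            raise ValueError(
                f"grid mismatch: values {values.shape} vs mask {self.included.shape}"
            )
        return values.ravel(order="C")[self.flat_index]

    def unflatten(self, vector: np.ndarray, fill: float = 0.0) -> np.ndarray:
        """Place a flat vector back into a 3-D field; outside-mask voxels = fill."""
        vector = np.asarray(vector, dtype=np.float64)
        if vector.shape != (self.n_voxels,):
            raise ValueError(
                f"vector length {vector.shape} does not match mask size {self.n_voxels}"
            )
        out = np.full(int(np.prod(self.grid_shape)), fill, dtype=np.float64)
        out[self.flat_index] = vector
        return out.reshape(self.grid_shape)

    def voxel_coords(self) -> np.ndarray:
        """(V, 3) integer coordinates of included voxels, in flat order."""
        return np.stack(np.unravel_index(self.flat_index, self.grid_shape), axis=1)


def read_volume(path: str | Path, subject_id: str = "", quantity: str = "arbitrary") -> ParametricVolume:
    """Load a single 3-D volume from a NIfTI file.

    4-D images with a singleton fourth axis are squeezed; any other 4-D shape
    is rejected. Header voxel spacing is authoritative.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"volume file not found: {path}")
    img = nib.load(str(path))
    data = np.asanyarray(img.dataobj, dtype=np.float64)
    if data.ndim == 4 and data.shape[3] == 1:
        data = data[:, :, :, 0]
    if data.ndim != 3:
        raise ValueError(f"{path} is not a single 3-D volume (shape {data.shape})")
    zooms = img.header.get_zooms()[:3]
    if any(not np.isfinite(z) or z <= 0 for z in zooms):
        raise ValueError(f"{path} has non-finite or non-positive voxel spacing {zooms}")
    return ParametricVolume(
        values=data,
        voxel_size_mm=tuple(float(z) for z in zooms),
        subject_id=subject_id or path.stem.replace(".nii", ""),
        quantity=quantity,
    )


def write_volume(vol: ParametricVolume, path: str | Path) -> None:
    """Write a volume as NIfTI-1 (float64 on disk, so round-trips are exact)."""
    path = Path(path)
    if not path.parent.exists():
        raise FileNotFoundError(f"parent directory does not exist: {path.parent}")
    affine = np.diag(list(vol.voxel_size_mm) + [1.0])
    img = nib.Nifti1Image(vol.values.astype(np.float64), affine)
    img.header.set_zooms(vol.voxel_size_mm)
    nib.save(img, str(path))


def read_mask(path: str | Path) -> VoxelMask:
    """Load a binary mask volume (non-zero = included)."""
    vol = read_volume(path)
    return VoxelMask(included=vol.values != 0)


def write_mask(mask: VoxelMask, path: str | Path, voxel_size_mm: Sequence[float] = (1.0, 1.0, 1.0)) -> None:
    vol = ParametricVolume(
        values=mask.included.astype(np.float64), voxel_size_mm=tuple(voxel_size_mm)
    )
    write_volume(vol, path)


def gaussian_smooth(vol: ParametricVolume, fwhm_mm: float) -> ParametricVolume:
    """Smooth a volume with an isotropic (in mm) Gaussian kernel.

    The per-axis sigma in voxel units is ``fwhm_mm / (voxel_size_mm * 2*sqrt(2 ln 2))``.
    Boundaries are reflective (mirror), so constant fields are preserved
    exactly and the output range never escapes the input range.
    """
    if fwhm_mm < 0:
        raise ValueError(f"fwhm_mm must be non-negative, got {fwhm_mm}")
    if fwhm_mm == 0:
        return vol.with_values(vol.values.copy())
    sigma_vox = [fwhm_mm / (s * FWHM_TO_SIGMA) for s in vol.voxel_size_mm]
    smoothed = ndimage.gaussian_filter(vol.values, sigma=sigma_vox, mode="mirror")
    return vol.with_values(smoothed)


def build_mask(
    volumes: Sequence[ParametricVolume],
    mode: str = "relative_mean",
    supplied: VoxelMask | None = None,
    fraction: float = 0.3,
) -> VoxelMask:
    """Build or validate the whole-brain analysis mask.

    ``mode="supplied"`` validates a user mask against the cohort grid and
    returns it. ``mode="relative_mean"`` includes voxels whose cross-subject
    mean exceeds ``fraction`` times the mean over voxels with positive
    cross-subject mean — a simple, reproducible intensity rule.
    """
    if not volumes:
        raise ValueError("no volumes given")
    shape = volumes[0].grid_shape
    for v in volumes[1:]:
        if v.grid_shape != shape:
            raise ValueError(
                f"grid mismatch: {v.subject_id!r} has shape {v.grid_shape}, expected {shape}"
            )
    if mode == "supplied":
        if supplied is None:
            raise ValueError("mode='supplied' requires a mask")
        if supplied.grid_shape != shape:
            raise ValueError(
                f"supplied mask shape {supplied.grid_shape} does not match volumes {shape}"
            )
        return supplied
    if mode != "relative_mean":
        raise ValueError(f"unknown mask mode {mode!r}")
    if not 0.0 < fraction < 1.0:
        raise ValueError(f"fraction must be in (0, 1), got {fraction}")
    mean_vol = np.mean([v.values for v in volumes], axis=0)
    positive = mean_vol > 0
    if not positive.any():
        raise ValueError("empty mask: no voxel has positive cross-subject mean")
    threshold = fraction * mean_vol[positive].mean()
    included = mean_vol > threshold
    if not included.any():
        raise ValueError("empty mask: no voxel exceeds the relative-mean threshold")
    return VoxelMask(included=included)
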