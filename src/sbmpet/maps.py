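"""Z-scaling of spatial sources and suprathreshold cluster extraction.

Each source row is scaled to zero mean / unit population SD over the mask
(a "Z map"), thresholded at |Z| > z_threshold, and the positive and negative
excursion sets are labelled separately into connected components. Clusters
smaller than ``min_size`` are dropped and the survivors reported ordered by
descending |peak Z| — the conventional cluster-table layout.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import ndimage

from .volumes import ParametricVolume, VoxelMask

_CONNECTIVITY_RANK = {6: 1, 18: 2, 26: 3}


@dataclass
class Cluster:
    source_index: int
    sign: str  # "positive" | "negative"
    peak_z: float  # signed; |peak_z| > threshold
    size_voxels: int
    peak_location: tuple[int, int, int]
    label: str | None = None


@dataclass
class ClusterTable:
    """Suprathreshold clusters of one source, ordered by descending |peak Z|."""

    source_index: int
    z_threshold: float
    min_size: int
    connectivity: int
    clusters: list[Cluster] = field(default_factory=list)

    def __len__(self) -> int:
        return len(self.clusters)

    def to_dataframe(self) -> pd.DataFrame:
        rows = [
            {
                "source": c.source_index,
                "sign": c.sign,
                "peak_z": c.peak_z,
                "size_voxels": c.size_voxels,
                "peak_i": c.peak_location[0],
                "peak_j": c.peak_location[1],
                "peak_k": c.peak_location[2],
                "label": c.label if c.label is not None else "",
            }
            for c in self.clusters
        ]
        return pd.DataFrame(
            rows,
            columns=[
                "source", "sign", "peak_z", "size_voxels",
                "peak_i", "peak_j", "peak_k", "label",
            ],
        )


def zscale_source(source_row: np.ndarray, mask: VoxelMask, voxel_size_mm=(1.0, 1.0, 1.0)) -> ParametricVolume:
    """Scale a flat source vector to mean 0, population SD 1, as a 3-D Z map.

    Outside-mask voxels are 0. Uses the population SD (divide by V) for
    bit-reproducibility.
    """
    source_row = np.asarray(source_row, dtype=np.float64)
    if source_row.shape != (mask.n_voxels,):
        raise ValueError(
            f"source length {source_row.shape} does not match mask ({mask.n_voxels})"
        )
    sd = source_row.std()  # population SD
    if sd == 0:
        raise ValueError("zero-variance source cannot be Z-scaled")
    z = (source_row - source_row.mean()) / sd
    return ParametricVolume(
        values=mask.unflatten(z, fill=0.0),
        voxel_size_mm=tuple(voxel_size_mm),
        quantity="arbitrary",
    )


def _labelled_clusters(
    excursion: np.ndarray,
    zvals: np.ndarray,
    source_index: int,
    sign: str,
    min_size: int,
    structure: np.ndarray,
    atlas: np.ndarray | None,
) -> list[Cluster]:
    labels, n = ndimage.label(excursion, structure=structure)
    clusters: list[Cluster] = []
    if n == 0:
        return clusters
    sizes = np.bincount(labels.ravel())[1:]
    # peak = extreme value of the signed Z within each component
    extremum = ndimage.maximum if sign == "positive" else ndimage.minimum
    peaks = np.atleast_1d(extremum(zvals, labels, index=np.arange(1, n + 1)))
    for comp in range(1, n + 1):
        size = int(sizes[comp - 1])
        if size < min_size:
            continue
        peak_z = float(peaks[comp - 1])
        inside = labels == comp
        candidates = np.argwhere(inside & (zvals == peak_z))
        loc = tuple(int(c) for c in candidates[0])
        label = None
        if atlas is not None:
            label = str(atlas[loc])
        clusters.append(
            Cluster(
                source_index=source_index,
                sign=sign,
                peak_z=peak_z,
                size_voxels=size,
                peak_location=loc,  # type: ignore[arg-type]
                label=label,
            )
        )
    return clusters


def extract_clusters(
    zmap: ParametricVolume,
    mask: VoxelMask,
    z_threshold: float = 3.0,
    min_size: int = 500,
    connectivity: int = 26,
    source_index: int = 0,
    atlas: np.ndarray | None = None,
) -> ClusterTable:
    """Label the positive and negative |Z| excursion sets into clusters.

    Positive ({Z > thr}) and negative ({Z < -thr}) sets are labelled
    separately under the declared connectivity (6 = faces, 18 = +edges,
    26 = +vertices); components below ``min_size`` voxels are discarded.
    An optional atlas (integer or string 3-D array on the same grid) attaches
    the label of the peak voxel to each cluster.
    """
    if z_threshold <= 0:
        raise ValueError("z_threshold must be positive")
    if min_size < 1:
        raise ValueError("min_size must be >= 1")
    if connectivity not in _CONNECTIVITY_RANK:
        raise ValueError(f"connectivity must be one of {sorted(_CONNECTIVITY_RANK)}")
    if zmap.grid_shape != mask.grid_shape:
        raise ValueError("zmap and mask grids differ")
    structure = ndimage.generate_binary_structure(3, _CONNECTIVITY_RANK[connectivity])
    zvals = zmap.values
    supported = mask.included
    clusters = _labelled_clusters(
        (zvals > z_threshold) & supported, zvals, source_index, "positive",
        min_size, structure, atlas,
    )
    clusters += _labelled_clusters(
        (zvals < -z_threshold) & supported, zvals, source_index, "negative",
        min_size, structure, atlas,
    )
    clusters.sort(key=lambda c: -abs(c.peak_z))
    return ClusterTable(
        source_index=source_index,
        z_threshold=z_threshold,
        min_size=min_size,
        connectivity=connectivity,
        clusters=clusters,
    )


def report_components(
    decomposition,
    mask: VoxelMask,
    z_threshold: float = 3.0,
    min_size: int = 500,
    connectivity: int = 26,
    voxel_size_mm=(1.0, 1.0, 1.0),
    atlas: np.ndarray | None = None,
) -> tuple[list[ClusterTable], list[ParametricVolume]]:
    """Z-scale every source, extract its clusters, and return maps + tables."""
    tables: list[ClusterTable] = []
    zmaps: list[ParametricVolume] = []
    for k in range(decomposition.sources.shape[0]):
        zmap = zscale_source(decomposition.sources[k], mask, voxel_size_mm)
        zmap.subject_id = f"source_{k:02d}"
        table = extract_clusters(
            zmap, mask, z_threshold=z_threshold, min_size=min_size,
            connectivity=connectivity, source_index=k, atlas=atlas,
        )
        tables.append(table)
        zmaps.append(zmap)
    return tables, zmaps


def combined_cluster_table(tables: list[ClusterTable]) -> pd.DataFrame:
    """Stack per-source tables; only sources with surviving clusters appear."""
    frames = [t.to_dataframe() for t in tables if len(t)]
    if not frames:
        return ClusterTable(0, 0.0, 1, 26).to_dataframe()
    return pd.concat(frames, ignore_index=True)
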