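"""Synthetic DVR cohorts with planted spatial sources and known ground truth.

The generator emulates the statistical structure of a multi-subject
synaptic-density PET study: a baseline DVR field near 1 on a brain-shaped
mask (with a cerebellum-like reference region fixed at exactly 1), a small
set of smooth, approximately decorrelated spatial sources mixed by
per-subject loading weights, group-level shifts in selected loadings
(AD < MCI < CN), additive voxel noise, and cognitive scores monotonically
linked to selected loadings. Everything is reproducible from a single seed.

Planted sources are unit-SD, zero-mean over the mask and exactly zero inside
the reference region, so the reference mean DVR stays at 1 up to noise.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import json
import numpy as np
import pandas as pd
from scipy import ndimage

from .volumes import FWHM_TO_SIGMA, ParametricVolume, VoxelMask, write_mask, write_volume

GEOMETRIES = ("focal_blobs", "bilateral_blobs", "mixed_sign", "medial")

#: natural-scale mapping for each cognitive score: (offset, scale, step, lo, hi)
#: value = clip(round_to_step(offset + scale * z), lo, hi)
SCORE_SCALES = {
    "mmse": (24.0, 2.5, 1.0, 0.0, 30.0),
    "cdr_sb": (3.0, 1.5, 0.5, 0.0, None),
    "lmii": (8.0, 4.0, 1.0, 0.0, None),
    "ravlt_delay": (6.0, 3.0, 1.0, 0.0, None),
}


@dataclass(frozen=True)
class ScoreLink:
    """Monotone link from one planted source's loadings to a cognitive score."""

    source: int
    slope: float  # loading-SD per score-SD
    noise_sd: float  # score noise, in score-SD units


@dataclass
class CohortConfig:
    """Study conditions for a synthetic cohort.

    Defaults mirror a three-group clinical SV2A-PET cohort at desk scale:
    32^3 grid at 2 mm, four planted sources with distinct geometries, a
    1.0-loading-SD CN->AD shift (MCI intermediate at 0.5) on the first
    source, DVR amplitude 0.05 per loading-SD and voxel noise SD 0.03, and
    an MMSE-like score (plus an inverted CDR-like score) linked to the first
    source's loadings with slope 1 and score noise SD 0.5.
    """

    grid_shape: tuple[int, int, int] = (32, 32, 32)
    voxel_size_mm: tuple[float, float, float] = (2.0, 2.0, 2.0)
    k_true: int = 4
    geometries: tuple[str, ...] = ("mixed_sign", "bilateral_blobs", "focal_blobs", "medial")
    smoothness_fwhm_mm: float = 12.0
    amplitude: float = 0.05
    noise_sd: float = 0.03
    #: per-source (CN, MCI, AD) mean loading offsets in loading-SD units
    group_shifts: tuple[tuple[float, float, float], ...] = (
        (1.0, 0.5, 0.0), (0.0, 0.0, 0.0), (0.0, 0.0, 0.0), (0.0, 0.0, 0.0),
    )
    score_links: dict = field(default_factory=lambda: {
        "mmse": ScoreLink(source=0, slope=1.0, noise_sd=0.5),
        "cdr_sb": ScoreLink(source=0, slope=-1.0, noise_sd=0.5),
    })
    n_per_group: tuple[int, int, int] = (19, 14, 24)  # CN, MCI, AD
    max_pairwise_corr: float = 0.2


@dataclass
class SyntheticTruth:
    """Ground-truth manifest of one generated cohort."""

    sources_true: np.ndarray  # K_true x V, unit SD, zero mean over mask
    loadings_true: np.ndarray  # N x K_true
    brain_mask: VoxelMask
    reference_mask: VoxelMask
    baseline: ParametricVolume
    config: CohortConfig
    seed: int


def default_brain_geometry(
    grid_shape: tuple[int, int, int] = (32, 32, 32)
) -> tuple[VoxelMask, VoxelMask]:
    """Ellipsoidal brain mask with a spherical cerebellum-like reference region.

    Both are symmetric about the first-axis midline so mirrored (bilateral)
    sources remain symmetric after reference zeroing.
    """
    nx, ny, nz = grid_shape
    ii, jj, kk = np.meshgrid(
        np.arange(nx), np.arange(ny), np.arange(nz), indexing="ij"
    )
    cx, cy, cz = (nx - 1) / 2.0, (ny - 1) / 2.0, (nz - 1) / 2.0 + 1.0
    rx, ry, rz = 0.42 * nx, 0.42 * ny, 0.36 * nz
    brain = ((ii - cx) / rx) ** 2 + ((jj - cy) / ry) ** 2 + ((kk - cz) / rz) ** 2 <= 1.0
    ref_center = (cx, (ny - 1) / 3.0, (nz - 1) / 4.0)
    ref_radius = 0.13 * min(grid_shape)
    ref = (
        (ii - ref_center[0]) ** 2
        + (jj - ref_center[1]) ** 2
        + (kk - ref_center[2]) ** 2
    ) <= ref_radius**2
    ref &= brain
    return VoxelMask(included=brain), VoxelMask(included=ref)


def _blob(coords_mm: np.ndarray, center_mm: np.ndarray, sigma_mm: float) -> np.ndarray:
    d2 = np.sum((coords_mm - center_mm) ** 2, axis=1)
    return np.exp(-d2 / (2.0 * sigma_mm**2))


def make_sources(
    grid_shape: tuple[int, int, int],
    mask: VoxelMask,
    k: int,
    geometries: Sequence[str],
    smoothness_fwhm_mm: float,
    seed: int,
    voxel_size_mm: tuple[float, float, float] = (2.0, 2.0, 2.0),
    exclude: VoxelMask | None = None,
    max_pairwise_corr: float = 0.2,
    max_retries: int = 200,
) -> np.ndarray:
    """Plant K smooth spatial sources on the mask, one geometry each.

    Geometries: ``focal_blobs`` (one Gaussian blob), ``bilateral_blobs``
    (blob mirrored across the first-axis midline), ``mixed_sign`` (one
    positive and one distant negative blob), ``medial`` (focal blob pinned
    to the midline). Sources are zeroed inside ``exclude`` (the reference
    region), mean-centred over the remaining mask and scaled to unit
    population SD over the whole mask. Placement is re-drawn until all
    pairwise spatial correlations satisfy ``|r| <= max_pairwise_corr``.
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    for g in geometries:
        if g not in GEOMETRIES:
            raise ValueError(f"unknown geometry {g!r}; choose from {GEOMETRIES}")
    rng = np.random.default_rng(seed)
    sigma_mm = smoothness_fwhm_mm / FWHM_TO_SIGMA
    sigma_vox = sigma_mm / min(voxel_size_mm)

    allowed = mask.included.copy()
    if exclude is not None:
        grown = ndimage.binary_dilation(exclude.included, iterations=int(np.ceil(sigma_vox)))
        allowed &= ~grown
    # keep blob centres a blob-width away from the mask boundary
    margin = max(1, int(round(sigma_vox)))
    allowed = ndimage.binary_erosion(allowed, iterations=margin)
    centers_all = np.argwhere(allowed)
    if centers_all.size == 0:
        raise ValueError("no admissible blob centres: blobs do not fit inside the mask")

    vox = np.asarray(voxel_size_mm)
    coords_mm = mask.voxel_coords() * vox
    nx = grid_shape[0]
    midline_mm = (nx - 1) / 2.0 * vox[0]

    ref_flat_zero = None
    if exclude is not None:
        inside_ref = exclude.included.ravel(order="C")[mask.flat_index]
        ref_flat_zero = inside_ref

    def _standardize(b: np.ndarray) -> np.ndarray:
        out = b.copy()
        if ref_flat_zero is not None:
            keep = ~ref_flat_zero
            out[keep] -= out[keep].mean()
            out[ref_flat_zero] = 0.0
        else:
            out -= out.mean()
        sd = out.std()
        if sd == 0:
            raise ValueError("degenerate (constant) planted source")
        return out / sd

    def _draw_center(medial: bool = False, lateral: bool = False) -> np.ndarray:
        pool = centers_all
        if medial:
            sel = np.abs(pool[:, 0] - (nx - 1) / 2.0) <= max(1.5, sigma_vox / 2)
            if sel.any():
                pool = pool[sel]
        if lateral:
            sel = pool[:, 0] < (nx - 1) / 2.0 - sigma_vox / 2
            if sel.any():
                pool = pool[sel]
        return pool[rng.integers(len(pool))] * vox

    def _one_source(geometry: str) -> np.ndarray:
        if geometry == "focal_blobs":
            b = _blob(coords_mm, _draw_center(), sigma_mm)
        elif geometry == "medial":
            b = _blob(coords_mm, _draw_center(medial=True), sigma_mm)
        elif geometry == "bilateral_blobs":
            c = _draw_center(lateral=True)
            mirrored = c.copy()
            mirrored[0] = 2.0 * midline_mm - c[0]
            b = _blob(coords_mm, c, sigma_mm) + _blob(coords_mm, mirrored, sigma_mm)
        elif geometry == "mixed_sign":
            c1 = _draw_center()
            # prefer centres >= 4 sigma apart; on cramped masks take the
            # farthest draw (never the same centre twice)
            best, best_d = None, -1.0
            for _ in range(50):
                c2 = _draw_center()
                d = float(np.linalg.norm(c2 - c1))
                if d > best_d:
                    best, best_d = c2, d
                if d >= 4.0 * sigma_mm:
                    break
            if best is None or best_d <= 0:
                raise RuntimeError("mask too small for a mixed-sign source")
            b = _blob(coords_mm, c1, sigma_mm) - _blob(coords_mm, best, sigma_mm)
        else:  # pragma: no cover - guarded above
            raise ValueError(geometry)
        return _standardize(b)

    sources: list[np.ndarray] = []
    for idx in range(k):
        geometry = geometries[idx % len(geometries)]
        for attempt in range(max_retries):
            cand = _one_source(geometry)
            corrs = [abs(np.corrcoef(cand, s)[0, 1]) for s in sources]
            if all(c <= max_pairwise_corr for c in corrs):
                sources.append(cand)
                break
        else:
            raise RuntimeError(
                f"could not place source {idx} ({geometry}) with pairwise "
                f"|r| <= {max_pairwise_corr} after {max_retries} retries"
            )
    return np.asarray(sources)


def _natural_scale(name: str, z: np.ndarray) -> np.ndarray:
    offset, scale, step, lo, hi = SCORE_SCALES[name]
    val = offset + scale * z
    val = np.round(val / step) * step
    if lo is not None:
        val = np.maximum(val, lo)
    if hi is not None:
        val = np.minimum(val, hi)
    return val


def make_cohort(
    config: CohortConfig | None = None,
    seed: int = 0,
    n_per_group: tuple[int, int, int] | None = None,
) -> tuple[list[ParametricVolume], pd.DataFrame, SyntheticTruth]:
    """Generate volumes, a metadata table, and the ground-truth manifest.

    Each subject's volume is ``baseline + amplitude * sum_k loading[i,k] *
    source_k + noise`` inside the brain mask (0 outside); loadings are
    ``group_shift + N(0,1)``; scores come from the configured monotone links
    mapped onto each score's natural range (MMSE integer 0-30, CDR-sb
    non-negative halves, memory scores non-negative integers).
    """
    config = config or CohortConfig()
    npg = n_per_group or config.n_per_group
    if len(npg) != 3 or any(n < 1 for n in npg):
        raise ValueError(f"invalid group sizes {npg}")
    if config.noise_sd < 0 or config.amplitude <= 0:
        raise ValueError("noise_sd must be >= 0 and amplitude > 0")
    if len(config.group_shifts) != config.k_true:
        raise ValueError("group_shifts must have one (CN, MCI, AD) triple per source")

    rng = np.random.default_rng(seed)
    brain, ref = default_brain_geometry(config.grid_shape)
    sources = make_sources(
        config.grid_shape,
        brain,
        config.k_true,
        config.geometries,
        config.smoothness_fwhm_mm,
        seed=int(rng.integers(2**31 - 1)),
        voxel_size_mm=config.voxel_size_mm,
        exclude=ref,
        max_pairwise_corr=config.max_pairwise_corr,
    )

    groups = ["CN"] * npg[0] + ["MCI"] * npg[1] + ["AD"] * npg[2]
    n = len(groups)
    shifts = np.asarray(config.group_shifts, dtype=np.float64)  # K x 3
    group_idx = np.array([("CN", "MCI", "AD").index(g) for g in groups])
    loadings = shifts[:, group_idx].T + rng.standard_normal((n, config.k_true))

    baseline_field = np.where(brain.included, 1.0, 0.0)
    baseline = ParametricVolume(
        values=baseline_field, voxel_size_mm=config.voxel_size_mm,
        subject_id="baseline", quantity="DVR",
    )
    signal = loadings @ sources  # N x V, DVR units after amplitude
    volumes: list[ParametricVolume] = []
    for i, g in enumerate(groups):
        vals = baseline_field.copy()
        flat = brain.flatten(vals)
        flat = flat + config.amplitude * signal[i]
        if config.noise_sd > 0:
            flat = flat + rng.normal(0.0, config.noise_sd, size=flat.size)
        vals = brain.unflatten(flat, fill=0.0)
        volumes.append(
            ParametricVolume(
                values=vals, voxel_size_mm=config.voxel_size_mm,
                subject_id=f"sub-{i + 1:03d}", quantity="DVR",
            )
        )

    meta_rows: dict = {
        "subject_id": [v.subject_id for v in volumes],
        "group": groups,
    }
    for score in SCORE_SCALES:
        link = config.score_links.get(score)
        if link is not None:
            z = link.slope * loadings[:, link.source] + rng.normal(
                0.0, link.noise_sd, size=n
            )
        else:
            z = rng.standard_normal(n)
        meta_rows[score] = _natural_scale(score, z)
    meta = pd.DataFrame(meta_rows)

    truth = SyntheticTruth(
        sources_true=sources,
        loadings_true=loadings,
        brain_mask=brain,
        reference_mask=ref,
        baseline=baseline,
        config=config,
        seed=seed,
    )
    return volumes, meta, truth


def write_cohort(
    volumes: list[ParametricVolume],
    meta: pd.DataFrame,
    truth: SyntheticTruth,
    out_dir: str | Path,
) -> Path:
    """Write a generated cohort to disk: NIfTI volumes, manifest, truth files."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    vox = truth.config.voxel_size_mm
    paths = []
    for vol in volumes:
        p = out / f"{vol.subject_id}_dvr.nii.gz"
        write_volume(vol, p)
        paths.append(str(p))
    manifest = meta.copy()
    manifest.insert(1, "path", paths)
    manifest.to_csv(out / "manifest.csv", index=False)
    write_mask(truth.brain_mask, out / "brain_mask.nii.gz", vox)
    write_mask(truth.reference_mask, out / "cerebellum_mask.nii.gz", vox)
    for k in range(truth.sources_true.shape[0]):
        vol = ParametricVolume(
            values=truth.brain_mask.unflatten(truth.sources_true[k]),
            voxel_size_mm=vox, subject_id=f"true_source_{k:02d}",
        )
        write_volume(vol, out / f"true_source_{k:02d}.nii.gz")
    np.savetxt(
        out / "true_loadings.tsv", truth.loadings_true, delimiter="\t",
        header="\t".join(f"source_{k:02d}" for k in range(truth.sources_true.shape[0])),
        comments="",
    )
    truth_meta = {
        "seed": truth.seed,
        "k_true": truth.config.k_true,
        "geometries": list(truth.config.geometries),
        "amplitude": truth.config.amplitude,
        "noise_sd": truth.config.noise_sd,
        "group_shifts": [list(t) for t in truth.config.group_shifts],
        "score_links": {
            name: {"source": l.source, "slope": l.slope, "noise_sd": l.noise_sd}
            for name, l in truth.config.score_links.items()
        },
        "n_per_group": list(truth.config.n_per_group),
        "grid_shape": list(truth.config.grid_shape),
        "voxel_size_mm": list(vox),
    }
    (out / "truth.json").write_text(json.dumps(truth_meta, indent=2))
    return out
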