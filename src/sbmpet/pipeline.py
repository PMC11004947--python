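"""End-to-end analysis orchestration.

Order of stages follows the method: smooth -> mask -> vectorize -> row-demean
-> PCA -> Infomax ICA -> orientation -> Z maps / cluster tables -> group and
cognition statistics. :func:`analyze_cohort` is the in-memory core (used by
tests and simulations); :func:`run_pipeline` adds manifest/NIfTI I/O, the
optional BP_ND->DVR conversion, and a machine-readable run log from which a
run can be repeated exactly.
"""

from __future__ import annotations

import hashlib
import json
import time
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
import yaml

from . import maps, stats
from .decomposition import SbmDecomposition, infomax_ica, orient_sources, pca_reduce
from .dvr import ReferenceRegion, bp_to_dvr
from .matrix import demean_rows, vectorize_cohort
from .maps import ClusterTable
from .volumes import (
    ParametricVolume,
    VoxelMask,
    build_mask,
    gaussian_smooth,
    read_mask,
    read_volume,
    write_volume,
)


class ValidationError(ValueError):
    """Configuration or input contract violation (CLI exit code 2)."""


class NumericalError(RuntimeError):
    """Numerical failure during decomposition (CLI exit code 3)."""


@dataclass
class RunConfig:
    """Effective parameters of one analysis run.

    Defaults follow the method's stated values where it states them:
    8 mm smoothing, 18 components, |Z| > 3 with clusters > 500 voxels,
    significance at p < 0.05.
    """

    manifest: str = ""
    output_dir: str = "sbm_out"
    mask_path: str | None = None  # supplied mask; None -> relative_mean rule
    mask_fraction: float = 0.3
    dvr_conversion: bool = False
    cerebellum_mask_path: str | None = None
    fwhm_mm: float = 8.0
    n_components: int = 18
    seed: int = 0
    z_threshold: float = 3.0
    min_cluster_voxels: int = 500
    connectivity: int = 26
    q: float = 0.05
    cohort_analyses: tuple[str, ...] = ("groups", "cognition_symptomatic", "cognition_full")
    learning_rate: float | None = None
    max_iterations: int = 512
    tolerance: float = 1e-6
    extended_infomax: bool = False

    @classmethod
    def from_file(cls, path: str | Path, **overrides) -> "RunConfig":
        """Load a YAML/JSON config; explicit keyword overrides win (CLI flags)."""
        text = Path(path).read_text()
        try:  # JSON first: YAML 1.1 misreads exponent literals like 1e-06
            raw = json.loads(text)
        except json.JSONDecodeError:
            raw = yaml.safe_load(text) or {}
        if "config" in raw and isinstance(raw["config"], dict):  # run-log reuse
            raw = raw["config"]
        known = {f for f in cls.__dataclass_fields__}
        kwargs = {k: v for k, v in raw.items() if k in known}
        kwargs.update({k: v for k, v in overrides.items() if v is not None})
        for key in ("cohort_analyses",):
            if key in kwargs and isinstance(kwargs[key], list):
                kwargs[key] = tuple(kwargs[key])
        return cls(**kwargs)


@dataclass
class PipelineResult:
    """Everything one run produces, in memory."""

    decomposition: SbmDecomposition
    mask: VoxelMask
    subject_ids: list[str]
    cluster_tables: list[ClusterTable]
    zmaps: list[ParametricVolume]
    group_table: pd.DataFrame | None
    cognition_tables: dict[str, pd.DataFrame]
    config: RunConfig
    stage_seconds: dict = field(default_factory=dict)


def analyze_cohort(
    volumes: Sequence[ParametricVolume],
    metadata: pd.DataFrame | None,
    config: RunConfig,
    mask: VoxelMask | None = None,
) -> PipelineResult:
    """Run the full decomposition + statistics on in-memory volumes.

    ``mask=None`` builds the analysis mask from the smoothed cohort with the
    relative-mean rule. ``metadata=None`` skips the statistical battery.
    """
    timings: dict[str, float] = {}
    t0 = time.perf_counter()
    if len(volumes) < 2:
        raise ValidationError("need at least 2 subjects")
    if config.n_components > len(volumes) - 1:
        raise ValidationError(
            f"n_components={config.n_components} exceeds N-1={len(volumes) - 1} "
            "for a row-demeaned matrix"
        )

    smoothed = [gaussian_smooth(v, config.fwhm_mm) for v in volumes]
    timings["smooth"] = time.perf_counter() - t0

    t0 = time.perf_counter()
    if mask is None:
        mask = build_mask(smoothed, mode="relative_mean", fraction=config.mask_fraction)
    else:
        mask = build_mask(smoothed, mode="supplied", supplied=mask)
    timings["mask"] = time.perf_counter() - t0

    t0 = time.perf_counter()
    m = vectorize_cohort(smoothed, mask)
    m = demean_rows(m)
    timings["matrix"] = time.perf_counter() - t0

    t0 = time.perf_counter()
    try:
        pca = pca_reduce(m, config.n_components)
        d = infomax_ica(
            pca,
            seed=config.seed,
            learning_rate=config.learning_rate,
            max_iterations=config.max_iterations,
            tolerance=config.tolerance,
            extended=config.extended_infomax,
            demeaned_data=m.data,
        )
    except np.linalg.LinAlgError as exc:  # pragma: no cover
        raise NumericalError(f"decomposition failed: {exc}") from exc
    d = orient_sources(d)
    timings["decomposition"] = time.perf_counter() - t0

    t0 = time.perf_counter()
    tables, zmaps = maps.report_components(
        d,
        mask,
        z_threshold=config.z_threshold,
        min_size=config.min_cluster_voxels,
        connectivity=config.connectivity,
        voxel_size_mm=volumes[0].voxel_size_mm,
    )
    timings["maps"] = time.perf_counter() - t0

    group_table = None
    cognition: dict[str, pd.DataFrame] = {}
    if metadata is not None:
        t0 = time.perf_counter()
        meta = stats.validate_metadata(metadata, subject_ids=m.subject_ids)
        if "groups" in config.cohort_analyses:
            group_table = stats.run_group_analysis(d.mixing, meta, q=config.q)
        if "cognition_symptomatic" in config.cohort_analyses:
            cognition["symptomatic_only"] = stats.run_cognition_analysis(
                d.mixing, meta, cohort="symptomatic_only", q=config.q
            )
        if "cognition_full" in config.cohort_analyses:
            cognition["full"] = stats.run_cognition_analysis(
                d.mixing, meta, cohort="full", q=config.q
            )
        timings["stats"] = time.perf_counter() - t0

    return PipelineResult(
        decomposition=d,
        mask=mask,
        subject_ids=m.subject_ids,
        cluster_tables=tables,
        zmaps=zmaps,
        group_table=group_table,
        cognition_tables=cognition,
        config=config,
        stage_seconds=timings,
    )


def _file_sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def load_manifest(path: str | Path) -> pd.DataFrame:
    """Read the cohort manifest (CSV/TSV with subject_id, path, group, scores)."""
    path = Path(path)
    if not path.exists():
        raise ValidationError(f"manifest not found: {path}")
    sep = "\t" if path.suffix in (".tsv", ".txt") else ","
    manifest = pd.read_csv(path, sep=sep)
    required = {"subject_id", "path"}
    if not required.issubset(manifest.columns):
        raise ValidationError(f"manifest must have columns {sorted(required)}")
    return manifest


def run_pipeline(config: RunConfig) -> Path:
    """Run the full analysis from a manifest on disk; returns the output dir.

    Writes per-source Z maps (NIfTI), the mixing matrix and cluster/statistics
    tables (TSV), and ``run_log.json`` capturing every effective parameter,
    input hashes, per-stage wall time and convergence diagnostics. Re-running
    with ``--config run_log.json`` reproduces the run.
    """
    wall_start = time.time()
    manifest = load_manifest(config.manifest)
    manifest_dir = Path(config.manifest).parent

    def _resolve(p: str) -> Path:
        q = Path(p)
        return q if q.is_absolute() else (manifest_dir / q)

    volumes = []
    input_hashes = {}
    for _, row in manifest.iterrows():
        p = _resolve(str(row["path"]))
        quantity = "BP_ND" if config.dvr_conversion else "DVR"
        vol = read_volume(p, subject_id=str(row["subject_id"]), quantity=quantity)
        input_hashes[str(row["subject_id"])] = _file_sha256(p)
        volumes.append(vol)

    if config.dvr_conversion:
        if not config.cerebellum_mask_path:
            raise ValidationError("dvr_conversion=True requires cerebellum_mask_path")
        ref = ReferenceRegion(mask=read_mask(_resolve(config.cerebellum_mask_path)))
        volumes = [bp_to_dvr(v, ref) for v in volumes]

    mask = None
    if config.mask_path:
        mask = read_mask(_resolve(config.mask_path))

    metadata = manifest.drop(columns=["path"]) if "group" in manifest.columns else None
    result = analyze_cohort(volumes, metadata, config, mask=mask)

    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    vox = volumes[0].voxel_size_mm
    for k, zmap in enumerate(result.zmaps):
        write_volume(zmap, out / f"source_{k:02d}_zmap.nii.gz")
    if config.dvr_conversion:
        for vol in volumes:
            write_volume(vol, out / f"{vol.subject_id}_dvr.nii.gz")
    mask_vol = ParametricVolume(
        values=result.mask.included.astype(np.float64), voxel_size_mm=vox
    )
    write_volume(mask_vol, out / "analysis_mask.nii.gz")

    mixing = pd.DataFrame(
        result.decomposition.mixing,
        index=pd.Index(result.subject_ids, name="subject_id"),
        columns=[f"source_{k:02d}" for k in range(result.decomposition.n_components)],
    )
    mixing.to_csv(out / "mixing.tsv", sep="\t")
    maps.combined_cluster_table(result.cluster_tables).to_csv(
        out / "clusters.tsv", sep="\t", index=False
    )
    if result.group_table is not None:
        result.group_table.to_csv(out / "group_stats.tsv", sep="\t", index=False)
    for name, table in result.cognition_tables.items():
        table.to_csv(out / f"cognition_{name}.tsv", sep="\t", index=False)

    d = result.decomposition
    log = {
        "config": asdict(config),
        "n_subjects": len(volumes),
        "n_masked_voxels": result.mask.n_voxels,
        "input_sha256": input_hashes,
        "convergence": {
            "converged": d.converged,
            "n_iterations": d.n_iterations,
            "reconstruction_rmse": d.reconstruction_rmse,
            "seed": d.seed,
        },
        "explained_variance_fraction": d.pca.explained_variance_fraction.tolist(),
        "stage_seconds": result.stage_seconds,
        "total_seconds": time.time() - wall_start,
    }
    (out / "run_log.json").write_text(json.dumps(log, indent=2, default=str))
    return out
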