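"""End-to-end pipeline: simulate -> extract -> grid -> score -> GLM -> report.

Every artifact is written under one run directory with a JSON run manifest
carrying the seed and a hash of the configuration, so a run is exactly
reproducible from (config, seed).
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import nibabel as nib
import numpy as np

from . import atlas as atlas_mod
from .atlas import WHOLE_GREY_MATTER, ParcellationAtlas, build_toy_atlas, infer_structure, load_atlas, save_atlas
from .cohort import default_ageing_model, preset, simulate_cohort, write_cohort
from .extraction import build_uptake_matrix, save_uptake_matrix, scale_volumes_by_reference
from .glm import build_design_matrix, run_glm, significant_volume_report
from .grid import compute_correlation_grid, save_grid, summarize_reference
from .scoring import select_references


@dataclass
class PipelineConfig:
    """Everything one run needs; serializable to/from plain dicts (TOML/JSON)."""

    out_dir: str
    seed: int = 0
    preset: str = "digital"
    # toy atlas parameters (used when no labelmap path is given)
    grid_shape: tuple[int, int, int] = (32, 40, 32)
    voxel_size_mm: tuple[float, float, float] = (4.0, 4.0, 4.0)
    n_regions: int = 12
    atlas_labelmap: str | None = None
    atlas_lookup: str | None = None
    # ageing model
    slope_range: tuple[float, float] = (-0.007, -0.002)
    flat_regions: tuple[str, ...] = ("Pons",)
    # cohort overrides (noise_sd, global_factor_sd, n_subjects, ...)
    cohort_overrides: dict = field(default_factory=dict)
    # scoring
    selection_threshold: float = -0.5
    # GLM
    glm_references: tuple[str, ...] = ("Pons", WHOLE_GREY_MATTER)
    alpha: float = 0.05
    n_perm: int = 500
    connectivity: int = 26
    fixed_t: float | None = None

    @classmethod
    def from_dict(cls, d: dict) -> "PipelineConfig":
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(d) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        d = dict(d)
        for key in ("grid_shape", "voxel_size_mm", "slope_range", "flat_regions", "glm_references"):
            if key in d:
                d[key] = tuple(d[key])
        return cls(**d)

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        for key, val in d.items():
            if isinstance(val, tuple):
                d[key] = list(val)
        return d

    def config_hash(self) -> str:
        return hashlib.sha256(
            json.dumps(self.to_dict(), sort_keys=True).encode()
        ).hexdigest()[:16]


def _write_json(path: Path, payload: dict) -> None:
    path.write_text(json.dumps(payload, indent=2, sort_keys=True) + "\n")


def _resolve_atlas(config: PipelineConfig) -> ParcellationAtlas:
    if config.atlas_labelmap is not None:
        if config.atlas_lookup is None:
            raise ValueError("atlas_lookup is required when atlas_labelmap is given")
        return load_atlas(config.atlas_labelmap, config.atlas_lookup)
    return build_toy_atlas(
        config.grid_shape, config.voxel_size_mm, config.n_regions, seed=config.seed
    )


def run_pipeline(config: PipelineConfig) -> dict:
    """Execute all stages; returns (and writes) the run manifest."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)

    atlas = _resolve_atlas(config)
    save_atlas(atlas, out / "atlas_labels.nii", out / "atlas_lookup.tsv")

    cohort_cfg = preset(config.preset, seed=config.seed, **config.cohort_overrides)
    model = default_ageing_model(
        atlas.region_names,
        seed=config.seed,
        slope_range=config.slope_range,
        flat_regions=config.flat_regions,
        reference_age=cohort_cfg.age_mean,
    )
    cohort, _, volumes = simulate_cohort(atlas, model, cohort_cfg)
    manifest_path = write_cohort(cohort, volumes, atlas, out / "cohort")

    matrix = build_uptake_matrix(manifest_path, atlas)
    save_uptake_matrix(matrix, out / "uptake_matrix.tsv")

    corr_grid = compute_correlation_grid(matrix)
    save_grid(corr_grid, out / "correlation_grid.tsv")
    summary = summarize_reference(corr_grid, system_label=config.preset)
    summary.to_frame().to_csv(out / "reference_summary.tsv", sep="\t", index=False, float_format="%.17g")

    selection = select_references(summary, threshold=config.selection_threshold)
    _write_json(
        out / "selection.json",
        {
            "threshold": selection.threshold,
            "selected_regions": selection.selected_regions,
            "selected_structures": selection.selected_structures,
            "ranking": selection.ranking,
        },
    )

    design = build_design_matrix(cohort)
    mask = atlas.brain_mask()
    results = {}
    affine = np.diag(list(atlas.voxel_size_mm) + [1.0])
    for ref in config.glm_references:
        scaled = scale_volumes_by_reference(volumes, atlas, ref)
        res = run_glm(
            scaled,
            design,
            mask,
            atlas.voxel_size_mm,
            alpha=config.alpha,
            n_perm=config.n_perm,
            seed=config.seed,
            connectivity=config.connectivity,
            fixed_t=config.fixed_t,
        )
        results[ref] = res
        tag = ref.replace(" ", "_").replace("-", "_")
        nib.save(
            nib.Nifti1Image(res.tmap.astype(np.float32), affine),
            str(out / f"tmap_{tag}.nii"),
        )
        res.cluster_frame().to_csv(out / f"clusters_{tag}.tsv", sep="\t", index=False)

    report = significant_volume_report(results)
    report.to_csv(out / "report.tsv", sep="\t", index=False, float_format="%.17g")
    _write_json(
        out / "report.json",
        {
            row["reference"]: {
                "total_significant_mm3": row["total_significant_mm3"],
                "t_max": row["t_max"],
                "threshold_t": row["threshold_t"],
                "n_clusters": int(row["n_clusters"]),
                "fold_of_best_vs_this": row["fold_of_best_vs_this"],
            }
            for _, row in report.iterrows()
        },
    )

    run_manifest = {
        "config": config.to_dict(),
        "config_hash": config.config_hash(),
        "seed": config.seed,
        "stages": ["simulate", "extract", "grid", "score", "glm", "report"],
        "artifacts": sorted(
            [p.name for p in out.iterdir() if p.is_file()] + ["run_manifest.json"]
        ),
    }
    _write_json(out / "run_manifest.json", run_manifest)
    return run_manifest
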