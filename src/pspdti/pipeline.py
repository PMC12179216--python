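"""End-to-end analysis: synthesis/ingest -> FA processing -> WBSS -> TOI/TFAS -> staging.

:class:`RunConfig` aggregates every tunable constant with the method's
defaults pre-filled (8-mm smoothing, FA floor 0.2, FDR alpha 0.05,
512-voxel cluster minimum, eigenvector scalar-product threshold 0.9,
0.5-mm tracking step, affectation offset 0.47). :func:`run_pipeline`
executes the stages in order, writes all result tables and masks to the
output directory, and is byte-reproducible for a fixed seed.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from . import dti, io, staging, synthetic, tract, wbss
from .errors import ConfigurationError, PspdtiError

logger = logging.getLogger("pspdti")


@dataclass
class RunConfig:
    """Parameters and paths for one pipeline run."""

    out_dir: str = "pspdti_out"
    # synthesis (used when no atlas/manifest paths are given)
    synthesize: bool = True
    n_controls: int = 20
    stage_counts: dict = field(default_factory=lambda: {1: 5, 2: 5, 3: 10})
    followup: float = 0.0
    grid_shape: tuple = synthetic.DEFAULT_GRID
    # real-data ingestion
    atlas_dir: str | None = None
    manifest_path: str | None = None
    volume_dir: str | None = None
    # processing parameters (method defaults)
    fwhm_mm: float = 8.0
    fa_floor: float = 0.2
    fdr_alpha: float = 0.05
    cluster_min_voxels: int = 512
    dot_threshold: float = 0.9
    step_mm: float = 0.5
    threshold_offset: float = 0.47
    seed: int = 0
    # toggles
    fast_fa_mode: bool = True
    score_scale: str = "shifted"  # or "raw_z"
    smooth: bool = True
    age_correction: bool = True
    save_volumes: bool = True

    def validate(self) -> None:
        if self.fwhm_mm <= 0 or self.step_mm <= 0:
            raise ConfigurationError("fwhm_mm and step_mm must be positive")
        if not 0 < self.fdr_alpha < 1:
            raise ConfigurationError("fdr_alpha must be in (0, 1)")
        if not 0 <= self.dot_threshold <= 1:
            raise ConfigurationError("dot_threshold must be in [0, 1]")
        if self.cluster_min_voxels < 1:
            raise ConfigurationError("cluster_min_voxels must be >= 1")
        if self.score_scale not in ("shifted", "raw_z"):
            raise ConfigurationError(f"unknown score scale {self.score_scale!r}")
        if not self.synthesize and (self.atlas_dir is None or self.manifest_path is None):
            raise ConfigurationError(
                "without synthesis, atlas_dir and manifest_path are required"
            )


@dataclass
class PipelineResult:
    """In-memory bundle of everything a run produced."""

    config: RunConfig
    atlas: synthetic.AtlasDefinition
    manifest: pd.DataFrame
    structure_table: pd.DataFrame
    wbss_result: wbss.WBSSResult
    reference: staging.ControlReference
    scores: list
    categories: list
    performance: pd.DataFrame
    category_summary: dict
    psprs_summary: pd.DataFrame | None
    longitudinal: staging.LongitudinalSummary | None


def _stage(name: str):
    """Decorator: surface any stage error with the failing stage's name."""

    def wrap(fn):
        def inner(*args, **kwargs):
            logger.info("stage %s: start", name)
            try:
                return fn(*args, **kwargs)
            except PspdtiError as exc:
                raise type(exc)(f"[stage {name}] {exc}") from exc

        return inner

    return wrap


def run_pipeline(config: RunConfig) -> PipelineResult:
    config.validate()
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    completion: list[str] = []
    run_log = {"schema_version": io.SCHEMA_VERSION, "parameters": _jsonable(asdict(config))}

    try:
        # --- inputs -------------------------------------------------------
        if config.synthesize:
            cohort = _stage("synth")(synthetic.simulate_cohort)(
                n_controls=config.n_controls,
                stage_counts=dict(config.stage_counts),
                followup=config.followup,
                seed=config.seed,
                grid_shape=config.grid_shape,
            )
            atlas, manifest = cohort.atlas, cohort.manifest
            maps = dict(cohort.fa_maps)
            control_ids, patient_ids = cohort.control_ids, cohort.patient_ids
            template_tensors = cohort.control_template_tensors()
        else:
            atlas = _stage("ingest")(io.load_atlas)(config.atlas_dir)
            manifest = io.load_manifest(config.manifest_path)
            maps = {}
            for _, row in manifest.iterrows():
                key = (str(row.subject_id), str(row.timepoint))
                path = Path(config.volume_dir) / f"{key[0]}_{key[1]}_fa.nii.gz"
                maps[key] = io.load_fa_map(path, subject_id=key[0], age=float(row.age))
            control_ids = sorted(set(manifest.loc[manifest.group == "control", "subject_id"]))
            patient_ids = sorted(set(manifest.loc[manifest.group == "psp", "subject_id"]))
            cohort = None
            template_tensors = None
        io.save_manifest(out / "manifest.csv", manifest)
        completion.append("inputs")

        # --- FA processing -------------------------------------------------
        keys = list(maps.keys())
        processed = [maps[k] for k in keys]
        if config.smooth:
            processed = [
                _stage("smooth")(dti.smooth_fa)(m, fwhm_mm=config.fwhm_mm) for m in processed
            ]
        if config.age_correction:
            # the voxelwise age slope is fitted on control baseline scans only
            baseline_control_ids = [
                k[0] for k in keys if k[1] == "baseline" and k[0] in set(control_ids)
            ]
            processed, slope, ref_age = _stage("age_correct")(dti.age_correct)(
                processed, baseline_control_ids
            )
            run_log["age_reference_years"] = ref_age
            if config.save_volumes:
                io.save_volume(out / "age_slope.nii.gz", slope.astype(np.float32))
        maps = dict(zip(keys, processed))
        completion.append("fa_processing")

        # --- WBSS ----------------------------------------------------------
        baseline_patients = [maps[k] for k in keys if k[1] == "baseline" and k[0] in set(patient_ids)]
        baseline_controls = [maps[k] for k in keys if k[1] == "baseline" and k[0] in set(control_ids)]
        result = _stage("wbss")(wbss.run_wbss)(
            baseline_patients,
            baseline_controls,
            fa_floor=config.fa_floor,
            fdr_alpha=config.fdr_alpha,
            min_cluster=config.cluster_min_voxels,
        )
        io.save_cluster_report(
            out / "clusters.json", result.clusters, config.fdr_alpha, config.cluster_min_voxels
        )
        if config.save_volumes:
            io.save_volume(out / "t_map.nii.gz", result.t_map.astype(np.float32))
            io.save_volume(out / "significant_mask.nii.gz", result.significant_mask)
        completion.append("wbss")

        # --- TOI / TFAS ----------------------------------------------------
        if template_tensors is None:
            raise ConfigurationError(
                "tract stage for real data needs per-subject tensor volumes; "
                "supply a synthetic cohort or precomputed structure table"
            )
        tois = _stage("tract")(tract.track_atlas_tois)(
            template_tensors, atlas,
            dot_threshold=config.dot_threshold, fa_floor=config.fa_floor,
            step_mm=config.step_mm,
        )
        table = _stage("tfas")(tract.build_structure_table)(
            atlas, tois, maps, fa_floor=config.fa_floor
        )
        io.save_structure_table(out / "structure_table.csv", table)
        completion.append("tract")

        # --- staging -------------------------------------------------------
        reference = _stage("staging")(staging.fit_control_reference)(table, control_ids)
        scores = staging.pattern_scores(
            table, reference, atlas,
            threshold_offset=config.threshold_offset, scale=config.score_scale,
        )
        categories = [staging.categorize(s) for s in scores]
        groups = {r: "control" for r in control_ids}
        groups.update({r: "psp" for r in patient_ids})
        baseline_scores = [s for s in scores if s.timepoint == "baseline"]
        performance = staging.diagnostic_performance(baseline_scores, groups)
        patient_categories = [
            c for c in categories
            if c.timepoint == "baseline" and groups.get(c.subject_id) == "psp"
        ]
        summary = staging.categorization_summary(patient_categories)

        psprs = None
        if "psprs_stage" in manifest.columns:
            stage_by_id = {
                str(r.subject_id): int(r.psprs_stage)
                for _, r in manifest.iterrows()
                if pd.notna(r.psprs_stage) and r.group == "psp"
            }
            if stage_by_id:
                psprs = staging.psprs_group_summary(
                    [s for s in baseline_scores if s.subject_id in stage_by_id], stage_by_id
                )

        longitudinal = None
        if any(k[1] == "followup" for k in maps):
            longitudinal = staging.longitudinal_summary(scores, table, control_ids, patient_ids)
        completion.append("staging")

        # --- outputs -------------------------------------------------------
        _write_scores(out / "scores.csv", scores)
        pd.DataFrame(
            [{"subject_id": c.subject_id, "timepoint": c.timepoint, "category": c.category}
             for c in categories]
        ).to_csv(out / "categories.csv", index=False)
        performance.to_csv(out / "performance.csv")
        summary_doc = dict(summary)
        if longitudinal is not None:
            summary_doc["longitudinal"] = {
                "delta_scores": list(longitudinal.delta_scores),
                "n_pairs": longitudinal.n_pairs,
                "retest_floor_mean": longitudinal.retest_floor_mean,
                "retest_floor_sd": longitudinal.retest_floor_sd,
                "n_control_pairs": longitudinal.n_control_pairs,
            }
        (out / "summary.json").write_text(json.dumps(_jsonable(summary_doc), indent=2))
        if psprs is not None:
            psprs.to_csv(out / "psprs_summary.csv")
        completion.append("outputs")
    finally:
        run_log["completed_stages"] = completion
        (out / "run_log.json").write_text(json.dumps(_jsonable(run_log), indent=2))

    logger.info("pipeline complete: %s", ", ".join(completion))
    return PipelineResult(
        config=config,
        atlas=atlas,
        manifest=manifest,
        structure_table=table,
        wbss_result=result,
        reference=reference,
        scores=scores,
        categories=categories,
        performance=performance,
        category_summary=summary,
        psprs_summary=psprs,
        longitudinal=longitudinal,
    )


def _write_scores(path: Path, scores) -> None:
    pd.DataFrame(
        [
            {
                "subject_id": s.subject_id,
                "timepoint": s.timepoint,
                "pattern1": s.scores[0],
                "pattern2": s.scores[1],
                "pattern3": s.scores[2],
                "affected1": s.affected[0],
                "affected2": s.affected[1],
                "affected3": s.affected[2],
                "scale": s.scale,
            }
            for s in scores
        ]
    ).to_csv(path, index=False)


def _jsonable(obj):
    if isinstance(obj, dict):
        return {str(k): _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    return obj
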