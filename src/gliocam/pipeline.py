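"""End-to-end orchestration: simulate -> train -> saliency -> probability
maps -> region attribution -> evaluation, with every artifact written under
one output directory and stamped with the configuration hash and seed.

Rerunning with the same configuration reproduces byte-identical JSON and
CSV outputs.
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path

import numpy as np
import pandas as pd

from . import atlas_attribution as attr
from . import evaluation as ev
from . import gradcam3d as gc
from .config import PipelineConfig, config_hash, derive_seeds, save_config
from .io_formats import (LabelTable, VolumeGrid, write_label_table,
                         write_metrics_csv, write_report, write_volume)
from .preprocessing import SurvivalLabel, crop_slices, mask_tumor, os_to_class
from .probability_maps import make_probability_maps, rescale01
from .survival_model import ModelConfig, TrainConfig, build_model, save_model, train
from .synthetic_data import CohortSpec, SubjectStudy, simulate_cohort

__all__ = ["PipelineState", "run_pipeline", "cohort_spec_from_config",
           "prepare_training_set"]

_STAGE_SEEDS = ["cohort", "model_init", "train"]


@dataclasses.dataclass
class PipelineState:
    """In-memory results of a full pipeline run."""

    config: PipelineConfig
    atlas_labels: np.ndarray
    label_table: LabelTable
    subjects: list[SubjectStudy]
    model: object
    loss_history: list[float]
    class_maps: dict
    probmaps: object
    silhouette: np.ndarray
    sweep_rows: list
    scatter: pd.DataFrame
    region_reports: dict[float, attr.RegionReport]
    template_grid: VolumeGrid
    crop_window: tuple[int, int]


def cohort_spec_from_config(config: PipelineConfig) -> CohortSpec:
    seeds = derive_seeds(config.seed, _STAGE_SEEDS)
    c = config.cohort
    return CohortSpec(
        n_short=c.n_short, n_medium=c.n_medium, n_long=c.n_long,
        grid=VolumeGrid(shape=tuple(c.grid_shape)),
        n_regions=c.n_regions, coupling=c.coupling,
        tumor_radius_frac=c.tumor_radius_frac,
        radius_jitter_sd=c.radius_jitter_sd, seed=seeds["cohort"])


def prepare_training_set(subjects: list[SubjectStudy], crop: tuple[int, int]
                         ) -> tuple[list[tuple], tuple[int, int]]:
    """Tumor-masked, slice-cropped training pairs and the crop window."""
    pairs = []
    window = None
    for subj in subjects:
        tumor = mask_tumor(subj)
        cropped, window = crop_slices(tumor.data, crop[0], crop[1])
        tumor.data = cropped
        tumor.slice_window = window
        pairs.append((tumor, os_to_class(subj.os_days)))
    return pairs, window


def run_pipeline(config: PipelineConfig, out_dir: str | Path) -> PipelineState:
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    seeds = derive_seeds(config.seed, _STAGE_SEEDS)
    chash = config_hash(config)
    manifest = {"config_hash": chash, "seed": config.seed, "artifacts": []}

    def _record(path: Path) -> None:
        manifest["artifacts"].append(str(path.relative_to(out)))

    def _fail(stage: str, exc: Exception):
        (out / "manifest.json").write_text(json.dumps(
            {**manifest, "failed_stage": stage}, sort_keys=True, indent=2) + "\n")
        raise RuntimeError(f"pipeline failed at stage {stage!r}: {exc}") from exc

    _record(save_config(config, out / "config.yaml"))

    # ---- simulate -------------------------------------------------------
    try:
        spec = cohort_spec_from_config(config)
        (atlas_labels, table), subjects = simulate_cohort(spec)
    except Exception as exc:
        _fail("simulate", exc)
    template_grid = spec.grid
    data_dir = out / "data"
    _record(write_volume(atlas_labels.astype(np.int16), template_grid,
                         data_dir / "atlas.nii"))
    _record(write_label_table(table, data_dir / "labels.tsv"))
    cohort_df = pd.DataFrame([{
        "subject_id": s.subject_id,
        "os_days": s.os_days,
        "age_years": s.age_years,
        "os_class": os_to_class(s.os_days).short_name,
    } for s in subjects])
    _record(write_metrics_csv(cohort_df, data_dir / "cohort.csv"))

    # ---- train ----------------------------------------------------------
    try:
        crop = (config.crop.n_inferior, config.crop.n_superior)
        pairs, crop_window = prepare_training_set(subjects, crop)
        input_shape = pairs[0][0].data.shape[:3]
        mcfg = ModelConfig(input_shape=input_shape,
                           filters_per_block=tuple(config.model.filters_per_block),
                           kernel=tuple(config.model.kernel),
                           pool=config.model.pool,
                           dropout=config.model.dropout)
        model = build_model(mcfg, seed=seeds["model_init"])
        tcfg = TrainConfig(batch_size=config.train.batch_size,
                           max_epochs=config.train.max_epochs,
                           learning_rate=config.train.learning_rate,
                           momentum=config.train.momentum,
                           seed=seeds["train"],
                           augment=config.train.augment,
                           max_rotation_deg=config.train.max_rotation_deg,
                           max_translation_vox=config.train.max_translation_vox)
        result = train(model, pairs, tcfg)
    except Exception as exc:
        _fail("train", exc)
    model_dir = out / "model"
    _record(save_model(model, model_dir / "model.npz"))
    _record(write_report({"loss_history": result.loss_history,
                          "accuracy_history": result.accuracy_history},
                         model_dir / "training_history.json"))

    # ---- saliency -------------------------------------------------------
    try:
        silhouette = gc.compute_silhouette(atlas_labels)
        class_maps = gc.class_saliency_maps(
            model, pairs, template_grid, crop_window, silhouette,
            use_probability=config.gradcam.use_probability)
    except Exception as exc:
        _fail("saliency", exc)
    sal_dir = out / "saliency"
    for label, vol in class_maps.items():
        _record(write_volume(vol.data, template_grid,
                             sal_dir / f"H_{label.short_name}.nii"))
    _record(write_volume(silhouette, template_grid, sal_dir / "silhouette.nii"))

    # ---- probability maps ----------------------------------------------
    try:
        rescaled = {c: rescale01(class_maps[c]) for c in SurvivalLabel}
        probmaps = make_probability_maps(
            rescaled[SurvivalLabel.SHORT], rescaled[SurvivalLabel.MEDIUM],
            rescaled[SurvivalLabel.LONG], epsilon=config.probmaps.epsilon)
    except Exception as exc:
        _fail("probmaps", exc)
    pm_dir = out / "probmaps"
    for label, d_map in probmaps.items():
        _record(write_volume(d_map, template_grid,
                             pm_dir / f"D_{label.short_name}.nii"))
    _record(write_volume(probmaps.support_mask, template_grid,
                         pm_dir / "support.nii"))

    # ---- region attribution --------------------------------------------
    try:
        region_reports: dict[float, attr.RegionReport] = {}
        count_rows = []
        for th in config.attribution.thresholds:
            overlaps = {}
            for label in SurvivalLabel:
                binary = attr.binarize(rescaled[label], th, target_class=label)
                overlaps[label] = attr.overlay_atlas(
                    binary, atlas_labels, min_voxels=config.attribution.min_voxels)
                for lab, cnt in sorted(overlaps[label].counts.items()):
                    count_rows.append({"threshold": th,
                                       "os_class": label.short_name,
                                       "label": lab,
                                       "region_name": table.name(lab),
                                       "voxel_count": cnt})
            sets = attr.region_sets(overlaps[SurvivalLabel.SHORT],
                                    overlaps[SurvivalLabel.MEDIUM],
                                    overlaps[SurvivalLabel.LONG])
            region_reports[th] = attr.region_report(sets, overlaps, table)
    except Exception as exc:
        _fail("attribute", exc)
    at_dir = out / "attribution"
    _record(write_report({f"th_{th:g}": r.to_json_dict()
                          for th, r in region_reports.items()},
                         at_dir / "regions.json"))
    _record(write_metrics_csv(
        pd.DataFrame(count_rows,
                     columns=["threshold", "os_class", "label", "region_name",
                              "voxel_count"]),
        at_dir / "region_counts.csv"))

    # ---- evaluation -----------------------------------------------------
    try:
        sweep_rows, scatter = ev.threshold_sweep(
            subjects, model, class_maps, silhouette, crop,
            thresholds=config.evaluation.thresholds,
            min_class_n=config.evaluation.min_class_n)
    except Exception as exc:
        _fail("evaluate", exc)
    ev_dir = out / "evaluation"
    _record(write_metrics_csv(ev.sweep_to_frame(sweep_rows), ev_dir / "sweep.csv"))
    _record(write_metrics_csv(scatter, ev_dir / "scatter.csv"))

    (out / "manifest.json").write_text(
        json.dumps(manifest, sort_keys=True, indent=2) + "\n")

    return PipelineState(
        config=config, atlas_labels=atlas_labels, label_table=table,
        subjects=subjects, model=model, loss_history=result.loss_history,
        class_maps=class_maps, probmaps=probmaps, silhouette=silhouette,
        sweep_rows=sweep_rows, scatter=scatter, region_reports=region_reports,
        template_grid=template_grid, crop_window=crop_window)
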