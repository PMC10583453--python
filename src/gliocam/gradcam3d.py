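"""3D gradient-weighted class activation mapping (Grad-CAM) for the
survival classifier, and the staged post-processing that turns per-subject
CAMs into class-average saliency volumes on the anatomical template.

Stages, in order:

1. forward pass, pick a target class ``c``,
2. activations ``A^k`` of the final ReLU and gradients of the class score
   ``y^c`` with respect to them,
3. channel weights ``alpha_k`` = global average pool of the gradients
   (``(1/Z) sum_ijk dy^c/dA^k_ijk`` with ``Z`` the voxel count of one
   feature map),
4. ``H' = max(sum_k alpha_k A^k, 0)`` — the raw CAM,
5. trilinear resampling onto the working (cropped-input) grid,
6. voxel-wise average over same-class subjects -> ``H_S, H_M, H_L``,
7. re-indexing the cropped slices back to their template slice positions,
8. masking with the per-slice brain silhouette of the template.

Every stage preserves nonnegativity.
"""

from __future__ import annotations

import dataclasses

import numpy as np
from scipy import ndimage

from .io_formats import VolumeGrid
from .preprocessing import SurvivalLabel, TumorVolume
from .survival_model import SurvivalCNN

__all__ = [
    "FeatureMapStack", "SaliencyVolume",
    "extract_features_and_grads", "cam_weights", "cam_combine",
    "resample_align", "class_average", "index_to_template", "silhouette_mask",
    "compute_silhouette", "subject_cam", "class_saliency_maps",
]

_STAGES = ("raw_cam", "resampled", "class_average", "template_indexed", "masked")


@dataclasses.dataclass
class FeatureMapStack:
    """Final-ReLU activations and class-score gradients for one subject."""

    activations: np.ndarray  # (x, y, z, K)
    gradients: np.ndarray    # (x, y, z, K)
    target_class: SurvivalLabel
    logits: np.ndarray

    def __post_init__(self) -> None:
        if self.activations.shape != self.gradients.shape:
            raise ValueError("activations and gradients must share shape")
        if self.activations.ndim != 4 or self.activations.shape[-1] < 1:
            raise ValueError("expected (x, y, z, K) stacks with K >= 1")

    @property
    def n_maps(self) -> int:
        return self.activations.shape[-1]

    @property
    def Z(self) -> int:
        """Spatial voxel count of one feature map (the GAP normalizer)."""
        return int(np.prod(self.activations.shape[:3]))


@dataclasses.dataclass
class SaliencyVolume:
    """A nonnegative scalar relevance volume at a known pipeline stage."""

    data: np.ndarray
    grid: VolumeGrid
    stage: str
    target_class: SurvivalLabel | None = None

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=np.float64)
        if self.stage not in _STAGES:
            raise ValueError(f"unknown stage {self.stage!r}")
        if tuple(self.data.shape) != self.grid.shape:
            raise ValueError(
                f"data shape {self.data.shape} does not match grid {self.grid.shape}")
        if (self.data < 0).any():
            raise ValueError("saliency volumes must be nonnegative")


def _require_stage(vol: SaliencyVolume, *allowed: str) -> None:
    if vol.stage not in allowed:
        raise ValueError(f"expected stage in {allowed}, got {vol.stage!r}")


def extract_features_and_grads(model: SurvivalCNN, volume,
                               target_class: SurvivalLabel,
                               use_probability: bool = False) -> FeatureMapStack:
    """Activations of the model's final ReLU and gradients of the target
    class score with respect to them (inference mode throughout)."""
    data = volume.data if isinstance(volume, TumorVolume) else np.asarray(volume)
    acts, grads, logits = model.class_score_gradients(
        data, int(target_class), use_probability=use_probability)
    return FeatureMapStack(activations=np.asarray(acts, dtype=np.float64),
                           gradients=np.asarray(grads, dtype=np.float64),
                           target_class=target_class,
                           logits=np.asarray(logits, dtype=np.float64))


def cam_weights(stack: FeatureMapStack) -> np.ndarray:
    """Channel importances: global average pooling of the gradients."""
    return stack.gradients.sum(axis=(0, 1, 2)) / stack.Z


def cam_combine(weights: np.ndarray, stack: FeatureMapStack) -> SaliencyVolume:
    """Weighted sum of feature maps, clamped at zero (the raw CAM)."""
    weights = np.asarray(weights, dtype=np.float64)
    if weights.shape != (stack.n_maps,):
        raise ValueError(f"expected {stack.n_maps} weights, got {weights.shape}")
    cam = np.maximum(np.tensordot(stack.activations, weights, axes=([3], [0])), 0.0)
    grid = VolumeGrid(shape=cam.shape)
    return SaliencyVolume(data=cam, grid=grid, stage="raw_cam",
                          target_class=stack.target_class)


def resample_align(cam: SaliencyVolume, target: VolumeGrid) -> SaliencyVolume:
    """Trilinear resample of the raw CAM onto the working grid.

    Corner-aligned coordinate mapping: source position for target index
    ``t`` along an axis of sizes ``m -> n`` is ``t * (m-1)/(n-1)``, so the
    first and last samples coincide and a 2x-1 upsample lands exactly on
    voxel midpoints.
    """
    _require_stage(cam, "raw_cam")
    if any(s < 1 for s in target.shape):
        raise ValueError(f"degenerate target grid {target.shape}")
    src = cam.data
    if tuple(target.shape) == src.shape:
        return SaliencyVolume(data=src.copy(), grid=target, stage="resampled",
                              target_class=cam.target_class)
    coords = np.meshgrid(*[
        np.linspace(0.0, m - 1.0, n) if n > 1 else np.array([(m - 1) / 2.0])
        for m, n in zip(src.shape, target.shape)
    ], indexing="ij")
    out = ndimage.map_coordinates(src, np.stack(coords), order=1, mode="nearest")
    out = np.maximum(out, 0.0)
    return SaliencyVolume(data=out, grid=target, stage="resampled",
                          target_class=cam.target_class)


def class_average(maps: list[SaliencyVolume],
                  target_class: SurvivalLabel) -> SaliencyVolume:
    """Voxel-wise arithmetic mean of same-class resampled CAMs."""
    if not maps:
        raise ValueError("class_average needs at least one map")
    grid = maps[0].grid
    for m in maps:
        _require_stage(m, "resampled")
        if m.grid != grid:
            raise ValueError("all maps must share one grid")
        if m.target_class != target_class:
            raise ValueError(
                f"map of class {m.target_class} in {target_class} average")
    mean = np.mean([m.data for m in maps], axis=0)
    return SaliencyVolume(data=mean, grid=grid, stage="class_average",
                          target_class=target_class)


def index_to_template(avg: SaliencyVolume, template_grid: VolumeGrid,
                      crop_window: tuple[int, int]) -> SaliencyVolume:
    """Place cropped-grid saliency slices at their original template slice
    indices; slices outside the retained window are zero."""
    _require_stage(avg, "class_average", "resampled")
    start, stop = crop_window
    if stop - start != avg.data.shape[2]:
        raise ValueError(
            f"crop window {crop_window} inconsistent with {avg.data.shape[2]} slices")
    if avg.data.shape[:2] != template_grid.shape[:2] or stop > template_grid.shape[2]:
        raise ValueError("crop window/grid inconsistent with template grid")
    out = np.zeros(template_grid.shape, dtype=np.float64)
    out[:, :, start:stop] = avg.data
    return SaliencyVolume(data=out, grid=template_grid, stage="template_indexed",
                          target_class=avg.target_class)


def silhouette_mask(vol: SaliencyVolume, silhouette: np.ndarray) -> SaliencyVolume:
    """Zero all saliency outside the template brain silhouette."""
    _require_stage(vol, "template_indexed")
    silhouette = np.asarray(silhouette)
    if silhouette.shape != vol.grid.shape:
        raise ValueError(
            f"silhouette shape {silhouette.shape} does not match grid {vol.grid.shape}")
    out = np.where(silhouette > 0, vol.data, 0.0)
    return SaliencyVolume(data=out, grid=vol.grid, stage="masked",
                          target_class=vol.target_class)


def compute_silhouette(template: np.ndarray) -> np.ndarray:
    """Per-slice foreground mask of a template: threshold at > 0, then fill
    in-plane holes so interior low-signal voxels stay inside."""
    fg = np.asarray(template) > 0
    out = np.zeros_like(fg)
    for k in range(fg.shape[2]):
        out[:, :, k] = ndimage.binary_fill_holes(fg[:, :, k])
    return out.astype(np.uint8)


def subject_cam(model: SurvivalCNN, volume, target_class: SurvivalLabel,
                working_grid: VolumeGrid,
                use_probability: bool = False) -> SaliencyVolume:
    """Raw CAM for one subject, resampled to the working (cropped) grid."""
    stack = extract_features_and_grads(model, volume, target_class,
                                       use_probability=use_probability)
    cam = cam_combine(cam_weights(stack), stack)
    return resample_align(cam, working_grid)


def class_saliency_maps(model: SurvivalCNN,
                        cohort: list[tuple[TumorVolume, SurvivalLabel]],
                        template_grid: VolumeGrid,
                        crop_window: tuple[int, int],
                        silhouette: np.ndarray,
                        use_probability: bool = False
                        ) -> dict[SurvivalLabel, SaliencyVolume]:
    """Class-average saliency maps H_S, H_M, H_L on the template grid.

    CAMs are computed with respect to each training subject's true class
    (all subjects of a class contribute, whether or not the model
    classifies them correctly), then averaged, template-indexed and
    silhouette-masked.
    """
    working_shape = cohort[0][0].data.shape[:3]
    working_grid = VolumeGrid(shape=working_shape, spacing=template_grid.spacing)
    per_class: dict[SurvivalLabel, list[SaliencyVolume]] = {c: [] for c in SurvivalLabel}
    for volume, label in cohort:
        per_class[label].append(
            subject_cam(model, volume, label, working_grid,
                        use_probability=use_probability))
    out: dict[SurvivalLabel, SaliencyVolume] = {}
    for label, maps in per_class.items():
        if not maps:
            raise ValueError(f"no subjects for class {label.short_name}")
        avg = class_average(maps, label)
        indexed = index_to_template(avg, template_grid, crop_window)
        out[label] = silhouette_mask(indexed, silhouette)
    return out
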