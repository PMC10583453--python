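"""Deployment-path survival prediction for a new subject.

The subject's tumor-masked volume is classified by the CNN, a Grad-CAM map
is computed for the CNN-predicted class, re-indexed onto the template and
rescaled to [0, 1]; a continuous Dice similarity against each class
probability map ``D_c`` is read as the probability of the event-of-interest
for that class, and the predicted OS class is the argmax. The thresholded
patient map overlaid on the atlas yields the textual region-contribution
explanation.
"""

from __future__ import annotations

import dataclasses

import numpy as np

from .atlas_attribution import binarize, overlay_atlas
from .gradcam3d import index_to_template, silhouette_mask, subject_cam
from .io_formats import LabelTable, VolumeGrid
from .preprocessing import SurvivalLabel, crop_slices, mask_tumor
from .probability_maps import ProbabilityMaps, rescale01
from .survival_model import PredictionScores, SurvivalCNN, predict_scores

__all__ = ["PatientRegionReport", "PredictionResult", "soft_dice", "binary_dice",
           "predict_os"]


@dataclasses.dataclass
class PatientRegionReport:
    """Regions contributing to one patient's prediction, with each region's
    share of the patient's suprathreshold saliency volume."""

    threshold: float
    regions: list[dict]

    def to_json_dict(self) -> dict:
        return {"threshold": self.threshold, "regions": self.regions}


@dataclasses.dataclass
class PredictionResult:
    dice_scores: dict[SurvivalLabel, float]
    predicted_class: SurvivalLabel
    cnn_scores: PredictionScores
    report: PatientRegionReport
    threshold_used: float
    tie: bool = False
    subject_id: str = ""
    # rescaled patient saliency on the template grid, for overlay export;
    # not serialized with the textual report
    patient_map: np.ndarray | None = None

    def to_json_dict(self) -> dict:
        return {
            "subject_id": self.subject_id,
            "dice_scores": {c.short_name: float(v)
                            for c, v in self.dice_scores.items()},
            "predicted_class": self.predicted_class.short_name,
            "cnn_scores": self.cnn_scores.to_json_dict(),
            "report": self.report.to_json_dict(),
            "threshold_used": self.threshold_used,
            "tie": self.tie,
        }


def soft_dice(a: np.ndarray, b: np.ndarray) -> float:
    """Continuous Dice overlap of two nonnegative volumes.

    ``2 sum(min(A, B)) / (sum A + sum B)``; equals classic Dice on binary
    inputs, and 0 by convention when both volumes are empty.
    """
    a = np.asarray(a, dtype=np.float64)
    b = np.asarray(b, dtype=np.float64)
    if a.shape != b.shape:
        raise ValueError(f"grid mismatch: {a.shape} vs {b.shape}")
    if (a < 0).any() or (b < 0).any():
        raise ValueError("soft_dice expects nonnegative volumes")
    denom = a.sum() + b.sum()
    if denom == 0:
        return 0.0
    return float(2.0 * np.minimum(a, b).sum() / denom)


def binary_dice(a: np.ndarray, b: np.ndarray) -> float:
    """Classic Dice on boolean masks."""
    return soft_dice(np.asarray(a) > 0, np.asarray(b) > 0)


def predict_os(subject, model: SurvivalCNN, probmaps: ProbabilityMaps,
               atlas: np.ndarray, table: LabelTable, th: float,
               crop: tuple[int, int], silhouette: np.ndarray,
               binarized_dice: bool = False) -> PredictionResult:
    """Predict a subject's OS class by Dice-matching its saliency map
    against the class probability maps, with a region-level explanation.

    ``crop`` is the (n_inferior, n_superior) slice crop used at training
    time; ``silhouette`` is the template foreground mask. With
    ``binarized_dice`` both maps are thresholded at ``th`` before Dice.
    """
    def _stage(name, fn, *args, **kwargs):
        try:
            return fn(*args, **kwargs)
        except Exception as exc:
            raise RuntimeError(f"predict_os failed at stage {name!r}: {exc}") from exc

    template_grid = probmaps.grid
    tumor = _stage("mask_tumor", mask_tumor, subject)
    cropped, window = _stage("crop_slices", crop_slices, tumor.data, crop[0], crop[1])
    scores = _stage("cnn_scores", predict_scores, model, cropped)
    cnn_class = scores.predicted_class
    working_grid = VolumeGrid(shape=cropped.shape[:3], spacing=template_grid.spacing)
    cam = _stage("gradcam", subject_cam, model, cropped, cnn_class, working_grid)
    indexed = _stage("template_indexing", index_to_template, cam, template_grid, window)
    masked = _stage("silhouette_mask", silhouette_mask, indexed, silhouette)
    patient = _stage("rescale", rescale01, masked)

    dice_scores: dict[SurvivalLabel, float] = {}
    for label, d_map in probmaps.items():
        if binarized_dice:
            a = (patient.data > th).astype(np.float64)
            b = (d_map > th).astype(np.float64)
        else:
            a, b = patient.data, d_map
        dice_scores[label] = _stage(f"dice_{label.short_name}", soft_dice, a, b)

    values = np.array([dice_scores[c] for c in SurvivalLabel])
    best = int(values.argmax())  # first max wins: short > medium > long
    tie = bool((values == values[best]).sum() > 1)

    binary = _stage("binarize", binarize, patient, th)
    overlap = _stage("overlay_atlas", overlay_atlas, binary, atlas)
    total = overlap.total_voxels
    regions = [{
        "label": lab,
        "region_name": table.name(lab),
        "voxel_count": cnt,
        "fraction_of_patient_volume": (cnt / total) if total else 0.0,
    } for lab, cnt in sorted(overlap.counts.items(),
                             key=lambda kv: (-kv[1], kv[0]))]
    report = PatientRegionReport(threshold=float(th), regions=regions)

    return PredictionResult(
        dice_scores=dice_scores,
        predicted_class=SurvivalLabel(best),
        cnn_scores=scores,
        report=report,
        threshold_used=float(th),
        tie=tie,
        subject_id=getattr(subject, "subject_id", ""),
        patient_map=patient.data,
    )
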