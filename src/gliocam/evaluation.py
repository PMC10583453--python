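"""Quantitative evaluation: threshold-sweep classification accuracy,
relative tumor volume, and the per-class Spearman correlation between tumor
volume and tumor/saliency Dice overlap across a threshold grid.

The threshold 0 row is a control with no threshold applied (all foreground
voxels included): the binary class map is then the whole brain silhouette
``W``, so for a tumor of volume ``V`` (inside the brain) the Dice overlap
``2V / (V + W)`` is strictly increasing in ``V`` and the Spearman
correlation with tumor volume is exactly 1 whenever volumes are distinct.
Raising the threshold shrinks the map and the correlation decays.
"""

from __future__ import annotations

import dataclasses
import warnings

import numpy as np
import pandas as pd
from scipy import stats

from .gradcam3d import (SaliencyVolume, index_to_template, silhouette_mask,
                        subject_cam)
from .io_formats import VolumeGrid
from .preprocessing import SurvivalLabel, crop_slices, mask_tumor, os_to_class
from .probability_maps import make_probability_maps, rescale01
from .os_prediction import binary_dice, soft_dice
from .survival_model import SurvivalCNN, predict_scores

__all__ = ["ThresholdSweepRow", "accuracy", "relative_volume", "spearman",
           "threshold_sweep", "sweep_to_frame"]

SWEEP_THRESHOLDS = (0.0, 0.1, 0.2, 0.3, 0.4, 0.5, 0.6)


@dataclasses.dataclass
class ThresholdSweepRow:
    threshold: float
    accuracy: float
    spearman_by_class: dict[SurvivalLabel, float]  # NaN where undefined


def accuracy(predictions: list[SurvivalLabel], truth: list[SurvivalLabel]) -> float:
    """Fraction of correct predictions."""
    if len(predictions) != len(truth):
        raise ValueError(
            f"length mismatch: {len(predictions)} predictions vs {len(truth)} truths")
    if not predictions:
        raise ValueError("accuracy of an empty prediction list is undefined")
    return sum(int(p == t) for p, t in zip(predictions, truth)) / len(predictions)


def relative_volume(mask: np.ndarray, grid: VolumeGrid | None = None) -> float:
    """Tumor voxels as a fraction of all grid voxels."""
    mask = np.asarray(mask)
    total = grid.n_voxels if grid is not None else mask.size
    if total == 0:
        raise ValueError("empty grid")
    return float((mask > 0).sum() / total)


def spearman(x, y) -> float:
    """Spearman rank correlation with average-rank tie handling.

    Raises on constant input, where the correlation is undefined.
    """
    x = np.asarray(x, dtype=np.float64)
    y = np.asarray(y, dtype=np.float64)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be 1-D sequences of equal length")
    if x.size < 3:
        raise ValueError(f"need at least 3 observations, got {x.size}")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError("Spearman correlation is undefined for constant input")
    # perfect (anti)concordance is exact by definition; short-circuit it so
    # floating-point rank summation cannot blur rho = +-1
    rx = stats.rankdata(x)
    ry = stats.rankdata(y)
    if np.array_equal(rx, ry):
        return 1.0
    if np.array_equal(rx, len(rx) + 1 - ry):
        return -1.0
    rho = stats.spearmanr(x, y).statistic
    return float(rho)


def _patient_template_map(model, subject, crop, template_grid, silhouette):
    tumor = mask_tumor(subject)
    cropped, window = crop_slices(tumor.data, crop[0], crop[1])
    scores = predict_scores(model, cropped)
    working_grid = VolumeGrid(shape=cropped.shape[:3], spacing=template_grid.spacing)
    cam = subject_cam(model, cropped, scores.predicted_class, working_grid)
    indexed = index_to_template(cam, template_grid, window)
    masked = silhouette_mask(indexed, silhouette)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")  # constant map -> zeros is acceptable here
        return rescale01(masked).data


def threshold_sweep(subjects, model: SurvivalCNN,
                    class_maps: dict[SurvivalLabel, SaliencyVolume],
                    silhouette: np.ndarray,
                    crop: tuple[int, int],
                    thresholds=SWEEP_THRESHOLDS,
                    min_class_n: int = 3,
                    ) -> tuple[list[ThresholdSweepRow], pd.DataFrame]:
    """Accuracy of the Dice-based predictor and per-class volume-vs-Dice
    Spearman correlations, across a saliency-threshold grid.

    The threshold is applied uniformly: class maps are zeroed below ``th``
    before building probability maps, the patient map is zeroed below
    ``th`` before Dice matching, and the Spearman column pairs each
    subject's relative tumor volume with the binary Dice between its tumor
    mask and the thresholded class map (the silhouette itself at the th=0
    control). Returns sweep rows plus tidy per-subject scatter data.
    """
    template_grid = class_maps[SurvivalLabel.SHORT].grid
    rescaled = {c: rescale01(m).data for c, m in class_maps.items()}
    sil = np.asarray(silhouette) > 0

    per_subject = []
    for subj in subjects:
        true_class = os_to_class(subj.os_days)
        per_subject.append({
            "subject_id": subj.subject_id,
            "true_class": true_class,
            "tumor_mask": np.asarray(subj.seg_mask) > 0,
            "rel_volume": relative_volume(subj.seg_mask),
            "patient_map": _patient_template_map(model, subj, crop,
                                                 template_grid, sil),
        })

    rows: list[ThresholdSweepRow] = []
    scatter_records = []
    for th in thresholds:
        th = float(th)
        th_maps = {c: np.where(m > th, m, 0.0) for c, m in rescaled.items()}
        pmaps = make_probability_maps(th_maps[SurvivalLabel.SHORT],
                                      th_maps[SurvivalLabel.MEDIUM],
                                      th_maps[SurvivalLabel.LONG])
        preds, truths = [], []
        for rec in per_subject:
            pm = np.where(rec["patient_map"] > th, rec["patient_map"], 0.0)
            dice = np.array([soft_dice(pm, pmaps.by_class(c)) for c in SurvivalLabel])
            preds.append(SurvivalLabel(int(dice.argmax())))
            truths.append(rec["true_class"])
        acc = accuracy(preds, truths)

        rho_by_class: dict[SurvivalLabel, float] = {}
        for cls in SurvivalLabel:
            members = [r for r in per_subject if r["true_class"] == cls]
            class_bin = sil if th == 0.0 else (rescaled[cls] > th)
            dices, volumes = [], []
            for rec in members:
                d = binary_dice(rec["tumor_mask"], class_bin)
                dices.append(d)
                volumes.append(rec["rel_volume"])
                scatter_records.append({
                    "subject_id": rec["subject_id"],
                    "os_class": cls.short_name,
                    "threshold": th,
                    "relative_volume": rec["rel_volume"],
                    "dice": d,
                })
            if len(members) < min_class_n:
                warnings.warn(
                    f"class {cls.short_name}: {len(members)} subjects < "
                    f"{min_class_n}, Spearman skipped", stacklevel=2)
                rho_by_class[cls] = float("nan")
                continue
            try:
                rho_by_class[cls] = spearman(volumes, dices)
            except ValueError as exc:
                warnings.warn(
                    f"class {cls.short_name} at th={th}: {exc}", stacklevel=2)
                rho_by_class[cls] = float("nan")
        rows.append(ThresholdSweepRow(threshold=th, accuracy=acc,
                                      spearman_by_class=rho_by_class))
    scatter = pd.DataFrame.from_records(
        scatter_records,
        columns=["subject_id", "os_class", "threshold", "relative_volume", "dice"])
    return rows, scatter


def sweep_to_frame(rows: list[ThresholdSweepRow]) -> pd.DataFrame:
    return pd.DataFrame([{
        "threshold": r.threshold,
        "accuracy": r.accuracy,
        **{f"spearman_{c.short_name}": r.spearman_by_class[c] for c in SurvivalLabel},
    } for r in rows])
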