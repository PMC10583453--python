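"""Cohort preprocessing: slice cropping, tumor masking, OS binning, augmentation.

Overall survival in days is converted to months (30.44 days/month, the mean
Gregorian month) and binned into three ordered classes: short (< 10 months),
medium ([10, 15) months) and long (>= 15 months). The half-open intervals
make the map total on (0, inf).
"""

from __future__ import annotations

import dataclasses
import enum

import numpy as np
from scipy import ndimage

__all__ = [
    "SurvivalLabel",
    "TumorVolume",
    "DAYS_PER_MONTH",
    "os_to_class",
    "crop_slices",
    "mask_tumor",
    "apply_rigid",
    "augment",
]

DAYS_PER_MONTH = 30.44

# class boundaries in months
_SHORT_UPPER = 10.0
_MEDIUM_UPPER = 15.0


class SurvivalLabel(enum.IntEnum):
    """Ordered overall-survival class: short < medium < long."""

    SHORT = 0
    MEDIUM = 1
    LONG = 2

    @property
    def short_name(self) -> str:
        return self.name.lower()

    @classmethod
    def from_name(cls, name: str) -> "SurvivalLabel":
        try:
            return cls[name.upper()]
        except KeyError:
            raise ValueError(f"unknown survival class {name!r}") from None


@dataclasses.dataclass
class TumorVolume:
    """A 4-channel volume with all non-tumor voxels zeroed.

    ``slice_window`` records the retained inferior->superior slice window
    ``(start, stop)`` on the original template grid after cropping, so
    saliency maps can later be re-indexed back onto the template.
    """

    data: np.ndarray  # (x, y, z, 4)
    source_id: str
    slice_window: tuple[int, int] | None = None

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        if self.data.ndim != 4 or self.data.shape[-1] != 4:
            raise ValueError(f"expected (x, y, z, 4) array, got {self.data.shape}")


def os_to_class(os_days: float, days_per_month: float = DAYS_PER_MONTH
                ) -> SurvivalLabel:
    """Bin survival in days into short/medium/long at 10 and 15 months."""
    if not os_days > 0:
        raise ValueError(f"os_days must be positive, got {os_days}")
    months = os_days / days_per_month
    if months < _SHORT_UPPER:
        return SurvivalLabel.SHORT
    if months < _MEDIUM_UPPER:
        return SurvivalLabel.MEDIUM
    return SurvivalLabel.LONG


def class_day_window(label: SurvivalLabel,
                     days_per_month: float = DAYS_PER_MONTH
                     ) -> tuple[float, float]:
    """Half-open ``[lo, hi)`` day window mapped to ``label`` by os_to_class."""
    edges = (0.0, _SHORT_UPPER * days_per_month, _MEDIUM_UPPER * days_per_month,
             np.inf)
    return edges[label.value], edges[label.value + 1]


def crop_slices(volume: np.ndarray, n_inferior: int, n_superior: int
                ) -> tuple[np.ndarray, tuple[int, int]]:
    """Drop the most inferior/superior slices along the z axis.

    Returns the cropped volume and the retained half-open slice window
    ``(n_inferior, n_slices - n_superior)`` on the input grid.
    """
    if n_inferior < 0 or n_superior < 0:
        raise ValueError("crop counts must be nonnegative")
    n_slices = volume.shape[2]
    stop = n_slices - n_superior
    if n_inferior >= stop:
        raise ValueError(
            f"cropping ({n_inferior}, {n_superior}) leaves no slices of {n_slices}")
    return volume[:, :, n_inferior:stop, ...], (n_inferior, stop)


def mask_tumor(subject) -> TumorVolume:
    """Zero every voxel outside the tumor segmentation mask.

    Matches the training-volume construction: the 4-channel MRI is kept
    only where the mask is positive, so the model sees tumor tissue alone.
    """
    volume = np.asarray(subject.volume)
    mask = np.asarray(subject.seg_mask)
    if volume.shape[:3] != mask.shape:
        raise ValueError(
            f"volume grid {volume.shape[:3]} does not match mask grid {mask.shape}")
    if not (mask > 0).any():
        raise ValueError(f"subject {subject.subject_id}: empty tumor mask")
    out = np.where((mask > 0)[..., None], volume, 0.0)
    return TumorVolume(data=out, source_id=subject.subject_id)


def apply_rigid(data: np.ndarray, angle_deg: float,
                shift_vox: tuple[int, int, int]) -> np.ndarray:
    """In-plane rotation about the z axis plus an integer voxel translation.

    Zero-fill outside the field of view; channels move together.
    """
    out = data
    if angle_deg != 0.0:
        out = ndimage.rotate(out, angle_deg, axes=(0, 1), reshape=False,
                             order=1, mode="constant", cval=0.0)
    shift_vox = tuple(int(s) for s in shift_vox)
    if any(shift_vox):
        full_shift = shift_vox + (0,) * (out.ndim - 3)
        out = ndimage.shift(out, full_shift, order=0, mode="constant", cval=0.0)
    return out


def augment(volume: TumorVolume, seed: int, max_rotation_deg: float = 10.0,
            max_translation_vox: int = 5) -> TumorVolume:
    """Random rigid jitter of a training volume, deterministic given ``seed``."""
    rng = np.random.default_rng(seed)
    angle = rng.uniform(-max_rotation_deg, max_rotation_deg)
    shift = rng.integers(-max_translation_vox, max_translation_vox + 1, size=3)
    data = apply_rigid(volume.data, float(angle), tuple(shift))
    return TumorVolume(data=data, source_id=volume.source_id,
                       slice_window=volume.slice_window)
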