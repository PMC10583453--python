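"""Region attribution: threshold saliency maps, overlay the parcellation
atlas, and reduce to region sets common to or unique to each survival class.

For a threshold ``th`` the rescaled class map is binarized (strictly
``> th``), multiplied with the atlas label volume, and the suprathreshold
voxels are histogrammed per label. With per-class label-presence sets
``P_S, P_M, P_L`` the common and unique region sets are

    B   = P_S n P_M n P_L
    B_S = P_S - P_M - P_L   (and cyclically for B_M, B_L)

Set operations act on label-presence sets, not voxel sets: reports name
regions, and set difference is order-independent at the label level.
"""

from __future__ import annotations

import dataclasses

import numpy as np

from .gradcam3d import SaliencyVolume
from .io_formats import LabelTable
from .preprocessing import SurvivalLabel

__all__ = [
    "BinaryMap", "RegionOverlap", "RegionSets", "RegionReport",
    "binarize", "overlay_atlas", "region_sets", "region_report",
]

DEFAULT_THRESHOLDS = (0.1, 0.2, 0.3, 0.4, 0.5, 0.6)


@dataclasses.dataclass
class BinaryMap:
    data: np.ndarray  # uint8 {0,1}
    threshold: float
    target_class: SurvivalLabel | None = None

    def __post_init__(self) -> None:
        vals = np.unique(self.data)
        if not np.isin(vals, (0, 1)).all():
            raise ValueError("binary map must contain only 0 and 1")


@dataclasses.dataclass
class RegionOverlap:
    """Suprathreshold voxel counts per atlas label for one class/threshold."""

    target_class: SurvivalLabel
    threshold: float
    counts: dict[int, int]
    min_voxels: int = 1

    @property
    def presence(self) -> frozenset[int]:
        return frozenset(self.counts)

    @property
    def total_voxels(self) -> int:
        return int(sum(self.counts.values()))


@dataclasses.dataclass
class RegionSets:
    common: frozenset[int]
    unique_short: frozenset[int]
    unique_medium: frozenset[int]
    unique_long: frozenset[int]

    def unique_by_class(self, label: SurvivalLabel) -> frozenset[int]:
        return (self.unique_short, self.unique_medium, self.unique_long)[label.value]


@dataclasses.dataclass
class RegionReport:
    """Named regions grouped by common / unique-per-class, with voxel counts
    and each region's fraction of its class's suprathreshold volume."""

    threshold: float
    common: list[dict]
    unique: dict[str, list[dict]]

    def to_json_dict(self) -> dict:
        return {"threshold": self.threshold, "common": self.common,
                "unique": self.unique}


def binarize(vol, th: float, target_class: SurvivalLabel | None = None) -> BinaryMap:
    """Binary map: 1 exactly where the rescaled saliency exceeds ``th``."""
    if not 0.0 <= th <= 1.0:
        raise ValueError(f"threshold must be in [0, 1], got {th}")
    if isinstance(vol, SaliencyVolume):
        data, cls = vol.data, vol.target_class
    else:
        data, cls = np.asarray(vol), target_class
    if data.max(initial=0.0) > 1 + 1e-12 or data.min(initial=0.0) < 0:
        raise ValueError("binarize expects a [0, 1]-rescaled map")
    return BinaryMap(data=(data > th).astype(np.uint8), threshold=float(th),
                     target_class=target_class if target_class is not None else cls)


def overlay_atlas(binary: BinaryMap, atlas: np.ndarray,
                  min_voxels: int = 1) -> RegionOverlap:
    """Histogram of atlas labels under the binary map's suprathreshold voxels.

    Labels with fewer than ``min_voxels`` suprathreshold voxels are dropped;
    background (label 0) is always excluded.
    """
    atlas = np.asarray(atlas)
    if atlas.shape != binary.data.shape:
        raise ValueError(
            f"atlas grid {atlas.shape} does not match map grid {binary.data.shape}")
    hit = atlas[binary.data > 0]
    hit = hit[hit > 0]
    labels, counts = np.unique(hit, return_counts=True)
    kept = {int(lab): int(cnt) for lab, cnt in zip(labels, counts)
            if cnt >= min_voxels}
    cls = binary.target_class if binary.target_class is not None else SurvivalLabel.SHORT
    return RegionOverlap(target_class=cls, threshold=binary.threshold,
                         counts=kept, min_voxels=min_voxels)


def region_sets(ov_short: RegionOverlap, ov_medium: RegionOverlap,
                ov_long: RegionOverlap) -> RegionSets:
    """Common and per-class-unique label sets from the three overlaps."""
    ths = {ov_short.threshold, ov_medium.threshold, ov_long.threshold}
    if len(ths) != 1:
        raise ValueError(f"threshold mismatch across overlaps: {sorted(ths)}")
    p_s, p_m, p_l = ov_short.presence, ov_medium.presence, ov_long.presence
    return RegionSets(
        common=p_s & p_m & p_l,
        unique_short=p_s - p_m - p_l,
        unique_medium=p_m - p_l - p_s,
        unique_long=p_l - p_s - p_m,
    )


def _rows(labels: frozenset[int], counts: dict[int, int], total: int,
          table: LabelTable) -> list[dict]:
    rows = []
    for lab in sorted(labels):
        if lab not in table:
            raise KeyError(f"label {lab} missing from label table")
        cnt = counts.get(lab, 0)
        rows.append({
            "label": int(lab),
            "region_name": table.name(lab),
            "voxel_count": int(cnt),
            "fraction_of_class_volume": (cnt / total) if total else 0.0,
        })
    return rows


def region_report(sets: RegionSets,
                  overlaps: dict[SurvivalLabel, RegionOverlap],
                  table: LabelTable) -> RegionReport:
    """Human-readable attribution: region names with voxel counts and the
    fraction of each class's total suprathreshold volume they cover."""
    threshold = overlaps[SurvivalLabel.SHORT].threshold
    totals = {c: overlaps[c].total_voxels for c in SurvivalLabel}
    # common regions reported with per-class max count for context
    common_rows = []
    for lab in sorted(sets.common):
        if lab not in table:
            raise KeyError(f"label {lab} missing from label table")
        per_class = {c.short_name: int(overlaps[c].counts.get(lab, 0))
                     for c in SurvivalLabel}
        common_rows.append({"label": int(lab), "region_name": table.name(lab),
                            "voxel_count_per_class": per_class})
    unique = {
        c.short_name: _rows(sets.unique_by_class(c), overlaps[c].counts,
                            totals[c], table)
        for c in SurvivalLabel
    }
    return RegionReport(threshold=threshold, common=common_rows, unique=unique)
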