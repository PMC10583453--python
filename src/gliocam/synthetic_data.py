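"""Synthetic stand-in for a template-aligned multimodal glioma cohort.

The generator emulates the statistical structure the pipeline assumes:

* a brain-silhouette parcellation atlas (ellipsoidal silhouette partitioned
  into contiguous Voronoi parcels of random interior seeds),
* per-subject 4-channel volumes (T1, T1c, T2, FLAIR) with a three-shell
  tumor — necrotic core, enhancing rim, edema halo — planted inside a
  class-preferred parcel, over independent Gaussian channel noise,
* overall survival in days drawn per class from a truncated normal
  (floor 1 day) with class means/SDs of 157+-79, 369+-41 and 761+-346 days
  and class sizes 42/30/46,
* a planted negative within-class coupling between tumor volume and OS
  (larger tumors, shorter survival) that the evaluation stage must recover.

Everything is a pure function of the cohort specification, including its
seed; per-subject seeds are spawned deterministically from the cohort seed.
"""

from __future__ import annotations

import dataclasses

import numpy as np
from scipy import ndimage, stats

from .io_formats import LabelTable, VolumeGrid
from .preprocessing import SurvivalLabel, class_day_window, os_to_class

__all__ = ["CohortSpec", "SubjectStudy", "make_atlas", "draw_os_days",
           "simulate_subject", "simulate_cohort"]

CHANNELS = ("t1", "t1c", "t2", "flair")

# mean background tissue intensity per channel, and additive offsets for the
# tumor subregions (rows: necrosis, edema, enhancing; cols follow CHANNELS)
_BACKGROUND_MEAN = np.array([0.60, 0.55, 0.50, 0.45])
_SUBREGION_OFFSET = {
    1: np.array([-0.25, -0.20, 0.25, 0.10]),   # necrotic core
    2: np.array([-0.05, 0.00, 0.30, 0.35]),    # edema halo
    3: np.array([0.00, 0.40, 0.15, 0.15]),     # enhancing rim
}
_NOISE_SD = 0.05


@dataclasses.dataclass
class SubjectStudy:
    """One subject: 4-channel volume, segmentation mask, survival, metadata.

    Mask labels: 0 background, 1 necrosis, 2 edema, 3 enhancing tumor.
    """

    volume: np.ndarray
    seg_mask: np.ndarray
    os_days: float
    age_years: float
    subject_id: str

    def __post_init__(self) -> None:
        self.volume = np.asarray(self.volume)
        self.seg_mask = np.asarray(self.seg_mask)
        if self.volume.shape[:3] != self.seg_mask.shape:
            raise ValueError("volume and mask must share a grid")
        if self.volume.ndim != 4 or self.volume.shape[-1] != len(CHANNELS):
            raise ValueError(f"expected 4-channel volume, got {self.volume.shape}")
        if not np.isin(np.unique(self.seg_mask), (0, 1, 2, 3)).all():
            raise ValueError("mask labels must lie in {0, 1, 2, 3}")
        if not self.os_days > 0:
            raise ValueError(f"os_days must be positive, got {self.os_days}")


@dataclasses.dataclass
class CohortSpec:
    """Study conditions for a synthetic cohort.

    Class sizes and OS means/SDs default to the training-cohort composition
    (42 short / 30 medium / 46 long; 157+-79, 369+-41, 761+-346 days).
    ``coupling`` scales how strongly tumor volume shrinks with longer OS
    within a class (0 decouples them). The default grid is a desk-scale
    48x48x24 stand-in for the 240x240x155 template.
    """

    n_short: int = 42
    n_medium: int = 30
    n_long: int = 46
    grid: VolumeGrid = dataclasses.field(
        default_factory=lambda: VolumeGrid(shape=(48, 48, 24)))
    os_mean_days: tuple[float, float, float] = (157.0, 369.0, 761.0)
    os_sd_days: tuple[float, float, float] = (79.0, 41.0, 346.0)
    coupling: float = 1.0
    n_regions: int = 12
    location_preference: dict[SurvivalLabel, list[int]] | None = None
    tumor_radius_frac: float = 0.18
    radius_jitter_sd: float = 0.10
    age_mean_years: float = 62.0
    age_sd_years: float = 12.0
    redraw_cap: int = 100
    seed: int = 0

    def __post_init__(self) -> None:
        if min(self.n_short, self.n_medium, self.n_long) < 0:
            raise ValueError("class counts must be nonnegative")
        means = self.os_mean_days
        if not (0 < means[0] < means[1] < means[2]):
            raise ValueError(
                f"class OS means must be positive and increasing, got {means}")

    def counts(self) -> dict[SurvivalLabel, int]:
        return {SurvivalLabel.SHORT: self.n_short,
                SurvivalLabel.MEDIUM: self.n_medium,
                SurvivalLabel.LONG: self.n_long}

    def preferred_labels(self, label: SurvivalLabel) -> list[int]:
        if self.location_preference is not None:
            return list(self.location_preference[label])
        # default: split parcels into three contiguous label groups
        per = max(self.n_regions // 3, 1)
        start = label.value * per + 1
        return list(range(start, min(start + per, self.n_regions + 1)))


def _silhouette(grid: VolumeGrid) -> np.ndarray:
    """Axis-aligned ellipsoidal brain silhouette filling ~90% of the grid."""
    nx, ny, nz = grid.shape
    center = (np.array(grid.shape) - 1) / 2.0
    semi = np.array(grid.shape) * 0.45
    x, y, z = np.meshgrid(*[np.arange(n) for n in grid.shape], indexing="ij")
    r2 = (((x - center[0]) / semi[0]) ** 2 + ((y - center[1]) / semi[1]) ** 2
          + ((z - center[2]) / semi[2]) ** 2)
    return (r2 <= 1.0)


def make_atlas(grid: VolumeGrid, n_regions: int, seed: int
               ) -> tuple[np.ndarray, LabelTable]:
    """Partition an ellipsoidal brain silhouette into contiguous parcels.

    Voxels inside the silhouette are assigned to the nearest of
    ``n_regions`` random interior seed points (a Voronoi parcellation, so
    every parcel is nonempty and contiguous); outside is label 0.
    """
    if n_regions < 3:
        raise ValueError(f"need at least 3 regions, got {n_regions}")
    sil = _silhouette(grid)
    inside = np.argwhere(sil)
    if len(inside) < n_regions:
        raise ValueError(
            f"{n_regions} regions exceed the {len(inside)}-voxel silhouette")
    rng = np.random.default_rng(seed)
    seeds = inside[rng.choice(len(inside), size=n_regions, replace=False)]
    # nearest-seed assignment in voxel space
    d2 = ((inside[:, None, :] - seeds[None, :, :]) ** 2).sum(axis=2)
    assignment = d2.argmin(axis=1) + 1
    labels = np.zeros(grid.shape, dtype=np.int32)
    labels[tuple(inside.T)] = assignment
    table = LabelTable([(i + 1, f"Parcel_{i + 1:02d}") for i in range(n_regions)])
    return labels, table


def draw_os_days(spec: CohortSpec, os_class: SurvivalLabel,
                 rng: np.random.Generator) -> float:
    """One survival draw: truncated normal (floor 1 day) with the class
    mean/SD. Class-consistency redraws happen at the cohort level."""
    mu = spec.os_mean_days[os_class.value]
    sd = spec.os_sd_days[os_class.value]
    a = (1.0 - mu) / sd  # truncate at the 1-day floor
    return float(stats.truncnorm.rvs(a, np.inf, loc=mu, scale=sd, random_state=rng))


def _tumor_radii(spec: CohortSpec, os_class: SurvivalLabel, os_days: float,
                 rng: np.random.Generator) -> np.ndarray:
    """Edema semi-axes (voxels): baseline scaled down for longer-than-mean
    survival within the class (volume factor exp(-coupling * z))."""
    mu = spec.os_mean_days[os_class.value]
    sd = spec.os_sd_days[os_class.value]
    z = np.clip((os_days - mu) / sd, -2.5, 2.5)
    volume_factor = np.exp(-spec.coupling * z)
    jitter = np.exp(rng.normal(0.0, spec.radius_jitter_sd))
    base = spec.tumor_radius_frac * min(spec.grid.shape)
    r = base * volume_factor ** (1.0 / 3.0) * jitter
    return np.array([r, r, 0.8 * r])


def _pick_center(parcel_mask: np.ndarray, sil: np.ndarray, radii: np.ndarray,
                 rng: np.random.Generator) -> np.ndarray:
    """A tumor center inside the parcel with enough clearance from the
    silhouette boundary to host most of the tumor."""
    edt = ndimage.distance_transform_edt(sil)
    clearance = 0.7 * radii.min()
    candidates = np.argwhere(parcel_mask & (edt >= clearance))
    if len(candidates) == 0:
        raise ValueError(
            f"preferred parcel too small for a tumor of radii {radii.round(1)}")
    return candidates[rng.integers(len(candidates))]


def _shell_mask(grid_shape, center, radii) -> np.ndarray:
    x, y, z = np.meshgrid(*[np.arange(n) for n in grid_shape], indexing="ij")
    r2 = (((x - center[0]) / radii[0]) ** 2 + ((y - center[1]) / radii[1]) ** 2
          + ((z - center[2]) / radii[2]) ** 2)
    return r2 <= 1.0


def simulate_subject(spec: CohortSpec, os_class: SurvivalLabel,
                     atlas: tuple[np.ndarray, LabelTable], seed: int,
                     subject_id: str | None = None) -> SubjectStudy:
    """Generate one subject with a three-shell tumor in a class-preferred
    parcel; deterministic given ``seed``."""
    labels, _ = atlas
    rng = np.random.default_rng(seed)
    os_days = draw_os_days(spec, os_class, rng)
    age = float(np.clip(rng.normal(spec.age_mean_years, spec.age_sd_years), 18, 95))

    sil = labels > 0
    radii = _tumor_radii(spec, os_class, os_days, rng)
    preferred = spec.preferred_labels(os_class)
    parcel = int(preferred[rng.integers(len(preferred))])
    center = _pick_center(labels == parcel, sil, radii, rng)

    # concentric shells: edema halo > enhancing rim > necrotic core
    edema = _shell_mask(spec.grid.shape, center, radii)
    enhancing = _shell_mask(spec.grid.shape, center, radii * 0.7)
    core = _shell_mask(spec.grid.shape, center, radii * 0.4)
    mask = np.zeros(spec.grid.shape, dtype=np.uint8)
    mask[edema] = 2
    mask[enhancing] = 3
    mask[core] = 1
    mask[~sil] = 0  # tumors live inside the brain

    volume = np.zeros(spec.grid.shape + (len(CHANNELS),), dtype=np.float64)
    noise = rng.normal(0.0, _NOISE_SD, size=volume.shape)
    volume[sil] = _BACKGROUND_MEAN + noise[sil]
    for sub_label, offset in _SUBREGION_OFFSET.items():
        volume[mask == sub_label] += offset
    volume = np.clip(volume, 0.0, None)

    return SubjectStudy(
        volume=volume, seg_mask=mask, os_days=os_days, age_years=age,
        subject_id=subject_id or f"synth-{os_class.short_name}-{seed}")


def simulate_cohort(spec: CohortSpec,
                    atlas: tuple[np.ndarray, LabelTable] | None = None
                    ) -> tuple[tuple[np.ndarray, LabelTable], list[SubjectStudy]]:
    """Generate the full cohort (and its atlas, unless one is supplied).

    Each subject's OS must fall in its requested class window under
    ``os_to_class``; inconsistent draws are redrawn with a fresh derived
    seed, up to ``spec.redraw_cap`` attempts per subject.
    """
    root = np.random.SeedSequence(spec.seed)
    atlas_seed, subject_seed = (int(s.generate_state(1)[0] % (2 ** 31))
                                for s in root.spawn(2))
    if atlas is None:
        atlas = make_atlas(spec.grid, spec.n_regions, atlas_seed)

    subjects: list[SubjectStudy] = []
    counts = spec.counts()
    index = 0
    for os_class in SurvivalLabel:
        lo, hi = class_day_window(os_class)
        for j in range(counts[os_class]):
            subject = None
            for attempt in range(spec.redraw_cap):
                seed = int(np.random.SeedSequence(
                    entropy=subject_seed, spawn_key=(index, attempt)
                ).generate_state(1)[0] % (2 ** 31))
                candidate = simulate_subject(
                    spec, os_class, atlas, seed,
                    subject_id=f"synth-{index:03d}-{os_class.short_name}")
                if os_to_class(candidate.os_days) == os_class:
                    subject = candidate
                    break
            if subject is None:
                raise RuntimeError(
                    f"could not draw a {os_class.short_name} survival in "
                    f"[{lo:.0f}, {hi:.0f}) days within {spec.redraw_cap} attempts")
            subjects.append(subject)
            index += 1
    return atlas, subjects
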