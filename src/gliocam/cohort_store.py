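"""On-disk cohort layout shared by the CLI subcommands.

A cohort directory holds ``atlas.nii``, ``labels.tsv``, ``cohort.csv``
(subject_id, os_days, age_years) and per-subject ``<id>_volume.nii`` /
``<id>_mask.nii`` pairs.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd

from .io_formats import (LabelTable, VolumeGrid, read_label_table, read_volume,
                         write_label_table, write_metrics_csv, write_volume)
from .synthetic_data import SubjectStudy

__all__ = ["write_cohort_dir", "load_cohort_dir"]


def write_cohort_dir(atlas_labels: np.ndarray, table: LabelTable,
                     subjects: list[SubjectStudy], grid: VolumeGrid,
                     out_dir: str | Path) -> Path:
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    write_volume(atlas_labels.astype(np.int16), grid, out / "atlas.nii")
    write_label_table(table, out / "labels.tsv")
    rows = []
    for s in subjects:
        write_volume(s.volume.astype(np.float32), grid,
                     out / f"{s.subject_id}_volume.nii")
        write_volume(s.seg_mask.astype(np.uint8), grid,
                     out / f"{s.subject_id}_mask.nii")
        rows.append({"subject_id": s.subject_id, "os_days": s.os_days,
                     "age_years": s.age_years})
    write_metrics_csv(pd.DataFrame(rows), out / "cohort.csv")
    return out


def load_cohort_dir(path: str | Path
                    ) -> tuple[np.ndarray, LabelTable, list[SubjectStudy], VolumeGrid]:
    path = Path(path)
    atlas, grid = read_volume(path / "atlas.nii")
    table = read_label_table(path / "labels.tsv")
    df = pd.read_csv(path / "cohort.csv")
    subjects = []
    for row in df.itertuples(index=False):
        volume, _ = read_volume(path / f"{row.subject_id}_volume.nii")
        mask, _ = read_volume(path / f"{row.subject_id}_mask.nii")
        subjects.append(SubjectStudy(
            volume=np.asarray(volume, dtype=np.float64),
            seg_mask=np.asarray(mask, dtype=np.uint8),
            os_days=float(row.os_days), age_years=float(row.age_years),
            subject_id=str(row.subject_id)))
    return np.asarray(atlas, dtype=np.int32), table, subjects, grid
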