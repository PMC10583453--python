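"""Reading and writing of external artifacts.

All volumes travel as NIfTI-1, label tables as TSV, reports as JSON and
metric tables as CSV. Every other module operates purely on in-memory
types; path strings cross module boundaries only here and in the CLI.

Conventions fixed once for the whole package:

* voxel arrays are ordered ``(x, y, z[, channel])`` with 0-based indices,
* the slice index ``k`` (third axis) runs inferior -> superior,
* atlas labels are 1-based positive integers, 0 is reserved background,
* JSON reports are written with sorted keys and a fixed indent so repeated
  writes of the same report are byte-identical.
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path
from typing import Sequence

import nibabel as nib
import numpy as np
import pandas as pd

__all__ = [
    "VolumeGrid",
    "LabelTable",
    "read_volume",
    "write_volume",
    "read_label_table",
    "write_label_table",
    "write_report",
    "read_report",
    "write_metrics_csv",
]


@dataclasses.dataclass(frozen=True)
class VolumeGrid:
    """Geometry of a voxel grid: shape, spacing and voxel->world affine."""

    shape: tuple[int, int, int]
    spacing: tuple[float, float, float] = (1.0, 1.0, 1.0)
    affine: np.ndarray | None = None

    def __post_init__(self) -> None:
        if len(self.shape) != 3 or any(int(s) < 1 for s in self.shape):
            raise ValueError(f"grid shape must be a positive triple, got {self.shape}")
        if len(self.spacing) != 3 or any(s <= 0 for s in self.spacing):
            raise ValueError(f"voxel spacing must be positive, got {self.spacing}")
        object.__setattr__(self, "shape", tuple(int(s) for s in self.shape))
        object.__setattr__(self, "spacing", tuple(float(s) for s in self.spacing))
        if self.affine is None:
            aff = np.diag(list(self.spacing) + [1.0])
            object.__setattr__(self, "affine", aff)
        else:
            aff = np.asarray(self.affine, dtype=float)
            if aff.shape != (4, 4):
                raise ValueError("affine must be a 4x4 matrix")
            object.__setattr__(self, "affine", aff)

    @property
    def n_voxels(self) -> int:
        return int(np.prod(self.shape))

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, VolumeGrid):
            return NotImplemented
        return (
            self.shape == other.shape
            and np.allclose(self.spacing, other.spacing)
            and np.allclose(self.affine, other.affine)
        )

    def __hash__(self) -> int:  # frozen dataclass with array field
        return hash((self.shape, self.spacing))


class LabelTable:
    """Atlas label -> region-name table.

    Labels are unique positive integers; names are unique and non-empty.
    Label 0 is reserved for background and never listed.
    """

    def __init__(self, entries: Sequence[tuple[int, str]]):
        seen_labels: set[int] = set()
        seen_names: set[str] = set()
        cleaned: list[tuple[int, str]] = []
        for label, name in entries:
            label = int(label)
            name = str(name).strip()
            if label == 0:
                raise ValueError("label 0 is reserved for background")
            if label < 0:
                raise ValueError(f"labels must be positive, got {label}")
            if label in seen_labels:
                raise ValueError(f"duplicate label {label}")
            if not name:
                raise ValueError(f"blank region name for label {label}")
            if name in seen_names:
                raise ValueError(f"duplicate region name {name!r}")
            seen_labels.add(label)
            seen_names.add(name)
            cleaned.append((label, name))
        self.entries: list[tuple[int, str]] = cleaned
        self._by_label = dict(cleaned)

    def __len__(self) -> int:
        return len(self.entries)

    def __contains__(self, label: int) -> bool:
        return int(label) in self._by_label

    def name(self, label: int) -> str:
        try:
            return self._by_label[int(label)]
        except KeyError:
            raise KeyError(f"label {label} not in table") from None

    def labels(self) -> list[int]:
        return [lab for lab, _ in self.entries]

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, LabelTable):
            return NotImplemented
        return self.entries == other.entries

    def __repr__(self) -> str:
        return f"LabelTable({len(self.entries)} regions)"


def _grid_from_img(img: nib.Nifti1Image) -> VolumeGrid:
    zooms = img.header.get_zooms()[:3]
    shape = img.shape[:3]
    return VolumeGrid(shape=tuple(shape), spacing=tuple(float(z) for z in zooms),
                      affine=np.asarray(img.affine, dtype=float))


def read_volume(path: str | Path) -> tuple[np.ndarray, VolumeGrid]:
    """Read a NIfTI-1 volume as ``(array, grid)``.

    The array keeps the on-disk ``(x, y, z[, channel])`` axis order; the
    grid carries the header affine and voxel spacing. Volumes containing
    NaN voxels are rejected.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"volume not found: {path}")
    try:
        img = nib.load(str(path))
    except Exception as exc:  # nibabel raises several types for bad payloads
        raise ValueError(f"not a readable NIfTI volume: {path} ({exc})") from exc
    data = np.asarray(img.dataobj)
    if data.ndim not in (3, 4):
        raise ValueError(f"expected a 3D or 4D volume, got ndim={data.ndim}: {path}")
    if np.issubdtype(data.dtype, np.floating) and np.isnan(data).any():
        raise ValueError(f"volume contains NaN voxels: {path}")
    return data, _grid_from_img(img)


def write_volume(data: np.ndarray, grid: VolumeGrid, path: str | Path) -> Path:
    """Write an ``(x, y, z[, channel])`` array to NIfTI-1."""
    data = np.asarray(data)
    if data.shape[:3] != grid.shape:
        raise ValueError(f"array shape {data.shape[:3]} does not match grid {grid.shape}")
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    img = nib.Nifti1Image(data, grid.affine)
    img.header.set_zooms(tuple(grid.spacing) + ((1.0,) if data.ndim == 4 else ()))
    nib.save(img, str(path))
    return path


def read_label_table(path: str | Path) -> LabelTable:
    """Parse a TSV with columns ``label`` and ``region_name``."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"label table not found: {path}")
    df = pd.read_csv(path, sep="\t", header=0, dtype={"label": int, "region_name": str},
                     keep_default_na=False)
    for col in ("label", "region_name"):
        if col not in df.columns:
            raise ValueError(f"label table missing column {col!r}: {path}")
    return LabelTable(list(zip(df["label"], df["region_name"])))


def write_label_table(table: LabelTable, path: str | Path) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    df = pd.DataFrame(table.entries, columns=["label", "region_name"])
    df.to_csv(path, sep="\t", index=False)
    return path


def _jsonify(obj):
    """Convert dataclasses / numpy scalars / arrays into JSON-safe values."""
    if hasattr(obj, "to_json_dict"):
        return _jsonify(obj.to_json_dict())
    if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
        return {k: _jsonify(v) for k, v in dataclasses.asdict(obj).items()}
    if isinstance(obj, dict):
        return {str(k): _jsonify(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple, set, frozenset)):
        seq = sorted(obj) if isinstance(obj, (set, frozenset)) else obj
        return [_jsonify(v) for v in seq]
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, np.ndarray):
        return _jsonify(obj.tolist())
    return obj


def write_report(report, path: str | Path) -> Path:
    """Serialize a report object to JSON.

    Keys are sorted and floats written via ``repr`` so that two writes of
    the same report produce byte-identical files.
    """
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    payload = _jsonify(report)
    text = json.dumps(payload, sort_keys=True, indent=2)
    path.write_text(text + "\n")
    return path


def read_report(path: str | Path) -> dict:
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"report not found: {path}")
    return json.loads(path.read_text())


def write_metrics_csv(df: pd.DataFrame, path: str | Path) -> Path:
    """Write a metrics table with a fixed float format (deterministic bytes)."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    df.to_csv(path, index=False, float_format="%.10g")
    return path
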