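"""Core domain types and I/O: volumes, tractograms, cohort tables.

Coordinate conventions: voxel indices are 0-based; world coordinates are
template (MNI-style) millimetres with ``world = affine @ [i, j, k, 1]``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import nibabel as nib
import numpy as np
import pandas as pd

__all__ = [
    "VoxelGrid",
    "EFieldImage",
    "Tractogram",
    "CohortTable",
    "RESPONDER_CLASSES",
    "load_efield",
    "save_efield",
    "load_tractogram",
    "save_tractogram",
    "load_cohort",
    "save_cohort",
    "improvement_pct",
    "classify_responder",
]

RESPONDER_CLASSES = ("poor", "middle", "top")


@dataclass
class VoxelGrid:
    """A scalar voxel volume with a world affine.

    ``affine`` maps 0-based voxel indices to world mm. ``values`` carries
    one scalar per voxel (dtype float or bool).
    """

    affine: np.ndarray
    values: np.ndarray

    def __post_init__(self) -> None:
        self.affine = np.asarray(self.affine, dtype=float)
        self.values = np.asarray(self.values)
        if self.affine.shape != (4, 4):
            raise ValueError("affine must be 4x4")
        if abs(np.linalg.det(self.affine)) < 1e-12:
            raise ValueError("affine is singular")
        if self.values.ndim != 3:
            raise ValueError("values must be a 3-D array")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.values.shape  # type: ignore[return-value]

    def voxel_to_world(self, ijk: np.ndarray) -> np.ndarray:
        """Map (..., 3) voxel indices to world mm."""
        ijk = np.asarray(ijk, dtype=float)
        return ijk @ self.affine[:3, :3].T + self.affine[:3, 3]

    def world_to_voxel(self, points: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        """Map (..., 3) world-mm points to nearest 0-based voxel indices.

        Returns ``(ijk, inside)`` where ``inside`` flags indices falling
        within the grid. Out-of-grid points are flagged, never raised.
        """
        points = np.asarray(points, dtype=float)
        inv = np.linalg.inv(self.affine)
        cont = points @ inv[:3, :3].T + inv[:3, 3]
        ijk = np.rint(cont).astype(int)
        shape = np.asarray(self.shape)
        inside = np.all((ijk >= 0) & (ijk < shape), axis=-1)
        return ijk, inside

    def world_coordinates(self) -> np.ndarray:
        """World mm of every voxel centre, shape ``(*shape, 3)``."""
        idx = np.indices(self.shape).reshape(3, -1).T
        return self.voxel_to_world(idx).reshape(*self.shape, 3)

    def like(self, values: np.ndarray) -> "VoxelGrid":
        values = np.asarray(values)
        if values.shape != self.values.shape:
            raise ValueError("replacement values have wrong shape")
        return VoxelGrid(self.affine.copy(), values)

    def spacing(self) -> np.ndarray:
        return np.sqrt((self.affine[:3, :3] ** 2).sum(axis=0))


@dataclass
class EFieldImage:
    """Electric-field magnitude volume in V/mm on a :class:`VoxelGrid`."""

    grid: VoxelGrid
    patient_id: str = ""

    def __post_init__(self) -> None:
        vals = np.asarray(self.grid.values, dtype=float)
        if not np.all(np.isfinite(vals)):
            raise ValueError("E-field contains non-finite values")
        if np.any(vals < 0):
            raise ValueError("negative E-field magnitude")
        self.grid = VoxelGrid(self.grid.affine, vals)

    @property
    def values(self) -> np.ndarray:
        return self.grid.values


@dataclass
class Tractogram:
    """Streamlines in template mm, with optional per-fiber annotations."""

    streamlines: list[np.ndarray]
    bundle_labels: np.ndarray | None = None
    scalars: np.ndarray | None = None

    def __post_init__(self) -> None:
        cleaned = []
        for sl in self.streamlines:
            sl = np.asarray(sl, dtype=float)
            if sl.ndim != 2 or sl.shape[1] != 3:
                raise ValueError("each streamline must be an (n, 3) array")
            if sl.shape[0] < 2:
                raise ValueError("streamline must have at least 2 points")
            if not np.all(np.isfinite(sl)):
                raise ValueError("streamline has non-finite coordinates")
            cleaned.append(sl)
        self.streamlines = cleaned
        for name in ("bundle_labels", "scalars"):
            arr = getattr(self, name)
            if arr is not None:
                arr = np.asarray(arr)
                if arr.shape != (len(cleaned),):
                    raise ValueError(f"{name} must have one entry per streamline")
                setattr(self, name, arr)

    def __len__(self) -> int:
        return len(self.streamlines)

    def subset(self, indices) -> "Tractogram":
        indices = np.asarray(indices)
        if indices.dtype == bool:
            indices = np.flatnonzero(indices)
        return Tractogram(
            [self.streamlines[i] for i in indices],
            None if self.bundle_labels is None else self.bundle_labels[indices],
            None if self.scalars is None else self.scalars[indices],
        )


@dataclass
class CohortTable:
    """Per-patient outcomes and stimulation metadata.

    Improvement is baseline-denominated percent change with POSITIVE =
    cognitive improvement (deficit score decreased).
    """

    table: pd.DataFrame = field(repr=False)

    REQUIRED = ("id", "baseline", "followup", "age", "efield_path")

    def __post_init__(self) -> None:
        df = self.table.copy()
        missing = [c for c in self.REQUIRED if c not in df.columns]
        if missing:
            raise ValueError(f"cohort table missing columns: {missing}")
        if df["id"].duplicated().any():
            raise ValueError("duplicate patient ids")
        if (df["baseline"] <= 0).any():
            raise ValueError("baseline score must be positive")
        df["improvement_pct"] = improvement_pct(
            df["baseline"].to_numpy(float), df["followup"].to_numpy(float)
        )
        df["responder_class"] = [classify_responder(v) for v in df["improvement_pct"]]
        self.table = df

    def __len__(self) -> int:
        return len(self.table)

    @property
    def improvements(self) -> np.ndarray:
        return self.table["improvement_pct"].to_numpy(float)

    @property
    def ids(self) -> list[str]:
        return [str(i) for i in self.table["id"]]


def improvement_pct(baseline, followup):
    """Percent improvement, ``100 * (baseline - followup) / baseline``.

    Positive values mean the deficit score decreased (improvement).
    """
    baseline = np.asarray(baseline, dtype=float)
    followup = np.asarray(followup, dtype=float)
    if np.any(baseline <= 0):
        raise ValueError("baseline must be > 0")
    out = 100.0 * (baseline - followup) / baseline
    return float(out) if out.ndim == 0 else out


def classify_responder(improvement: float) -> str:
    """Partition improvement %: <= -21 poor; (-21, 0] middle; > 0 top."""
    if not math.isfinite(float(improvement)):
        raise ValueError("improvement must be finite")
    if improvement <= -21.0:
        return "poor"
    if improvement <= 0.0:
        return "middle"
    return "top"


# ---------------------------------------------------------------------------
# I/O


def load_efield(path, patient_id: str | None = None) -> EFieldImage:
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    img = nib.load(str(path))
    data = np.asarray(img.dataobj, dtype=float)
    if data.ndim == 4 and data.shape[3] == 1:
        data = data[..., 0]
    if data.ndim != 3:
        raise ValueError(f"expected a 3-D scalar NIfTI, got shape {data.shape}")
    grid = VoxelGrid(np.asarray(img.affine, dtype=float), data)
    return EFieldImage(grid, patient_id or path.stem.replace(".nii", ""))


def save_efield(E: EFieldImage, path) -> None:
    img = nib.Nifti1Image(np.asarray(E.values, dtype=np.float64), E.grid.affine)
    nib.save(img, str(path))


def save_volume(grid: VoxelGrid, path) -> None:
    img = nib.Nifti1Image(np.asarray(grid.values, dtype=np.float64), grid.affine)
    nib.save(img, str(path))


def load_volume(path) -> VoxelGrid:
    img = nib.load(str(path))
    data = np.asarray(img.dataobj, dtype=float)
    if data.ndim != 3:
        raise ValueError(f"expected a 3-D NIfTI, got shape {data.shape}")
    return VoxelGrid(np.asarray(img.affine, dtype=float), data)


def load_tractogram(path) -> Tractogram:
    """Read a TRK or TCK streamline file (coordinates in template mm)."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if path.suffix.lower() not in (".trk", ".tck"):
        raise ValueError(f"unknown tractogram extension: {path.suffix}")
    tf = nib.streamlines.load(str(path))
    streamlines = [np.asarray(sl, dtype=float) for sl in tf.streamlines]
    scalars = None
    dps = getattr(tf.tractogram, "data_per_streamline", None)
    if dps and "scalars" in dps:
        scalars = np.asarray([float(v[0]) for v in dps["scalars"]])
    if not streamlines:
        return Tractogram([])
    return Tractogram(streamlines, scalars=scalars)


def save_tractogram(tract: Tractogram, path) -> None:
    path = Path(path)
    data_per_streamline = {}
    if tract.scalars is not None:
        data_per_streamline["scalars"] = tract.scalars.reshape(-1, 1)
    nt = nib.streamlines.Tractogram(
        [np.asarray(sl, dtype=np.float32) for sl in tract.streamlines],
        data_per_streamline=data_per_streamline or None,
        affine_to_rasmm=np.eye(4),
    )
    if path.suffix.lower() == ".trk":
        nib.streamlines.save(nt, str(path))
    elif path.suffix.lower() == ".tck":
        nib.streamlines.save(nt, str(path))
    else:
        raise ValueError(f"unknown tractogram extension: {path.suffix}")


def load_cohort(path) -> CohortTable:
    df = pd.read_csv(path)
    return CohortTable(df)


def save_cohort(cohort: CohortTable, path) -> None:
    cols = list(CohortTable.REQUIRED)
    cohort.table[cols].to_csv(path, index=False)
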