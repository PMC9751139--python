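"""Analytic point-source electric-field model, thresholds, coverage, mirroring.

The field of a current point source in an infinite homogeneous isotropic
medium: potential ``V(r) = I / (4 pi sigma r)`` and field magnitude
``|E(r)| = I / (4 pi sigma r^2)``. With current in mA, distances in mm and
conductivity in S/m these formulas conveniently give volts and V/mm
directly. Multiple sources superpose as vectors, so the magnitude of the
summed field is reported (fields can cancel between equal sources).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

from stimmap.data_model import EFieldImage, VoxelGrid

__all__ = [
    "PointSource",
    "CoverageMask",
    "simulate_efield",
    "potential_at",
    "efield_vector_at",
    "efield_magnitude_at",
    "threshold_efield",
    "coverage_mask",
    "mirror_efield",
]

DEFAULT_SIGMA = 0.2  # S/m, gray-matter order of magnitude
CLAMP_MM = 0.5  # near-source singularity clamp radius


@dataclass(frozen=True)
class PointSource:
    """Current point source: position in template mm, current in mA."""

    position: tuple[float, float, float]
    current_ma: float
    sigma: float = DEFAULT_SIGMA

    def __post_init__(self) -> None:
        if self.sigma <= 0:
            raise ValueError("conductivity sigma must be > 0")
        if self.current_ma == 0:
            raise ValueError("active source must have nonzero current")


@dataclass
class CoverageMask:
    """Boolean volume of voxels suprathreshold in >= fraction of fields."""

    grid: VoxelGrid  # boolean values
    threshold: float
    fraction: float

    @property
    def values(self) -> np.ndarray:
        return self.grid.values


def _check_sources(sources: Sequence[PointSource]) -> float:
    if not sources:
        raise ValueError("need at least one source")
    sigmas = {s.sigma for s in sources}
    if len(sigmas) > 1:
        raise ValueError("all sources must share one conductivity")
    return sigmas.pop()


def potential_at(sources: Sequence[PointSource], points: np.ndarray,
                 clamp_mm: float = CLAMP_MM) -> np.ndarray:
    """Superposed potential (V) at (..., 3) mm points."""
    sigma = _check_sources(sources)
    points = np.asarray(points, dtype=float)
    out = np.zeros(points.shape[:-1])
    for s in sources:
        r = np.linalg.norm(points - np.asarray(s.position), axis=-1)
        r = np.maximum(r, clamp_mm)
        out += s.current_ma / (4.0 * np.pi * sigma * r)
    return out


def efield_vector_at(sources: Sequence[PointSource], points: np.ndarray,
                     clamp_mm: float = CLAMP_MM) -> np.ndarray:
    """Superposed E-field vector (V/mm) at (..., 3) mm points.

    ``E = -grad V`` points away from a positive source; the radial
    magnitude is clamped at its value ``clamp_mm`` from the source.
    """
    sigma = _check_sources(sources)
    points = np.asarray(points, dtype=float)
    out = np.zeros(points.shape[:-1] + (3,))
    for s in sources:
        d = points - np.asarray(s.position, dtype=float)
        r = np.linalg.norm(d, axis=-1)
        r_eff = np.maximum(r, clamp_mm)
        mag = s.current_ma / (4.0 * np.pi * sigma * r_eff**2)
        with np.errstate(invalid="ignore", divide="ignore"):
            unit = d / r[..., None]
        unit = np.where(np.isfinite(unit), unit, 0.0)  # exactly at source
        out += mag[..., None] * unit
    return out


def efield_magnitude_at(sources: Sequence[PointSource], points: np.ndarray,
                        clamp_mm: float = CLAMP_MM) -> np.ndarray:
    return np.linalg.norm(efield_vector_at(sources, points, clamp_mm), axis=-1)


def simulate_efield(sources: Sequence[PointSource], grid: VoxelGrid,
                    patient_id: str = "", clamp_mm: float = CLAMP_MM) -> EFieldImage:
    """Voxelise the superposed field magnitude onto ``grid`` (V/mm)."""
    if min(grid.shape) < 1:
        raise ValueError("degenerate grid")
    coords = grid.world_coordinates()
    mag = efield_magnitude_at(sources, coords, clamp_mm=clamp_mm)
    return EFieldImage(grid.like(mag), patient_id)


def threshold_efield(E: EFieldImage, thr: float) -> np.ndarray:
    """Boolean volume: magnitude >= thr (inclusive convention)."""
    if thr <= 0:
        raise ValueError("threshold must be > 0")
    return np.asarray(E.values) >= thr


def coverage_mask(fields: Sequence[EFieldImage], thr: float,
                  fraction: float) -> CoverageMask:
    """Voxels suprathreshold in at least ``fraction`` of the cohort fields."""
    if not fields:
        raise ValueError("need at least one field")
    if not (0.0 < fraction <= 1.0):
        raise ValueError("fraction must be in (0, 1]")
    ref = fields[0].grid
    counts = np.zeros(ref.shape, dtype=int)
    for f in fields:
        if f.grid.shape != ref.shape or not np.allclose(f.grid.affine, ref.affine):
            raise ValueError("all fields must share one grid")
        counts += threshold_efield(f, thr)
    mask = counts / len(fields) >= fraction
    return CoverageMask(ref.like(mask), thr, fraction)


def _x_flip_check(grid: VoxelGrid) -> None:
    """The rigid x-flip values[::-1] is a world x -> -x map only when the
    i axis is the world x axis and the grid is centred on x = 0."""
    A = grid.affine
    if not (np.allclose(A[0, 1:3], 0) and np.allclose(A[1:3, 0], 0)):
        raise ValueError("grid x axis must be voxel axis 0 for mirroring")
    # world x of index i is A00*i + A03; symmetry needs x(0) == -x(n-1)
    n = grid.shape[0]
    if abs(A[0, 0] * (n - 1) + 2 * A[0, 3]) > 1e-9:
        raise ValueError("grid is not symmetric about the x=0 plane")


def mirror_efield(E: EFieldImage) -> EFieldImage:
    """Reflect the field across the mid-sagittal plane (x -> -x)."""
    _x_flip_check(E.grid)
    flipped = np.ascontiguousarray(E.values[::-1, :, :])
    return EFieldImage(E.grid.like(flipped), E.patient_id)


def mirror_volume(grid: VoxelGrid) -> VoxelGrid:
    _x_flip_check(grid)
    return grid.like(np.ascontiguousarray(grid.values[::-1, :, :]))
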