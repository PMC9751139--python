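"""Voxel-wise sweetspot / sourspot mapping and cluster extraction.

Within a cohort-coverage mask, each voxel receives the Spearman
correlation between field magnitudes across patients and clinical
improvements. Positive voxels are "sweet" (more field, better outcome),
negative "sour". An unseen field is scored by the masked mean of
field x map products.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from skimage import measure

from stimmap.data_model import EFieldImage, VoxelGrid
from stimmap.efield import CoverageMask, coverage_mask, mirror_efield
from stimmap.stats import spearman_columns

__all__ = [
    "SweetspotMap",
    "ClusterRecord",
    "fit_sweetspot",
    "score_efield_map",
    "extract_clusters",
    "clusters_to_frame",
]

E_THRESHOLD = 0.2  # V/mm (= 200 V/m)
COVERAGE_FRACTION = 0.20


@dataclass
class SweetspotMap:
    """R-map on a coverage mask; NaN everywhere outside the mask."""

    grid: VoxelGrid            # R values, NaN outside mask
    mask: CoverageMask
    e_thr: float
    coverage_fraction: float
    mirrored: bool

    @property
    def values(self) -> np.ndarray:
        return self.grid.values


@dataclass
class ClusterRecord:
    sign: str                  # "sweet" | "sour"
    hemisphere: str            # "left" (x<0) | "right" (x>=0)
    peak_mm: np.ndarray
    peak_r: float
    cog_mm: np.ndarray
    n_voxels: int


def fit_sweetspot(fields: Sequence[EFieldImage], outcomes,
                  e_thr: float = E_THRESHOLD,
                  coverage_fraction: float = COVERAGE_FRACTION,
                  mirrored: bool = False) -> SweetspotMap:
    """Fit the voxel-wise R-map on the cohort coverage mask.

    With ``mirrored=True`` every field also contributes its x-flip with
    the same outcome (rows are duplicated, effectively doubling N).
    """
    fields = list(fields)
    outcomes = np.asarray(outcomes, dtype=float)
    if len(fields) < 3:
        raise ValueError("need at least 3 fields")
    if outcomes.shape != (len(fields),):
        raise ValueError("outcomes must align with fields")
    if mirrored:
        fields = fields + [mirror_efield(f) for f in fields]
        outcomes = np.concatenate([outcomes, outcomes])
    cm = coverage_mask(fields, e_thr, coverage_fraction)
    mask = cm.values
    if not mask.any():
        raise ValueError("empty coverage mask")
    stack = np.stack([f.values[mask] for f in fields])  # (N, n_masked)
    rho = spearman_columns(stack, outcomes)
    out = np.full(mask.shape, np.nan)
    out[mask] = rho
    return SweetspotMap(fields[0].grid.like(out), cm, e_thr,
                        coverage_fraction, mirrored)


def score_efield_map(smap: SweetspotMap, E: EFieldImage) -> float:
    """Masked mean of voxel-wise field x R products."""
    if E.grid.shape != smap.grid.shape or not np.allclose(
            E.grid.affine, smap.grid.affine):
        raise ValueError("field and map must share one grid")
    defined = np.isfinite(smap.values)
    if not defined.any():
        raise ValueError("no masked voxels to score on")
    return float(np.mean(E.values[defined] * smap.values[defined]))


def _components(binary: np.ndarray, connectivity: int) -> np.ndarray:
    conn = {6: 1, 18: 2, 26: 3}[connectivity]
    return measure.label(binary, connectivity=conn)


def extract_clusters(smap: SweetspotMap, connectivity: int = 26,
                     weighted_cog: bool = True) -> list[ClusterRecord]:
    """Connected components of {R>0} and {R<0}, split per hemisphere.

    Components are labelled within each hemisphere (x<0 / x>=0 in world
    mm) so midline-crossing blobs are reported per side. The peak is the
    max-|R| voxel (ties: lowest linear index); the centre of gravity is
    |R|-weighted by default.
    """
    if connectivity not in (6, 18, 26):
        raise ValueError("connectivity must be 6, 18 or 26")
    vals = smap.values
    if not np.isfinite(vals).any():
        raise ValueError("empty map")
    world = smap.grid.world_coordinates()
    wx = world[..., 0]
    records: list[ClusterRecord] = []
    for sign, binary in (("sweet", np.nan_to_num(vals) > 0),
                         ("sour", np.nan_to_num(vals) < 0)):
        for hemi, hmask in (("left", wx < 0), ("right", wx >= 0)):
            labels = _components(binary & hmask, connectivity)
            for lab in range(1, labels.max() + 1):
                comp = labels == lab
                absr = np.abs(np.where(comp, vals, 0.0))
                peak_flat = int(np.argmax(absr))  # ties -> lowest linear index
                peak_ijk = np.unravel_index(peak_flat, vals.shape)
                coords = world[comp]
                if weighted_cog:
                    w = absr[comp]
                    cog = (coords * w[:, None]).sum(axis=0) / w.sum()
                else:
                    cog = coords.mean(axis=0)
                records.append(ClusterRecord(
                    sign=sign,
                    hemisphere=hemi,
                    peak_mm=world[peak_ijk],
                    peak_r=float(vals[peak_ijk]),
                    cog_mm=cog,
                    n_voxels=int(comp.sum()),
                ))
    return records


def clusters_to_frame(records: list[ClusterRecord]) -> pd.DataFrame:
    rows = []
    for rec in records:
        rows.append({
            "sign": rec.sign,
            "hemisphere": rec.hemisphere,
            "peak_x": rec.peak_mm[0], "peak_y": rec.peak_mm[1], "peak_z": rec.peak_mm[2],
            "peak_R": rec.peak_r,
            "cog_x": rec.cog_mm[0], "cog_y": rec.cog_mm[1], "cog_z": rec.cog_mm[2],
            "n_voxels": rec.n_voxels,
        })
    return pd.DataFrame(rows)
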