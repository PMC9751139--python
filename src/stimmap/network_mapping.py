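"""Field-seeded connectivity fingerprints and network R-map models.

A connectome is a brain mask plus one BOLD-like timeseries per masked
voxel. Seeding from a patient's field produces a Fisher-z connectivity
fingerprint; fingerprints are rank-correlated with outcomes voxel-wise
into an R-map, and unseen fingerprints are scored by spatial similarity
to the R-map.

Storage layout: NIfTI mask + flat float32 timeseries matrix + JSON
sidecar; voxel order is mask scan order with x (axis 0) fastest.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import nibabel as nib
import numpy as np

from stimmap.data_model import EFieldImage, VoxelGrid
from stimmap.stats import spearman, spearman_columns

__all__ = [
    "Connectome",
    "Fingerprint",
    "NetworkRMap",
    "compute_fingerprint",
    "fit_rmap",
    "score_fingerprint",
    "decode_rmap",
    "save_connectome",
    "load_connectome",
]

_CLIP = 1.0 - 1e-7


@dataclass
class Connectome:
    """Brain mask plus per-masked-voxel timeseries (n_masked, T)."""

    mask: VoxelGrid          # boolean values
    timeseries: np.ndarray

    def __post_init__(self) -> None:
        m = np.asarray(self.mask.values, dtype=bool)
        self.mask = VoxelGrid(self.mask.affine, m)
        ts = np.asarray(self.timeseries, dtype=float)
        if ts.ndim != 2 or ts.shape[0] != int(m.sum()):
            raise ValueError("timeseries must be (n_masked_voxels, T)")
        if ts.shape[1] < 20:
            raise ValueError("need at least 20 time samples")
        if not np.all(np.isfinite(ts)):
            raise ValueError("non-finite timeseries")
        if np.any(ts.std(axis=1) == 0):
            raise ValueError("masked voxel with zero timeseries variance")
        self.timeseries = ts

    @property
    def n_voxels(self) -> int:
        return self.timeseries.shape[0]

    def mask_indices(self) -> np.ndarray:
        """(n_masked, 3) voxel indices in scan order, x fastest."""
        m = np.asarray(self.mask.values, dtype=bool)
        flat = np.flatnonzero(m.ravel(order="F"))
        return np.stack(np.unravel_index(flat, m.shape, order="F"), axis=1)

    def values_at_mask(self, volume: np.ndarray) -> np.ndarray:
        idx = self.mask_indices()
        return np.asarray(volume)[idx[:, 0], idx[:, 1], idx[:, 2]]

    def embed(self, values: np.ndarray, fill=np.nan) -> np.ndarray:
        out = np.full(self.mask.shape, fill, dtype=float)
        idx = self.mask_indices()
        out[idx[:, 0], idx[:, 1], idx[:, 2]] = values
        return out


@dataclass
class Fingerprint:
    values: np.ndarray       # Fisher-z per masked voxel
    patient_id: str = ""

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        if not np.all(np.isfinite(v)):
            raise ValueError("fingerprint must be finite")
        self.values = v


@dataclass
class NetworkRMap:
    values: np.ndarray       # Spearman rho per masked voxel
    mask: VoxelGrid


def compute_fingerprint(E: EFieldImage, conn: Connectome,
                        weighted: bool = True) -> Fingerprint:
    """Correlate a field-weighted seed timeseries with every masked voxel.

    The seed is the field-magnitude-weighted average of masked voxel
    timeseries (binary suprathreshold seed if ``weighted=False``); the
    per-voxel Pearson r is clipped and Fisher-z transformed. Invariant to
    positive rescaling of the field.
    """
    if E.grid.shape != conn.mask.shape or not np.allclose(
            E.grid.affine, conn.mask.affine):
        raise ValueError("field and connectome mask must share one grid")
    w = conn.values_at_mask(E.values)
    if not weighted:
        w = (w > 0).astype(float)
    if w.sum() <= 0:
        raise ValueError("field has no overlap with the connectome mask")
    seed = (w / w.sum()) @ conn.timeseries
    ts = conn.timeseries
    seed_c = seed - seed.mean()
    ts_c = ts - ts.mean(axis=1, keepdims=True)
    denom = np.linalg.norm(seed_c) * np.linalg.norm(ts_c, axis=1)
    if np.linalg.norm(seed_c) == 0:
        raise ValueError("seed timeseries is constant")
    r = (ts_c @ seed_c) / denom
    z = np.arctanh(np.clip(r, -_CLIP, _CLIP))
    return Fingerprint(z, E.patient_id)


def fit_rmap(fingerprints: Sequence[Fingerprint], outcomes,
             mask: VoxelGrid | None = None) -> NetworkRMap:
    """Voxel-wise Spearman of fingerprint values vs outcomes across patients."""
    fps = list(fingerprints)
    outcomes = np.asarray(outcomes, dtype=float)
    if len(fps) < 3:
        raise ValueError("need at least 3 fingerprints")
    if outcomes.shape != (len(fps),):
        raise ValueError("outcomes must align with fingerprints")
    if np.ptp(outcomes) == 0:
        raise ValueError("zero outcome variance")
    X = np.stack([fp.values for fp in fps])
    rho = spearman_columns(X, outcomes)
    return NetworkRMap(rho, mask)


def score_fingerprint(rmap: NetworkRMap, fp: Fingerprint) -> float:
    """Spatial Spearman similarity between a fingerprint and the R-map."""
    if fp.values.shape != rmap.values.shape:
        raise ValueError("fingerprint and R-map must share one mask")
    return spearman(fp.values, rmap.values)


def decode_rmap(rmap: NetworkRMap, term_maps: dict[str, np.ndarray],
                method: str = "spearman") -> list[tuple[str, float]]:
    """Rank a library of term maps by spatial similarity to the R-map.

    Term maps are flat vectors on the R-map's masked-voxel order. NaNs in
    the R-map or a term map are dropped pairwise. Returns (term,
    similarity) sorted descending.
    """
    if not term_maps:
        raise ValueError("empty term-map library")
    out = []
    rv = np.asarray(rmap.values, dtype=float)
    for term, tv in term_maps.items():
        tv = np.asarray(tv, dtype=float)
        if tv.shape != rv.shape:
            raise ValueError(f"term map {term!r} has wrong shape")
        ok = np.isfinite(rv) & np.isfinite(tv)
        if method == "spearman":
            sim = spearman(rv[ok], tv[ok])
        elif method == "pearson":
            sim = float(np.corrcoef(rv[ok], tv[ok])[0, 1])
        else:
            raise ValueError("method must be 'spearman' or 'pearson'")
        out.append((term, sim))
    return sorted(out, key=lambda kv: -kv[1])


def save_connectome(conn: Connectome, directory) -> None:
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    nib.save(nib.Nifti1Image(conn.mask.values.astype(np.uint8), conn.mask.affine),
             str(directory / "mask.nii"))
    ts = conn.timeseries.astype(np.float32)
    ts.tofile(directory / "timeseries.bin")
    meta = {"n_voxels": int(ts.shape[0]), "n_samples": int(ts.shape[1]),
            "dtype": "float32", "voxel_order": "mask scan order, x fastest"}
    (directory / "connectome.json").write_text(json.dumps(meta, indent=2))


def load_connectome(directory) -> Connectome:
    directory = Path(directory)
    meta = json.loads((directory / "connectome.json").read_text())
    img = nib.load(str(directory / "mask.nii"))
    mask = VoxelGrid(np.asarray(img.affine, dtype=float),
                     np.asarray(img.dataobj).astype(bool))
    ts = np.fromfile(directory / "timeseries.bin", dtype=np.float32)
    ts = ts.reshape(meta["n_voxels"], meta["n_samples"]).astype(float)
    return Connectome(mask, ts)
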