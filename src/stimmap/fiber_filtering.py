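"""Streamline-level outcome mapping ("fiber filtering").

Each patient's field assigns every streamline a weight — the peak field
magnitude sampled along it. Fibers suprathreshold in enough patients are
kept, and each kept fiber receives the Spearman correlation between its
weights and clinical improvements across the cohort. An unseen field is
scored by rank-correlating its fiber weights against the fitted R profile.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable, Sequence

import numpy as np

from stimmap.data_model import EFieldImage, Tractogram
from stimmap.stats import spearman, spearman_columns

__all__ = [
    "FiberScoreModel",
    "resample_streamline",
    "peak_weights",
    "weight_matrix",
    "filter_fibers",
    "fit_fiber_model",
    "score_efield",
    "score_weights",
    "connected_fibers",
]

E_THRESHOLD = 0.36  # V/mm
COVERAGE_FRACTION = 0.20


def resample_streamline(points: np.ndarray, step: float) -> np.ndarray:
    """Resample a polyline to uniform arc-length spacing <= step."""
    points = np.asarray(points, dtype=float)
    seg = np.linalg.norm(np.diff(points, axis=0), axis=1)
    arc = np.concatenate([[0.0], np.cumsum(seg)])
    total = arc[-1]
    if total == 0.0:
        return points[:1].repeat(2, axis=0)
    n = max(int(np.ceil(total / step)) + 1, 2)
    t = np.linspace(0.0, total, n)
    out = np.empty((n, 3))
    for d in range(3):
        out[:, d] = np.interp(t, arc, points[:, d])
    return out


def _sampling_step(E: EFieldImage, step: float | None) -> float:
    # fine enough that thin voxels are not skipped
    return step if step is not None else 0.5 * float(E.grid.spacing().min())


def _resample_all(tract: Tractogram, step: float) -> tuple[np.ndarray, np.ndarray]:
    """Concatenate resampled points of all fibers; return (points, fiber_id)."""
    pts, fid = [], []
    for i, sl in enumerate(tract.streamlines):
        rs = resample_streamline(sl, step)
        pts.append(rs)
        fid.append(np.full(len(rs), i))
    return np.concatenate(pts), np.concatenate(fid)


def _segment_max(values: np.ndarray, fiber_id: np.ndarray, n_fibers: int) -> np.ndarray:
    out = np.zeros(n_fibers)
    np.maximum.at(out, fiber_id, values)
    return out


def peak_weights(E: EFieldImage, tract: Tractogram,
                 step: float | None = None) -> np.ndarray:
    """Peak field magnitude along each fiber (nearest-voxel lookup).

    Points falling outside the grid contribute 0, so a fiber entirely
    outside the field has weight 0.
    """
    if len(tract) == 0:
        raise ValueError("empty tractogram")
    pts, fid = _resample_all(tract, _sampling_step(E, step))
    ijk, inside = E.grid.world_to_voxel(pts)
    vals = np.zeros(len(pts))
    if inside.any():
        ii = ijk[inside]
        vals[inside] = E.values[ii[:, 0], ii[:, 1], ii[:, 2]]
    return _segment_max(vals, fid, len(tract))


def peak_weights_from_function(field_fn: Callable[[np.ndarray], np.ndarray],
                               tract: Tractogram, step: float) -> np.ndarray:
    """Peak of an analytic field evaluated at resampled fiber points."""
    if len(tract) == 0:
        raise ValueError("empty tractogram")
    pts, fid = _resample_all(tract, step)
    return _segment_max(np.asarray(field_fn(pts), dtype=float), fid, len(tract))


def weight_matrix(fields: Sequence[EFieldImage], tract: Tractogram,
                  step: float | None = None) -> np.ndarray:
    """Stack per-patient peak weights into (n_patients, n_fibers).

    Fibers are resampled once and reused across the cohort.
    """
    if not fields:
        raise ValueError("need at least one field")
    st = _sampling_step(fields[0], step)
    pts, fid = _resample_all(tract, st)
    W = np.zeros((len(fields), len(tract)))
    for r, E in enumerate(fields):
        ijk, inside = E.grid.world_to_voxel(pts)
        vals = np.zeros(len(pts))
        if inside.any():
            ii = ijk[inside]
            vals[inside] = E.values[ii[:, 0], ii[:, 1], ii[:, 2]]
        W[r] = _segment_max(vals, fid, len(tract))
    return W


def filter_fibers(W: np.ndarray, e_thr: float = E_THRESHOLD,
                  coverage_fraction: float = COVERAGE_FRACTION) -> np.ndarray:
    """Keep fibers suprathreshold in >= coverage_fraction of rows."""
    W = np.asarray(W, dtype=float)
    if W.size == 0:
        raise ValueError("empty weight matrix")
    frac = (W >= e_thr).sum(axis=0) / W.shape[0]
    return frac >= coverage_fraction


@dataclass
class FiberScoreModel:
    """Per-fiber Spearman R with inclusion flags and fit parameters."""

    r: np.ndarray          # NaN for excluded fibers
    included: np.ndarray   # bool per fiber
    e_thr: float
    coverage_fraction: float

    @property
    def n_included(self) -> int:
        return int(self.included.sum())

    def to_dict(self) -> dict:
        return {
            "e_thr": self.e_thr,
            "coverage_fraction": self.coverage_fraction,
            "r": [None if not np.isfinite(v) else float(v) for v in self.r],
            "included": self.included.astype(bool).tolist(),
        }

    @classmethod
    def from_dict(cls, d: dict) -> "FiberScoreModel":
        r = np.array([np.nan if v is None else v for v in d["r"]], dtype=float)
        return cls(r, np.asarray(d["included"], dtype=bool),
                   float(d["e_thr"]), float(d["coverage_fraction"]))


def fit_fiber_model(W: np.ndarray, outcomes: np.ndarray,
                    e_thr: float = E_THRESHOLD,
                    coverage_fraction: float = COVERAGE_FRACTION,
                    aggregation: str = "peak") -> FiberScoreModel:
    """Correlate each kept fiber's weights with outcomes across all rows.

    Mass-univariate by design: the per-fiber R values are descriptive,
    not significance-tested. Fibers with zero weight variance (or a
    constant outcome vector) have undefined R and are excluded. May
    return an empty model.
    """
    if aggregation != "peak":
        raise ValueError("only 'peak' aggregation is implemented")
    W = np.asarray(W, dtype=float)
    outcomes = np.asarray(outcomes, dtype=float)
    if W.ndim != 2 or W.shape[0] != outcomes.shape[0]:
        raise ValueError("rows of W must align with outcomes")
    if W.shape[0] < 3:
        raise ValueError("need at least 3 rows")
    included = filter_fibers(W, e_thr, coverage_fraction)
    r = np.full(W.shape[1], np.nan)
    if included.any():
        r[included] = spearman_columns(W[:, included], outcomes)
    included = included & np.isfinite(r)
    r[~included] = np.nan
    return FiberScoreModel(r, included, e_thr, coverage_fraction)


def score_weights(model: FiberScoreModel, weights: np.ndarray,
                  positive_only: bool = False) -> float:
    """Score one field's fiber-weight vector against the fitted R profile.

    Spearman across included fibers between the field's peak weights and
    the model R values; higher predicts better outcome.
    """
    weights = np.asarray(weights, dtype=float)
    if weights.shape[0] != model.r.shape[0]:
        raise ValueError("weights must align with model fibers")
    sel = model.included.copy()
    if positive_only:
        sel &= model.r > 0
    if sel.sum() < 3:
        raise ValueError("too few included fibers to score")
    s = spearman(weights[sel], model.r[sel])
    if np.isnan(s):
        raise ValueError("zero variance in weights or model R values")
    return s


def score_efield(model: FiberScoreModel, E: EFieldImage, tract: Tractogram,
                 step: float | None = None, positive_only: bool = False) -> float:
    return score_weights(model, peak_weights(E, tract, step), positive_only)


def score_weight_rows(model: FiberScoreModel, W: np.ndarray,
                      positive_only: bool = False) -> np.ndarray:
    """Vectorised :func:`score_weights` over the rows of a weight matrix."""
    W = np.asarray(W, dtype=float)
    sel = model.included.copy()
    if positive_only:
        sel &= model.r > 0
    if sel.sum() < 3:
        raise ValueError("too few included fibers to score")
    return spearman_columns(W[:, sel].T, model.r[sel])


def connected_fibers(model: FiberScoreModel, E: EFieldImage, tract: Tractogram,
                     e_thr: float | None = None, step: float | None = None) -> np.ndarray:
    """Indices of included fibers whose peak weight under ``E`` exceeds e_thr."""
    thr = model.e_thr if e_thr is None else e_thr
    w = peak_weights(E, tract, step)
    return np.flatnonzero(model.included & (w > thr))
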