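"""Cross-validation, permutation testing and prediction metrics.

All three mapping levels plug in through :class:`ModelSpec`: a ``fit``
closure mapping (training indices, training outcomes) to a fitted model,
and a ``score`` closure mapping (model, unit indices) to unitless scores.
Scores become predicted improvements (%) through a per-fold affine
calibration, so error metrics live on the clinical scale.

Beware the initialism: MAE here is the MEDIAN absolute error.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Any, Callable, Sequence

import numpy as np

from stimmap import fiber_filtering as ff
from stimmap import network_mapping as nm
from stimmap import sweetspot as ss
from stimmap.stats import spearman_with_p

__all__ = [
    "ModelSpec",
    "CVResult",
    "PermutationResult",
    "loocv",
    "kfold",
    "permutation_test",
    "calibrate",
    "prediction_metrics",
    "fiber_spec",
    "sweetspot_spec",
    "network_spec",
]


@dataclass
class ModelSpec:
    """One mapping level packaged for cross-validation."""

    level: str
    outcomes: np.ndarray
    fit: Callable[[np.ndarray, np.ndarray], Any]
    score: Callable[[Any, np.ndarray], np.ndarray]
    params: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.outcomes = np.asarray(self.outcomes, dtype=float)

    @property
    def n(self) -> int:
        return self.outcomes.shape[0]


@dataclass
class CVResult:
    scores: np.ndarray        # held-out unitless score per unit
    predicted: np.ndarray     # calibrated predicted improvement (%)
    r: float
    p: float
    rms: float
    mae: float                # MEDIAN absolute error
    r2_sse: float
    folds: np.ndarray         # fold index per unit
    seed: int | None


@dataclass
class PermutationResult:
    observed_r: float
    null_r: np.ndarray
    p: float
    n_perm: int
    seed: int


def calibrate(train_scores, train_outcomes) -> tuple[float, float]:
    """Least-squares affine map score -> improvement %: (slope, intercept)."""
    s = np.asarray(train_scores, dtype=float)
    y = np.asarray(train_outcomes, dtype=float)
    if s.shape != y.shape or s.ndim != 1:
        raise ValueError("scores and outcomes must be 1-D and aligned")
    if s.size < 3:
        raise ValueError("need at least 3 calibration points")
    if np.ptp(s) == 0:
        raise ValueError("zero score variance")
    slope, intercept = np.polyfit(s, y, 1)
    return float(slope), float(intercept)


def prediction_metrics(predicted, actual) -> dict[str, float]:
    """Spearman R/p, RMS error, MEDIAN absolute error, sum-of-squares R^2.

    ``r2_sse = 1 - SSE/SST`` (can be negative; 0 for a constant-mean
    prediction). R is NaN when either vector is constant.
    """
    pred = np.asarray(predicted, dtype=float)
    act = np.asarray(actual, dtype=float)
    if pred.shape != act.shape or pred.ndim != 1:
        raise ValueError("predicted and actual must be 1-D and aligned")
    if pred.size < 3:
        raise ValueError("need at least 3 pairs")
    r, p = spearman_with_p(pred, act)
    err = pred - act
    rms = float(np.sqrt(np.mean(err**2)))
    mae = float(np.median(np.abs(err)))
    sst = float(np.sum((act - act.mean()) ** 2))
    sse = float(np.sum(err**2))
    r2 = 1.0 - sse / sst if sst > 0 else float("nan")
    return {"r": r, "p": p, "rms": rms, "mae": mae, "r2_sse": r2}


def _fold_assignment(n: int, k: int, seed: int | None) -> np.ndarray:
    """Seeded shuffle then contiguous split; remainder to the first folds."""
    order = (np.random.default_rng(seed).permutation(n)
             if seed is not None else np.arange(n))
    sizes = np.full(k, n // k)
    sizes[: n % k] += 1
    folds = np.empty(n, dtype=int)
    start = 0
    for f, sz in enumerate(sizes):
        folds[order[start:start + sz]] = f
        start += sz
    return folds


def _run_cv(spec: ModelSpec, folds: np.ndarray, seed: int | None) -> CVResult:
    n = spec.n
    scores = np.full(n, np.nan)
    predicted = np.full(n, np.nan)
    for f in range(folds.max() + 1):
        test = np.flatnonzero(folds == f)
        train = np.flatnonzero(folds != f)
        y_train = spec.outcomes[train]
        if np.ptp(y_train) == 0:
            raise ValueError("degenerate fold: constant outcomes in training")
        model = spec.fit(train, y_train)
        scores[test] = spec.score(model, test)
        slope, intercept = calibrate(spec.score(model, train), y_train)
        predicted[test] = slope * scores[test] + intercept
    r, p = spearman_with_p(scores, spec.outcomes)
    m = prediction_metrics(predicted, spec.outcomes)
    return CVResult(scores, predicted, r, p, m["rms"], m["mae"], m["r2_sse"],
                    folds, seed)


def loocv(spec: ModelSpec) -> CVResult:
    """Leave-one-out: fit on N-1, score the held-out unit, for every unit."""
    if spec.n < 4:
        raise ValueError("need at least 4 units for LOOCV")
    return _run_cv(spec, np.arange(spec.n), seed=None)


def kfold(spec: ModelSpec, k: int, seed: int = 0) -> CVResult:
    """Seeded k-fold with near-equal fold sizes (|size difference| <= 1)."""
    if k < 2:
        raise ValueError("k must be >= 2")
    if k > spec.n:
        raise ValueError("k cannot exceed the number of units")
    return _run_cv(spec, _fold_assignment(spec.n, k, seed), seed)


def _insample_r(spec: ModelSpec, outcomes: np.ndarray) -> float:
    all_idx = np.arange(spec.n)
    model = spec.fit(all_idx, outcomes)
    scores = spec.score(model, all_idx)
    r, _ = spearman_with_p(scores, outcomes)
    return r


def permutation_test(spec: ModelSpec, n_perm: int = 1000,
                     seed: int = 0) -> PermutationResult:
    """One-sided permutation test of the in-sample score/outcome correlation.

    ``p = (1 + #{null >= observed}) / (n_perm + 1)`` — never exactly 0.
    """
    if n_perm < 99:
        raise ValueError("need at least 99 permutations")
    rng = np.random.default_rng(seed)
    observed = _insample_r(spec, spec.outcomes)
    null = np.empty(n_perm)
    for i in range(n_perm):
        null[i] = _insample_r(spec, rng.permutation(spec.outcomes))
    p = (1 + int(np.sum(null >= observed))) / (n_perm + 1)
    return PermutationResult(observed, null, p, n_perm, seed)


# ---------------------------------------------------------------------------
# Level adapters


def fiber_spec(W: np.ndarray, outcomes, e_thr: float = ff.E_THRESHOLD,
               coverage_fraction: float = ff.COVERAGE_FRACTION,
               positive_only: bool = False) -> ModelSpec:
    """Fiber-filtering level on a precomputed (patients x fibers) matrix."""
    W = np.asarray(W, dtype=float)

    def fit(idx, y):
        return ff.fit_fiber_model(W[idx], y, e_thr, coverage_fraction)

    def score(model, idx):
        return ff.score_weight_rows(model, W[idx], positive_only)

    return ModelSpec("fibers", outcomes, fit, score,
                     {"e_thr": e_thr, "coverage_fraction": coverage_fraction})


def sweetspot_spec(fields: Sequence, outcomes, e_thr: float = ss.E_THRESHOLD,
                   coverage_fraction: float = ss.COVERAGE_FRACTION,
                   mirrored: bool = False) -> ModelSpec:
    fields = list(fields)

    def fit(idx, y):
        return ss.fit_sweetspot([fields[i] for i in idx], y, e_thr,
                                coverage_fraction, mirrored)

    def score(model, idx):
        return np.array([ss.score_efield_map(model, fields[i]) for i in idx])

    return ModelSpec("sweetspot", outcomes, fit, score,
                     {"e_thr": e_thr, "coverage_fraction": coverage_fraction,
                      "mirrored": mirrored})


def network_spec(fingerprints: Sequence, outcomes) -> ModelSpec:
    fps = list(fingerprints)

    def fit(idx, y):
        return nm.fit_rmap([fps[i] for i in idx], y)

    def score(model, idx):
        return np.array([nm.score_fingerprint(model, fps[i]) for i in idx])

    return ModelSpec("network", outcomes, fit, score, {})
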