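"""Rank-correlation machinery shared by all three mapping levels.

Everything here is Spearman: ranks with average ties, then a Pearson
product-moment on the ranks. The mass-univariate helpers operate on
columns of a matrix so that per-fiber / per-voxel maps are a single
vectorised pass rather than a Python loop.
"""

from __future__ import annotations

import numpy as np
from scipy import special, stats as sps

__all__ = [
    "spearman",
    "spearman_with_p",
    "spearman_columns",
    "spearman_columns_with_p",
]


def _rank(a: np.ndarray, axis: int = 0) -> np.ndarray:
    return sps.rankdata(a, method="average", axis=axis)


def spearman(a, b) -> float:
    """Spearman rho between two 1-D vectors; NaN if either is constant."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.shape != b.shape or a.ndim != 1:
        raise ValueError("inputs must be 1-D vectors of equal length")
    if a.size < 2:
        raise ValueError("need at least 2 observations")
    ra, rb = _rank(a), _rank(b)
    ra = ra - ra.mean()
    rb = rb - rb.mean()
    denom = np.sqrt((ra @ ra) * (rb @ rb))
    if denom == 0.0:
        return float("nan")
    return float((ra @ rb) / denom)


def _p_from_rho(rho: np.ndarray, n: int) -> np.ndarray:
    """Two-sided p via the t approximation with n-2 dof."""
    rho = np.asarray(rho, dtype=float)
    with np.errstate(divide="ignore", invalid="ignore"):
        t = rho * np.sqrt((n - 2) / (1.0 - rho**2))
    # |rho| == 1 -> infinite t -> p = 0; NaN rho propagates
    p = 2.0 * special.stdtr(n - 2, -np.abs(t))
    p = np.where(np.isclose(np.abs(rho), 1.0), 0.0, p)
    return np.where(np.isnan(rho), np.nan, p)


def spearman_with_p(a, b) -> tuple[float, float]:
    rho = spearman(a, b)
    n = np.asarray(a).size
    if n < 3 or np.isnan(rho):
        return rho, float("nan")
    return rho, float(_p_from_rho(np.array(rho), n))


def spearman_columns(X: np.ndarray, y: np.ndarray) -> np.ndarray:
    """Spearman rho of every column of ``X`` (n_obs x n_feat) against ``y``.

    Columns with zero rank variance — and the case of constant ``y`` —
    yield NaN rather than raising: downstream models treat NaN as
    "undefined, excluded".
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    if X.ndim != 2:
        raise ValueError("X must be 2-D (observations x features)")
    if y.shape != (X.shape[0],):
        raise ValueError("y length must match number of rows of X")
    rX = _rank(X, axis=0)
    ry = _rank(y)
    rX = rX - rX.mean(axis=0)
    ry = ry - ry.mean()
    ssx = np.einsum("ij,ij->j", rX, rX)
    ssy = ry @ ry
    with np.errstate(divide="ignore", invalid="ignore"):
        rho = (ry @ rX) / np.sqrt(ssx * ssy)
    return rho


def spearman_columns_with_p(X: np.ndarray, y: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    rho = spearman_columns(X, y)
    return rho, _p_from_rho(rho, np.asarray(X).shape[0])
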