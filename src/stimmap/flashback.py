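"""Probe-level fiber filtering against binary stimulation-evoked events.

Probes (patient x contact x amplitude settings) replace patients as the
unit of analysis. Each kept fiber is rank-correlated with the 0/1 event
vector (rank point-biserial) and flagged by Benjamini-Hochberg FDR.
Within-patient dependence between probes is deliberately not modelled.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from stimmap import fiber_filtering as ff
from stimmap.stats import spearman_columns_with_p

__all__ = [
    "ProbeSet",
    "FlashbackFiberResult",
    "fit_flashback_fibers",
    "fdr_correct",
]


@dataclass
class ProbeSet:
    """Stimulation probes: one row per (patient, contact, amplitude) setting.

    Columns: patient, contact, amplitude, event (bool), optional
    intensity (discrete severity score, carried through but unused by the
    default binary contrast).
    """

    table: pd.DataFrame = field(repr=False)

    REQUIRED = ("patient", "contact", "amplitude", "event")

    def __post_init__(self) -> None:
        missing = [c for c in self.REQUIRED if c not in self.table.columns]
        if missing:
            raise ValueError(f"probe table missing columns: {missing}")
        self.table = self.table.reset_index(drop=True)

    def __len__(self) -> int:
        return len(self.table)

    @property
    def events(self) -> np.ndarray:
        return self.table["event"].to_numpy(bool)


@dataclass
class FlashbackFiberResult:
    r: np.ndarray            # NaN for excluded fibers
    p: np.ndarray            # two-sided, NaN for excluded fibers
    significant: np.ndarray  # BH rejection at q over included fibers
    included: np.ndarray
    q: float


def fdr_correct(p_values, q: float = 0.05) -> np.ndarray:
    """Benjamini-Hochberg step-up rejection flags at level ``q``.

    Rejects all p <= p_(k*) where k* = max{k : p_(k) <= k*q/m}.
    """
    p = np.asarray(p_values, dtype=float)
    if p.ndim != 1:
        raise ValueError("p_values must be 1-D")
    if np.any((p < 0) | (p > 1) | ~np.isfinite(p)):
        raise ValueError("p-values must lie in [0, 1]")
    m = p.size
    if m == 0:
        return np.zeros(0, dtype=bool)
    order = np.argsort(p, kind="stable")
    sorted_p = p[order]
    thresh = q * np.arange(1, m + 1) / m
    passing = np.flatnonzero(sorted_p <= thresh)
    if passing.size == 0:
        return np.zeros(m, dtype=bool)
    cutoff = sorted_p[passing[-1]]
    return p <= cutoff


def fit_flashback_fibers(W: np.ndarray, events, e_thr: float = ff.E_THRESHOLD,
                         coverage_fraction: float = ff.COVERAGE_FRACTION,
                         q: float = 0.05) -> FlashbackFiberResult:
    """Correlate fiber weights with binary events; flag FDR-significant fibers.

    ``W`` is a (probes x fibers) peak-weight matrix; inclusion follows the
    same coverage rule as outcome-based fiber filtering.
    """
    W = np.asarray(W, dtype=float)
    ev = np.asarray(events).astype(bool)
    if W.ndim != 2 or W.shape[0] != ev.shape[0]:
        raise ValueError("rows of W must align with events")
    if ev.all() or not ev.any():
        raise ValueError("need both event and non-event probes")
    included = ff.filter_fibers(W, e_thr, coverage_fraction)
    r = np.full(W.shape[1], np.nan)
    p = np.full(W.shape[1], np.nan)
    if included.any():
        r_in, p_in = spearman_columns_with_p(W[:, included], ev.astype(float))
        r[included] = r_in
        p[included] = p_in
    included = included & np.isfinite(r)
    significant = np.zeros(W.shape[1], dtype=bool)
    if included.any():
        significant[included] = fdr_correct(p[included], q)
    return FlashbackFiberResult(r, p, significant, included, q)
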