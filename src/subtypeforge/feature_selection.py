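"""Classifier probe-set selection keyed to pivotal genes.

Candidate probes are screened by their linear (Pearson) or quadratic
(degree-2 polynomial R^2) correlation with any of a curated list of pivotal
genes, then filtered on mean log2 intensity, dynamic range, and density
kurtosis.  Low Pearson kurtosis (m4/m2^2 < 3) flags flat or multi-modal
densities, which make robust classifier features; heavy-tailed unimodal
probes are discarded.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np

from .dataio import ExpressionMatrix

__all__ = [
    "PivotalGeneSet",
    "ProbeFilterCriteria",
    "linear_correlation",
    "quadratic_r2",
    "kurtosis",
    "select_classifier_probes",
]


@dataclass
class PivotalGeneSet:
    """Probe ids of the pivotal (anchor) genes, as rows of the matrix."""

    probe_ids: list[str]

    def __post_init__(self) -> None:
        if not self.probe_ids:
            raise ValueError("pivotal gene set must not be empty")
        if len(set(self.probe_ids)) != len(self.probe_ids):
            raise ValueError("pivotal gene ids must be unique")


@dataclass
class ProbeFilterCriteria:
    """Thresholds for classifier probe selection.

    ``min_abs_linear_r`` / ``min_quadratic_r2`` are effect-size thresholds
    (a probe passes if either is met versus *any* pivotal gene); intensity
    and range are in log2 units; kurtosis is the Pearson m4/m2^2 form and
    acts as an upper bound.
    """

    min_abs_linear_r: float = 0.5
    min_quadratic_r2: float = 0.5
    min_mean_intensity: float = math.log2(100.0)
    min_range: float = 2.0
    max_kurtosis: float = 3.0

    def __post_init__(self) -> None:
        if not 0 <= self.min_abs_linear_r <= 1:
            raise ValueError("min_abs_linear_r must be in [0, 1]")
        if not 0 <= self.min_quadratic_r2 <= 1:
            raise ValueError("min_quadratic_r2 must be in [0, 1]")
        for v in (self.min_mean_intensity, self.min_range, self.max_kurtosis):
            if math.isnan(v):
                raise ValueError("thresholds must not be NaN")


def linear_correlation(x, y) -> float:
    """Pearson correlation; NaN (not an exception) for constant input."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be 1-D of equal length")
    if len(x) < 3:
        raise ValueError("need at least 3 observations")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        return float("nan")
    xc = x - x.mean()
    yc = y - y.mean()
    return float(np.dot(xc, yc) / math.sqrt(np.dot(xc, xc) * np.dot(yc, yc)))


def quadratic_r2(x, y) -> float:
    """R^2 of the least-squares degree-2 polynomial fit of y on x.

    Returns NaN when the design is degenerate (fewer than 3 distinct x
    values) or y is constant.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be 1-D of equal length")
    if len(x) < 4:
        raise ValueError("need at least 4 observations")
    if len(np.unique(x)) < 3:
        return float("nan")
    sst = float(np.sum((y - y.mean()) ** 2))
    if sst == 0:
        return float("nan")
    design = np.column_stack([np.ones_like(x), x, x * x])
    coef, *_ = np.linalg.lstsq(design, y, rcond=None)
    ssr = float(np.sum((y - design @ coef) ** 2))
    return max(0.0, min(1.0, 1.0 - ssr / sst))


def kurtosis(v) -> float:
    """Pearson kurtosis m4/m2^2 (population moments, not excess)."""
    v = np.asarray(v, dtype=float)
    if v.ndim != 1 or len(v) < 4:
        raise ValueError("need a 1-D vector of length >= 4")
    c = v - v.mean()
    m2 = float(np.mean(c * c))
    if m2 == 0:
        return float("nan")
    return float(np.mean(c ** 4) / m2 ** 2)


def _corr_matrix(values: np.ndarray, pivot: np.ndarray) -> np.ndarray:
    """|Pearson r| of every row of `values` against one pivot vector."""
    pc = pivot - pivot.mean()
    denom_p = float(np.dot(pc, pc))
    vc = values - values.mean(axis=1, keepdims=True)
    denom_v = np.einsum("ij,ij->i", vc, vc)
    with np.errstate(invalid="ignore", divide="ignore"):
        r = (vc @ pc) / np.sqrt(denom_v * denom_p)
    return r


def _quad_r2_matrix(values: np.ndarray, pivot: np.ndarray) -> np.ndarray:
    """Degree-2 fit R^2 of every row of `values` on one pivot vector."""
    design = np.column_stack([np.ones_like(pivot), pivot, pivot * pivot])
    # least squares of all rows at once on the shared design
    coef, *_ = np.linalg.lstsq(design, values.T, rcond=None)
    fitted = (design @ coef).T
    sst = np.sum((values - values.mean(axis=1, keepdims=True)) ** 2, axis=1)
    ssr = np.sum((values - fitted) ** 2, axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        r2 = 1.0 - ssr / sst
    return np.clip(r2, 0.0, 1.0)


def select_classifier_probes(m: ExpressionMatrix, pivots: PivotalGeneSet,
                             criteria: ProbeFilterCriteria) -> list[str]:
    """Select probes correlated with any pivotal gene and passing the
    intensity/range/kurtosis filters.

    A probe qualifies when, versus at least one pivotal gene other than
    itself, ``|r| >= min_abs_linear_r`` or ``quadratic R^2 >=
    min_quadratic_r2``, and additionally its mean log2 intensity, range
    (max - min), and kurtosis satisfy the remaining thresholds.  Undefined
    (constant-probe) correlations never qualify.  Output preserves matrix
    row order.
    """
    probe_index = {p: i for i, p in enumerate(m.probe_ids)}
    missing = [p for p in pivots.probe_ids if p not in probe_index]
    if missing:
        raise KeyError(f"pivotal probes absent from matrix: {missing[:5]}")

    v = m.values
    ptp = np.ptp(v, axis=1)
    nonconstant = ptp > 0

    corr_ok = np.zeros(v.shape[0], dtype=bool)
    for p in pivots.probe_ids:
        pivot = v[probe_index[p]]
        if np.ptp(pivot) == 0:
            continue
        with np.errstate(invalid="ignore"):
            r = _corr_matrix(v, pivot)
            hit = np.abs(r) >= criteria.min_abs_linear_r
            r2 = _quad_r2_matrix(v, pivot)
            hit |= r2 >= criteria.min_quadratic_r2
        hit[probe_index[p]] = False  # a pivot is not its own correlation target
        corr_ok |= np.where(nonconstant, hit, False)

    mean_ok = v.mean(axis=1) >= criteria.min_mean_intensity
    range_ok = ptp >= criteria.min_range
    c = v - v.mean(axis=1, keepdims=True)
    m2 = np.mean(c * c, axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        kurt = np.mean(c ** 4, axis=1) / m2 ** 2
    kurt_ok = np.where(nonconstant, kurt <= criteria.max_kurtosis, False)

    keep = corr_ok & mean_ok & range_ok & kurt_ok
    selected = [p for i, p in enumerate(m.probe_ids) if keep[i]]
    if not selected:
        warnings.warn("no probes passed the selection criteria")
    return selected
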