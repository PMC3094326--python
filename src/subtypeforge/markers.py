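"""Receptor status calling from bimodal marker-gene expression.

ER, PR and HER2 expression on log2 microarray scale is typically bimodal:
a negative (low) and a positive (high) mode.  A two-component Gaussian
mixture is fitted by EM and the cut-point placed where posterior membership
in the two components is equal; samples above the cut-point are called
positive.  A density-minimum cut is available as an alternative.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np
from scipy.optimize import brentq, minimize_scalar
from scipy.stats import norm
from sklearn.mixture import GaussianMixture

__all__ = ["MarkerCutpoints", "fit_bimodal_cutpoint", "call_status"]


@dataclass
class MarkerCutpoints:
    """A fitted bimodal cut-point for one marker gene.

    ``means``/``sds``/``weight`` describe the two-component Gaussian
    mixture (component 1 is the lower mode; ``weight`` is its mixing
    proportion).  ``weakly_bimodal`` flags fits whose modes are closer
    than half the pooled SD.
    """

    role: str
    cutpoint: float
    means: tuple[float, float]
    sds: tuple[float, float]
    weight: float
    log_likelihood: float
    converged: bool
    weakly_bimodal: bool = False

    def __post_init__(self) -> None:
        if not self.means[0] < self.cutpoint < self.means[1]:
            raise ValueError("cutpoint must lie strictly between the component means")
        if not 0 < self.weight < 1:
            raise ValueError("mixture weight must be in (0, 1)")


def _posterior_equal_cut(m1: float, s1: float, w1: float,
                         m2: float, s2: float, w2: float) -> float:
    """Point between the means where the two weighted component densities
    (hence the posteriors) are equal."""

    def diff(x: float) -> float:
        return (math.log(w1) + norm.logpdf(x, m1, s1)
                - math.log(w2) - norm.logpdf(x, m2, s2))

    lo, hi = m1, m2
    flo, fhi = diff(lo), diff(hi)
    if flo > 0 > fhi:
        return float(brentq(diff, lo, hi, xtol=1e-10))
    # no sign change strictly inside (extreme weights): fall back to the
    # admissible point closest to equality
    grid = np.linspace(lo, hi, 2001)[1:-1]
    vals = np.abs([diff(x) for x in grid])
    return float(grid[int(np.argmin(vals))])


def _density_min_cut(m1: float, s1: float, w1: float,
                     m2: float, s2: float, w2: float) -> float:
    def dens(x: float) -> float:
        return w1 * norm.pdf(x, m1, s1) + w2 * norm.pdf(x, m2, s2)

    res = minimize_scalar(dens, bounds=(m1, m2), method="bounded",
                          options={"xatol": 1e-10})
    return float(res.x)


def fit_bimodal_cutpoint(values, role: str = "ER", n_restarts: int = 20,
                         seed: int | None = None,
                         method: str = "posterior") -> MarkerCutpoints:
    """Fit a two-Gaussian mixture to marker expression and place the
    positive/negative cut-point.

    Parameters
    ----------
    values : array-like
        log2 expression of the marker gene across >= 30 samples.
    n_restarts : int
        EM restarts; the best log-likelihood fit is kept.
    method : {"posterior", "density-min"}
        Posterior-equality cut (default) or the mixture-density minimum
        between the two modes.
    """
    v = np.asarray(values, dtype=float)
    if v.ndim != 1 or len(v) < 30:
        raise ValueError("need a 1-D vector of at least 30 values")
    if not np.all(np.isfinite(v)):
        raise ValueError("marker values must be finite")
    gm = GaussianMixture(
        n_components=2,
        covariance_type="full",
        tol=1e-8,
        max_iter=2000,
        n_init=n_restarts,
        init_params="random",
        random_state=seed,
    )
    gm.fit(v.reshape(-1, 1))
    if not gm.converged_:
        raise RuntimeError("EM failed to converge in all restarts")
    means = gm.means_.ravel()
    sds = np.sqrt(gm.covariances_.ravel())
    weights = gm.weights_.ravel()
    order = np.argsort(means)
    m1, m2 = float(means[order[0]]), float(means[order[1]])
    s1, s2 = float(sds[order[0]]), float(sds[order[1]])
    w1, w2 = float(weights[order[0]]), float(weights[order[1]])

    pooled = math.sqrt(w1 * s1**2 + w2 * s2**2)
    weak = (m2 - m1) < 0.5 * pooled
    if weak:
        warnings.warn(f"{role}: component means closer than 0.5 x pooled SD; "
                      "fit is weakly bimodal")

    if method == "posterior":
        cut = _posterior_equal_cut(m1, s1, w1, m2, s2, w2)
    elif method == "density-min":
        cut = _density_min_cut(m1, s1, w1, m2, s2, w2)
    else:
        raise ValueError(f"unknown cut-point method {method!r}")
    # keep strictly inside the mode interval
    cut = min(max(cut, np.nextafter(m1, m2)), np.nextafter(m2, m1))

    ll = float(gm.score(v.reshape(-1, 1)) * len(v))
    return MarkerCutpoints(
        role=role,
        cutpoint=float(cut),
        means=(m1, m2),
        sds=(s1, s2),
        weight=w1,
        log_likelihood=ll,
        converged=bool(gm.converged_),
        weakly_bimodal=bool(weak),
    )


def call_status(values, cut: MarkerCutpoints) -> np.ndarray:
    """Call pos/neg per sample: positive iff value > cutpoint (a value
    exactly at the cut-point is called negative)."""
    v = np.asarray(values, dtype=float)
    return np.where(v > cut.cutpoint, "pos", "neg")
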