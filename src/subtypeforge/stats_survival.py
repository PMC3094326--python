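"""Contingency, survival, and cross-dataset concordance statistics.

Exact r x c Fisher tests (probability-mass two-sided criterion) back the
clinical association tables; Kaplan-Meier estimation and the unweighted
log-rank test back the survival comparisons; a label-permutation test backs
the cross-dataset concordance of per-subtype mean expression profiles.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from lifelines import KaplanMeierFitter
from scipy import stats as _sps

from ._fisher import fisher_exact_2xc as _fisher_2xc
from ._fisher import fisher_exact_rxc as _fisher_rxc
from .dataio import ExpressionMatrix

__all__ = [
    "ContingencyTable",
    "ConcordanceResult",
    "KaplanMeierCurve",
    "LogrankResult",
    "fisher_exact_2xc",
    "fisher_exact_rxc",
    "km_estimate",
    "logrank_test",
    "subtype_concordance",
]


@dataclass
class ContingencyTable:
    """r x c non-negative integer counts with optional axis labels."""

    counts: np.ndarray
    row_labels: list[str] | None = None
    col_labels: list[str] | None = None

    def __post_init__(self) -> None:
        a = np.asarray(self.counts)
        if a.ndim != 2:
            raise ValueError("counts must be 2-D")
        if not np.issubdtype(a.dtype, np.integer):
            f = a.astype(float)
            if np.any(f != np.round(f)) or not np.all(np.isfinite(f)):
                raise ValueError("counts must be integers")
            a = f.astype(np.int64)
        if (a < 0).any():
            raise ValueError("counts must be non-negative")
        if a.sum() == 0:
            raise ValueError("table total must be positive")
        self.counts = a.astype(np.int64)
        if self.row_labels is not None and len(self.row_labels) != a.shape[0]:
            raise ValueError("row_labels length mismatch")
        if self.col_labels is not None and len(self.col_labels) != a.shape[1]:
            raise ValueError("col_labels length mismatch")

    @classmethod
    def from_labels(cls, a, b) -> "ContingencyTable":
        """Cross-tabulate two equal-length label vectors."""
        tab = pd.crosstab(pd.Series(a), pd.Series(b))
        return cls(tab.to_numpy(), [str(x) for x in tab.index],
                   [str(x) for x in tab.columns])


def fisher_exact_2xc(table) -> float:
    """Exact two-sided Fisher p for a 2 x c table (probability-mass
    criterion, exact integer arithmetic)."""
    counts = table.counts if isinstance(table, ContingencyTable) else table
    return _fisher_2xc(counts)


def fisher_exact_rxc(table, *, mode: str = "exact", B: int = 100_000,
                     seed: int | None = None, **kwargs) -> float:
    """Exact (or seeded Monte-Carlo) two-sided Fisher p for an r x c table."""
    counts = table.counts if isinstance(table, ContingencyTable) else table
    return _fisher_rxc(counts, mode=mode, B=B, seed=seed, **kwargs)


@dataclass
class KaplanMeierCurve:
    """Product-limit survival estimate as a right-continuous step function."""

    times: np.ndarray
    survival: np.ndarray
    n_at_risk: np.ndarray = field(default=None, repr=False)

    def __call__(self, t) -> np.ndarray | float:
        t = np.asarray(t, dtype=float)
        idx = np.searchsorted(self.times, t, side="right") - 1
        out = np.where(idx < 0, 1.0, self.survival[np.clip(idx, 0, None)])
        return float(out) if out.ndim == 0 else out


def km_estimate(times, events) -> KaplanMeierCurve:
    """Kaplan-Meier product-limit estimator.

    Censored observations tied with events at the same time are considered
    at risk for that event (the conventional events-first ordering).
    """
    t = np.asarray(times, dtype=float)
    e = np.asarray(events, dtype=bool)
    if t.ndim != 1 or len(t) == 0 or t.shape != e.shape:
        raise ValueError("times and events must be equal-length, non-empty 1-D")
    if (t < 0).any():
        raise ValueError("negative survival time")
    kmf = KaplanMeierFitter()
    kmf.fit(t, event_observed=e)
    sf = kmf.survival_function_
    grid = sf.index.to_numpy(dtype=float)
    surv = sf.iloc[:, 0].to_numpy(dtype=float)
    return KaplanMeierCurve(times=grid, survival=surv)


@dataclass
class LogrankResult:
    chi2: float
    df: int
    p: float


def logrank_test(groups) -> LogrankResult:
    """Unweighted k-sample log-rank test.

    ``groups`` is a sequence of (times, events) pairs, one per group.
    Ties use the hypergeometric variance with ties.  With zero events
    overall the test is degenerate and p = 1 is returned with a warning.
    """
    if len(groups) < 2:
        raise ValueError("need at least two groups")
    times, events, labels = [], [], []
    for g, (t, e) in enumerate(groups):
        t = np.asarray(t, dtype=float)
        e = np.asarray(e, dtype=bool)
        if len(t) == 0:
            raise ValueError(f"group {g} is empty")
        if (t < 0).any():
            raise ValueError("negative survival time")
        times.append(t)
        events.append(e)
        labels.append(np.full(len(t), g))
    t = np.concatenate(times)
    e = np.concatenate(events)
    g = np.concatenate(labels)
    k = len(groups)
    df = k - 1
    if not e.any():
        warnings.warn("no events in any group; log-rank test is degenerate")
        return LogrankResult(chi2=0.0, df=df, p=1.0)

    event_times = np.unique(t[e])
    n_et = len(event_times)
    n_risk = np.empty((n_et, k))
    d = np.empty((n_et, k))
    for j in range(k):
        tj = np.sort(times[j])
        n_risk[:, j] = len(tj) - np.searchsorted(tj, event_times, side="left")
        tj_ev = np.sort(times[j][events[j]])
        lo = np.searchsorted(tj_ev, event_times, side="left")
        hi = np.searchsorted(tj_ev, event_times, side="right")
        d[:, j] = hi - lo
    n_tot = n_risk.sum(axis=1)
    d_tot = d.sum(axis=1)
    frac = n_risk / n_tot[:, None]
    obs = d.sum(axis=0)
    exp = (d_tot[:, None] * frac).sum(axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        v = np.where(n_tot > 1, d_tot * (n_tot - d_tot) / (n_tot - 1), 0.0)
    cov = (np.einsum("t,tj,tk->jk", -v, frac, frac)
           + np.diag(np.einsum("t,tj->j", v, frac)))
    z = (obs - exp)[:df]
    vmat = cov[:df, :df]
    try:
        chi2 = float(z @ np.linalg.solve(vmat, z))
    except np.linalg.LinAlgError:
        chi2 = float(z @ np.linalg.pinv(vmat) @ z)
    chi2 = max(0.0, chi2)
    p = float(_sps.chi2.sf(chi2, df))
    return LogrankResult(chi2=chi2, df=df, p=p)


@dataclass
class ConcordanceResult:
    r_obs: float
    p_perm: float
    B: int

    def __post_init__(self) -> None:
        if not self.p_perm >= 1.0 / (self.B + 1):
            raise ValueError("permutation p cannot undercut 1/(B+1)")


def _standardized_subtype_means(values: np.ndarray, labels: np.ndarray,
                                label_order: list) -> np.ndarray:
    z = values - values.mean(axis=1, keepdims=True)
    sd = values.std(axis=1, keepdims=True)
    sd[sd == 0] = 1.0
    z = z / sd
    return np.column_stack([z[:, labels == lab].mean(axis=1) for lab in label_order])


def subtype_concordance(mean_a: pd.DataFrame, dataset_b: ExpressionMatrix,
                        labels_b, B: int = 10_000,
                        seed: int | None = None) -> ConcordanceResult:
    """Permutation test for cross-dataset concordance of subtype profiles.

    ``mean_a`` holds per-gene subtype means of the reference dataset
    (genes x subtypes, already on a per-gene standardized scale or raw --
    it is re-standardized per gene here).  The observed statistic is the
    Pearson correlation between the vectorized per-gene subtype means of
    the two datasets; the null permutes dataset B's subtype labels across
    samples ``B`` times, and ``p = (1 + #{r_perm >= r_obs}) / (B + 1)``.
    """
    if B < 1:
        raise ValueError("B must be >= 1")
    labels_b = np.asarray(labels_b)
    if len(labels_b) != len(dataset_b.sample_ids):
        raise ValueError("one label per dataset-B sample required")
    label_order = list(mean_a.columns)
    missing = [lab for lab in label_order if lab not in set(labels_b)]
    if missing:
        raise ValueError(f"subtype(s) absent in dataset B: {missing}")
    shared = [gene for gene in mean_a.index if gene in set(dataset_b.probe_ids)]
    if not shared:
        raise ValueError("no shared genes between mean_a and dataset B")

    a = mean_a.loc[shared].to_numpy(dtype=float)
    a = a - a.mean(axis=1, keepdims=True)
    sd = a.std(axis=1, keepdims=True)
    sd[sd == 0] = 1.0
    a = (a / sd).ravel()

    b_matrix = dataset_b.subset_probes(shared).values

    def stat(lbls: np.ndarray) -> float:
        b = _standardized_subtype_means(b_matrix, lbls, label_order)
        b = b - b.mean(axis=1, keepdims=True)
        sdb = b.std(axis=1, keepdims=True)
        sdb[sdb == 0] = 1.0
        return float(np.corrcoef(a, (b / sdb).ravel())[0, 1])

    r_obs = stat(labels_b)
    rng = np.random.default_rng(seed)
    hits = 0
    lbls = labels_b.copy()
    for _ in range(B):
        rng.shuffle(lbls)  # preserves label counts, so every subtype stays present
        if stat(lbls) >= r_obs:
            hits += 1
    return ConcordanceResult(r_obs=r_obs, p_perm=(1 + hits) / (B + 1), B=B)
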