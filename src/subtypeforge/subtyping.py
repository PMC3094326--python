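"""Molecular subtype discovery and nearest-centroid classification.

Subtypes are discovered by a two-step k-means procedure on per-probe
z-scored expression: a conventional Euclidean k-means (best of many random
restarts) seeds the partition, after which every sample is iteratively
reassigned to the centroid it correlates with best (Spearman by default,
the usual single-sample-predictor practice) until the partition is stable.
New samples or whole external datasets are classified against the stored
centroids, optionally after probe-to-gene mapping across platforms.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import stats as _sps
from sklearn.cluster import KMeans

from .dataio import ExpressionMatrix

__all__ = [
    "ROMAN_LABELS",
    "SubtypeModel",
    "SubtypeAssignment",
    "two_step_kmeans",
    "compute_centroids",
    "classify_by_centroid",
    "map_cross_platform",
]

log = logging.getLogger(__name__)

ROMAN_LABELS = ["I", "II", "III", "IV", "V", "VI", "VII", "VIII", "IX", "X"]


@dataclass
class SubtypeModel:
    """K subtype centroids over the classifier probe list.

    Centroids live on the standardized (per-probe z-score) scale; the
    fit-time center/scale vectors are stored so that new samples are
    standardized identically at classification time.
    """

    classifier_probes: list[str]
    centroids: np.ndarray = field(repr=False)  # probes x K
    labels: list[str]
    center: np.ndarray = field(repr=False)
    scale: np.ndarray = field(repr=False)

    def __post_init__(self) -> None:
        self.centroids = np.asarray(self.centroids, dtype=float)
        k = self.centroids.shape[1]
        if k < 2:
            raise ValueError("a subtype model needs at least 2 centroids")
        if len(self.labels) != k or len(set(self.labels)) != k:
            raise ValueError("labels must be distinct, one per centroid")
        if self.centroids.shape[0] != len(self.classifier_probes):
            raise ValueError("centroid rows must match classifier probes")
        if not np.all(np.isfinite(self.centroids)):
            raise ValueError("centroids must be finite")

    @property
    def k(self) -> int:
        return self.centroids.shape[1]


@dataclass
class SubtypeAssignment:
    sample_id: str
    label: str
    correlation_to_best: float
    margin: float

    def __post_init__(self) -> None:
        if self.margin < 0:
            raise ValueError("margin must be non-negative")


def _standardize(values: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    center = values.mean(axis=1)
    scale = values.std(axis=1)
    scale = np.where(scale == 0, 1.0, scale)
    z = (values - center[:, None]) / scale[:, None]
    return z, center, scale


def _rank_rows(a: np.ndarray) -> np.ndarray:
    return np.apply_along_axis(_sps.rankdata, 0, a)


def _corr_columns(x: np.ndarray, c: np.ndarray, method: str) -> np.ndarray:
    """Correlation of every column of x with every column of c -> (nx, nc)."""
    if method == "spearman":
        x = _rank_rows(x)
        c = _rank_rows(c)
    elif method != "pearson":
        raise ValueError(f"unknown correlation method {method!r}")
    xc = x - x.mean(axis=0)
    cc = c - c.mean(axis=0)
    num = xc.T @ cc
    denom = np.outer(np.sqrt(np.sum(xc**2, axis=0)), np.sqrt(np.sum(cc**2, axis=0)))
    with np.errstate(invalid="ignore", divide="ignore"):
        out = num / denom
    return np.nan_to_num(out, nan=0.0)


def _order_clusters(z: np.ndarray, assign: np.ndarray, k: int,
                    anchor: np.ndarray | None) -> list[int]:
    """Deterministic cluster ordering for label assignment.

    With an anchor vector (e.g. an estrogen-receptor probe), clusters are
    ordered by ascending mean anchor expression -- the most
    anchor-negative cluster gets the first label -- with larger size
    breaking ties.  Without one, ordering falls back to descending size,
    then lowest member index.
    """
    keys = []
    for g in range(k):
        members = np.flatnonzero(assign == g)
        size = len(members)
        first = int(members.min()) if size else np.inf
        if anchor is not None and size:
            keys.append((float(anchor[members].mean()), -size, first, g))
        else:
            keys.append((0.0, -size, first, g))
    return [g for *_, g in sorted(keys)]


def two_step_kmeans(m: ExpressionMatrix, k: int = 6, n_restarts: int = 100,
                    seed: int | None = None, max_iter: int = 50,
                    method: str = "spearman",
                    anchor_probe: str | None = None
                    ) -> tuple[list[str], SubtypeModel]:
    """Two-step k-means subtype discovery.

    Step 1 runs Euclidean k-means on per-probe z-scored data over
    ``n_restarts`` random initializations, keeping the lowest-inertia
    solution.  Step 2 computes per-cluster centroids and iteratively
    reassigns every sample to its best-correlated centroid until a fixed
    point (at most ``max_iter`` sweeps).  Clusters emptied by reassignment
    are dropped with a warning.

    Returns per-sample labels and the fitted :class:`SubtypeModel`.
    """
    n_samples = len(m.sample_ids)
    if k < 2:
        raise ValueError("k must be >= 2")
    if k > n_samples:
        raise ValueError(f"k={k} exceeds the {n_samples} available samples")
    if seed is None:
        raise ValueError("a seed is required for reproducible clustering")
    log.info("two_step_kmeans: k=%d restarts=%d seed=%d", k, n_restarts, seed)

    z, center, scale = _standardize(m.values)
    km = KMeans(n_clusters=k, n_init=n_restarts, random_state=seed,
                algorithm="lloyd")
    assign = km.fit_predict(z.T)

    for _ in range(max_iter):
        centroids = np.column_stack([
            z[:, assign == g].mean(axis=1) for g in range(k)
        ])
        corr = _corr_columns(z, centroids, method)
        new_assign = np.argmax(corr, axis=1)
        if np.array_equal(new_assign, assign):
            break
        assign = new_assign
        present = np.unique(assign)
        if len(present) < k:
            warnings.warn(
                f"reassignment emptied {k - len(present)} cluster(s); "
                f"continuing with K={len(present)}"
            )
            remap = {g: i for i, g in enumerate(present)}
            assign = np.array([remap[g] for g in assign])
            k = len(present)

    centroids = np.column_stack([z[:, assign == g].mean(axis=1) for g in range(k)])
    anchor = None
    if anchor_probe is not None:
        anchor = m.probe_values(anchor_probe)
    order = _order_clusters(z, assign, k, anchor)
    labels_vocab = ROMAN_LABELS[:k]
    relabel = {g: labels_vocab[i] for i, g in enumerate(order)}
    labels = [relabel[g] for g in assign]
    model = SubtypeModel(
        classifier_probes=list(m.probe_ids),
        centroids=centroids[:, order],
        labels=labels_vocab,
        center=center,
        scale=scale,
    )
    return labels, model


def compute_centroids(m: ExpressionMatrix, labels: list[str]) -> SubtypeModel:
    """Build a centroid model from a labeled expression matrix.

    Each centroid is the per-probe mean of its member columns on the
    standardized scale; label order follows first appearance after
    sorting by the Roman-numeral vocabulary where applicable.
    """
    if len(labels) != len(m.sample_ids):
        raise ValueError("one label per sample required")
    uniq: list[str] = []
    for lab in labels:
        if lab not in uniq:
            uniq.append(lab)
    roman_rank = {lab: i for i, lab in enumerate(ROMAN_LABELS)}
    uniq.sort(key=lambda lab: (roman_rank.get(lab, len(ROMAN_LABELS)), lab))
    z, center, scale = _standardize(m.values)
    arr = np.asarray(labels)
    centroids = np.column_stack([z[:, arr == lab].mean(axis=1) for lab in uniq])
    return SubtypeModel(list(m.probe_ids), centroids, uniq, center, scale)


def classify_by_centroid(profiles: ExpressionMatrix, model: SubtypeModel,
                         method: str = "spearman") -> list[SubtypeAssignment]:
    """Assign each sample to the subtype centroid it correlates with best.

    At least half of the model's classifier probes must be resolvable in
    the profile matrix; ties between centroids are broken in favor of the
    earlier label, with a warning.
    """
    probe_pos = {p: i for i, p in enumerate(profiles.probe_ids)}
    resolved = [(i, probe_pos[p]) for i, p in enumerate(model.classifier_probes)
                if p in probe_pos]
    overlap = len(resolved) / len(model.classifier_probes)
    if overlap < 0.5:
        raise ValueError(
            f"only {overlap:.0%} of classifier probes resolvable (need >= 50%)"
        )
    model_rows = np.array([i for i, _ in resolved])
    profile_rows = np.array([j for _, j in resolved])
    z = ((profiles.values[profile_rows] - model.center[model_rows, None])
         / model.scale[model_rows, None])
    corr = _corr_columns(z, model.centroids[model_rows], method)
    out: list[SubtypeAssignment] = []
    for s, sid in enumerate(profiles.sample_ids):
        row = corr[s]
        best = int(np.argmax(row))
        ties = np.flatnonzero(row >= row[best] - 1e-12)
        if len(ties) > 1:
            warnings.warn(f"correlation tie for sample {sid!r}; "
                          f"assigning first label in order")
            best = int(ties.min())
        rest = np.delete(row, best)
        margin = float(row[best] - rest.max()) if rest.size else 0.0
        out.append(SubtypeAssignment(sid, model.labels[best],
                                     float(row[best]), max(0.0, margin)))
    return out


def map_cross_platform(target_probe_ids: list[str], gene_map: dict[str, str],
                       external: ExpressionMatrix) -> ExpressionMatrix:
    """Project an external dataset onto a target probe id space.

    ``gene_map`` relates target probe ids to gene symbols; external rows
    whose id (or mapped gene) matches a target's gene are averaged.
    Unmatched target ids are dropped and reported in the log.
    """
    covered = [p for p in target_probe_ids if p in gene_map]
    if len(covered) / max(1, len(target_probe_ids)) < 0.5:
        raise ValueError("gene map covers < 50% of target probe ids")
    ext_by_gene: dict[str, list[int]] = {}
    for i, pid in enumerate(external.probe_ids):
        gene = gene_map.get(pid, pid)
        ext_by_gene.setdefault(gene, []).append(i)
    rows = []
    kept: list[str] = []
    dropped: list[str] = []
    for p in target_probe_ids:
        gene = gene_map.get(p)
        idx = ext_by_gene.get(gene) if gene is not None else None
        if not idx:
            dropped.append(p)
            continue
        rows.append(external.values[idx].mean(axis=0))
        kept.append(p)
    if not kept:
        raise ValueError("no target probes could be matched in the external dataset")
    if dropped:
        log.info("map_cross_platform: dropped %d unmatched target ids", len(dropped))
    return ExpressionMatrix(kept, list(external.sample_ids), np.vstack(rows))
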