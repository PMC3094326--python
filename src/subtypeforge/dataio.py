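"""Expression/clinical I/O, preprocessing, and cohort eligibility filters.

Expression matrices are tab-separated text: the header row carries sample
ids, the first column probe ids, and every other cell a log2 (or linear,
before :func:`preprocess`) intensity.  Clinical tables are CSV with one row
per sample.  Preprocessing follows the standard single-channel microarray
chain: per-sample trimmed-mean scaling to a common target, log2 transform,
then quantile normalization across samples.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as _sps

__all__ = [
    "ExpressionMatrix",
    "CLINICAL_COLUMNS",
    "QC_COLUMNS",
    "read_expression",
    "write_expression",
    "read_clinical",
    "write_clinical",
    "validate_clinical",
    "read_qc",
    "preprocess",
    "quantile_normalize",
    "filter_eligible",
]


@dataclass
class ExpressionMatrix:
    """A probes x samples grid of expression intensities.

    Attributes
    ----------
    probe_ids : list of str
        Unique row identifiers (probe-sets).
    sample_ids : list of str
        Unique column identifiers.
    values : ndarray of shape (n_probes, n_samples)
        Finite intensities; log2 scale after :func:`preprocess`.
    """

    probe_ids: list[str]
    sample_ids: list[str]
    values: np.ndarray = field(repr=False)

    def __post_init__(self) -> None:
        self.probe_ids = [str(p) for p in self.probe_ids]
        self.sample_ids = [str(s) for s in self.sample_ids]
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise ValueError("values must be a 2-D array")
        if self.values.shape != (len(self.probe_ids), len(self.sample_ids)):
            raise ValueError(
                f"values shape {self.values.shape} does not match "
                f"{len(self.probe_ids)} probes x {len(self.sample_ids)} samples"
            )
        if self.values.size == 0:
            raise ValueError("expression matrix must not be empty")
        for name, ids in (("probe", self.probe_ids), ("sample", self.sample_ids)):
            seen: set[str] = set()
            for i in ids:
                if i in seen:
                    raise ValueError(f"duplicate {name} id: {i!r}")
                seen.add(i)
        if not np.all(np.isfinite(self.values)):
            raise ValueError("expression values must be finite")

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.probe_ids, columns=self.sample_ids)

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "ExpressionMatrix":
        return cls(list(df.index), list(df.columns), df.to_numpy(dtype=float))

    def subset_probes(self, probes: list[str]) -> "ExpressionMatrix":
        index = {p: i for i, p in enumerate(self.probe_ids)}
        missing = [p for p in probes if p not in index]
        if missing:
            raise KeyError(f"probes not in matrix: {missing[:5]}")
        rows = [index[p] for p in probes]
        return ExpressionMatrix(list(probes), list(self.sample_ids), self.values[rows])

    def subset_samples(self, samples: list[str]) -> "ExpressionMatrix":
        index = {s: i for i, s in enumerate(self.sample_ids)}
        missing = [s for s in samples if s not in index]
        if missing:
            raise KeyError(f"samples not in matrix: {missing[:5]}")
        cols = [index[s] for s in samples]
        return ExpressionMatrix(list(self.probe_ids), list(samples), self.values[:, cols])

    def probe_values(self, probe: str) -> np.ndarray:
        try:
            i = self.probe_ids.index(probe)
        except ValueError:
            raise KeyError(f"probe {probe!r} not in matrix") from None
        return self.values[i]


#: clinical CSV schema, one row per sample
CLINICAL_COLUMNS = [
    "sample_id",
    "age_years",
    "t_stage",
    "n_stage",
    "m_stage",
    "tnm_stage",
    "nuclear_grade",
    "er_ihc",
    "pr_ihc",
    "her2_ihc",
    "chemo_regimen",
    "hormonal_rx",
    "radiation_rx",
    "followup_years",
    "dead_of_disease",
    "mfs_time_years",
    "mfs_event",
    "os_time_years",
    "os_event",
]

QC_COLUMNS = ["sample_id", "rna_ok", "rna_sufficient", "array_ok"]

_IHC_LEVELS = {"pos", "neg", "unknown"}
_REGIMENS = {"CMF", "CAF", "taxane", "none"}


def validate_clinical(df: pd.DataFrame) -> pd.DataFrame:
    """Validate a clinical table against the expected schema."""
    missing = [c for c in CLINICAL_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"clinical table missing columns: {missing}")
    df = df.copy()
    if df["sample_id"].duplicated().any():
        dup = df.loc[df["sample_id"].duplicated(), "sample_id"].iloc[0]
        raise ValueError(f"duplicate sample id in clinical table: {dup!r}")
    for col in ("er_ihc", "pr_ihc", "her2_ihc"):
        bad = set(df[col].astype(str)) - _IHC_LEVELS
        if bad:
            raise ValueError(f"invalid {col} values: {sorted(bad)}")
    bad = set(df["chemo_regimen"].astype(str)) - _REGIMENS
    if bad:
        raise ValueError(f"invalid chemo_regimen values: {sorted(bad)}")
    for col in ("followup_years", "mfs_time_years", "os_time_years"):
        if (df[col].astype(float) < 0).any():
            raise ValueError(f"negative times in column {col}")
    for col in ("hormonal_rx", "radiation_rx", "dead_of_disease", "mfs_event", "os_event"):
        df[col] = df[col].astype(bool)
    return df


def read_expression(path, fmt: str = "tsv") -> ExpressionMatrix:
    """Read a probes x samples expression TSV (header = sample ids,
    first column = probe ids)."""
    if fmt != "tsv":
        raise ValueError(f"unsupported format {fmt!r}")
    df = pd.read_csv(path, sep="\t", index_col=0, dtype=str)
    probe_ids = [str(p) for p in df.index]
    for ids, name in ((probe_ids, "probe"), (list(df.columns), "sample")):
        seen: set[str] = set()
        for i in ids:
            if i in seen:
                raise ValueError(f"duplicate {name} id in {path}: {i!r}")
            seen.add(i)
    try:
        values = df.to_numpy(dtype=float)
    except ValueError:
        for j, col in enumerate(df.columns):
            for i, v in enumerate(df[col]):
                try:
                    float(v)
                except (TypeError, ValueError):
                    raise ValueError(
                        f"non-numeric cell at probe {probe_ids[i]!r}, "
                        f"sample {col!r}: {v!r}"
                    ) from None
        raise
    return ExpressionMatrix(probe_ids, list(df.columns), values)


def write_expression(m: ExpressionMatrix, path) -> None:
    """Write an expression matrix as TSV with >= 12 significant digits."""
    m.to_frame().to_csv(path, sep="\t", float_format="%.17g",
                        index_label="probe_id")


def read_clinical(path) -> pd.DataFrame:
    df = pd.read_csv(path)
    return validate_clinical(df)


def write_clinical(df: pd.DataFrame, path) -> None:
    validate_clinical(df).to_csv(path, index=False, float_format="%.17g")


def read_qc(path) -> pd.DataFrame:
    df = pd.read_csv(path)
    missing = [c for c in QC_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"QC table missing columns: {missing}")
    for col in QC_COLUMNS[1:]:
        df[col] = df[col].astype(bool)
    return df


def preprocess(raw: ExpressionMatrix, target_trimmed_mean: float = 500.0,
               trim_fraction: float = 0.02) -> ExpressionMatrix:
    """Scale each sample to a common trimmed mean, then log2-transform.

    Parameters
    ----------
    raw : ExpressionMatrix
        Linear-scale intensities, strictly positive.
    target_trimmed_mean : float
        Post-scaling trimmed mean of every sample column (default 500).
    trim_fraction : float
        Fraction discarded from *each* tail before averaging (default 2%,
        the usual single-channel array convention).
    """
    if not 0 <= trim_fraction < 0.25:
        raise ValueError("trim_fraction must be in [0, 0.25)")
    if target_trimmed_mean <= 0:
        raise ValueError("target_trimmed_mean must be positive")
    v = raw.values
    if np.any(v <= 0):
        raise ValueError("preprocess requires strictly positive linear intensities")
    tm = _sps.trim_mean(v, trim_fraction, axis=0)
    scaled = v * (target_trimmed_mean / tm)
    return ExpressionMatrix(list(raw.probe_ids), list(raw.sample_ids), np.log2(scaled))


def quantile_normalize(m: ExpressionMatrix) -> ExpressionMatrix:
    """Force every sample column onto the common per-rank mean distribution.

    Ties within a column receive the mean of the reference values at the
    tied ranks.  With a single sample the matrix is returned unchanged
    (with a warning), as there is nothing to normalize against.
    """
    v = m.values
    n_probes, n_samples = v.shape
    if n_samples < 2:
        warnings.warn("quantile_normalize: single sample, returning input unchanged")
        return ExpressionMatrix(list(m.probe_ids), list(m.sample_ids), v.copy())
    ref = np.mean(np.sort(v, axis=0), axis=1)
    out = np.empty_like(v)
    for j in range(n_samples):
        order = np.argsort(v[:, j], kind="stable")
        col_sorted = v[order, j]
        starts = np.concatenate([[0], np.flatnonzero(np.diff(col_sorted)) + 1])
        lengths = np.diff(np.concatenate([starts, [n_probes]]))
        seg_means = np.add.reduceat(ref, starts) / lengths
        out[order, j] = np.repeat(seg_means, lengths)
    return ExpressionMatrix(list(m.probe_ids), list(m.sample_ids), out)


def filter_eligible(clinical: pd.DataFrame, qc: pd.DataFrame,
                    min_followup_years: float = 3.0) -> list[str]:
    """Apply QC then follow-up eligibility, returning kept sample ids.

    A sample is kept when all three QC flags pass and its follow-up is at
    least ``min_followup_years`` -- unless the patient died of disease, in
    which case short follow-up does not exclude them.
    """
    clinical = validate_clinical(clinical)
    qc_map = qc.set_index("sample_id")
    kept: list[str] = []
    for _, row in clinical.iterrows():
        sid = row["sample_id"]
        if sid not in qc_map.index:
            raise ValueError(f"missing QC record for sample {sid!r}")
        q = qc_map.loc[sid]
        if not (bool(q["rna_ok"]) and bool(q["rna_sufficient"]) and bool(q["array_ok"])):
            continue
        if float(row["followup_years"]) >= min_followup_years or bool(row["dead_of_disease"]):
            kept.append(sid)
    return kept
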