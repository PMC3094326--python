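"""Distant-recurrence risk scores: the 21-gene recurrence score and a
good-prognosis-template correlation score.

The recurrence score (RS) combines 16 informative genes into four group
scores (HER2/GRB7, ER, proliferation, invasion) plus three singleton genes,
with floors on the HER2 and proliferation groups:

    GRB7g  = max(8,   0.9*GRB7 + 0.1*HER2)
    ERg    = (0.8*ER + 1.2*PGR + BCL2 + SCUBE2) / 4
    PROLIFg= max(6.5, mean(BIRC5, KI67, MYBL2, CCNB1, AURKA))
    INVg   = mean(CTSL2, MMP11)
    RSu    = 0.47*GRB7g - 0.34*ERg + 1.04*PROLIFg + 0.10*INVg
             + 0.05*CD68 - 0.08*GSTM1 - 0.07*BAG1
    RS     = clamp(20*(RSu - 6.7), 0, 100)

with risk groups low (< 18), intermediate (18-30), high (>= 31).  Inputs
are reference-normalized expression on the assay's 0-15 scale;
:func:`reference_normalize` provides the documented default affine map
from cohort log2 values.

The template score is the Pearson correlation of a tumor profile with a
good-prognosis template profile; negative correlation means high risk.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping

import numpy as np

__all__ = [
    "ONCOTYPE_GENES",
    "RecurrenceScore",
    "MammaprintScore",
    "oncotype_rs",
    "mammaprint_score",
    "reference_normalize",
]

#: the 16 informative genes of the recurrence-score model
ONCOTYPE_GENES = [
    "GRB7", "HER2", "ER", "PGR", "BCL2", "SCUBE2",
    "BIRC5", "KI67", "MYBL2", "CCNB1", "AURKA",
    "CTSL2", "MMP11", "CD68", "GSTM1", "BAG1",
]

#: accepted aliases for the informative genes
GENE_ALIASES = {"STK15": "AURKA", "Survivin": "BIRC5", "ESR1": "ER",
                "ERBB2": "HER2", "MKI67": "KI67"}


@dataclass
class RecurrenceScore:
    unscaled: float
    scaled: float
    group: str

    def __post_init__(self) -> None:
        if not 0 <= self.scaled <= 100:
            raise ValueError("scaled RS must be within [0, 100]")
        if self.group not in {"low", "intermediate", "high"}:
            raise ValueError(f"invalid risk group {self.group!r}")


@dataclass
class MammaprintScore:
    score: float
    group: str

    def __post_init__(self) -> None:
        if not -1 <= self.score <= 1:
            raise ValueError("correlation score must be in [-1, 1]")
        expected = "high" if self.score < 0 else "low"
        if self.group != expected:
            raise ValueError("group must be high iff score < 0")


def _rs_group(scaled: float) -> str:
    if scaled < 18:
        return "low"
    if scaled < 31:
        return "intermediate"
    return "high"


def oncotype_rs(x: Mapping[str, float]) -> RecurrenceScore:
    """Compute the recurrence score from reference-normalized expression.

    ``x`` maps each informative gene (see :data:`ONCOTYPE_GENES`; common
    aliases accepted) to its reference-normalized value.  Missing genes
    raise a KeyError naming the gene.
    """
    vals: dict[str, float] = {}
    for key, v in x.items():
        vals[GENE_ALIASES.get(key, key)] = float(v)
    for gene in ONCOTYPE_GENES:
        if gene not in vals:
            raise KeyError(f"missing gene for recurrence score: {gene}")
        if not np.isfinite(vals[gene]):
            raise ValueError(f"non-finite value for gene {gene}")

    grb7_g = max(8.0, 0.9 * vals["GRB7"] + 0.1 * vals["HER2"])
    er_g = (0.8 * vals["ER"] + 1.2 * vals["PGR"] + vals["BCL2"] + vals["SCUBE2"]) / 4
    prolif_g = max(6.5, float(np.mean([vals[g] for g in
                                       ("BIRC5", "KI67", "MYBL2", "CCNB1", "AURKA")])))
    inv_g = float(np.mean([vals["CTSL2"], vals["MMP11"]]))
    unscaled = (0.47 * grb7_g - 0.34 * er_g + 1.04 * prolif_g + 0.10 * inv_g
                + 0.05 * vals["CD68"] - 0.08 * vals["GSTM1"] - 0.07 * vals["BAG1"])
    scaled = float(np.clip(20 * (unscaled - 6.7), 0.0, 100.0))
    return RecurrenceScore(unscaled=float(unscaled), scaled=scaled,
                           group=_rs_group(scaled))


def reference_normalize(values: np.ndarray, low: float | None = None,
                        high: float | None = None) -> np.ndarray:
    """Affine map of cohort log2 expression onto the 0-15 reference scale.

    By default the cohort's own min/max define the map; fixed anchors can
    be supplied to normalize external cohorts consistently.
    """
    v = np.asarray(values, dtype=float)
    lo = float(v.min()) if low is None else low
    hi = float(v.max()) if high is None else high
    if hi <= lo:
        raise ValueError("reference range must have high > low")
    return 15.0 * (v - lo) / (hi - lo)


def mammaprint_score(profile, template) -> MammaprintScore:
    """Correlation of a tumor profile with the good-prognosis template.

    Score is the Pearson correlation over the shared gene list; a score
    below zero is called high risk, zero or above low risk.
    """
    p = np.asarray(profile, dtype=float)
    t = np.asarray(template, dtype=float)
    if p.shape != t.shape or p.ndim != 1:
        raise ValueError("profile and template must be 1-D of equal length")
    mask = np.isfinite(p) & np.isfinite(t)
    if mask.sum() < 0.5 * len(p):
        raise ValueError("fewer than 50% of template genes shared with profile")
    p, t = p[mask], t[mask]
    if np.ptp(p) == 0 or np.ptp(t) == 0:
        raise ValueError("profile and template must be non-constant")
    r = float(np.corrcoef(p, t)[0, 1])
    r = max(-1.0, min(1.0, r))
    return MammaprintScore(score=r, group="high" if r < 0 else "low")
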