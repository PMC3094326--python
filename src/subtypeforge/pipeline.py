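"""End-to-end orchestration: preprocessing -> probe selection -> subtyping
-> marker cut-points -> risk scores -> association/survival statistics.

The pipeline is configured by a validated :class:`PipelineConfig` (YAML on
disk), logs every stage's parameters and seed, and writes machine-readable
JSON/CSV outputs plus a copy of the fully-resolved configuration for
provenance.
"""

from __future__ import annotations

import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import dataio, feature_selection, markers, risk_scores, stats_survival, subtyping
from .synthetic import SyntheticConfig, generate_cohort

__all__ = ["PipelineConfig", "run_pipeline"]

log = logging.getLogger(__name__)

MARKER_ROLES = {"ER": "ESR1", "PR": "PGR", "HER2": "ERBB2"}


@dataclass
class PipelineConfig:
    """Validated configuration for one pipeline run.

    Either ``expression_path`` (TSV) or ``synthetic: true`` must be given;
    unknown keys in the source YAML are rejected.
    """

    out_dir: str
    seed: int
    expression_path: str | None = None
    clinical_path: str | None = None
    synthetic: bool = False
    preprocess: bool = False
    quantile: bool = True
    target_trimmed_mean: float = 500.0
    trim_fraction: float = 0.02
    k: int = 6
    n_restarts: int = 100
    pivotal_probes: list[str] = field(default_factory=list)
    selection: dict = field(default_factory=dict)
    marker_probes: dict = field(default_factory=lambda: dict(MARKER_ROLES))
    anchor_probe: str | None = "ESR1"
    concordance_permutations: int = 1000

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        raw = yaml.safe_load(Path(path).read_text())
        return cls.from_dict(raw)

    @classmethod
    def from_dict(cls, raw: dict) -> "PipelineConfig":
        known = set(cls.__dataclass_fields__)
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        cfg = cls(**raw)
        cfg.validate()
        return cfg

    def validate(self) -> None:
        if self.seed is None:
            raise ValueError("seed is required")
        if not self.synthetic:
            if not self.expression_path:
                raise ValueError("expression_path required unless synthetic: true")
            if not Path(self.expression_path).exists():
                raise ValueError(f"expression file not found: {self.expression_path}")
            if self.clinical_path and not Path(self.clinical_path).exists():
                raise ValueError(f"clinical file not found: {self.clinical_path}")
        if self.k < 2:
            raise ValueError("k must be >= 2")
        unknown_sel = set(self.selection) - set(
            feature_selection.ProbeFilterCriteria.__dataclass_fields__)
        if unknown_sel:
            raise ValueError(f"unknown selection keys: {sorted(unknown_sel)}")


def _stage(name: str):
    def deco(fn):
        def wrapped(*args, **kwargs):
            log.info("stage %s: starting", name)
            try:
                return fn(*args, **kwargs)
            except Exception as exc:
                raise RuntimeError(f"pipeline stage {name!r} failed: {exc}") from exc
        return wrapped
    return deco


def run_pipeline(cfg: PipelineConfig) -> dict:
    """Run the full analysis and write the report bundle to ``cfg.out_dir``.

    Returns the report dict (also written as ``report.json``): subtype
    assignments, marker cut-points and statuses, recurrence/template risk
    scores, marker x subtype Fisher tests, per-subtype log-rank results,
    and self-concordance of the fitted subtype means.
    """
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    report: dict = {"seed": cfg.seed}

    # ---- inputs -------------------------------------------------------
    if cfg.synthetic:
        sim = SyntheticConfig(seed=cfg.seed)
        expr, clinical, truth = generate_cohort(sim)
        pivotal = truth["pivotal_probes"]
    else:
        expr = dataio.read_expression(cfg.expression_path)
        clinical = dataio.read_clinical(cfg.clinical_path) if cfg.clinical_path else None
        truth = None
        pivotal = cfg.pivotal_probes
        if not pivotal:
            raise RuntimeError("pipeline stage 'inputs' failed: no pivotal probes configured")

    if cfg.preprocess:
        expr = _stage("preprocess")(dataio.preprocess)(
            expr, cfg.target_trimmed_mean, cfg.trim_fraction)
    if cfg.quantile:
        expr = _stage("quantile_normalize")(dataio.quantile_normalize)(expr)

    # ---- probe selection ---------------------------------------------
    criteria = feature_selection.ProbeFilterCriteria(**cfg.selection)
    selected = _stage("select_probes")(feature_selection.select_classifier_probes)(
        expr, feature_selection.PivotalGeneSet(pivotal), criteria)
    report["n_selected_probes"] = len(selected)
    (out / "probes.txt").write_text("\n".join(selected) + "\n")

    # ---- subtyping ----------------------------------------------------
    anchor = cfg.anchor_probe if cfg.anchor_probe in expr.probe_ids else None
    fit_matrix = (_with_anchor(expr, selected, anchor) if anchor is not None
                  else expr.subset_probes(selected))
    labels, model = _stage("two_step_kmeans")(subtyping.two_step_kmeans)(
        fit_matrix, k=cfg.k, n_restarts=cfg.n_restarts, seed=cfg.seed,
        anchor_probe=anchor)
    assignments = _stage("classify")(subtyping.classify_by_centroid)(
        expr.subset_probes(model.classifier_probes), model)
    asn = pd.DataFrame([{
        "sample_id": a.sample_id, "subtype": a.label,
        "correlation": a.correlation_to_best, "margin": a.margin,
    } for a in assignments])
    asn.to_csv(out / "assignments.csv", index=False)
    report["subtype_counts"] = asn["subtype"].value_counts().to_dict()

    # ---- marker cut-points -------------------------------------------
    cutpoints: dict[str, float] = {}
    statuses: dict[str, np.ndarray] = {}
    for role, probe in cfg.marker_probes.items():
        if probe not in expr.probe_ids:
            continue
        cut = _stage(f"marker_{role}")(markers.fit_bimodal_cutpoint)(
            expr.probe_values(probe), seed=cfg.seed, role=role)
        cutpoints[role] = cut.cutpoint
        statuses[role] = markers.call_status(expr.probe_values(probe), cut)
    report["marker_cutpoints"] = cutpoints
    pd.DataFrame({role: status for role, status in statuses.items()},
                 index=expr.sample_ids).to_csv(out / "marker_status.csv",
                                               index_label="sample_id")

    # ---- risk scores --------------------------------------------------
    risk = _stage("risk_scores")(_compute_risk_scores)(expr, truth)
    if risk is not None:
        risk.to_csv(out / "risk_scores.csv", index=False)
        report["mean_rs_by_subtype"] = (
            risk.assign(subtype=asn["subtype"].to_numpy())
            .groupby("subtype")["rs_scaled"].mean().round(2).to_dict())

    # ---- statistics ---------------------------------------------------
    fisher: dict[str, float] = {}
    for role, status in statuses.items():
        table = stats_survival.ContingencyTable.from_labels(
            status, asn["subtype"].to_numpy())
        fisher[f"{role}_x_subtype"] = _stage("fisher")(
            stats_survival.fisher_exact_2xc)(table)
    report["fisher_p"] = fisher

    if clinical is not None:
        surv = clinical.set_index("sample_id").loc[expr.sample_ids]
        groups = []
        for lab in model.labels:
            members = asn["subtype"].to_numpy() == lab
            if members.sum() == 0:
                continue
            groups.append((surv["mfs_time_years"].to_numpy()[members],
                           surv["mfs_event"].to_numpy()[members]))
        if len(groups) >= 2:
            lr = _stage("logrank")(stats_survival.logrank_test)(groups)
            report["mfs_logrank"] = {"chi2": lr.chi2, "df": lr.df, "p": lr.p}

    # self-concordance of the fitted subtype means (sanity check of the
    # permutation machinery; r_obs is 1 by construction)
    shared = model.classifier_probes[: min(60, len(model.classifier_probes))]
    sub = expr.subset_probes(shared)
    mean_a = pd.DataFrame(
        stats_survival._standardized_subtype_means(
            sub.values, asn["subtype"].to_numpy(), model.labels),
        index=shared, columns=model.labels)
    conc = _stage("concordance")(stats_survival.subtype_concordance)(
        mean_a, sub, asn["subtype"].to_numpy(),
        B=cfg.concordance_permutations, seed=cfg.seed)
    report["concordance"] = {"r_obs": conc.r_obs, "p_perm": conc.p_perm, "B": conc.B}

    if truth is not None:
        from .synthetic import truth_report
        rec = truth_report(truth, fitted_labels=labels,
                           fitted_cutpoints={MARKER_ROLES[r]: c for r, c in cutpoints.items()},
                           fitted_status={MARKER_ROLES[r]: s for r, s in statuses.items()})
        report["truth_recovery"] = {
            "ari": rec["ari"],
            "cutpoint_errors": rec["cutpoint_errors"],
            "marker_accuracy": rec["marker_accuracy"],
        }

    (out / "config.yaml").write_text(yaml.safe_dump(asdict(cfg)))
    (out / "report.json").write_text(json.dumps(_jsonify(report), indent=2))
    return report


def _with_anchor(expr, selected, anchor):
    probes = list(selected)
    if anchor not in probes:
        probes.append(anchor)
    return expr.subset_probes(probes)


def _compute_risk_scores(expr, truth) -> pd.DataFrame | None:
    gene_rows = {
        "GRB7": "GRB7", "HER2": "ERBB2", "ER": "ESR1", "PGR": "PGR",
        "BCL2": "BCL2", "SCUBE2": "SCUBE2", "BIRC5": "BIRC5", "KI67": "KI67",
        "MYBL2": "MYBL2", "CCNB1": "CCNB1", "AURKA": "AURKA", "CTSL2": "CTSL2",
        "MMP11": "MMP11", "CD68": "CD68", "GSTM1": "GSTM1", "BAG1": "BAG1",
    }
    missing = [row for row in gene_rows.values() if row not in expr.probe_ids]
    if missing:
        log.info("risk scores skipped; missing rows: %s", missing)
        return None
    sub = expr.subset_probes(list(gene_rows.values()))
    norm = np.vstack([
        risk_scores.reference_normalize(sub.values[i])
        for i in range(sub.values.shape[0])
    ])
    records = []
    template = truth["mammaprint_template"] if truth else None
    if template is not None:
        tv = expr.subset_probes(list(template.index)).values
        deviations = tv - tv.mean(axis=1, keepdims=True)
    for s, sid in enumerate(expr.sample_ids):
        x = {gene: norm[i, s] for i, gene in enumerate(gene_rows)}
        rs = risk_scores.oncotype_rs(x)
        rec = {"sample_id": sid, "rs_unscaled": rs.unscaled,
               "rs_scaled": rs.scaled, "rs_group": rs.group}
        if template is not None:
            mp = risk_scores.mammaprint_score(deviations[:, s], template.to_numpy())
            rec["template_score"] = mp.score
            rec["template_group"] = mp.group
        records.append(rec)
    return pd.DataFrame(records)


def _jsonify(obj):
    if isinstance(obj, dict):
        return {str(k): _jsonify(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonify(v) for v in obj]
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    return obj
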