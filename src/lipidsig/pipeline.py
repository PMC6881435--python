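"""End-to-end discovery run: QC -> scaling -> PCA/OPLS-DA -> S-plot ->
covariate screen -> FS-PLS -> DRS/ROC.

The run mirrors a biomarker-discovery workflow on an untargeted feature
table: features are filtered on pooled-QC repeatability and dilution
linearity; flagged sample outliers are removed only when explicitly
confirmed in the config; the pareto-scaled study matrix is modelled by
OPLS-DA and accepted only if cross-validated Q2 is positive and a label
permutation test is significant — otherwise the signature stages are
skipped with a warning (a degenerate dataset must not yield a signature);
S-plot tails are shortlisted, screened against age and sex, reduced to a
sparse signature by FS-PLS (with a screen-robustness re-run), and the
signature is scored by DRS and bootstrap ROC against the best single
features.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field

import numpy as np
import yaml

from . import evaluate, multivariate, qc, selection, tableio
from .tableio import FeatureTable

__all__ = ["PipelineConfig", "RunReport", "run_discovery", "report_markdown"]


@dataclass
class PipelineConfig:
    """Every knob of the discovery run, serializable to YAML."""

    qc: qc.QcConfig = field(default_factory=qc.QcConfig)
    fspls: selection.FsPlsConfig = field(default_factory=selection.FsPlsConfig)
    log_transform: bool = True
    pseudocount: float = 1.0
    n_ortho: int = 1
    n_folds: int = 7
    n_perm: int = 999
    splot_cutoff: float = 0.05
    screen_groupings: tuple = ("age_median_split", "sex")
    screen_alpha: float = 0.05
    screen_moderate: bool = False
    n_boot: int = 500
    seed: int = 0
    outlier_removal: tuple = ()   # sample ids confirmed for removal

    def to_yaml(self) -> str:
        return yaml.safe_dump(dataclasses.asdict(self), sort_keys=True)

    @classmethod
    def from_yaml(cls, text: str) -> "PipelineConfig":
        raw = yaml.safe_load(text) or {}
        raw["qc"] = qc.QcConfig(**raw.get("qc", {}))
        raw["fspls"] = selection.FsPlsConfig(**raw.get("fspls", {}))
        for key in ("screen_groupings", "outlier_removal"):
            if key in raw:
                raw[key] = tuple(raw[key])
        return cls(**raw)

    def config_hash(self) -> str:
        return hashlib.sha256(self.to_yaml().encode()).hexdigest()[:12]


@dataclass
class RunReport:
    """Stage-by-stage record of one discovery run."""

    counts: dict = field(default_factory=dict)        # stage -> feature count
    n_samples: dict = field(default_factory=dict)     # stage -> sample count
    outliers_flagged: list = field(default_factory=list)
    outliers_removed: list = field(default_factory=list)
    pca_explained: list = field(default_factory=list)
    r2x: float = np.nan
    r2y: float = np.nan
    q2: float = np.nan
    permutation_p: float = np.nan
    model_valid: bool = False
    shortlist: list = field(default_factory=list)
    screen_flagged: dict = field(default_factory=dict)  # grouping -> ids
    signature: dict = field(default_factory=dict)       # feature_id -> direction
    signature_weights: dict = field(default_factory=dict)
    screen_agreement: bool | None = None
    signature_auc: float = np.nan
    signature_ci: tuple = (np.nan, np.nan)
    single_feature_auc: dict = field(default_factory=dict)  # top features
    warnings: list = field(default_factory=list)
    config_hash: str = ""
    stage_seeds: dict = field(default_factory=dict)

    def to_json(self) -> str:
        def default(o):
            if isinstance(o, (np.floating, np.integer)):
                return o.item()
            if isinstance(o, np.ndarray):
                return o.tolist()
            if isinstance(o, (np.bool_,)):
                return bool(o)
            raise TypeError(f"not JSON serializable: {type(o)}")

        return json.dumps(dataclasses.asdict(self), indent=1, default=default)


def run_discovery(table: FeatureTable, config: PipelineConfig | None = None) -> RunReport:
    """Run the full discovery chain on a raw feature table."""
    config = config or PipelineConfig()
    rng = np.random.default_rng(config.seed)
    seeds = {stage: int(rng.integers(2**31))
             for stage in ("cv", "perm", "fspls", "boot")}
    report = RunReport(config_hash=config.config_hash(), stage_seeds=seeds)
    report.counts["acquired"] = table.n_features
    report.n_samples["acquired"] = table.n_samples

    # --- QC filtering and advisory outlier flags --------------------------
    filtered, qc_report = qc.apply_qc(table, config.qc)
    report.counts["qc_retained"] = filtered.n_features
    report.n_samples["study"] = filtered.n_samples
    outlier_flags = qc.flag_outliers(table, config.qc)
    report.outliers_flagged = list(outlier_flags.index[outlier_flags["outlier"]])

    removable = [s for s in config.outlier_removal if s in filtered.intensities.index]
    if removable:
        keep = [s for s in filtered.intensities.index if s not in removable]
        filtered = filtered.subset_samples(keep)
        report.outliers_removed = removable
        report.n_samples["after_outlier_removal"] = filtered.n_samples

    # --- transform and scale ----------------------------------------------
    if config.log_transform:
        filtered = tableio.log_transform(filtered, config.pseudocount)
    y = tableio.class_vector(filtered)
    scaled = multivariate.pareto_scale(filtered.intensities)

    # --- unsupervised overview --------------------------------------------
    k = min(config.qc.n_pca_components, filtered.n_samples - 1)
    pca = multivariate.fit_pca(scaled, k=k)
    report.pca_explained = list(pca.explained_variance_fraction)

    # --- supervised model + validation ------------------------------------
    model = multivariate.fit_oplsda(scaled, y, n_ortho=config.n_ortho)
    model.q2_cum = multivariate.cross_validated_q2(
        scaled, y, n_ortho=config.n_ortho, n_folds=config.n_folds, seed=seeds["cv"]
    )
    perm = multivariate.permutation_test(
        scaled, y, n_ortho=config.n_ortho, n_perm=config.n_perm,
        seed=seeds["perm"], n_folds=config.n_folds,
    )
    report.r2x, report.r2y, report.q2 = model.r2x_cum, model.r2y_cum, model.q2_cum
    report.permutation_p = perm.p_value
    report.model_valid = perm.valid
    if not perm.valid:
        report.warnings.append(
            f"OPLS-DA model not valid (Q2={perm.observed_q2:.3f}, "
            f"p={perm.p_value:.3f}); signature stages skipped"
        )
        return report

    # --- S-plot shortlist --------------------------------------------------
    splot = multivariate.s_plot(model, scaled, cutoff=config.splot_cutoff)
    report.shortlist = list(splot.index[splot["shortlisted"]])
    report.counts["shortlisted"] = len(report.shortlist)
    if not report.shortlist:
        report.warnings.append("no features passed the S-plot cutoff")
        return report
    shortlist_table = filtered.subset_features(report.shortlist)

    # --- covariate screen + FS-PLS with robustness check -------------------
    screens = [
        selection.diff_abundance(shortlist_table, grouping, moderate=config.screen_moderate)
        for grouping in config.screen_groupings
    ]
    flagged: set = set()
    for screen in screens:
        ids = screen.significant_ids(config.screen_alpha)
        report.screen_flagged[screen.grouping] = ids
        flagged |= set(ids)
    report.counts["screen_passed"] = len(report.shortlist) - len(flagged)

    fspls_config = dataclasses.replace(config.fspls, seed=seeds["fspls"])
    if screens:
        combined = selection.DiffAbundanceResult(
            grouping="+".join(config.screen_groupings),
            table=screens[0].table.assign(
                fdr_adjusted_p=np.min([s.table["fdr_adjusted_p"] for s in screens], axis=0)
            ),
        )
        full_model, _screened_model, agreement = selection.robustness_check(
            shortlist_table.study_samples().intensities, y, combined,
            config=fspls_config, alpha=config.screen_alpha,
        )
        report.screen_agreement = agreement
    else:
        full_model = selection.fspls_select(
            shortlist_table.study_samples().intensities, y, fspls_config
        )
    signature = full_model.signature()
    report.signature = dict(signature.features)
    report.signature_weights = dict(signature.weights)
    report.counts["signature"] = len(signature)
    if len(signature) == 0:
        report.warnings.append("FS-PLS selected no features at the configured p_thresh")
        return report

    # --- evaluation ---------------------------------------------------------
    drs = evaluate.disease_risk_score(filtered, signature)
    roc = evaluate.bootstrap_ci(drs.scores.to_numpy(), y,
                                n_boot=config.n_boot, seed=seeds["boot"])
    report.signature_auc = roc.auc
    report.signature_ci = (roc.ci_lower, roc.ci_upper)
    ranked = evaluate.rank_single_features(filtered, report.shortlist, y)
    report.single_feature_auc = {
        fid: float(a) for fid, a in ranked["auc"].head(3).items()
    }
    return report


def report_markdown(report: RunReport) -> str:
    """Human-readable summary of a completed run."""
    lines = ["# Discovery run report", ""]
    chain = " -> ".join(f"{stage}: {count}" for stage, count in report.counts.items())
    lines += [f"Feature counts: {chain}", ""]
    if report.outliers_flagged:
        lines.append(f"Outliers flagged: {', '.join(report.outliers_flagged)}")
    if report.outliers_removed:
        lines.append(f"Outliers removed (confirmed): {', '.join(report.outliers_removed)}")
    lines += [
        "",
        f"OPLS-DA: R2X = {report.r2x:.3f}, R2Y = {report.r2y:.3f}, "
        f"Q2 = {report.q2:.3f}, permutation p = {report.permutation_p:.4g}",
        f"Model valid: {report.model_valid}",
        "",
    ]
    for warning in report.warnings:
        lines.append(f"WARNING: {warning}")
    if report.signature:
        lines += ["", f"Signature ({len(report.signature)} features):"]
        for fid, direction in report.signature.items():
            weight = report.signature_weights.get(fid, float("nan"))
            lines.append(f"  - {fid}: {direction} (coefficient {weight:+.3f})")
        lines += [
            "",
            f"Signature DRS AUC = {report.signature_auc:.3f} "
            f"(95% CI {report.signature_ci[0]:.3f}-{report.signature_ci[1]:.3f})",
        ]
        if report.single_feature_auc:
            best = ", ".join(f"{fid}: {a:.3f}" for fid, a in report.single_feature_auc.items())
            lines.append(f"Top single-feature AUCs: {best}")
    if report.screen_agreement is not None:
        lines.append(
            f"Signature unchanged after covariate screen: {report.screen_agreement}"
        )
    lines += ["", f"Config hash: {report.config_hash}"]
    return "\n".join(lines) + "\n"
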