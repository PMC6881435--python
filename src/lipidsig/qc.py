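"""Feature-retention filters and PCA-based sample outlier flagging.

Two filters, both computed on QC-role injections only (study-sample values
never influence retention):

* pooled-QC repeatability — a feature is kept when its coefficient of
  variation (sd/mean of raw intensity) across the undiluted SQC injections
  is below a threshold (default 15%);
* dilution linearity — a feature is kept when its raw intensity correlates
  with the relative concentration across the SQC dilution series with a
  coefficient above a threshold (default Pearson r > 0.9).  Background
  artifacts do not respond to dilution and fail this filter.

Sample outliers are flagged (never auto-dropped) by Hotelling's T2 on the
first principal-component scores of the pareto-scaled study samples.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .multivariate import fit_pca, pareto_scale
from .tableio import FeatureTable

__all__ = [
    "QcConfig",
    "QcReport",
    "sqc_cv_filter",
    "dilution_filter",
    "apply_qc",
    "flag_outliers",
]


@dataclass
class QcConfig:
    """Thresholds of the retention filters and the outlier test."""

    cv_threshold: float = 0.15
    dilution_r_threshold: float = 0.9
    dilution_method: str = "pearson"   # or "spearman"
    outlier_alpha: float = 0.05
    n_pca_components: int = 2

    def validate(self) -> "QcConfig":
        if not 0 < self.cv_threshold:
            raise ValueError(f"cv_threshold must be positive, got {self.cv_threshold}")
        if not -1 <= self.dilution_r_threshold <= 1:
            raise ValueError(f"dilution_r_threshold must be in [-1, 1], got {self.dilution_r_threshold}")
        if self.dilution_method not in ("pearson", "spearman"):
            raise ValueError(f"unknown dilution_method: {self.dilution_method!r}")
        if not 0 < self.outlier_alpha < 1:
            raise ValueError(f"outlier_alpha must be in (0, 1), got {self.outlier_alpha}")
        if self.n_pca_components < 1:
            raise ValueError(f"n_pca_components must be >= 1, got {self.n_pca_components}")
        return self


@dataclass
class QcReport:
    """Per-feature filter values and verdicts, per-sample outlier flags.

    ``features`` has columns ``sqc_cv``, ``dilution_r``, ``retained``,
    ``drop_reason`` (``none``/``cv``/``dilution``/``both``); ``samples`` has
    ``hotelling_t2`` and ``outlier``.  Either frame may be absent when only
    a partial report was computed.
    """

    features: pd.DataFrame | None = None
    samples: pd.DataFrame | None = None

    def retained_ids(self) -> list:
        return list(self.features.index[self.features["retained"]])


def sqc_cv_filter(table: FeatureTable, threshold: float = 0.15) -> pd.DataFrame:
    """Per-feature CV across undiluted SQC injections; retain iff CV < threshold.

    CV is sd/mean on raw (pre-log) intensities, the pooled-QC convention.
    A zero-mean feature has an undefined CV and is dropped.
    """
    if table.log_scale:
        raise ValueError("CV filter must run on raw, not log-transformed, intensities")
    sqc = table.intensities.to_numpy(dtype=float)[table.role_mask("sqc")]
    if sqc.shape[0] < 3:
        raise ValueError(f"need >= 3 undiluted SQC samples, found {sqc.shape[0]}")
    mean = sqc.mean(axis=0)
    sd = sqc.std(axis=0, ddof=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        cv = np.where(mean != 0, sd / mean, np.nan)
    return pd.DataFrame(
        {"sqc_cv": cv, "retain_cv": np.nan_to_num(cv, nan=np.inf) < threshold},
        index=table.intensities.columns,
    )


def dilution_filter(table: FeatureTable, threshold: float = 0.9,
                    method: str = "pearson") -> pd.DataFrame:
    """Correlation of raw intensity with relative concentration across the
    dilution series; retain iff r > threshold.  Features constant across the
    series have an undefined correlation and are dropped."""
    if table.log_scale:
        raise ValueError("dilution filter must run on raw, not log-transformed, intensities")
    mask = table.role_mask("dilution")
    X = table.intensities.to_numpy(dtype=float)[mask]
    d = table.samples.loc[mask, "dilution_factor"].to_numpy(dtype=float)
    if len(np.unique(d)) < 3:
        raise ValueError(f"need >= 3 distinct dilution factors, found {len(np.unique(d))}")
    if method == "spearman":
        X = stats.rankdata(X, axis=0)
        d = stats.rankdata(d)
    d_c = d - d.mean()
    X_c = X - X.mean(axis=0)
    denom = np.sqrt(np.sum(X_c**2, axis=0) * np.sum(d_c**2))
    with np.errstate(invalid="ignore", divide="ignore"):
        r = np.where(denom > 0, X_c.T @ d_c / denom, np.nan)
    return pd.DataFrame(
        {"dilution_r": r, "retain_dilution": np.nan_to_num(r, nan=-np.inf) > threshold},
        index=table.intensities.columns,
    )


def apply_qc(table: FeatureTable, config: QcConfig | None = None) -> tuple[FeatureTable, QcReport]:
    """Run both filters and restrict the table to study samples x retained
    features (feature order preserved).  The full per-feature report is
    returned alongside; the two filters commute, so their order is moot."""
    config = (config or QcConfig()).validate()
    cv_part = sqc_cv_filter(table, config.cv_threshold)
    dil_part = dilution_filter(table, config.dilution_r_threshold, config.dilution_method)

    report = cv_part.join(dil_part)
    report["retained"] = report["retain_cv"] & report["retain_dilution"]
    reason = np.select(
        [
            ~report["retain_cv"] & ~report["retain_dilution"],
            ~report["retain_cv"],
            ~report["retain_dilution"],
        ],
        ["both", "cv", "dilution"],
        default="none",
    )
    report["drop_reason"] = reason
    report = report.drop(columns=["retain_cv", "retain_dilution"])

    retained = list(report.index[report["retained"]])
    if not retained:
        raise ValueError("QC filters retained zero features; check thresholds and QC samples")
    filtered = table.study_samples().subset_features(retained)
    return filtered, QcReport(features=report)


def flag_outliers(table: FeatureTable, config: QcConfig | None = None) -> pd.DataFrame:
    """Hotelling T2 outlier flags on PCA scores of the study samples.

    T2 is computed on the first ``n_pca_components`` scores of the
    pareto-scaled matrix and compared with the exact in-sample limit
    ((n-1)^2/n times a Beta quantile) at ``outlier_alpha``.  Flags are
    advisory: removal is an explicit, confirmed pipeline step.
    """
    config = (config or QcConfig()).validate()
    study = table.study_samples()
    k = config.n_pca_components
    n = study.n_samples
    if n <= k + 1:
        raise ValueError(f"need more than {k + 1} samples for a {k}-component T2 test")
    X = study.intensities
    sds = X.to_numpy(dtype=float).std(axis=0, ddof=1)
    scaled = pareto_scale(X.loc[:, sds > 0])
    pca = fit_pca(scaled, k=k)
    lam = pca.scores.var(axis=0, ddof=1)
    t2 = np.sum(pca.scores**2 / lam, axis=1)
    # in-sample T2 limit: T2 ~ (n-1)^2/n * Beta(k/2, (n-k-1)/2)
    limit = (n - 1) ** 2 / n * stats.beta.ppf(1 - config.outlier_alpha, k / 2, (n - k - 1) / 2)
    return pd.DataFrame(
        {"hotelling_t2": t2, "outlier": t2 > limit, "t2_limit": limit},
        index=X.index,
    )
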