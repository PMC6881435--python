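"""Disease risk score and ROC/AUC evaluation with bootstrap intervals.

The disease risk score (DRS) collapses a signature into one number per
sample: the sum of z-scored log abundances over up-in-bacterial features
minus the sum over up-in-viral features, so higher DRS means more
bacterial-like.  Because each feature is z-scored over the study samples,
the DRS is invariant to per-feature affine rescaling of the raw abundances.

AUC is computed by concordant-pair counting with half credit for ties,
i.e. exactly the Mann-Whitney concordance probability; confidence intervals
use a class-stratified percentile bootstrap (default 500 draws).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .selection import Signature
from .tableio import FeatureTable

__all__ = [
    "DrsResult",
    "RocResult",
    "disease_risk_score",
    "roc_auc",
    "bootstrap_ci",
    "rank_single_features",
]


@dataclass
class DrsResult:
    scores: pd.Series               # per study sample
    signature: Signature
    class_summary: pd.DataFrame     # median / IQR per class


def disease_risk_score(table: FeatureTable, signature: Signature) -> DrsResult:
    """DRS per study sample for a directed signature.

    Standardization is a per-feature z-score over the study samples of the
    log-abundance matrix; direction comes from the signature, so the score
    rises with every up-in-bacterial feature and falls with every
    up-in-viral feature.
    """
    if not table.log_scale:
        raise ValueError("DRS expects log-transformed intensities")
    if len(signature) == 0:
        raise ValueError("empty signature: no features to score")
    study = table.study_samples()
    missing = [f for f in signature.feature_ids if f not in study.intensities.columns]
    if missing:
        raise KeyError(f"signature features absent from table: {missing}")

    X = study.intensities[signature.feature_ids].to_numpy(dtype=float)
    z = (X - X.mean(axis=0)) / X.std(axis=0, ddof=1)
    direction = np.array(
        [1.0 if signature.features[f] == "up-in-bacterial" else -1.0
         for f in signature.feature_ids]
    )
    drs = pd.Series(z @ direction, index=study.intensities.index, name="drs")

    labels = study.samples["class"]
    summary = pd.DataFrame(
        {
            "median": drs.groupby(labels).median(),
            "iqr": drs.groupby(labels).quantile(0.75) - drs.groupby(labels).quantile(0.25),
        }
    )
    return DrsResult(scores=drs, signature=signature, class_summary=summary)


@dataclass
class RocResult:
    thresholds: np.ndarray
    sensitivity: np.ndarray
    specificity: np.ndarray
    auc: float
    ci_lower: float = np.nan
    ci_upper: float = np.nan
    n_boot: int = 0
    seed: int | None = None


def _auc_mann_whitney(scores: np.ndarray, y: np.ndarray) -> float:
    """Tie-aware AUC via midranks: U / (n1 * n0)."""
    ranks = stats.rankdata(scores)
    n1 = int(y.sum())
    n0 = len(y) - n1
    u = float(ranks[y == 1].sum()) - n1 * (n1 + 1) / 2
    return u / (n1 * n0)


def roc_auc(scores, y) -> RocResult:
    """ROC point set and tie-aware AUC for scores against the 0/1 class."""
    scores = np.asarray(scores, dtype=float)
    y = np.asarray(y, dtype=float)
    if y.min() == y.max():
        raise ValueError("both classes are required for a ROC curve")
    order = np.argsort(-scores, kind="stable")
    s_sorted, y_sorted = scores[order], y[order]
    distinct = np.r_[np.flatnonzero(np.diff(s_sorted)), len(s_sorted) - 1]
    tp = np.cumsum(y_sorted)[distinct]
    fp = np.cumsum(1 - y_sorted)[distinct]
    n1, n0 = y.sum(), (1 - y).sum()
    sens = np.r_[0.0, tp / n1]
    spec = np.r_[1.0, 1 - fp / n0]
    thresholds = np.r_[np.inf, s_sorted[distinct]]
    return RocResult(
        thresholds=thresholds, sensitivity=sens, specificity=spec,
        auc=_auc_mann_whitney(scores, y),
    )


def bootstrap_ci(scores, y, n_boot: int = 500, seed: int = 0) -> RocResult:
    """Percentile bootstrap CI for the AUC, resampling within each class.

    Stratified resampling guarantees every draw contains both classes; the
    interval is the 2.5/97.5 percentile of the bootstrap AUC distribution.
    """
    if n_boot < 1:
        raise ValueError(f"n_boot must be >= 1, got {n_boot}")
    scores = np.asarray(scores, dtype=float)
    y = np.asarray(y, dtype=float)
    result = roc_auc(scores, y)
    rng = np.random.default_rng(seed)
    pos = np.flatnonzero(y == 1)
    neg = np.flatnonzero(y == 0)
    aucs = np.empty(n_boot)
    for b in range(n_boot):
        take = np.r_[rng.choice(pos, size=len(pos)), rng.choice(neg, size=len(neg))]
        aucs[b] = _auc_mann_whitney(scores[take], y[take])
    result.ci_lower, result.ci_upper = np.percentile(aucs, [2.5, 97.5])
    result.n_boot, result.seed = n_boot, seed
    return result


def rank_single_features(table: FeatureTable, shortlist, y,
                         n_boot: int = 0, seed: int = 0) -> pd.DataFrame:
    """Per-feature ROC over a shortlist, sorted by descending AUC.

    AUC is folded to >= 0.5 (direction-agnostic), recording the orientation:
    ``higher-in-bacterial`` when the raw abundance already discriminates in
    the bacterial direction, else ``higher-in-viral``.  With ``n_boot > 0``
    a bootstrap CI is attached per feature.
    """
    shortlist = list(shortlist)
    if not shortlist:
        raise ValueError("empty shortlist")
    study = table.study_samples()
    y = np.asarray(y, dtype=float)
    rows = []
    for i, fid in enumerate(shortlist):
        scores = study.intensities[fid].to_numpy(dtype=float)
        auc = _auc_mann_whitney(scores, y)
        orientation = "higher-in-bacterial" if auc >= 0.5 else "higher-in-viral"
        oriented = scores if auc >= 0.5 else -scores
        row = {"feature_id": fid, "auc": max(auc, 1 - auc), "orientation": orientation}
        if n_boot > 0:
            ci = bootstrap_ci(oriented, y, n_boot=n_boot, seed=seed + i)
            row["ci_lower"], row["ci_upper"] = ci.ci_lower, ci.ci_upper
        rows.append(row)
    out = pd.DataFrame(rows).set_index("feature_id")
    return out.sort_values("auc", ascending=False, kind="stable")
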