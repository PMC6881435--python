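"""Covariate screening and forward-selection PLS (FS-PLS) signature search.

The screen is a per-feature two-group comparison on log abundances (class,
sex, or an above/below-median-age split) with Benjamini-Hochberg control of
the false discovery rate across features; optionally the group variances are
moderated by an empirical-Bayes squeeze before testing.

FS-PLS builds a small signature of mutually uncorrelated features: at each
step it fits one univariate regression per remaining feature (logistic by
default, maximum-likelihood coefficient with a Wald test), selects the
feature with the smallest p-value, then projects the selected column's
direction out of every remaining column (a rank-1 SVD deflation) so later
steps see only residual predictor variation.  Optionally the step fits can
additionally carry the already-selected model as a fixed GLM offset
(``condition_on_selected``), turning the step test into a full partial
association; the default keeps the plain univariate step, which is the more
conservative choice for admitting later features.  Selection stops when the best p-value
exceeds ``p_thresh`` or a safety cap is reached; the final coefficients come
from one joint refit of the selected features on their original scale.
Perfectly separating steps fall back to Firth's penalized likelihood.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import special, stats
from statsmodels.stats.multitest import multipletests

from .tableio import FeatureTable

__all__ = [
    "DiffAbundanceResult",
    "FsPlsConfig",
    "FsPlsModel",
    "Signature",
    "diff_abundance",
    "fspls_select",
    "robustness_check",
]


# ---------------------------------------------------------------------------
# differential-abundance screen


@dataclass
class DiffAbundanceResult:
    grouping: str
    table: pd.DataFrame  # estimate, t_statistic, p_value, fdr_adjusted_p per feature

    def significant_ids(self, alpha: float = 0.05) -> list:
        return list(self.table.index[self.table["fdr_adjusted_p"] < alpha])


def _squeeze_var(s2: np.ndarray, df: int) -> tuple[np.ndarray, float]:
    """Empirical-Bayes variance moderation (scaled-F moment fit).

    Returns posterior variances and the extra prior degrees of freedom d0.
    """
    z = np.log(np.maximum(s2, 1e-300))
    e = z - special.digamma(df / 2) + np.log(df / 2)
    e_var = max(float(np.var(e, ddof=1)) - float(special.polygamma(1, df / 2)), 1e-8)
    # invert trigamma(d0/2) = e_var by Newton from a moment-based start
    x = 0.5 + 1.0 / e_var
    for _ in range(50):
        tri = special.polygamma(1, x)
        step = tri * (tri - e_var) / special.polygamma(2, x)
        x += step
        if abs(step) < 1e-10:
            break
    d0 = 2.0 * float(x)
    s0_sq = float(np.exp(np.mean(e) + special.digamma(x) - np.log(x)))
    post = (d0 * s0_sq + df * s2) / (d0 + df)
    return post, d0


def _grouping_labels(table: FeatureTable, grouping: str) -> np.ndarray:
    samples = table.study_samples().samples
    if grouping == "class":
        return (samples["class"] == "bacterial").to_numpy()
    if grouping == "sex":
        return (samples["sex"] == "male").to_numpy()
    if grouping == "age_median_split":
        age = samples["age_months"].to_numpy(dtype=float)
        return age > np.median(age)
    raise ValueError(f"unknown grouping: {grouping!r}")


def diff_abundance(table: FeatureTable, grouping: str,
                   moderate: bool = False) -> DiffAbundanceResult:
    """Two-group t-tests on log abundances with BH adjustment across features.

    ``grouping`` is ``class``, ``sex`` or ``age_median_split`` (samples
    dichotomized at the median age).  ``moderate=True`` squeezes the pooled
    variances toward a common prior before testing; with shortlist-sized
    feature sets the moderation is minor and it defaults off.
    """
    if not table.log_scale:
        raise ValueError("differential abundance expects log-transformed intensities")
    study = table.study_samples()
    g = _grouping_labels(table, grouping)
    X = study.intensities.to_numpy(dtype=float)
    n1, n0 = int(g.sum()), int((~g).sum())
    if min(n1, n0) < 2:
        raise ValueError(f"grouping {grouping!r} leaves a group of size < 2 ({n1} vs {n0})")

    m1, m0 = X[g].mean(axis=0), X[~g].mean(axis=0)
    v1 = X[g].var(axis=0, ddof=1)
    v0 = X[~g].var(axis=0, ddof=1)
    df = n1 + n0 - 2
    pooled = ((n1 - 1) * v1 + (n0 - 1) * v0) / df
    if moderate:
        pooled, d0 = _squeeze_var(pooled, df)
        df = df + d0
    se = np.sqrt(pooled * (1 / n1 + 1 / n0))
    with np.errstate(invalid="ignore", divide="ignore"):
        t = np.where(se > 0, (m1 - m0) / se, 0.0)
    p = 2 * stats.t.sf(np.abs(t), df)
    fdr = multipletests(p, method="fdr_bh")[1]
    out = pd.DataFrame(
        {"estimate": m1 - m0, "t_statistic": t, "p_value": p, "fdr_adjusted_p": fdr},
        index=study.intensities.columns,
    )
    return DiffAbundanceResult(grouping=grouping, table=out)


# ---------------------------------------------------------------------------
# univariate fits for FS-PLS


def _logistic_irls(X: np.ndarray, y: np.ndarray, firth: bool = False,
                   offset: np.ndarray | None = None,
                   max_iter: int = 60, tol: float = 1e-9):
    """Newton/IRLS logistic fit; returns (beta, se, loglik, converged).

    ``offset`` is a fixed component of the linear predictor (used by the
    forward-selection steps to condition on the already-selected variables).
    With ``firth=True`` the score is penalized by half the derivative of the
    log determinant of the information (Firth 1993), which keeps estimates
    finite under perfect separation.
    """
    n, k = X.shape
    if offset is None:
        offset = np.zeros(n)
    beta = np.zeros(k)
    converged = False
    for _ in range(max_iter):
        eta = np.clip(offset + X @ beta, -35, 35)
        mu = special.expit(eta)
        w = mu * (1 - mu)
        info = (X * w[:, None]).T @ X
        try:
            info_inv = np.linalg.inv(info)
        except np.linalg.LinAlgError:
            break
        score = X.T @ (y - mu)
        if firth:
            # hat diagonal of W^{1/2} X (X'WX)^{-1} X' W^{1/2}
            h = np.einsum("ij,jk,ik->i", X, info_inv, X) * w
            score = X.T @ (y - mu + h * (0.5 - mu))
        step = info_inv @ score
        beta = beta + step
        if np.max(np.abs(step)) < tol:
            converged = True
            break
    eta = np.clip(offset + X @ beta, -35, 35)
    mu = special.expit(eta)
    loglik = float(np.sum(y * eta - np.logaddexp(0.0, eta)))
    if firth:
        w = mu * (1 - mu)
        sign, logdet = np.linalg.slogdet((X * w[:, None]).T @ X)
        loglik += 0.5 * logdet
    w = mu * (1 - mu)
    info = (X * w[:, None]).T @ X
    try:
        se = np.sqrt(np.diag(np.linalg.inv(info)))
    except np.linalg.LinAlgError:
        se = np.full(k, np.inf)
    return beta, se, loglik, converged


_SEPARATION_BOUND = 15.0  # |slope| beyond this on standardized columns ⇒ separation


def _fit_univariate(x: np.ndarray, y: np.ndarray, family: str,
                    offset: np.ndarray | None = None):
    """Single-feature fit with intercept: (coef, p_value, loglik, penalized).

    ``offset`` carries the linear predictor of the already-selected model, so
    the Wald test assesses the candidate's contribution beyond it (for the
    linear family this is equivalent to regressing the response residual).
    """
    n = len(y)
    if family == "linear":
        target = y if offset is None else y - offset
        X = np.column_stack([np.ones(n), x])
        beta, res, *_ = np.linalg.lstsq(X, target, rcond=None)
        resid = target - X @ beta
        s2 = float(resid @ resid) / (n - 2)
        sxx = float(np.sum((x - x.mean()) ** 2))
        se = np.sqrt(s2 / sxx) if sxx > 0 else np.inf
        t = beta[1] / se if np.isfinite(se) and se > 0 else 0.0
        p = 2 * stats.t.sf(abs(t), n - 2)
        loglik = -0.5 * n * (np.log(2 * np.pi * s2) + 1)
        return float(beta[1]), float(p), float(loglik), False

    X = np.column_stack([np.ones(n), x])
    beta, se, loglik, converged = _logistic_irls(X, y, offset=offset)
    penalized = (not converged) or abs(beta[1]) > _SEPARATION_BOUND or not np.isfinite(se[1])
    if penalized:
        beta, se, loglik, _ = _logistic_irls(X, y, firth=True, offset=offset)
    z = beta[1] / se[1] if se[1] > 0 else 0.0
    p = 2 * stats.norm.sf(abs(z))
    return float(beta[1]), float(p), float(loglik), penalized


# ---------------------------------------------------------------------------
# FS-PLS


@dataclass
class FsPlsConfig:
    """Stopping threshold, safety cap and model family of the selection.

    ``condition_on_selected`` switches the step test from the plain
    univariate fit on the deflated column (the default) to a fit that
    carries the already-selected model as a GLM offset; the latter measures
    the full partial association and admits later features more readily.
    """

    p_thresh: float = 0.01
    max_features: int = 10
    model_family: str = "logistic"  # or "linear"
    condition_on_selected: bool = False
    seed: int = 0

    def validate(self) -> "FsPlsConfig":
        if not 0 < self.p_thresh < 1:
            raise ValueError(f"p_thresh must be in (0, 1), got {self.p_thresh}")
        if self.max_features < 1:
            raise ValueError(f"max_features must be >= 1, got {self.max_features}")
        if self.model_family not in ("logistic", "linear"):
            raise ValueError(f"unknown model_family: {self.model_family!r}")
        return self


@dataclass
class FsPlsModel:
    """Ordered selection record plus the joint refit.

    ``selected`` rows: (feature_id, step_p_value, step_loglik);
    ``final_coefficients`` maps ``intercept`` and each selected feature id to
    its coefficient in the joint model on the original standardized columns;
    ``deflation_record`` notes, per step, the projection applied and whether
    the step needed penalized likelihood.
    """

    selected: list = field(default_factory=list)
    final_coefficients: dict = field(default_factory=dict)
    deflation_record: list = field(default_factory=list)
    stop_reason: str = ""

    @property
    def selected_ids(self) -> list:
        return [fid for fid, _, _ in self.selected]

    def signature(self) -> "Signature":
        weights = {fid: self.final_coefficients[fid] for fid in self.selected_ids}
        return Signature(
            features={
                fid: ("up-in-bacterial" if w >= 0 else "up-in-viral")
                for fid, w in weights.items()
            },
            weights=weights,
        )


@dataclass
class Signature:
    """Selected features with direction (by coefficient sign) and weight."""

    features: dict  # feature_id -> up-in-bacterial | up-in-viral
    weights: dict = field(default_factory=dict)

    @property
    def feature_ids(self) -> list:
        return list(self.features)

    def __len__(self) -> int:
        return len(self.features)


_ZERO_COLUMN_TOL = 1e-8  # deflated column norm below this can never be selected


def fspls_select(X, y, config: FsPlsConfig | None = None,
                 feature_ids=None) -> FsPlsModel:
    """Forward selection with rank-1 SVD deflation.

    ``X`` is a samples x features matrix (DataFrame or array) of log
    abundances; columns are standardized internally.  ``y`` is the 0/1 class
    encoding.  See the module docstring for the algorithm.
    """
    config = (config or FsPlsConfig()).validate()
    if isinstance(X, pd.DataFrame):
        feature_ids = list(X.columns)
        X = X.to_numpy(dtype=float)
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    n, p = X.shape
    if feature_ids is None:
        feature_ids = list(range(p))
    if config.model_family == "logistic" and y.min() == y.max():
        raise ValueError("both classes must be present in y")

    sds = X.std(axis=0, ddof=1)
    keep = sds > 0
    Z = np.zeros_like(X)
    Z[:, keep] = (X[:, keep] - X[:, keep].mean(axis=0)) / sds[keep]
    Z_orig = Z.copy()

    model = FsPlsModel()
    remaining = [j for j in range(p) if keep[j]]
    selected_cols: list[np.ndarray] = []  # deflated basis of selected columns
    offset = np.zeros(n)  # linear predictor of the model selected so far
    stop = "exhausted"
    while remaining:
        if len(model.selected) >= config.max_features:
            stop = "max_features"
            break
        best = None  # (p, -loglik, order, j, coef, penalized)
        for j in remaining:
            col = Z[:, j]
            norm = np.linalg.norm(col)
            if norm < _ZERO_COLUMN_TOL * np.sqrt(n):
                continue  # fully explained by already-selected features
            coef, pval, loglik, penalized = _fit_univariate(
                col, y, config.model_family,
                offset=offset if config.condition_on_selected else None,
            )
            key = (pval, -loglik, j)
            if best is None or key < best[0]:
                best = (key, j, coef, pval, loglik, penalized)
        if best is None:
            stop = "no_informative_columns"
            break
        _, j_star, coef, pval, loglik, penalized = best
        if pval > config.p_thresh:
            stop = "p_thresh"
            break
        model.selected.append((feature_ids[j_star], pval, loglik))
        s = Z[:, j_star].copy()
        selected_cols.append(s)
        remaining.remove(j_star)
        proj = s @ Z[:, remaining] / (s @ s)
        Z[:, remaining] -= np.outer(s, proj)
        model.deflation_record.append(
            {"feature_id": feature_ids[j_star], "step": len(model.selected),
             "projection_norm": float(np.linalg.norm(proj)), "penalized": penalized}
        )
        # refit the running model on the (mutually orthogonal) deflated basis
        # so the next step tests each candidate's contribution beyond it
        design = np.column_stack([np.ones(n)] + selected_cols)
        if config.model_family == "logistic":
            beta, _, _, converged = _logistic_irls(design, y)
            if not converged or np.max(np.abs(beta[1:])) > _SEPARATION_BOUND:
                beta, _, _, _ = _logistic_irls(design, y, firth=True)
        else:
            beta, *_ = np.linalg.lstsq(design, y, rcond=None)
        offset = design @ beta
    else:
        stop = "exhausted"
    model.stop_reason = stop

    if model.selected:
        sel_idx = [feature_ids.index(fid) for fid in model.selected_ids]
        design = np.column_stack([np.ones(n), Z_orig[:, sel_idx]])
        if config.model_family == "logistic":
            beta, se, _, converged = _logistic_irls(design, y)
            if not converged or np.max(np.abs(beta[1:])) > _SEPARATION_BOUND:
                beta, se, _, _ = _logistic_irls(design, y, firth=True)
        else:
            beta, *_ = np.linalg.lstsq(design, y, rcond=None)
        model.final_coefficients = {"intercept": float(beta[0])}
        model.final_coefficients.update(
            {fid: float(b) for fid, b in zip(model.selected_ids, beta[1:])}
        )
    return model


def robustness_check(X, y, covariate_screen: DiffAbundanceResult,
                     config: FsPlsConfig | None = None, alpha: float = 0.05,
                     feature_ids=None) -> tuple[FsPlsModel, FsPlsModel, bool]:
    """Re-run FS-PLS after removing covariate-associated features.

    Fits the signature on the full shortlist and again on the shortlist with
    screen-significant features (FDR < ``alpha``) removed; returns both models
    and whether the two selected feature sets are identical — the check that
    a signature is robust to, e.g., age effects.
    """
    if isinstance(X, pd.DataFrame):
        feature_ids = list(X.columns)
        X_arr = X.to_numpy(dtype=float)
    else:
        X_arr = np.asarray(X, dtype=float)
        if feature_ids is None:
            feature_ids = list(range(X_arr.shape[1]))
    full = fspls_select(X_arr, y, config, feature_ids=feature_ids)

    flagged = set(covariate_screen.significant_ids(alpha))
    kept = [j for j, fid in enumerate(feature_ids) if fid not in flagged]
    if not kept:
        raise ValueError("covariate screen removed every shortlisted feature")
    filtered = fspls_select(
        X_arr[:, kept], y, config, feature_ids=[feature_ids[j] for j in kept]
    )
    agreement = set(full.selected_ids) == set(filtered.selected_ids)
    return full, filtered, agreement
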