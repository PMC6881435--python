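"""Pareto scaling, PCA, OPLS-DA, Q2 cross-validation, permutation test, S-plot.

The supervised workhorse is orthogonal projections to latent structures
discriminant analysis (OPLS-DA): a single class-predictive latent component
plus ``n_ortho`` components that capture structured variation orthogonal to
class.  Model quality is summarised by R2X (fraction of X sum of squares
modelled), R2Y (fraction of the class encoding explained in-sample) and Q2
(fraction predicted under stratified cross-validation).  Because a supervised
fit on many features overfits easily, a model is accepted only when Q2 > 0
and a label-permutation test yields p < 0.05.

Feature shortlisting uses the S-plot: each feature's model covariance
loading (x-axis, ``p1``) against its correlation with the predictive score
(y-axis, ``pcorr``).  Features in the tails of the S — large |p1| — drive the
class separation.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "ScaledMatrix",
    "PcaModel",
    "OplsModel",
    "PermutationResult",
    "pareto_scale",
    "fit_pca",
    "fit_oplsda",
    "cross_validated_q2",
    "permutation_test",
    "s_plot",
    "stratified_folds",
]


# ---------------------------------------------------------------------------
# scaling


@dataclass
class ScaledMatrix:
    """Column-scaled matrix with enough state to invert the transform."""

    values: np.ndarray
    column_means: np.ndarray
    column_sds: np.ndarray
    scaling: str  # none | uv | pareto
    feature_ids: list = field(default_factory=list)
    sample_ids: list = field(default_factory=list)

    def inverse(self) -> np.ndarray:
        if self.scaling == "pareto":
            return self.values * np.sqrt(self.column_sds) + self.column_means
        if self.scaling == "uv":
            return self.values * self.column_sds + self.column_means
        return self.values + self.column_means


def pareto_scale(matrix, feature_ids=None, sample_ids=None, scaling: str = "pareto") -> ScaledMatrix:
    """Columnwise (x - mean) / sqrt(sd) — intermediate between centering and
    unit-variance scaling, the metabolomics convention: it shrinks the
    dominance of high-abundance features without amplifying noise the way
    full autoscaling does.

    Zero-variance columns are rejected (they carry no information and make
    the scaling undefined), naming the offending features.
    """
    if isinstance(matrix, pd.DataFrame):
        feature_ids = list(matrix.columns)
        sample_ids = list(matrix.index)
        matrix = matrix.to_numpy(dtype=float)
    X = np.asarray(matrix, dtype=float)
    means = X.mean(axis=0)
    sds = X.std(axis=0, ddof=1)
    zero = np.flatnonzero(sds == 0)
    if zero.size:
        names = [feature_ids[j] for j in zero] if feature_ids else list(zero)
        raise ValueError(f"zero-variance columns cannot be scaled: {names[:10]}")
    if scaling == "pareto":
        scaled = (X - means) / np.sqrt(sds)
    elif scaling == "uv":
        scaled = (X - means) / sds
    elif scaling == "none":
        scaled = X - means
    else:
        raise ValueError(f"unknown scaling: {scaling!r}")
    return ScaledMatrix(scaled, means, sds, scaling,
                        feature_ids or [], sample_ids or [])


# ---------------------------------------------------------------------------
# PCA


@dataclass
class PcaModel:
    scores: np.ndarray                      # samples x k  (U @ diag(s))
    loadings: np.ndarray                    # features x k (V)
    explained_variance_fraction: np.ndarray


def fit_pca(scaled: ScaledMatrix, k: int) -> PcaModel:
    """Truncated SVD of the (already centered) scaled matrix."""
    X = scaled.values
    n, p = X.shape
    if not 1 <= k <= min(n - 1, p):
        raise ValueError(f"k={k} out of range for a {n} x {p} matrix")
    U, s, Vt = np.linalg.svd(X, full_matrices=False)
    total = float(np.sum(s**2))
    return PcaModel(
        scores=U[:, :k] * s[:k],
        loadings=Vt[:k].T,
        explained_variance_fraction=s[:k] ** 2 / total,
    )


# ---------------------------------------------------------------------------
# OPLS-DA


@dataclass
class OplsModel:
    """One predictive + ``n_ortho`` orthogonal components of an O-PLS fit.

    Scores/loadings follow the usual notation: ``t_p``/``p_p``/``w_p`` are the
    predictive score, loading and weight; ``t_o``/``p_o``/``w_o`` hold the
    orthogonal components columnwise.
    """

    t_p: np.ndarray
    p_p: np.ndarray
    w_p: np.ndarray
    t_o: np.ndarray
    p_o: np.ndarray
    w_o: np.ndarray
    b: float                 # inner regression ŷ = y_mean + t_p * b
    y_mean: float
    n_ortho: int
    r2x_cum: float = np.nan
    r2y_cum: float = np.nan
    q2_cum: float = np.nan

    def predict(self, X: np.ndarray) -> np.ndarray:
        """Predict the class encoding for rows already in the scaled space."""
        X = np.atleast_2d(np.asarray(X, dtype=float)).copy()
        for k in range(self.n_ortho):
            t_o = X @ self.w_o[:, k]
            X -= np.outer(t_o, self.p_o[:, k])
        return self.y_mean + (X @ self.w_p) * self.b


def fit_oplsda(scaled, y, n_ortho: int = 1) -> OplsModel:
    """Fit OPLS-DA by the orthogonal-deflation scheme.

    The predictive weight is w ∝ Xᵀy; each orthogonal component takes the
    part of the current X-loading orthogonal to w, deflates X by it, and the
    final predictive component is fit on the deflated matrix.  With
    ``n_ortho=0`` this is exactly single-component PLS-DA.
    """
    X = scaled.values if isinstance(scaled, ScaledMatrix) else np.asarray(scaled, dtype=float)
    X = X.copy()
    y = np.asarray(y, dtype=float)
    if y.min() == y.max():
        raise ValueError("single-class y: OPLS-DA needs both classes")
    if n_ortho < 0:
        raise ValueError(f"n_ortho must be >= 0, got {n_ortho}")
    n, p = X.shape
    if n_ortho > min(n, p) - 2:
        raise ValueError(f"n_ortho={n_ortho} too large for a {n} x {p} matrix")

    ss_x_total = float(np.sum(X**2))
    y_mean = float(y.mean())
    yc = y - y_mean

    w = X.T @ yc
    w /= np.linalg.norm(w)

    t_o = np.empty((n, n_ortho))
    p_o = np.empty((p, n_ortho))
    w_o = np.empty((p, n_ortho))
    ss_ortho = 0.0
    for k in range(n_ortho):
        t = X @ w
        p_load = X.T @ t / (t @ t)
        wo = p_load - (w @ p_load) * w      # part of the loading orthogonal to w
        norm = np.linalg.norm(wo)
        if norm < 1e-12:
            raise ValueError(f"no orthogonal variation left for component {k + 1}")
        wo /= norm
        to = X @ wo
        po = X.T @ to / (to @ to)
        X -= np.outer(to, po)
        t_o[:, k], p_o[:, k], w_o[:, k] = to, po, wo
        ss_ortho += float((to @ to) * (po @ po))

    t_p = X @ w
    p_p = X.T @ t_p / (t_p @ t_p)
    b = float((t_p @ yc) / (t_p @ t_p))

    ss_pred = float((t_p @ t_p) * (p_p @ p_p))
    resid = yc - t_p * b
    r2y = 1.0 - float(resid @ resid) / float(yc @ yc)
    r2x = (ss_pred + ss_ortho) / ss_x_total

    return OplsModel(t_p=t_p, p_p=p_p, w_p=w, t_o=t_o, p_o=p_o, w_o=w_o,
                     b=b, y_mean=y_mean, n_ortho=n_ortho,
                     r2x_cum=r2x, r2y_cum=r2y)


def stratified_folds(y: np.ndarray, n_folds: int, rng: np.random.Generator) -> list[np.ndarray]:
    """Deterministic stratified fold assignment.

    One global permutation orders the samples; within each class, members are
    dealt round-robin in that order.  Each fold keeps both classes whenever
    counts allow, and the assignment depends only on the class *partition*,
    so swapping the two labels leaves the folds unchanged.
    """
    y = np.asarray(y)
    order = rng.permutation(len(y))
    rank = np.empty(len(y), dtype=int)
    rank[order] = np.arange(len(y))
    assignment = np.empty(len(y), dtype=int)
    for value in np.unique(y):
        idx = np.flatnonzero(y == value)
        idx = idx[np.argsort(rank[idx])]
        assignment[idx] = np.arange(len(idx)) % n_folds
    folds = [np.flatnonzero(assignment == f) for f in range(n_folds)]
    return [f for f in folds if f.size]


def cross_validated_q2(scaled, y, n_ortho: int = 1, n_folds: int = 7,
                       seed: int = 0) -> float:
    """Q2 = 1 - PRESS/SSY over stratified folds (default 7, the SIMCA
    convention).  Each fold refits the full OPLS-DA on the training rows and
    predicts the held-out rows; SSY is the total centered sum of squares of
    the class encoding."""
    X = scaled.values if isinstance(scaled, ScaledMatrix) else np.asarray(scaled, dtype=float)
    y = np.asarray(y, dtype=float)
    if n_folds < 2:
        raise ValueError(f"n_folds must be >= 2, got {n_folds}")
    rng = np.random.default_rng(seed)
    press = 0.0
    for test_idx in stratified_folds(y, n_folds, rng):
        train = np.setdiff1d(np.arange(len(y)), test_idx)
        model = fit_oplsda(X[train], y[train], n_ortho=n_ortho)
        y_hat = model.predict(X[test_idx])
        press += float(np.sum((y[test_idx] - y_hat) ** 2))
    ssy = float(np.sum((y - y.mean()) ** 2))
    return 1.0 - press / ssy


@dataclass
class PermutationResult:
    observed_q2: float
    permuted_q2: np.ndarray
    p_value: float
    valid: bool              # observed Q2 > 0 and p < 0.05
    n_perm: int


def permutation_test(scaled, y, n_ortho: int = 1, n_perm: int = 999,
                     seed: int = 0, n_folds: int = 7) -> PermutationResult:
    """Compare the observed Q2 with Q2 under random label permutations.

    p = (1 + #{permuted >= observed}) / (1 + n_perm), the add-one estimator:
    unbiased under exchangeability and never exactly zero.  The model is
    declared valid when Q2 > 0 and p < 0.05.
    """
    if n_perm < 1:
        raise ValueError(f"n_perm must be >= 1, got {n_perm}")
    X = scaled.values if isinstance(scaled, ScaledMatrix) else np.asarray(scaled, dtype=float)
    y = np.asarray(y, dtype=float)
    rng = np.random.default_rng(seed)
    observed = cross_validated_q2(X, y, n_ortho=n_ortho, n_folds=n_folds,
                                  seed=int(rng.integers(2**31)))
    permuted = np.empty(n_perm)
    for i in range(n_perm):
        y_perm = y[rng.permutation(len(y))]
        permuted[i] = cross_validated_q2(X, y_perm, n_ortho=n_ortho, n_folds=n_folds,
                                         seed=int(rng.integers(2**31)))
    p = (1.0 + float(np.sum(permuted >= observed))) / (1.0 + n_perm)
    return PermutationResult(observed_q2=observed, permuted_q2=permuted,
                             p_value=p, valid=(observed > 0 and p < 0.05),
                             n_perm=n_perm)


# ---------------------------------------------------------------------------
# S-plot


def s_plot(model: OplsModel, scaled: ScaledMatrix, cutoff: float = 0.05) -> pd.DataFrame:
    """S-plot coordinates and shortlist verdict for every feature.

    ``p1`` is the model covariance loading normalized to a unit-length
    loading vector (the scale on which loading plots are conventionally
    drawn, making a fixed cutoff transferable across feature-set sizes);
    ``pcorr`` is the Pearson correlation of each scaled feature column with
    the predictive score.  A feature is shortlisted when |p1| >= cutoff;
    its direction comes from the sign of p1 under the bacterial=1 encoding.
    """
    X = scaled.values
    t = model.t_p
    n = X.shape[0]
    cov = X.T @ (t - t.mean()) / (n - 1)
    p1 = cov / np.linalg.norm(cov)
    sd_x = X.std(axis=0, ddof=1)
    sd_t = t.std(ddof=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        pcorr = cov / (sd_x * sd_t)
    pcorr = np.clip(np.nan_to_num(pcorr), -1.0, 1.0)
    entries = pd.DataFrame(
        {
            "p1": p1,
            "pcorr": pcorr,
            "shortlisted": np.abs(p1) >= cutoff,
            "direction": np.where(p1 >= 0, "up-in-bacterial", "up-in-viral"),
        },
        index=pd.Index(scaled.feature_ids or range(X.shape[1]), name="feature_id"),
    )
    return entries
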