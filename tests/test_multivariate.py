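"""Scaling, PCA and OPLS-DA identities, cross-validated Q2, permutation, S-plot."""

import numpy as np
import pytest

import lipidsig as L
from lipidsig import multivariate as mv
from lipidsig import qc, tableio


# ---------------------------------------------------------------------------
# pareto scaling


def test_pareto_scale_hand_arithmetic():
    scaled = mv.pareto_scale(np.array([[1.0], [2.0], [3.0]]))
    np.testing.assert_allclose(scaled.values[:, 0], [-1.0, 0.0, 1.0])


def test_pareto_scale_zero_variance_names_column():
    X = np.column_stack([np.arange(3.0), np.full(3, 5.0)])
    with pytest.raises(ValueError, match="fB"):
        mv.pareto_scale(X, feature_ids=["fA", "fB"])


def test_pareto_scale_centers_and_inverts():
    rng = np.random.default_rng(1)
    X = rng.lognormal(8, 0.5, size=(15, 6))
    scaled = mv.pareto_scale(X)
    np.testing.assert_allclose(scaled.values.mean(axis=0), 0.0, atol=1e-12)
    np.testing.assert_allclose(scaled.inverse(), X, atol=1e-10)


# ---------------------------------------------------------------------------
# PCA


def test_pca_rank_one_explains_everything():
    u = np.arange(1.0, 7.0)[:, None]
    v = np.array([[2.0, -1.0, 0.5]])
    scaled = mv.pareto_scale(u @ v + 10)
    model = mv.fit_pca(scaled, k=2)
    assert model.explained_variance_fraction[0] > 0.999999


def test_pca_full_rank_reconstruction():
    rng = np.random.default_rng(3)
    scaled = mv.pareto_scale(rng.normal(10, 1, size=(8, 5)))
    model = mv.fit_pca(scaled, k=5)
    np.testing.assert_allclose(model.scores @ model.loadings.T, scaled.values, atol=1e-8)


def test_pca_matches_covariance_eigendecomposition():
    """SVD route equals a brute-force eigendecomposition of the covariance."""
    rng = np.random.default_rng(4)
    X = rng.normal(size=(20, 50))
    scaled = mv.pareto_scale(X)
    model = mv.fit_pca(scaled, k=4)
    cov = scaled.values.T @ scaled.values
    eigval, eigvec = np.linalg.eigh(cov)
    order = np.argsort(eigval)[::-1]
    for k in range(4):
        ref = eigvec[:, order[k]]
        dot = abs(model.loadings[:, k] @ ref)
        assert np.isclose(dot, 1.0, atol=1e-8)
    np.testing.assert_allclose(
        model.explained_variance_fraction, eigval[order[:4]] / eigval.sum(), atol=1e-10
    )


def test_sqc_samples_cluster_in_pca(default_sim):
    """Pooled-QC injections sit tighter than study samples in score space."""
    table, _ = default_sim
    roles = table.samples["role"]
    keep = roles.isin(["study", "sqc"])
    logged = tableio.log_transform(table.subset_samples(table.samples.index[keep]))
    scaled = mv.pareto_scale(logged.intensities)
    model = mv.fit_pca(scaled, k=2)
    is_sqc = (roles[keep] == "sqc").to_numpy()

    def mean_pairwise(points):
        d = np.linalg.norm(points[:, None] - points[None, :], axis=-1)
        return d[np.triu_indices(len(points), 1)].mean()

    assert mean_pairwise(model.scores[is_sqc]) < mean_pairwise(model.scores[~is_sqc])


# ---------------------------------------------------------------------------
# OPLS-DA


def _noise_problem(seed, n=40, p=80):
    rng = np.random.default_rng(seed)
    X = rng.normal(size=(n, p))
    y = np.array([1.0] * (n // 2) + [0.0] * (n // 2))
    return mv.pareto_scale(X), y


def test_oplsda_recovers_planted_score():
    rng = np.random.default_rng(8)
    n = 40
    y = np.array([1.0] * 20 + [0.0] * 20)
    X = rng.normal(size=(n, 60))
    X[:, 0] = y + rng.normal(0, 0.05, size=n)
    scaled = mv.pareto_scale(X)
    model = mv.fit_oplsda(scaled, y, n_ortho=1)
    assert abs(np.corrcoef(model.t_p, y)[0, 1]) > 0.95


def test_predictive_scores_orthogonal_to_orthogonal_scores():
    scaled, y = _noise_problem(0)
    model = mv.fit_oplsda(scaled, y, n_ortho=3)
    for k in range(3):
        assert abs(model.t_p @ model.t_o[:, k]) < 1e-8


def test_oplsda_zero_ortho_equals_pls1_oracle():
    """n_ortho=0 must coincide with single-component PLS regression."""
    from sklearn.cross_decomposition import PLSRegression

    for seed in range(5):
        rng = np.random.default_rng(seed)
        X = rng.normal(size=(20, 50))
        y = rng.integers(0, 2, size=20).astype(float)
        y[:2] = [0, 1]  # both classes
        Xc = X - X.mean(axis=0)
        model = mv.fit_oplsda(Xc, y, n_ortho=0)
        ours = model.predict(Xc)
        oracle = PLSRegression(n_components=1, scale=False).fit(X, y).predict(X).ravel()
        np.testing.assert_allclose(ours, oracle, atol=1e-8)


def test_r2_decomposition_and_bounds(default_sim):
    table, _ = default_sim
    filtered, _ = qc.apply_qc(table)
    logged = tableio.log_transform(filtered)
    y = tableio.class_vector(logged)
    scaled = mv.pareto_scale(logged.intensities)
    model = mv.fit_oplsda(scaled, y, n_ortho=1)
    assert 0 <= model.r2x_cum <= 1
    assert 0 <= model.r2y_cum <= 1
    # modelled + residual X sum of squares equals the total
    X_hat = (np.outer(model.t_p, model.p_p)
             + model.t_o @ model.p_o.T)
    resid = scaled.values - X_hat
    total = np.sum(scaled.values**2)
    assert np.isclose(model.r2x_cum + np.sum(resid**2) / total, 1.0, atol=1e-10)


def test_overfit_signature_on_pure_noise():
    """High in-sample R2Y with non-positive Q2 is the overfitting fingerprint.

    Checked at 40 x 50, where held-out predictions are aggressive enough for
    the null Q2 to be reliably negative; for much wider matrices the inner
    PLS coefficient shrinks like 1/sqrt(p) and null Q2 concentrates near
    -n/p, so the sign is no longer a reliable fingerprint.
    """
    results = []
    for seed in range(10):
        scaled, y = _noise_problem(seed, p=50)
        model = mv.fit_oplsda(scaled, y, n_ortho=1)
        q2 = mv.cross_validated_q2(scaled, y, n_ortho=1, seed=seed)
        results.append((model.r2y_cum, q2))
    r2y = np.array([r for r, _ in results])
    q2 = np.array([q for _, q in results])
    assert np.median(r2y) > 0.5
    assert np.mean(q2 <= 0) >= 0.9


def test_q2_strong_signal_and_bounds():
    rng = np.random.default_rng(5)
    y = np.array([1.0] * 20 + [0.0] * 20)
    X = rng.normal(0.0, 0.05, size=(40, 30))  # negligible noise features
    X[:, 0] = y * 4 + rng.normal(0, 0.05, size=40)
    scaled = mv.pareto_scale(X)
    q2 = mv.cross_validated_q2(scaled, y, n_ortho=1, seed=0)
    assert q2 > 0.9
    assert q2 <= 1.0


def test_q2_null_median_negative():
    q2s = [mv.cross_validated_q2(*_noise_problem(seed), n_ortho=1, seed=seed)
           for seed in range(20)]
    assert np.median(q2s) < 0


def test_q2_folds_are_deterministic_given_seed():
    scaled, y = _noise_problem(1)
    assert mv.cross_validated_q2(scaled, y, seed=7) == mv.cross_validated_q2(scaled, y, seed=7)


def test_stratified_folds_keep_both_classes():
    y = np.array([1.0] * 20 + [0.0] * 20)
    folds = mv.stratified_folds(y, 7, np.random.default_rng(0))
    assert sorted(np.concatenate(folds)) == list(range(40))
    for f in folds:
        assert 0 < y[f].mean() < 1


# ---------------------------------------------------------------------------
# permutation test


def test_permutation_p_floor_on_strong_signal():
    rng = np.random.default_rng(6)
    y = np.array([1.0] * 15 + [0.0] * 15)
    X = rng.normal(size=(30, 20))
    X[:, 0] = y * 5 + rng.normal(0, 0.05, size=30)
    scaled = mv.pareto_scale(X)
    result = mv.permutation_test(scaled, y, n_perm=49, seed=0)
    assert result.p_value == 1 / 50
    assert result.valid


def test_permutation_p_invariant_to_label_swap():
    scaled, y = _noise_problem(2)
    a = mv.permutation_test(scaled, y, n_perm=49, seed=3)
    b = mv.permutation_test(scaled, 1 - y, n_perm=49, seed=3)
    assert a.p_value == b.p_value
    assert np.isclose(a.observed_q2, b.observed_q2)


def test_permutation_p_value_formula():
    scaled, y = _noise_problem(3)
    result = mv.permutation_test(scaled, y, n_perm=19, seed=1)
    k = int(np.sum(result.permuted_q2 >= result.observed_q2))
    assert result.p_value == (1 + k) / 20
    assert 1 / 20 <= result.p_value <= 1


# ---------------------------------------------------------------------------
# S-plot


def test_splot_self_and_orthogonal_features():
    rng = np.random.default_rng(9)
    y = np.array([1.0] * 10 + [0.0] * 10)
    t_like = y - y.mean() + rng.normal(0, 0.01, 20)
    X = rng.normal(size=(20, 30))
    X[:, 0] = t_like * 10
    scaled = mv.pareto_scale(X, feature_ids=[f"f{j}" for j in range(30)])
    model = mv.fit_oplsda(scaled, y, n_ortho=0)
    entries = mv.s_plot(model, scaled, cutoff=0.05)
    assert entries.loc["f0", "pcorr"] > 0.95
    # a feature orthogonal to the score: tiny covariance, not shortlisted
    orth = entries.drop("f0")
    assert orth["p1"].abs().max() < entries.loc["f0", "p1"]


def test_splot_shortlist_recovers_strong_planted_features():
    """With a clearly separated planted effect the 0.05 loading cutoff gives
    high recall and precision (weak planted effects are not resolvable from
    thousands of noise features at n=40 by any per-feature statistic)."""
    recalls, precisions = [], []
    for seed in range(5):
        table, truth = L.simulate_study(
            L.SimConfig(seed=seed, effect_size=2.5, n_features=2000)
        )
        filtered, _ = qc.apply_qc(table)
        logged = tableio.log_transform(filtered)
        y = tableio.class_vector(logged)
        scaled = mv.pareto_scale(logged.intensities)
        model = mv.fit_oplsda(scaled, y, n_ortho=1)
        entries = mv.s_plot(model, scaled, cutoff=0.05)
        short = set(entries.index[entries["shortlisted"]])
        disc = set(truth.discriminatory_ids)
        recalls.append(len(short & disc) / len(disc))
        precisions.append(len(short & disc) / max(len(short), 1))
    assert np.median(recalls) >= 0.8
    assert np.median(precisions) >= 0.8


def test_splot_directions_match_planted_signs(default_sim):
    table, truth = default_sim
    filtered, _ = qc.apply_qc(table)
    logged = tableio.log_transform(filtered)
    y = tableio.class_vector(logged)
    scaled = mv.pareto_scale(logged.intensities)
    model = mv.fit_oplsda(scaled, y, n_ortho=1)
    entries = mv.s_plot(model, scaled, cutoff=0.05)
    short = entries[entries["shortlisted"]]
    planted = {f: d for f, d in truth.discriminatory.items() if f in short.index}
    agree = [short.loc[f, "direction"] == d for f, d in planted.items()]
    assert np.mean(agree) == 1.0
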