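"""NIPALS PLS1: correctness against oracles and latent-count selection."""

import warnings

import numpy as np
import pytest

from hybridferm.pls import (
    ResidualTable,
    build_residual_table,
    pls_fit,
    pls_predict,
    report_coefficients,
    select_latent,
)


def make_table(X, y, columns=None):
    n, p = X.shape
    return ResidualTable(
        X=X, y=y - y.mean(),
        columns=columns or [f"c{i}" for i in range(p)],
        col_mean=np.zeros(p), col_scale=np.ones(p),
        y_mean=float(y.mean()), batch_ids=["b"] * n,
    )


def standardized(rng, n, p):
    X = rng.standard_normal((n, p))
    return (X - X.mean(0)) / X.std(0)


def make_rank3_table(seed, n=240, p=12, noise=0.15):
    """Response living exactly in the span of the top three principal scores
    of a variance-graded input block."""
    rng = np.random.default_rng(seed)
    U = np.linalg.qr(rng.standard_normal((n, p)))[0]
    V = np.linalg.qr(rng.standard_normal((p, p)))[0]
    s = np.array([30.0, 15.0, 6.0] + [1.0] * (p - 3))
    X = U @ np.diag(s) @ V.T
    Z = (X - X.mean(0)) / X.std(0)
    _, _, vt = np.linalg.svd(Z, full_matrices=False)
    t = Z @ vt[:3].T
    t = t / t.std(0)
    y = 1.0 * t[:, 0] + 0.7 * t[:, 1] + 0.5 * t[:, 2] + noise * rng.standard_normal(n)
    return make_table(Z, y)


def test_single_direction_fully_explained_by_one_component():
    """With uncorrelated inputs, a response linear in one input is fully
    captured by the first latent variable."""
    rng = np.random.default_rng(0)
    A = rng.standard_normal((100, 6))
    A -= A.mean(0)
    Q = np.linalg.qr(A)[0]
    X = Q / Q.std(0)
    y = 3.0 * X[:, 2]
    m = pls_fit(make_table(X, y), 1)
    assert m.explained_variance == pytest.approx(1.0, abs=1e-9)


def test_full_components_equal_ols():
    """With as many components as full-rank inputs, PLS1 reproduces the
    normal-equations solution."""
    rng = np.random.default_rng(1)
    X = standardized(rng, 150, 8)
    y = X @ rng.standard_normal(8) + 0.1 * rng.standard_normal(150)
    tbl = make_table(X, y)
    m = pls_fit(tbl, 8)
    ols = np.linalg.solve(X.T @ X, X.T @ tbl.y)
    assert np.abs(m.coef - ols).max() <= 1e-8


def test_matches_sklearn_reference():
    """Independent cross-check of the NIPALS implementation."""
    sklearn_pls = pytest.importorskip("sklearn.cross_decomposition")
    rng = np.random.default_rng(2)
    X = standardized(rng, 120, 10)
    y = X @ rng.standard_normal(10) + 0.2 * rng.standard_normal(120)
    tbl = make_table(X, y)
    for a in (1, 3, 6):
        ours = pls_fit(tbl, a)
        ref = sklearn_pls.PLSRegression(n_components=a, scale=False).fit(X, tbl.y)
        assert np.abs(ours.coef - ref.coef_.ravel()).max() < 1e-10


def test_permuted_response_explains_little():
    rng = np.random.default_rng(3)
    X = standardized(rng, 200, 12)
    y = X @ rng.standard_normal(12)
    y_perm = y[rng.permutation(200)]
    m = pls_fit(make_table(X, y_perm), 4)
    assert m.explained_variance < 0.2


def test_explained_variance_monotone_in_components():
    tbl = make_rank3_table(0)
    evs = [pls_fit(tbl, a).explained_variance for a in range(1, 9)]
    assert np.all(np.diff(evs) >= -1e-12)


def test_latent_count_recovery_and_noise_guard():
    """Cross-validated selection recovers a planted rank-3 dependence and
    stays low for a pure-noise response."""
    tbl = make_rank3_table(7)
    chosen, winners = select_latent(tbl, max_latent=8, n_repeats=20, seed=0)
    assert chosen == 3
    assert len(winners) == 20
    assert select_latent(tbl, max_latent=8, n_repeats=20, seed=0)[0] == chosen

    rng = np.random.default_rng(4)
    X = standardized(rng, 240, 12)
    noise_tbl = make_table(X, rng.standard_normal(240))
    assert select_latent(noise_tbl, max_latent=8, n_repeats=20, seed=0)[0] <= 2


def test_coefficient_report_ranks_planted_variable_first():
    rng = np.random.default_rng(5)
    X = standardized(rng, 150, 12)
    cols = ["T", "pH", "u_C", "u_Base", "agitation", "acetate"] + [
        f"{c}^2" for c in ["T", "pH", "u_C", "u_Base", "agitation", "acetate"]
    ]
    y = 2.0 * X[:, 5] + 0.05 * rng.standard_normal(150)  # acetate column
    m = pls_fit(make_table(X, y, cols), 2)
    report = report_coefficients(m, cols)
    assert report.iloc[0]["variable"] == "acetate"
    # zero response -> zero coefficients
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        m0 = pls_fit(make_table(X, np.zeros(150), cols), 2)
    assert np.allclose(m0.coef, 0.0)


def test_residual_table_structure(fit_noiseless, study_noisy_doe):
    """Twelve standardized columns (six variables plus squares), restricted to
    acetate-bearing batches, each column mean 0 and variance 1."""
    pool = [b for b in study_noisy_doe if b.offline.acetate is not None]
    tbl = build_residual_table(fit_noiseless.params, pool)
    assert len(tbl.columns) == 12
    assert tbl.X.shape[1] == 12
    assert np.allclose(tbl.X.mean(axis=0), 0.0, atol=1e-12)
    assert np.allclose(tbl.X.var(axis=0), 1.0, atol=1e-12)
    assert abs(tbl.y.mean()) < 1e-12
    no_acetate = [b for b in study_noisy_doe if b.offline.acetate is None]
    if no_acetate:
        with pytest.raises(ValueError):
            build_residual_table(fit_noiseless.params, no_acetate)


def test_perfect_model_gives_zero_residuals(study_noiseless_doe, fit_noiseless):
    """When the measured product equals the model's own prediction, every
    residual in the table is exactly zero."""
    from dataclasses import replace as dc_replace

    from hybridferm.model import euler_integrate, predict_offline

    pool = []
    for b in study_noiseless_doe[:5]:
        if b.offline.acetate is None:
            continue
        traj = euler_integrate(fit_noiseless.params, b)
        off = dc_replace(b.offline, P=predict_offline(traj, b.offline.t, "P"))
        pool.append(dc_replace(b, offline=off))
    tbl = build_residual_table(fit_noiseless.params, pool)
    assert np.allclose(tbl.y + tbl.y_mean, 0.0, atol=1e-12)
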