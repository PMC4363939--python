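import numpy as np
import pandas as pd
import pytest
from sklearn.cross_decomposition import PLSRegression

from plsig.pls import (
    PLSNipals,
    choose_components,
    q2_score,
    select_and_refit,
    vip_scores,
)


def _random_instance(seed, n=8, p=50, r=1, noise=0.1):
    rng = np.random.default_rng(seed)
    X = rng.normal(size=(n, p))
    B = rng.normal(size=(p, r))
    Y = X @ B + noise * rng.normal(size=(n, r))
    return X, Y


@pytest.mark.parametrize("r", [1, 3])
@pytest.mark.parametrize("seed", [0, 1, 2])
def test_coefficients_match_reference_implementation(seed, r):
    """Complete-data NIPALS agrees with sklearn's PLS to 1e-6 relative."""
    X, Y = _random_instance(seed, r=r)
    A = 3
    ref = PLSRegression(n_components=A, scale=True, tol=1e-14,
                        max_iter=5000).fit(X, Y)
    mine = PLSNipals(n_components=A, tol=1e-13, max_iter=5000).fit(X, Y)
    ref_coef = ref.coef_.T
    assert np.abs(mine.coef_ - ref_coef).max() <= 1e-6 * np.abs(ref_coef).max()


def test_scores_are_orthogonal_and_r2_monotone():
    X, Y = _random_instance(3, r=2)
    r2y_prev = 0.0
    for A in (1, 2, 3, 4):
        model = PLSNipals(n_components=A).fit(X, Y)
        T = model.x_scores_
        gram = T.T @ T
        off = np.abs(gram - np.diag(np.diag(gram))).max()
        assert off < 1e-8 * np.diag(gram).max()
        assert model.r2y_ >= r2y_prev - 1e-12
        r2y_prev = model.r2y_


def test_perfect_fit_when_response_is_a_predictor_direction():
    # orthogonal X columns make the first weight vector point exactly at Y
    rng = np.random.default_rng(0)
    M = rng.normal(size=(8, 6))
    M -= M.mean(axis=0)  # so centering/scaling preserves orthogonality
    Q, _ = np.linalg.qr(M)
    X = Q[:, :5]
    y = X[:, 0].copy()
    model = PLSNipals(n_components=1).fit(X, y)
    assert model.r2y_ == pytest.approx(1.0, abs=1e-10)


def test_scaling_invariance_of_predictions():
    X, Y = _random_instance(4)
    scaled = X.copy()
    scaled[:, 0] *= 17.0
    scaled[:, 3] *= 0.02
    a = PLSNipals(n_components=2).fit(X, Y).predict(X)
    b = PLSNipals(n_components=2).fit(scaled, Y).predict(scaled)
    np.testing.assert_allclose(a, b, rtol=1e-8, atol=1e-10)


def test_fit_input_validation():
    X, Y = _random_instance(0)
    with pytest.raises(ValueError, match="n_components"):
        PLSNipals(n_components=10).fit(X, Y)  # > n-1
    with pytest.raises(ValueError, match="2 observations"):
        PLSNipals(n_components=1).fit(X[:1], Y[:1])
    bad = X.copy()
    bad[:, 2] = np.nan
    with pytest.raises(ValueError, match="no observed entries"):
        PLSNipals(n_components=1).fit(bad, Y)
    const = X.copy()
    const[:, 5] = 2.5
    with pytest.warns(UserWarning, match="zero-variance"):
        model = PLSNipals(n_components=1).fit(const, Y)
    assert model.dropped_features_ == [5]


def test_predict_consistency_and_no_information_limit():
    X, Y = _random_instance(5, r=2)
    model = PLSNipals(n_components=2).fit(X, Y)
    np.testing.assert_allclose(
        model.predict(X), model.fitted_values(), rtol=1e-8, atol=1e-10
    )
    blank = np.full((1, X.shape[1]), np.nan)
    np.testing.assert_allclose(
        model.predict(blank)[0], Y.mean(axis=0), rtol=1e-10
    )


def test_prediction_moves_linearly_on_noiseless_fixture():
    # rank-1 X and exactly linear y: prediction responds linearly to a
    # perturbation along the latent direction
    rng = np.random.default_rng(6)
    t = rng.normal(size=10)
    load = rng.normal(size=6)
    X = np.outer(t, load)
    y = 2.0 * t
    model = PLSNipals(n_components=1).fit(X, y)
    base = model.predict(X[:1])[0, 0]
    deltas = []
    for eps in (0.5, 1.0, 2.0):
        pert = X[:1] + eps * load
        deltas.append(model.predict(pert)[0, 0] - base)
    assert deltas[1] == pytest.approx(2 * deltas[0], rel=1e-8)
    assert deltas[2] == pytest.approx(4 * deltas[0], rel=1e-8)


def test_missing_entries_are_tolerated_in_fit_and_predict():
    rng = np.random.default_rng(7)
    t = rng.normal(size=12)
    X = np.outer(t, rng.normal(size=8)) + 0.01 * rng.normal(size=(12, 8))
    y = 3.0 * t + 1.0
    Xm = X.copy()
    mask = rng.random(X.shape) < 0.2
    Xm[mask] = np.nan
    model = PLSNipals(n_components=1).fit(Xm, y)
    pred = model.predict(Xm)[:, 0]
    # far better than predicting the mean despite 20% missing entries
    assert np.corrcoef(pred, y)[0, 1] > 0.99


def test_vip_identities():
    X, Y = _random_instance(8, p=20, r=2)
    model = PLSNipals(n_components=3).fit(X, Y)
    vip = vip_scores(model).to_numpy()
    assert (vip >= 0).all()
    assert np.mean(vip**2) == pytest.approx(1.0, abs=1e-8)
    # brute-force recomputation from the stored weights and SS_a
    W, ss = model.x_weights_, model.y_ss_per_component_
    p = W.shape[0]
    brute = np.array(
        [
            np.sqrt(
                p
                * sum(
                    ss[a] * (W[j, a] / np.linalg.norm(W[:, a])) ** 2
                    for a in range(W.shape[1])
                )
                / ss.sum()
            )
            for j in range(p)
        ]
    )
    np.testing.assert_allclose(vip, brute, rtol=1e-10)


def test_vip_single_component_reduction():
    X, Y = _random_instance(9, p=15, r=1)
    model = PLSNipals(n_components=1).fit(X, Y)
    vip = vip_scores(model).to_numpy()
    w = model.x_weights_[:, 0]
    expected = np.sqrt(len(w)) * np.abs(w) / np.linalg.norm(w)
    np.testing.assert_allclose(vip, expected, rtol=1e-10)


def test_q2_press_matches_reference_foldwise_recomputation():
    # leave-one-out on a small fixture; PRESS recomputed independently
    # with sklearn models per fold
    rng = np.random.default_rng(10)
    X = rng.normal(size=(4, 2))
    y = X @ np.array([1.0, -2.0]) + 0.05 * rng.normal(size=4)
    folds, seed, A = 4, 3, 1
    diag = q2_score(X, y, n_components=A, folds=folds, seed=seed)

    from plsig.pls import _fold_assignment

    fold_id = _fold_assignment(4, folds, seed)
    sd = y.std(ddof=1)
    press = 0.0
    for k in range(folds):
        test = fold_id == k
        ref = PLSRegression(n_components=A, scale=True).fit(X[~test], y[~test])
        press += float(
            (((y[test] - ref.predict(X[test]).ravel()) / sd) ** 2).sum()
        )
    ss = float((((y - y.mean()) / sd) ** 2).sum())
    assert diag.q2 == pytest.approx(1 - press / ss, rel=1e-8)


def test_q2_fold_validation():
    X, Y = _random_instance(11)
    with pytest.raises(ValueError, match="folds"):
        q2_score(X, Y, n_components=1, folds=9)
    with pytest.raises(ValueError, match="folds"):
        q2_score(X, Y, n_components=1, folds=1)


def test_choose_components_never_accepts_negative_increment():
    for seed in range(5):
        X, Y = _random_instance(seed, n=10, p=30, noise=0.5)
        A, diag = choose_components(X, Y, seed=seed)
        assert A >= 1
        if A > 1:
            assert all(inc > 0.01 for inc in diag.q2_increments[1:A])


def test_select_and_refit_contracts():
    X, Y = _random_instance(12, p=20)
    Xf = pd.DataFrame(X, columns=[f"g{j}" for j in range(20)])
    # cutoff 0 keeps everything and the refit matches the original
    sel, refit, diags = select_and_refit(Xf, Y, n_components=2, cutoff=0.0)
    assert len(sel) == 20
    base = PLSNipals(n_components=2).fit(Xf, Y)
    np.testing.assert_allclose(refit.predict(Xf), base.predict(Xf),
                               rtol=1e-6, atol=1e-8)
    # cutoff above the maximum VIP is an error suggesting a lower cutoff
    with pytest.raises(ValueError, match="lower cutoff"):
        select_and_refit(Xf, Y, n_components=2, cutoff=1e6)


def test_json_round_trip_preserves_predictions():
    X, Y = _random_instance(13, r=2)
    Xf = pd.DataFrame(X, columns=[f"g{j}" for j in range(X.shape[1])])
    model = PLSNipals(n_components=2).fit(Xf, Y)
    clone = PLSNipals.from_json(model.to_json())
    np.testing.assert_allclose(clone.predict(Xf), model.predict(Xf),
                               rtol=1e-12)
    with pytest.raises(ValueError, match="unknown predictor"):
        clone.predict(pd.DataFrame(X, columns=[f"h{j}" for j in
                                               range(X.shape[1])]))
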