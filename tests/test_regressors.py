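"""Regression models: LASSO limits, network training, LSTM cell, CV."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from angioflow import regressors as rg
from angioflow._nn import lstm_cell_step


def linear_table(n=3000, noise=0.0, seed=0):
    rng = np.random.default_rng(seed)
    X = rng.normal(size=(n, 4))
    W = np.array([[0.5, -0.2, 0.1, 0.0], [0.0, 0.8, 0.0, -0.3]])
    Y = X @ W.T + noise * rng.normal(size=(n, 2))
    df = pd.DataFrame(np.hstack([X, Y]),
                      columns=["u_ofm", "v_ofm", "Ix", "Iy", "u_truth", "v_truth"])
    return df, X, Y, W


# ---------------------------------------------------------------------------
# LASSO


def test_lasso_small_penalty_matches_least_squares():
    """With penalty -> 0 the coefficients match the normal equations."""
    df, X, Y, _ = linear_table(n=2000, noise=0.05, seed=1)
    model = rg.fit_lasso(df, penalty=1e-10)
    # closed-form OLS oracle on the same standardized data
    xs = model.x_scaler.transform(X)
    ys = model.y_scaler.transform(Y)
    xa = np.hstack([xs, np.ones((len(xs), 1))])
    beta = np.linalg.lstsq(xa, ys, rcond=None)[0]
    assert np.allclose(model.coef, beta[:-1].T, atol=1e-6)


def test_lasso_large_penalty_predicts_mean():
    df, X, Y, _ = linear_table(n=1000, noise=0.05, seed=2)
    model = rg.fit_lasso(df, penalty=1e6)
    assert np.allclose(model.coef, 0.0)
    pred = model.predict(X)
    assert np.allclose(pred, Y.mean(axis=0), atol=1e-9)


def test_lasso_noiseless_linear_training_error_vanishes():
    df, X, Y, _ = linear_table(n=1000, noise=0.0, seed=3)
    model = rg.fit_lasso(df, penalty=1e-12)
    assert np.mean(np.abs(model.predict(X) - Y)) < 1e-8


def test_lasso_parameter_recovery_under_noise():
    """Coefficients recovered within 3 sigma on 1e4 noisy rows."""
    sigma = 0.1
    df, X, Y, W = linear_table(n=10_000, noise=sigma, seed=4)
    model = rg.fit_lasso(df, penalty=1e-8)
    # un-standardize the fitted coefficients back to raw units
    coef_raw = (model.coef * model.y_scaler.std[:, None]) / model.x_scaler.std[None, :]
    se = 3.0 * sigma / np.sqrt(len(df))        # per-coefficient 3-sigma band
    assert np.all(np.abs(coef_raw - W) < 5 * se + 1e-3)


# ---------------------------------------------------------------------------
# neural models


@pytest.mark.parametrize("kind,kw", [
    ("mlp", dict(dropout=0.0, epochs=80)),
    ("cnn", dict(epochs=250, batch_size=128, learning_rate=3e-3)),
    ("lstm", dict(epochs=200, batch_size=128, learning_rate=3e-3)),
])
def test_network_approaches_linear_oracle(kind, kw):
    """On a noisy linear task each net lands near the LASSO baseline.

    The irreducible noise floor dominates, so a well-trained network's
    test MAE must come within 25% of the linear model's.
    """
    df, _, _, W = linear_table(n=4000, noise=0.05, seed=5)
    test_df, Xte, Yte, _ = linear_table(n=2000, noise=0.05, seed=6)
    base = rg.fit_lasso(df, penalty=1e-6)
    base_mae = np.mean(np.abs(base.predict(Xte) - Yte))
    model = rg.fit_model(df, rg.ModelConfig(kind=kind, seed=11, **kw))
    net_mae = np.mean(np.abs(model.predict(Xte) - Yte))
    assert net_mae < 1.25 * base_mae


def test_prediction_shape_and_unfitted_error():
    df, X, _, _ = linear_table(n=200, seed=7)
    model = rg.fit_model(df, rg.ModelConfig(kind="mlp", epochs=2))
    assert model.predict(X[:17]).shape == (17, 2)
    empty = rg.TrainedModel(config=rg.ModelConfig(kind="mlp"),
                            x_scaler=model.x_scaler, y_scaler=model.y_scaler)
    with pytest.raises(RuntimeError):
        empty.predict(X[:3])


def test_training_deterministic_under_seed():
    df, _, _, _ = linear_table(n=500, seed=8)
    cfg = rg.ModelConfig(kind="mlp", epochs=5, seed=42)
    m1 = rg.fit_model(df, cfg)
    m2 = rg.fit_model(df, rg.ModelConfig(kind="mlp", epochs=5, seed=42))
    for k in m1.net.params:
        assert np.array_equal(m1.net.params[k], m2.net.params[k])


def test_serialization_roundtrip_bit_identical(tmp_path):
    df, X, _, _ = linear_table(n=400, seed=9)
    for kind in ("lasso", "mlp", "cnn", "lstm"):
        cfg = rg.ModelConfig(kind=kind, epochs=3, batch_size=64)
        model = rg.fit_model(df, cfg)
        p = tmp_path / f"{kind}.npz"
        model.save(p)
        back = rg.TrainedModel.load(p)
        assert np.array_equal(model.predict(X[:50]), back.predict(X[:50]))


# ---------------------------------------------------------------------------
# LSTM cell


def test_lstm_cell_zero_weights():
    """sigma(0) = 0.5, tanh(0) = 0: gates half-open, state stays zero."""
    H = 4
    w = {f"w_{g}": np.zeros((H, H + 1)) for g in "ifco"}
    w.update({f"b_{g}": np.zeros(H) for g in "ifco"})
    h, c = lstm_cell_step(w, np.array([[1.3]]), np.zeros((1, H)), np.zeros((1, H)))
    assert np.allclose(c, 0.0)
    assert np.allclose(h, 0.0)


def test_lstm_cell_hand_computed_state():
    """With zero weights and c_prev = 2: c = 1.0, h = 0.5 tanh(1)."""
    H = 2
    w = {f"w_{g}": np.zeros((H, H + 1)) for g in "ifco"}
    w.update({f"b_{g}": np.zeros(H) for g in "ifco"})
    h, c = lstm_cell_step(w, np.array([[0.2]]), np.zeros((1, H)),
                          np.full((1, H), 2.0))
    assert np.allclose(c, 1.0)
    assert np.allclose(h, 0.5 * np.tanh(1.0))


@settings(max_examples=30, deadline=None)
@given(st.integers(0, 10_000))
def test_lstm_output_bounded(seed):
    """|h_t| < 1 always: o_t in (0,1) and tanh in (-1,1)."""
    rng = np.random.default_rng(seed)
    H = 5
    w = {f"w_{g}": rng.normal(0, 2, (H, H + 1)) for g in "ifco"}
    w.update({f"b_{g}": rng.normal(0, 2, H) for g in "ifco"})
    h, c = np.zeros((3, H)), rng.normal(0, 3, (3, H))
    for t in range(4):
        h, c = lstm_cell_step(w, rng.normal(0, 5, (3, 1)), h, c)
        assert np.all(np.abs(h) < 1.0)


# ---------------------------------------------------------------------------
# cross-validation


def test_cv_produces_30_fold_scores():
    df, _, _, _ = linear_table(n=600, seed=10)
    scores = rg.cross_validate(rg.ModelConfig(kind="lasso"), df, seed=1)
    assert len(scores) == 30
    assert set(scores["repeat"]) == {0, 1, 2}
    assert set(scores["fold"]) == set(range(10))


def test_cv_constant_model_equals_fold_mad():
    """A mean-only model's fold MAE equals the fold targets' deviation.

    Direct-computation oracle: replicate the same fold partition and
    compare against mean |y - mean(y_train)| per fold.
    """
    from sklearn.model_selection import RepeatedKFold

    df, X, Y, _ = linear_table(n=500, noise=0.05, seed=11)
    cfg = rg.ModelConfig(kind="lasso", l1_penalty=1e9)   # predicts the mean
    scores = rg.cross_validate(cfg, df, k=5, repeats=1, seed=21)
    rkf = RepeatedKFold(n_splits=5, n_repeats=1, random_state=21)
    expected = [np.mean(np.abs(Y[va] - Y[tr].mean(axis=0)))
                for tr, va in rkf.split(X)]
    assert np.allclose(scores["mae"].to_numpy(), expected, rtol=1e-9)


def test_cv_requires_enough_rows():
    df, _, _, _ = linear_table(n=5, seed=12)
    with pytest.raises(ValueError):
        rg.cross_validate(rg.ModelConfig(kind="lasso"), df, k=10)
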