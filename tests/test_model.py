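"""Model-structure contracts: recursions, rollouts, decomposition, spectra."""

import numpy as np
import pytest

from braid.model import (BRAIDModel, ModelSection, SignalScaler, TransformSpec,
                         forecast_rollout, linearize_Afw, predictor_step)


def _linear_section(rng, n=2, n_y=3, n_z=2, n_u=2, signals=("y", "u")):
    specs = {k: TransformSpec(k, mode="linear") for k in
             ("A", "Afw", "K", "Kfw", "Cy", "Cz")}
    return ModelSection(1, n, n_y, n_z, n_u, signals, specs, rng)


def _set_linear(mp, W, b=None):
    mp.layers[0].W[:] = np.asarray(W, float).T  # row convention: x_next = W x
    mp.layers[0].b[:] = 0.0 if b is None else b


def test_predictor_step_zero_and_identity_maps():
    rng = np.random.default_rng(0)
    sec = _linear_section(rng)
    _set_linear(sec.maps["A"], np.zeros((2, 2)))
    _set_linear(sec.maps["K"], np.zeros((2, 5)))
    assert np.allclose(predictor_step(sec, [1.0, -2.0], np.ones(5)), 0.0)
    _set_linear(sec.maps["A"], np.eye(2))
    s = np.array([0.3, -1.2])
    assert np.allclose(predictor_step(sec, s, np.ones(5)), s)


def test_predictor_step_matches_dense_algebra():
    rng = np.random.default_rng(1)
    sec = _linear_section(rng, n=2, n_y=1, n_u=2)
    A = np.array([[0.5, 0.1], [-0.2, 0.8]])
    K = np.array([[1.0, 0.0, 2.0], [0.5, -1.0, 0.0]])
    _set_linear(sec.maps["A"], A)
    _set_linear(sec.maps["K"], K)
    s = np.array([1.0, -1.0])
    o = np.array([0.2, 0.4, -0.6])
    assert np.allclose(predictor_step(sec, s, o), A @ s + K @ o)
    with pytest.raises(ValueError, match="entries"):
        predictor_step(sec, np.ones(3), o)


def test_forecast_rollout_identity_and_closed_form():
    rng = np.random.default_rng(2)
    sec = _linear_section(rng)
    s = np.array([0.7, -0.4])
    assert np.allclose(forecast_rollout(sec, s, None, 1), s)

    _set_linear(sec.maps["Afw"], np.eye(2))
    _set_linear(sec.maps["Kfw"], np.zeros((2, 2)))
    assert np.allclose(forecast_rollout(sec, s, np.zeros((4, 2)), 5), s)

    Afw = np.array([[0.9, 0.2], [0.0, 0.7]])
    Kfw = np.array([[1.0, 0.0], [0.3, -0.5]])
    _set_linear(sec.maps["Afw"], Afw)
    _set_linear(sec.maps["Kfw"], Kfw)
    u = np.array([[0.1, 0.2], [-0.3, 0.4]])
    expected = Afw @ Afw @ s + Afw @ Kfw @ u[0] + Kfw @ u[1]
    assert np.allclose(forecast_rollout(sec, s, u, 3), expected)
    with pytest.raises(ValueError, match="future input"):
        forecast_rollout(sec, s, u[:1], 3)


def test_forecast_rollout_composes():
    """Rolling m1 then m2 steps equals one (m1+m2)-step rollout."""
    rng = np.random.default_rng(3)
    specs = {k: TransformSpec(k, mode="nonlinear", hidden_units=6,
                              activation="tanh")
             for k in ("A", "Afw", "K", "Kfw", "Cy", "Cz")}
    sec = ModelSection(1, 3, 2, 2, 2, ("y", "u"), specs, rng)
    s = rng.standard_normal(3)
    u = rng.standard_normal((5, 2))
    one_shot = forecast_rollout(sec, s, u, 6)
    mid = forecast_rollout(sec, s, u[:2], 3)
    again = forecast_rollout(sec, mid, u[2:], 4)
    assert np.allclose(one_shot, again, atol=1e-12)


def _reference_linear_filter(A, K, obs, n):
    T = obs.shape[0]
    X = np.zeros((T, n))
    for k in range(T - 1):
        X[k + 1] = A @ X[k] + K @ obs[k]
    return X


def test_filter_matches_reference_linear_filter():
    rng = np.random.default_rng(4)
    sec = _linear_section(rng, n=3, n_y=4, n_u=2)
    A = 0.5 * rng.standard_normal((3, 3))
    K = rng.standard_normal((3, 6))
    _set_linear(sec.maps["A"], A)
    _set_linear(sec.maps["K"], K)
    obs = rng.standard_normal((200, 6))
    assert np.allclose(sec.filter(obs), _reference_linear_filter(A, K, obs, 3),
                       atol=1e-12)


def test_filter_is_causal_and_validates_input():
    rng = np.random.default_rng(5)
    sec = _linear_section(rng)
    obs = rng.standard_normal((100, 5))
    full = sec.filter(obs)
    prefix = sec.filter(obs[:40])
    assert np.allclose(full[:40], prefix)
    obs2 = obs.copy()
    obs2[60:] = 99.0  # future perturbation must not affect the past
    assert np.allclose(sec.filter(obs2)[:61], full[:61])
    obs2[10] = np.nan
    with pytest.raises(ValueError, match="non-finite"):
        sec.filter(obs2)


def test_zeroed_weights_give_zero_states():
    rng = np.random.default_rng(6)
    sec = _linear_section(rng)
    _set_linear(sec.maps["A"], np.zeros((2, 2)))
    _set_linear(sec.maps["K"], np.zeros((2, 5)))
    assert np.allclose(sec.filter(rng.standard_normal((50, 5))), 0.0)


def _identity_scalers(dims):
    return {k: SignalScaler(mean=np.zeros(d), std=np.ones(d))
            for k, d in dims.items()}


def test_two_section_decomposition_matches_monolithic_computation():
    """Summed per-section contributions equal one dense reference computation."""
    rng = np.random.default_rng(7)
    n_y, n_z, n_u = 3, 2, 2
    sec1 = _linear_section(rng, n=2, n_y=n_y, n_z=n_z, n_u=n_u)
    specs = {k: TransformSpec(k, mode="linear") for k in
             ("A", "Afw", "K", "Kfw", "Cy", "Cz")}
    sec2 = ModelSection(2, 2, n_y, n_z, n_u, ("y", "u", "x1"), specs, rng,
                        x1_dim=2)
    model = BRAIDModel(sections={1: sec1, 2: sec2},
                       scalers=_identity_scalers({"y": n_y, "z": n_z, "u": n_u}))
    y = rng.standard_normal((150, n_y))
    u = rng.standard_normal((150, n_u))
    states = model.filter_sequence(y, u)
    zhat, yhat = model.predict_observations(states, u=u, horizon=1)

    def lin(mp):
        return mp.layers[0].W.T, mp.layers[0].b

    A1, _ = lin(sec1.maps["A"])
    K1, _ = lin(sec1.maps["K"])
    A2, _ = lin(sec2.maps["A"])
    K2, _ = lin(sec2.maps["K"])
    X1 = _reference_linear_filter(A1, K1, np.hstack([y, u]), 2)
    X2 = _reference_linear_filter(A2, K2, np.hstack([y, u, X1]), 2)
    Cz1, bz1 = lin(sec1.maps["Cz"])
    Cz2, bz2 = lin(sec2.maps["Cz"])
    Cy1, by1 = lin(sec1.maps["Cy"])
    Cy2, by2 = lin(sec2.maps["Cy"])
    z_ref = X1 @ Cz1.T + bz1 + X2 @ Cz2.T + bz2
    y_ref = X1 @ Cy1.T + by1 + X2 @ Cy2.T + by2
    assert np.allclose(zhat, z_ref, atol=1e-10)
    assert np.allclose(yhat, y_ref, atol=1e-10)


def test_section_isolation_zero_decoder_removes_contribution():
    rng = np.random.default_rng(8)
    n_y, n_z, n_u = 3, 2, 2
    sec1 = _linear_section(rng, n=2, n_y=n_y, n_z=n_z, n_u=n_u)
    specs = {k: TransformSpec(k, mode="linear") for k in
             ("A", "Afw", "K", "Kfw", "Cy", "Cz")}
    sec2 = ModelSection(2, 2, n_y, n_z, n_u, ("y", "u", "x1"), specs, rng,
                        x1_dim=2)
    model = BRAIDModel(sections={1: sec1, 2: sec2},
                       scalers=_identity_scalers({"y": n_y, "z": n_z, "u": n_u}))
    y = rng.standard_normal((80, n_y))
    u = rng.standard_normal((80, n_u))
    states = model.filter_sequence(y, u)
    z_full, _ = model.predict_observations(states, u=u, horizon=1)
    _set_linear(sec2.maps["Cz"], np.zeros((n_z, 2)))
    z_one, _ = model.predict_observations(states, u=u, horizon=1)
    only1 = sec1.decode(states[1], "Cz")
    assert np.allclose(z_one, only1, atol=1e-12)
    assert not np.allclose(z_full, z_one)


def test_section3_never_reads_neural_activity():
    rng = np.random.default_rng(9)
    specs = {k: TransformSpec(k, mode="linear") for k in
             ("A", "Afw", "K", "Kfw", "Cy", "Cz")}
    with pytest.raises(ValueError, match="section 3"):
        ModelSection(3, 2, 3, 2, 2, ("y", "u"), specs, rng)
    sec3 = ModelSection(3, 2, 3, 2, 2, ("u",), specs, rng)
    assert sec3.encoder_input_dim() == 2


def test_linearize_Afw_eigenvalues():
    rng = np.random.default_rng(10)
    sec = _linear_section(rng)
    _set_linear(sec.maps["Afw"], np.diag([0.9, 0.5]))
    _, eigs = linearize_Afw(sec)
    assert np.allclose(eigs, [0.9, 0.5])

    th = 0.3
    R = 0.8 * np.array([[np.cos(th), -np.sin(th)], [np.sin(th), np.cos(th)]])
    _set_linear(sec.maps["Afw"], R)
    _, eigs = linearize_Afw(sec)
    expected = 0.8 * np.exp(1j * np.array([th, -th]))
    assert np.allclose(sorted(eigs, key=np.imag), sorted(expected, key=np.imag))


def test_linearize_nonlinear_Afw_with_zero_hidden_weights():
    """With zeroed hidden path the Jacobian reduces to the affine read-out."""
    rng = np.random.default_rng(11)
    specs = {k: TransformSpec(k, mode=("nonlinear" if k == "Afw" else "linear"),
                              hidden_units=8, activation="tanh")
             for k in ("A", "Afw", "K", "Kfw", "Cy", "Cz")}
    sec = ModelSection(1, 2, 3, 2, 2, ("y", "u"), specs, rng)
    afw = sec.maps["Afw"]
    afw.layers[0].W[:] = 0.0
    afw.layers[0].b[:] = 0.0
    afw.layers[1].W[:] = 0.0
    _, eigs = linearize_Afw(sec)
    assert np.allclose(eigs, 0.0)
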