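"""Loss arithmetic, stage contracts, special-case variants, auto-selection."""

import numpy as np
import pytest

from braid import (TrainingConfig, auto_select_nonlinearity, fit_braid,
                   loss_mstep, metric_cc, preprocess_behavior, simulate)
from braid.training import fit_stage3

from conftest import LINEAR_ASSIGN, NONLIN_CZ_ASSIGN, quick_config


# -- loss --------------------------------------------------------------------

def test_loss_mstep_zero_for_perfect_predictions():
    t = np.random.default_rng(0).standard_normal((50, 2))
    assert loss_mstep([t[1:], t[3:]], t, [1, 3]) == 0.0


def test_loss_mstep_constant_offset_gives_squared_error():
    t = np.zeros((40, 1))
    pred = np.full((39, 1), 0.5)
    assert loss_mstep([pred], t, [1]) == pytest.approx(0.25)


def test_loss_mstep_sums_horizon_mses():
    rng = np.random.default_rng(1)
    t = rng.standard_normal((30, 2))
    p1, p2 = rng.standard_normal((29, 2)), rng.standard_normal((28, 2))
    m1 = np.mean((t[1:] - p1) ** 2)
    m2 = np.mean((t[2:] - p2) ** 2)
    assert loss_mstep([p1, p2], t, [1, 2]) == pytest.approx(m1 + m2)
    assert loss_mstep([p1, p2], t, [1, 2], weights=[2.0, 0.5]) == \
        pytest.approx(2 * m1 + 0.5 * m2)
    with pytest.raises(ValueError, match="rows"):
        loss_mstep([p1[:-1]], t, [1])


def test_training_config_validation():
    with pytest.raises(ValueError, match="horizons"):
        TrainingConfig(horizons=(1, 1, 2))
    with pytest.raises(ValueError, match="variant"):
        TrainingConfig(variant="bogus")
    cfg = TrainingConfig(variant="linear_braid",
                         nonlinearity={"A": "nonlinear", "K": "linear",
                                       "Cy": "linear", "Cz": "nonlinear"})
    assert all(v == "linear" for v in cfg.nonlinearity.values())


# -- preprocessor --------------------------------------------------------------

def test_preprocessor_recovers_memoryless_linear_map():
    rng = np.random.default_rng(2)
    y = rng.standard_normal((1500, 4))
    W = rng.standard_normal((4, 2))
    z = y @ W
    _, zpre = preprocess_behavior(y, z, quick_config(epochs=120))
    assert metric_cc(zpre[10:], z[10:]) > 0.98


def test_preprocessor_at_chance_on_time_shuffled_neural_data():
    rng = np.random.default_rng(3)
    t = np.arange(1200)
    y = np.column_stack([np.sin(0.05 * t), np.cos(0.05 * t)])
    z = y[:, :1].copy()
    y_shuf = y[rng.permutation(len(y))]
    _, zpre = preprocess_behavior(y_shuf, z, quick_config(epochs=40))
    assert abs(metric_cc(zpre[10:], z[10:])) < 0.25


def test_preprocessor_warns_on_degenerate_channel():
    rng = np.random.default_rng(4)
    y = rng.standard_normal((400, 3))
    z = np.column_stack([y[:, 0], np.full(400, 2.5)])
    with pytest.warns(UserWarning, match="zero variance"):
        _, zpre = preprocess_behavior(y, z, quick_config(epochs=10))
    assert np.allclose(zpre[:, 1], 2.5)


# -- stages and variants -------------------------------------------------------

@pytest.fixture(scope="module")
def sinus_fold(sinus_dataset):
    sinus_dataset.assign_folds(2)
    return sinus_dataset.split_fold(1)


def test_stage1_decodes_realizable_noiseless_system():
    """z equal to a 1-D latent state is decoded nearly perfectly."""
    from braid.simulation import TrueSimModel

    m = TrueSimModel(A_fw=np.array([[0.8]]), K_fw=np.array([[1.0]]),
                     Cy=np.array([[1.0], [0.5]]), Q=np.array([[0.01]]),
                     R=1e-12 * np.eye(2), eps_std=np.zeros(1),
                     input_pole=0.9, input_std=np.ones(1), nonlinearity="none",
                     cz_params={"Hz": np.array([[1.0]])})
    ds = simulate(m, T=2500, seed=5)
    model = fit_braid(ds, n1=1, config=quick_config(epochs=120))
    zp, _ = model.predict(ds.y, ds.u, horizon=1)
    assert metric_cc(zp[5:], ds.z[5:]) > 0.95


def test_stage1_weights_frozen_by_stage2(sinus_fold):
    train, _ = sinus_fold
    cfg = quick_config(epochs=25)
    model = fit_braid(train, n1=2, n2=2, config=cfg)
    cfg2 = quick_config(epochs=25)
    solo = fit_braid(train, n1=2, n2=0, config=cfg2)
    for name in ("A", "K", "Afw", "Kfw", "Cz", "Cy"):
        for k, v in model.sections[1].maps[name].params.items():
            assert np.array_equal(v, solo.sections[1].maps[name].params[k]), name
    assert 2 in model.sections and 2 not in solo.sections


def test_stage2_improves_neural_prediction_on_neural_only_subspace():
    """A latent subspace invisible to z is only captured by stage 2."""
    from braid import generate_random_system

    m = generate_random_system(4, 10, 2, 2, nonlinearity="none", seed=21,
                               n_z_latent_dims=2, input_share=0.5,
                               cy_dim_gains=[1, 1, 2, 2])
    ds = simulate(m, T=5000, seed=22)
    ds.assign_folds(2)
    train, test = ds.split_fold(1)
    cfg = quick_config(epochs=120)
    m1 = fit_braid(train, n1=2, config=cfg)
    m12 = fit_braid(train, n1=2, n2=2, config=quick_config(epochs=120))
    _, y1 = m1.predict(test.y, test.u, horizon=1)
    _, y12 = m12.predict(test.y, test.u, horizon=1)
    cc1 = metric_cc(y1[2:], test.y[2:])
    cc12 = metric_cc(y12[2:], test.y[2:])
    assert cc12 > cc1 + 0.05


def test_stage3_requires_input():
    with pytest.raises(ValueError, match="n_u"):
        fit_stage3(None, {1: np.zeros((10, 1))}, 2, quick_config(),
                   np.random.default_rng(0), n_y=3)


def test_fit_is_deterministic_given_seed(sinus_fold):
    train, test = sinus_fold
    cc = []
    for _ in range(2):
        model = fit_braid(train, n1=4, config=quick_config(epochs=15, seed=9))
        zp, _ = model.predict(test.y, test.u, horizon=1)
        cc.append(metric_cc(zp[1:], test.z[1:]))
    assert cc[0] == cc[1]


def test_no_input_variant_ignores_input(sinus_fold):
    train, test = sinus_fold
    cfg = quick_config(epochs=15, variant="no_input_ablation")
    model = fit_braid(train, n1=4, config=cfg)
    zp, _ = model.predict(test.y, test.u, horizon=1)
    zp2, _ = model.predict(test.y, np.zeros_like(test.u), horizon=1)
    assert np.allclose(zp, zp2)


def test_braid_variant_requires_input(sinus_fold):
    train, _ = sinus_fold
    ds = type(train)(y=train.y, z=train.z, u=np.zeros((train.T, 0)))
    with pytest.raises(ValueError, match="measured input"):
        fit_braid(ds, n1=2, config=quick_config(epochs=5))


def test_ubraid_learns_states_without_behavior_supervision(sinus_fold):
    train, test = sinus_fold
    cfg = quick_config(epochs=60, variant="u_braid")
    model = fit_braid(train, n1=4, config=cfg)
    zp, yp = model.predict(test.y, test.u, horizon=1)
    # neural prediction must be decent; decoder was fitted post hoc
    assert metric_cc(yp[1:], test.y[1:]) > 0.5
    assert metric_cc(zp[1:], test.z[1:]) > 0.1


# -- automatic nonlinearity selection -----------------------------------------

def test_autoselect_picks_better_of_two_candidates(sinus_fold):
    train, _ = sinus_fold
    cfg = quick_config(epochs=40)
    cands = [dict(LINEAR_ASSIGN), dict(NONLIN_CZ_ASSIGN)]
    best, model, scores = auto_select_nonlinearity(train, n1=4, config=cfg,
                                                   candidates=cands)
    assert len(scores) == 2
    assert dict(max(scores, key=scores.get)) == best
    assert best["Cz"] == "nonlinear"
    assert model.sections[1].specs["Cz"].mode == "nonlinear"


def test_autoselect_tie_break_prefers_fewer_nonlinear_maps():
    from braid.training import auto_select_nonlinearity as asn  # noqa: F401
    # exercise the ranking directly: equal scores -> fewer nonlinear maps win
    key_simple = tuple(sorted(dict(NONLIN_CZ_ASSIGN).items()))
    key_complex = tuple(sorted({"A": "nonlinear", "K": "nonlinear",
                                "Cy": "nonlinear", "Cz": "nonlinear"}.items()))
    scores = {key_simple: 0.7, key_complex: 0.7}

    def _rank(key):
        n_nonlin = sum(1 for _, mode in key if mode == "nonlinear")
        return (-scores[key], n_nonlin, key)

    assert min(scores, key=_rank) == key_simple
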