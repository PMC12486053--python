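"""Multi-stage learning of the model from neural-behavioral-input data.

The loss is a weighted sum of m-step-ahead mean-squared prediction errors
over a set of horizons (all weights default to 1).  Horizons greater than 1
route state predictions through the generative-form recursion, which is what
forces the intrinsic dynamics (``Afw``/``Kfw``) to be learned.

Stages (each an independent optimization, earlier stages frozen):

* preprocessing (optional) — a causal regressor predicts behavior from
  neural activity alone; its output replaces behavior as the stage-1a/2b
  target so that stage-1 states are guaranteed to be encoded in the
  recorded neural activity;
* stage 1a — section-1 recursions + behavior decoder minimise the behavior
  loss; 1b — freeze states, fit the section-1 neural read-out;
* stage 2a — section-2 recursions + neural read-out minimise the neural
  loss on the residual left by stage 1; 2b — freeze, fit the section-2
  behavior read-out on the behavior residual;
* stage 3 (optional, post hoc) — an input-only section absorbs any behavior
  residual that is predictable from the measured input (behavior-specific
  dynamics not encoded in neural activity).

Special cases: ``linear_braid`` forces every map linear; ``u_braid`` drops
stage 1 (states learned from the neural loss only, behavior decoder fitted
post hoc on frozen states); ``no_input_ablation`` removes the measured
input everywhere.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np

from .model import BRAIDModel, ModelSection, SignalScaler, TransformSpec
from .nn import MLP, Adam

__all__ = [
    "TrainingConfig", "TrainingError", "loss_mstep", "preprocess_behavior",
    "fit_stage1", "fit_stage2", "fit_stage3", "fit_braid",
    "auto_select_nonlinearity", "NONLIN_GRID",
]

VARIANTS = ("braid", "linear_braid", "u_braid", "no_input_ablation")


class TrainingError(RuntimeError):
    """Raised when an optimization produces non-finite losses."""


@dataclass
class TrainingConfig:
    horizons: tuple = (1, 2, 3, 4, 5)
    weights_z: tuple = None           # per-horizon; None -> all ones
    weights_y: tuple = None
    learning_rate: float = 3e-3
    epochs: int = 500
    decoder_epochs: int = 300
    batch_length: int = 128
    batch_segments: int = 8
    seed: int = 0
    val_frac: float = 0.15
    patience: int = 20
    lr_drops: int = 2            # plateau-triggered learning-rate reductions
    lr_drop_factor: float = 0.3
    hidden_units: int = 64
    hidden_layers: int = 1
    activation: str = "tanh"
    variant: str = "braid"
    preprocess: bool = False
    preprocessor_dim: int = None      # default: n1
    # linear/nonlinear assignment for {A, K, Cy, Cz}; Afw/Kfw inherit A/K
    nonlinearity: dict = field(default_factory=lambda: {
        "A": "linear", "K": "linear", "Cy": "linear", "Cz": "linear"})
    decoder_uses_input: bool = False  # optional (x, u) decoder inputs

    def __post_init__(self):
        hs = tuple(self.horizons)
        if len(set(hs)) != len(hs) or any(m < 1 for m in hs):
            raise ValueError("horizons must be distinct and >= 1")
        self.horizons = tuple(sorted(hs))
        if self.variant not in VARIANTS:
            raise ValueError(f"unknown variant {self.variant!r}")
        if self.variant == "linear_braid":
            self.nonlinearity = {k: "linear" for k in ("A", "K", "Cy", "Cz")}

    def specs(self) -> dict:
        """Six TransformSpecs from the 4-way linear/nonlinear assignment."""
        kw = dict(hidden_layers=self.hidden_layers,
                  hidden_units=self.hidden_units, activation=self.activation)
        nl = self.nonlinearity
        return {name: TransformSpec(name, mode=nl[{"Afw": "A", "Kfw": "K"}.get(name, name)], **kw)
                for name in ("A", "Afw", "K", "Kfw", "Cy", "Cz")}


def loss_mstep(predictions, targets, horizons, weights=None) -> float:
    """Weighted sum of m-step-ahead MSEs.

    ``predictions[i]`` holds the m_i-step predictions, aligned so the
    prediction at index k is compared with ``targets[k + m_i]``; it must
    therefore have ``len(targets) - m_i`` rows.
    """
    horizons = list(horizons)
    if len(predictions) != len(horizons):
        raise ValueError("one prediction series per horizon is required")
    targets = np.asarray(targets, dtype=float)
    if weights is None:
        weights = np.ones(len(horizons))
    total = 0.0
    for pred, m, w in zip(predictions, horizons, weights):
        pred = np.asarray(pred, dtype=float)
        if pred.shape[0] != targets.shape[0] - m:
            raise ValueError(
                f"{m}-step predictions must have {targets.shape[0] - m} rows, "
                f"got {pred.shape[0]}")
        total += w * float(np.mean((targets[m:] - pred) ** 2))
    return total


# ---------------------------------------------------------------------------
# Recurrent-section trainer (truncated backpropagation through time)
# ---------------------------------------------------------------------------

def _segments(T: int, length: int, hop: int):
    starts = list(range(0, max(T - length, 0) + 1, hop))
    if not starts:
        starts = [0]
        length = T
    return starts, length


def _forward_section(sec, obs, u, horizons, want_cache):
    """Forward pass over a batch of segments.

    obs: (B, L, d_obs); u: (B, L, n_u) or None.
    Returns per-horizon state tensors P[m] of shape (B, L, n) where
    ``P[m][:, k] = x_{k|k-m}`` (valid for k >= m) and, optionally, caches.
    """
    A, K = sec.maps["A"], sec.maps["K"]
    Afw, Kfw = sec.maps["Afw"], sec.maps["Kfw"]
    B, L = obs.shape[:2]
    n = sec.state_dim
    X = np.zeros((B, L, n))
    cA, cK = [], []
    x = np.zeros((B, n))
    for k in range(L - 1):
        if want_cache:
            a, ca = A.forward_cache(x)
            kk, ck = K.forward_cache(obs[:, k])
            cA.append(ca)
            cK.append(ck)
        else:
            a, kk = A.forward(x), K.forward(obs[:, k])
        x = a + kk
        X[:, k + 1] = x
    P = {1: X}
    cAfw, cKfw = {}, {}
    mmax = max(horizons)
    for m in range(2, mmax + 1):
        Pm = np.zeros((B, L, n))
        src = P[m - 1][:, m - 1:L - 1]
        if want_cache:
            a, ca = Afw.forward_cache(src)
            cAfw[m] = ca
        else:
            a = Afw.forward(src)
        if Kfw is not None and u is not None:
            uin = u[:, m - 1:L - 1]
            if want_cache:
                b, cb = Kfw.forward_cache(uin)
                cKfw[m] = cb
            else:
                b = Kfw.forward(uin)
            a = a + b
        Pm[:, m:] = a
        P[m] = Pm
    caches = {"A": cA, "K": cK, "Afw": cAfw, "Kfw": cKfw} if want_cache else None
    return P, caches


def _loss_and_grads(sec, decoder, obs, u, targets, horizons, weights):
    """Loss + parameter gradients for one batch of segments.

    ``targets`` maps horizon -> (B, L, d) array (target at its own index k).
    Accumulates grads into the maps; returns the scalar loss.
    """
    B, L = obs.shape[:2]
    P, caches = _forward_section(sec, obs, u, horizons, want_cache=True)
    GP = {m: np.zeros_like(P[m]) for m in P}
    loss = 0.0
    for m, w in zip(horizons, weights):
        if L <= m:
            continue
        pred, cD = decoder.forward_cache(P[m][:, m:])
        err = pred - targets[m][:, m:]
        count = err.size
        loss += w * float(np.sum(err ** 2)) / count
        g = decoder.backward(cD, (2.0 * w / count) * err)
        GP[m][:, m:] += g
    if not np.isfinite(loss):
        raise TrainingError("non-finite training loss (diverging optimization)")
    # back through the generative rollout chains
    Afw, Kfw = sec.maps["Afw"], sec.maps["Kfw"]
    for m in range(max(P), 1, -1):
        g = GP[m][:, m:]
        if not np.any(g):
            continue
        gin = Afw.backward(caches["Afw"][m], g)
        GP[m - 1][:, m - 1:L - 1] += gin
        if Kfw is not None and u is not None:
            Kfw.backward(caches["Kfw"][m], g)
    # back through the predictor recursion
    A, K = sec.maps["A"], sec.maps["K"]
    GX = GP[1]
    for k in range(L - 2, -1, -1):
        g = GX[:, k + 1]
        if not np.any(g):
            continue
        GX[:, k] += A.backward(caches["A"][k], g)
        K.backward(caches["K"][k], g)
    return loss


def _eval_loss(sec, decoder, obs, u, targets, horizons, weights):
    P, _ = _forward_section(sec, obs[None], None if u is None else u[None],
                            horizons, want_cache=False)
    loss = 0.0
    for m, w in zip(horizons, weights):
        pred = decoder.forward(P[m][0, m:])
        loss += w * float(np.mean((pred - targets[m][m:]) ** 2))
    return loss


def train_recurrent_section(sec: ModelSection, decoder: MLP, obs: np.ndarray,
                            u, targets: dict, config: TrainingConfig,
                            rng: np.random.Generator, log: list = None):
    """Jointly train a section's recursions/encoders and one decoder.

    ``targets`` maps each horizon to a (T, d) series in normalised units.
    Training uses overlapping truncated segments with zero initial states;
    early stopping monitors the loss on a held-out tail of the training
    series and restores the best parameters.
    """
    horizons = list(config.horizons)
    weights = list(config.weights_z or np.ones(len(horizons)))
    T = obs.shape[0]
    n_val = max(int(config.val_frac * T), max(horizons) + 2)
    tr = slice(0, T - n_val)
    va = slice(T - n_val, T)
    L = min(config.batch_length, (T - n_val))
    starts, L = _segments(T - n_val, L, max(L // 2, 1))

    def _batchify(idx):
        o = np.stack([obs[s:s + L] for s in idx])
        uu = None if u is None else np.stack([u[s:s + L] for s in idx])
        tt = {m: np.stack([targets[m][s:s + L] for s in idx]) for m in horizons}
        return o, uu, tt

    maps = [sec.maps[k] for k in ("A", "Afw", "K", "Kfw") if sec.maps[k] is not None]
    maps.append(decoder)
    opt = Adam(maps, lr=config.learning_rate)
    val_targets = {m: targets[m][va] for m in horizons}
    best = (np.inf, opt.state_snapshot())
    since_best, lr_drops = 0, 0
    order = np.arange(len(starts))
    for epoch in range(config.epochs):
        rng.shuffle(order)
        ep_loss = 0.0
        for i in range(0, len(order), config.batch_segments):
            idx = [starts[j] for j in order[i:i + config.batch_segments]]
            o, uu, tt = _batchify(idx)
            opt.zero_grad()
            ep_loss += _loss_and_grads(sec, decoder, o, uu, tt, horizons, weights)
            opt.step()
        vl = _eval_loss(sec, decoder, obs[va], None if u is None else u[va],
                        val_targets, horizons, weights)
        if log is not None:
            log.append({"epoch": epoch, "train_loss": ep_loss, "val_loss": vl})
        if not np.isfinite(vl):
            raise TrainingError(f"non-finite validation loss at epoch {epoch}")
        if vl < best[0] - 1e-7:
            best = (vl, opt.state_snapshot())
            since_best = 0
        else:
            since_best += 1
            if since_best >= config.patience:
                # plateau: restore the best weights, anneal, and continue
                opt.restore(best[1])
                lr_drops += 1
                if lr_drops > config.lr_drops:
                    break
                opt.lr *= config.lr_drop_factor
                since_best = 0
    opt.restore(best[1])
    _ = tr
    return sec, decoder


# ---------------------------------------------------------------------------
# Decoder-only fits on frozen states
# ---------------------------------------------------------------------------

def _stacked_horizon_states(sec: ModelSection, obs, u, targets, horizons):
    X = sec.filter(obs)
    feats, tgts = [], []
    for m in horizons:
        Pm = sec.rollout_states(X, u, m)
        feats.append(Pm[m:])
        tgts.append(targets[m:])
    return np.vstack(feats), np.vstack(tgts)


def fit_decoder(decoder: MLP, states: np.ndarray, targets: np.ndarray,
                config: TrainingConfig, rng: np.random.Generator):
    """Fit a read-out map on frozen states (exact LS when linear)."""
    if decoder.hidden_layers == 0:
        Xa = np.hstack([states, np.ones((states.shape[0], 1))])
        beta, *_ = np.linalg.lstsq(Xa, targets, rcond=None)
        decoder.layers[0].W[:] = beta[:-1]
        decoder.layers[0].b[:] = beta[-1]
        return decoder
    opt = Adam([decoder], lr=config.learning_rate)
    N = states.shape[0]
    bs = 512
    idx = np.arange(N)
    best = (np.inf, opt.state_snapshot())
    since, drops = 0, 0
    for epoch in range(config.decoder_epochs):
        rng.shuffle(idx)
        for i in range(0, N, bs):
            sel = idx[i:i + bs]
            opt.zero_grad()
            pred, c = decoder.forward_cache(states[sel])
            err = pred - targets[sel]
            decoder.backward(c, 2.0 * err / err.size)
            opt.step()
        loss = float(np.mean((decoder.forward(states) - targets) ** 2))
        if not np.isfinite(loss):
            raise TrainingError("non-finite decoder loss")
        if loss < best[0] - 1e-9:
            best = (loss, opt.state_snapshot())
            since = 0
        else:
            since += 1
            if since >= config.patience:
                opt.restore(best[1])
                drops += 1
                if drops > config.lr_drops:
                    break
                opt.lr *= config.lr_drop_factor
                since = 0
    opt.restore(best[1])
    return decoder


# ---------------------------------------------------------------------------
# Behavior preprocessor (causal y -> z regressor)
# ---------------------------------------------------------------------------

class FilterRegressor:
    """Causal recurrent regressor from neural activity to behavior.

    State update ``x_{k+1} = A(x_k) + K(y_k)`` with read-out
    ``z_hat_k = D([x_k, y_k])``: the current sample of y enters as a direct
    feedthrough so memoryless y-to-z maps are representable, while the
    output at time k remains a function of ``y_{1..k}`` only.
    """

    def __init__(self, n_y: int, n_z: int, state_dim: int,
                 config: TrainingConfig, rng: np.random.Generator):
        self.state_dim = state_dim
        self.A = MLP(state_dim, state_dim, rng, hidden_layers=0, out_scale=0.3)
        self.K = MLP(n_y, state_dim, rng, hidden_layers=0)
        self.D = MLP(state_dim + n_y, n_z, rng,
                     hidden_layers=config.hidden_layers,
                     hidden_units=config.hidden_units,
                     activation=config.activation)

    def states(self, y):
        T = y.shape[0]
        X = np.zeros((T, self.state_dim))
        x = np.zeros(self.state_dim)
        for k in range(T - 1):
            x = self.A.forward(x) + self.K.forward(y[k])
            X[k + 1] = x
        return X

    def predict_scaled(self, y):
        X = self.states(y)
        return self.D.forward(np.concatenate([X, y], axis=-1))

    def fit(self, y, z, config: TrainingConfig, rng: np.random.Generator):
        T = y.shape[0]
        n_val = max(int(config.val_frac * T), 4)
        L = min(config.batch_length, T - n_val)
        starts, L = _segments(T - n_val, L, max(L // 2, 1))
        opt = Adam([self.A, self.K, self.D], lr=config.learning_rate)
        best = (np.inf, opt.state_snapshot())
        since, drops = 0, 0
        order = np.arange(len(starts))
        yv, zv = y[T - n_val:], z[T - n_val:]
        for epoch in range(config.epochs):
            rng.shuffle(order)
            for i in range(0, len(order), config.batch_segments):
                idx = [starts[j] for j in order[i:i + config.batch_segments]]
                yb = np.stack([y[s:s + L] for s in idx])
                zb = np.stack([z[s:s + L] for s in idx])
                opt.zero_grad()
                self._step(yb, zb)
                opt.step()
            vl = float(np.mean((self.predict_scaled(yv) - zv) ** 2))
            if not np.isfinite(vl):
                raise TrainingError(f"non-finite preprocessor loss at epoch {epoch}")
            if vl < best[0] - 1e-7:
                best = (vl, opt.state_snapshot())
                since = 0
            else:
                since += 1
                if since >= config.patience:
                    opt.restore(best[1])
                    drops += 1
                    if drops > config.lr_drops:
                        break
                    opt.lr *= config.lr_drop_factor
                    since = 0
        opt.restore(best[1])
        return self

    def _step(self, yb, zb):
        B, L = yb.shape[:2]
        n = self.state_dim
        X = np.zeros((B, L, n))
        cA, cK = [], []
        x = np.zeros((B, n))
        for k in range(L - 1):
            a, ca = self.A.forward_cache(x)
            kk, ck = self.K.forward_cache(yb[:, k])
            cA.append(ca)
            cK.append(ck)
            x = a + kk
            X[:, k + 1] = x
        dec_in = np.concatenate([X, yb], axis=-1)
        pred, cD = self.D.forward_cache(dec_in)
        err = pred - zb
        g = self.D.backward(cD, 2.0 * err / err.size)
        GX = g[..., :n]
        for k in range(L - 2, -1, -1):
            gk = GX[:, k + 1]
            if not np.any(gk):
                continue
            GX[:, k] += self.A.backward(cA[k], gk)
            self.K.backward(cK[k], gk)


def preprocess_behavior(y: np.ndarray, z: np.ndarray, config: TrainingConfig,
                        state_dim: int = None):
    """Fit the behavior preprocessor and return (regressor, z_hat_pre).

    ``z_hat_pre`` is the neurally-predicted behavior in original units, a
    causal function of y alone; downstream stages use it in place of z as
    the stage-1a/2b target.  Zero-variance behavior channels are passed
    through as their mean with a warning.
    """
    z = np.asarray(z, dtype=float)
    zero_var = z.std(axis=0) < 1e-12
    if np.any(zero_var):
        warnings.warn(f"behavior channels {np.where(zero_var)[0].tolist()} have "
                      "zero variance; passed through as their mean")
    sy, sz = SignalScaler.fit(y), SignalScaler.fit(z)
    rng = np.random.default_rng(config.seed + 101)
    dim = state_dim or config.preprocessor_dim or max(2, y.shape[1] // 4)
    reg = FilterRegressor(y.shape[1], z.shape[1], dim, config, rng)
    reg.fit(sy.transform(y), sz.transform(z), config, rng)
    zs = reg.predict_scaled(sy.transform(y))
    zs[:, zero_var] = 0.0
    reg.scalers = {"y": sy, "z": sz}
    return reg, sz.inverse(zs)


# ---------------------------------------------------------------------------
# Stages
# ---------------------------------------------------------------------------

def _input_signals(config, section_id):
    if section_id == 3:
        return ("u",)
    sig = ["y"]
    if config.variant != "no_input_ablation":
        sig.append("u")
    if section_id == 2:
        sig.append("x1")
    return tuple(sig)


def fit_stage1(ys, us, z_target, n1: int, config: TrainingConfig,
               rng: np.random.Generator, y_for_cy=None, log=None):
    """Stage 1a (recursions + Cz on the behavior loss) and 1b (Cy fit).

    All series are in normalised units; ``z_target`` is the behavior (or
    the neurally-predicted behavior when preprocessing is on).
    """
    specs = config.specs()
    n_u = 0 if us is None else us.shape[1]
    sec = ModelSection(1, n1, ys.shape[1], z_target.shape[1], n_u,
                       _input_signals(config, 1), specs, rng)
    obs = sec.gather_inputs(y=ys, u=us)
    targets = {m: z_target for m in config.horizons}
    train_recurrent_section(sec, sec.maps["Cz"], obs, us, targets, config, rng,
                            log=log)
    if y_for_cy is not None:
        feats, tgts = _stacked_horizon_states(sec, obs, us, y_for_cy,
                                              config.horizons)
        fit_decoder(sec.maps["Cy"], feats, tgts, config, rng)
    return sec


def _horizon_predictions(sec, obs, u, horizons, which):
    """Per-horizon decoded predictions (dict m -> (T, d), valid from row m)."""
    X = sec.filter(obs)
    out = {}
    for m in horizons:
        Pm = sec.rollout_states(X, u, m)
        out[m] = sec.decode(Pm, which)
    return out


def fit_stage2(ys, us, z_target, sec1: ModelSection, n2: int,
               config: TrainingConfig, rng: np.random.Generator, log=None):
    """Stage 2a/2b: residual neural dynamics, then their behavior read-out.

    Section 2's encoder additionally receives the (frozen) section-1 states.
    """
    specs = config.specs()
    n_u = 0 if us is None else us.shape[1]
    obs1 = sec1.gather_inputs(y=ys, u=us)
    X1 = sec1.filter(obs1)
    yhat1 = _horizon_predictions(sec1, obs1, us, config.horizons, "Cy")
    zhat1 = _horizon_predictions(sec1, obs1, us, config.horizons, "Cz")

    sec2 = ModelSection(2, n2, ys.shape[1], z_target.shape[1], n_u,
                        _input_signals(config, 2), specs, rng,
                        x1_dim=sec1.state_dim)
    obs2 = sec2.gather_inputs(y=ys, u=us, x1=X1)
    ry = {m: ys - yhat1[m] for m in config.horizons}
    train_recurrent_section(sec2, sec2.maps["Cy"], obs2, us, ry, config, rng,
                            log=log)
    rz = {m: z_target - zhat1[m] for m in config.horizons}
    feats, tgts = [], []
    X2 = sec2.filter(obs2)
    for m in config.horizons:
        Pm = sec2.rollout_states(X2, us, m)
        feats.append(Pm[m:])
        tgts.append(rz[m][m:])
    fit_decoder(sec2.maps["Cz"], np.vstack(feats), np.vstack(tgts), config, rng)
    return sec2


def fit_stage3(us, z_residuals: dict, n3: int, config: TrainingConfig,
               rng: np.random.Generator, n_y: int, log=None):
    """Post-hoc stage: input-driven behavior-specific dynamics.

    ``z_residuals`` maps horizon -> behavior residual series left by the
    earlier stages.  The section reads the measured input only.
    """
    if us is None or us.shape[1] == 0:
        raise ValueError("stage 3 requires a measured input (n_u >= 1)")
    specs = config.specs()
    n_z = next(iter(z_residuals.values())).shape[1]
    sec3 = ModelSection(3, n3, n_y, n_z, us.shape[1], ("u",), specs, rng)
    train_recurrent_section(sec3, sec3.maps["Cz"], us, us, z_residuals,
                            config, rng, log=log)
    return sec3


def _fit_unsupervised(ys, us, zs, n_x: int, config, rng, log=None):
    """U-BRAID: states learned from the neural loss only; Cz fitted post hoc."""
    specs = config.specs()
    n_u = 0 if us is None else us.shape[1]
    sec = ModelSection(1, n_x, ys.shape[1], zs.shape[1], n_u,
                       _input_signals(config, 1), specs, rng)
    obs = sec.gather_inputs(y=ys, u=us)
    targets = {m: ys for m in config.horizons}
    train_recurrent_section(sec, sec.maps["Cy"], obs, us, targets, config, rng,
                            log=log)
    feats, tgts = _stacked_horizon_states(sec, obs, us, zs, config.horizons)
    fit_decoder(sec.maps["Cz"], feats, tgts, config, rng)
    return sec


def fit_braid(dataset, n1: int, n2: int = 0, n3: int = 0,
              config: TrainingConfig = None) -> BRAIDModel:
    """Fit the full model on a training dataset (arrays or TimeSeriesDataset).

    Returns a :class:`BRAIDModel` whose ``meta['log']`` holds per-stage
    epoch/loss traces.
    """
    config = config or TrainingConfig()
    y, z = np.asarray(dataset.y, float), np.asarray(dataset.z, float)
    u = None if dataset.u is None else np.asarray(dataset.u, float)
    if config.variant == "no_input_ablation":
        u = None
    if config.variant != "no_input_ablation" and (u is None or u.shape[1] == 0):
        raise ValueError(f"variant {config.variant!r} requires a measured input; "
                         "use variant='no_input_ablation' for input-free fits")
    rng = np.random.default_rng(config.seed)
    scalers = {"y": SignalScaler.fit(y), "z": SignalScaler.fit(z)}
    ys, zs = scalers["y"].transform(y), scalers["z"].transform(z)
    us = None
    if u is not None:
        scalers["u"] = SignalScaler.fit(u)
        us = scalers["u"].transform(u)

    log = {"stage1": [], "stage2": [], "stage3": [], "preprocess": []}
    sections = {}
    preprocessor = None

    if config.variant == "u_braid":
        sections[1] = _fit_unsupervised(ys, us, zs, n1 + n2, config, rng,
                                        log=log["stage1"])
        return BRAIDModel(sections=sections, scalers=scalers,
                          variant=config.variant, meta={"log": log})

    z_target = zs
    if config.preprocess:
        preprocessor = FilterRegressor(ys.shape[1], zs.shape[1],
                                       config.preprocessor_dim or n1,
                                       config, rng)
        preprocessor.fit(ys, zs, config, rng)
        z_target = preprocessor.predict_scaled(ys)

    sections[1] = fit_stage1(ys, us, z_target, n1, config, rng, y_for_cy=ys,
                             log=log["stage1"])
    if n2 > 0:
        sections[2] = fit_stage2(ys, us, z_target, sections[1], n2, config,
                                 rng, log=log["stage2"])
    if n3 > 0:
        obs1 = sections[1].gather_inputs(y=ys, u=us)
        zhat = _horizon_predictions(sections[1], obs1, us, config.horizons, "Cz")
        if 2 in sections:
            X1 = sections[1].filter(obs1)
            obs2 = sections[2].gather_inputs(y=ys, u=us, x1=X1)
            zhat2 = _horizon_predictions(sections[2], obs2, us,
                                         config.horizons, "Cz")
            zhat = {m: zhat[m] + zhat2[m] for m in zhat}
        rz = {m: zs - zhat[m] for m in config.horizons}
        sections[3] = fit_stage3(us, rz, n3, config, rng, n_y=ys.shape[1],
                                 log=log["stage3"])
    return BRAIDModel(sections=sections, scalers=scalers,
                      preprocessor=preprocessor, variant=config.variant,
                      meta={"log": log})


# ---------------------------------------------------------------------------
# Automatic nonlinearity selection
# ---------------------------------------------------------------------------

NONLIN_GRID = [
    {"A": a, "K": k, "Cy": cy, "Cz": cz}
    for a in ("linear", "nonlinear") for k in ("linear", "nonlinear")
    for cy in ("linear", "nonlinear") for cz in ("linear", "nonlinear")
]


def auto_select_nonlinearity(dataset, n1: int, config: TrainingConfig,
                             candidates=None):
    """Grid over linear/nonlinear assignments of {A, K, Cy, Cz}.

    Each candidate is fitted (stage 1) on the training data and scored by
    its training-set behavior decoding CC; the best assignment wins, with
    ties broken toward fewer nonlinear maps.  Returns
    (assignment, fitted_model, scores).
    """
    from .evaluation import metric_cc

    candidates = candidates if candidates is not None else NONLIN_GRID
    scores, models = {}, {}
    for assign in candidates:
        key = tuple(sorted(assign.items()))
        cand_cfg = replace(config, nonlinearity=dict(assign))
        try:
            model = fit_braid(dataset, n1=n1, config=cand_cfg)
            zhat, _ = model.predict(dataset.y, dataset.u, horizon=1)
            scores[key] = metric_cc(zhat[1:], dataset.z[1:])
            models[key] = model
        except TrainingError as err:  # pragma: no cover - rare
            warnings.warn(f"candidate {assign} failed to train: {err}")
    if not scores:
        raise TrainingError("all nonlinearity candidates failed to train")

    def _rank(key):
        n_nonlin = sum(1 for _, mode in key if mode == "nonlinear")
        return (-scores[key], n_nonlin, key)

    best = min(scores, key=_rank)
    return dict(best), models[best], scores
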