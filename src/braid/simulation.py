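"""Synthetic neural-behavioral-input data with ground-truth oracles.

The generator produces stable linear latent dynamics driven by a
temporally-structured stochastic input (first-order autoregressive process)
plus state noise, observed through configurable nonlinear maps:

* ``sinusoidal_cz`` — behavior read-out ``f(nu) = a*sin(nu) + b*nu`` applied
  elementwise to linear latent projections;
* ``spiral_manifold`` — behavior lies on a spiral: two latent coordinates set
  radius and angle of a planar curve;
* ``trig_manifold`` — each behavior channel is a fixed mix of sin/cos of
  affine latent projections;
* ``trig_input_encoder`` — the input drives the state update through an
  elementwise sine of an affine map (observations stay linear);
* ``none`` — fully linear system.

Neural observations are always linear in the latent state, so the exact
ideal predictor of the latent state is the steady-state Kalman filter of the
linear core; ideal observation predictions apply the true (possibly
nonlinear) read-out maps to the Kalman states.

Noise scales default to a moderately hard regime in which the ideal
1-step-ahead behavior decoding tops out well below 1 and a best linear
read-out loses roughly half of the attainable correlation; see
``docs/methods.md`` for the calibration rationale.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.linalg import solve_discrete_are, solve_discrete_lyapunov

__all__ = [
    "TrueSimModel", "TimeSeriesDataset", "generate_random_system",
    "apply_sinusoidal_cz", "simulate", "add_behavior_specific",
    "ideal_prediction_oracle", "state_covariance", "analytic_ideal_behavior_cc",
]

NONLINEARITIES = ("sinusoidal_cz", "spiral_manifold", "trig_manifold",
                  "trig_input_encoder", "none")

_DIVERGENCE_LIMIT = 1e8


def apply_sinusoidal_cz(nu, a: float, b: float):
    """Elementwise sinusoidal behavior read-out ``a*sin(nu) + b*nu``."""
    nu = np.asarray(nu, dtype=float)
    return a * np.sin(nu) + b * nu


@dataclass
class TimeSeriesDataset:
    """Aligned neural (y), behavior (z) and input (u) time series."""

    y: np.ndarray
    z: np.ndarray
    u: np.ndarray
    dt: float = 1.0
    fold_ids: np.ndarray = None
    seed: int = 0
    latents: np.ndarray = None      # simulation ground truth, never seen by models
    extras: dict = field(default_factory=dict)

    def __post_init__(self):
        T = self.y.shape[0]
        if self.z.shape[0] != T or self.u.shape[0] != T:
            raise ValueError("y, z, u must share the same length")

    @property
    def T(self):
        return self.y.shape[0]

    def assign_folds(self, n_folds: int):
        """Partition samples into contiguous blocks covering the series."""
        if n_folds < 2:
            raise ValueError("n_folds must be >= 2")
        edges = np.linspace(0, self.T, n_folds + 1).astype(int)
        fold_ids = np.zeros(self.T, dtype=int)
        for i in range(n_folds):
            fold_ids[edges[i]:edges[i + 1]] = i
        self.fold_ids = fold_ids
        return self

    def split_fold(self, fold: int):
        """(train, test) datasets for one held-out contiguous fold."""
        if self.fold_ids is None:
            raise ValueError("call assign_folds first")
        test = self.fold_ids == fold
        train = ~test

        def _take(mask):
            return TimeSeriesDataset(
                y=self.y[mask], z=self.z[mask], u=self.u[mask], dt=self.dt,
                seed=self.seed,
                latents=self.latents[mask] if self.latents is not None else None,
                extras={k: v[mask] for k, v in self.extras.items()
                        if isinstance(v, np.ndarray) and v.shape[:1] == (self.T,)},
            )
        return _take(train), _take(test)


@dataclass
class TrueSimModel:
    """Ground-truth simulation system with retrievable intrinsic dynamics."""

    A_fw: np.ndarray                 # (n_x, n_x), spectral radius < 1
    K_fw: np.ndarray                 # (n_x, n_u)
    Cy: np.ndarray                   # (n_y, n_x) linear neural read-out
    Q: np.ndarray                    # state-noise covariance
    R: np.ndarray                    # neural observation-noise covariance
    eps_std: np.ndarray              # behavior observation-noise std per channel
    input_pole: float                # AR(1) pole of the input process
    input_std: np.ndarray            # stationary std per input channel
    nonlinearity: str = "none"
    cz_params: dict = field(default_factory=dict)
    input_encoder: dict = None       # {"S": matrix} for trig_input_encoder
    behavior_specific: dict = None   # optional non-encoded behavior sub-system
    seed: int = 0

    def __post_init__(self):
        rho = np.max(np.abs(np.linalg.eigvals(self.A_fw)))
        if rho >= 1.0:
            raise ValueError(f"unstable true system: spectral radius {rho:.3f} >= 1")
        for name, C in (("Q", self.Q), ("R", self.R)):
            if not np.allclose(C, C.T):
                raise ValueError(f"{name} must be symmetric")
            if np.min(np.linalg.eigvalsh(C)) < -1e-10:
                raise ValueError(f"{name} must be positive semidefinite")

    # -- dimensions -----------------------------------------------------------
    @property
    def n_x(self):
        return self.A_fw.shape[0]

    @property
    def n_y(self):
        return self.Cy.shape[0]

    @property
    def n_z(self):
        return len(self.eps_std)

    @property
    def n_u(self):
        return self.K_fw.shape[1]

    @property
    def eigenvalues(self):
        eigs = np.linalg.eigvals(self.A_fw)
        order = np.lexsort((np.angle(eigs), -np.abs(eigs)))
        return eigs[order]

    # -- observation maps -----------------------------------------------------
    def encode_input(self, u):
        """Signal actually entering the state update (identity or sine)."""
        if self.nonlinearity == "trig_input_encoder":
            return np.sin(u @ self.input_encoder["S"].T)
        return u

    def C_y_map(self, x):
        return x @ self.Cy.T

    def C_z_map(self, x):
        p = self.cz_params
        nu = x @ p["Hz"].T
        if self.nonlinearity == "sinusoidal_cz":
            return apply_sinusoidal_cz(nu, p["a"], p["b"])
        if self.nonlinearity == "spiral_manifold":
            r = p["r0"] + p["r1"] * nu[..., 0]
            th = p["th1"] * nu[..., 1]
            z = np.stack([r * np.cos(th), r * np.sin(th)], axis=-1)
            if nu.shape[-1] > 2:
                z = np.concatenate([z, nu[..., 2:]], axis=-1)
            return z
        if self.nonlinearity == "trig_manifold":
            return p["amp_s"] * np.sin(nu) + p["amp_c"] * np.cos(p["Hz2_mix"] * nu)
        # linear read-out ("none" and "trig_input_encoder")
        return nu


def state_covariance(model: TrueSimModel) -> np.ndarray:
    """Stationary latent covariance of the linear core.

    Solves the discrete Lyapunov equation for the system augmented with its
    AR(1) input process; valid when the input enters linearly.
    """
    if model.nonlinearity == "trig_input_encoder":
        raise ValueError("analytic covariance needs a linear input encoder")
    n_x, n_u = model.n_x, model.n_u
    A_aug = np.zeros((n_x + n_u, n_x + n_u))
    A_aug[:n_x, :n_x] = model.A_fw
    A_aug[:n_x, n_x:] = model.K_fw
    A_aug[n_x:, n_x:] = model.input_pole * np.eye(n_u)
    Q_aug = np.zeros_like(A_aug)
    Q_aug[:n_x, :n_x] = model.Q
    innov_var = model.input_std ** 2 * (1.0 - model.input_pole ** 2)
    Q_aug[n_x:, n_x:] = np.diag(innov_var)
    S = solve_discrete_lyapunov(A_aug, Q_aug)
    return S[:n_x, :n_x]


def _stable_matrix(rng, n, radius):
    A = rng.standard_normal((n, n))
    return A * (radius / np.max(np.abs(np.linalg.eigvals(A))))


def _sinusoid_var(a, b, s2):
    """Var of a*sin(X) + b*X for X ~ N(0, s2)."""
    return (a * a * (1 - np.exp(-2 * s2)) / 2
            + 2 * a * b * s2 * np.exp(-s2 / 2) + b * b * s2)


def analytic_ideal_behavior_cc(model: TrueSimModel) -> float:
    """Closed-form ideal 1-step behavior decoding CC (sinusoidal read-out).

    Uses the steady-state Kalman prediction-error covariance and Gaussian
    moments of the sinusoidal map; channel-averaged.  Valid for linear input
    encoding and the ``sinusoidal_cz`` (or linear, a=0/b=1) read-out.
    """
    Sx = state_covariance(model)
    P = solve_discrete_are(model.A_fw.T, model.Cy.T, model.Q, model.R)
    Hz = model.cz_params["Hz"]
    a = model.cz_params.get("a", 0.0)
    b = model.cz_params.get("b", 1.0)
    ccs = []
    for j in range(Hz.shape[0]):
        vx = float(Hz[j] @ Sx @ Hz[j])
        err = float(Hz[j] @ P @ Hz[j])
        vy = max(vx - err, 1e-12)
        c = vy  # Cov(nu, nu_hat) equals Var(nu_hat) for the optimal predictor
        cov_ss = 0.5 * np.exp(-(vx + vy) / 2) * (np.exp(c) - np.exp(-c))
        cov = (a * a * cov_ss + a * b * c * np.exp(-vx / 2)
               + a * b * c * np.exp(-vy / 2) + b * b * c)
        eps2 = float(model.eps_std[j] ** 2)
        ccs.append(cov / np.sqrt(_sinusoid_var(a, b, vy)
                                 * (_sinusoid_var(a, b, vx) + eps2)))
    return float(np.mean(ccs))


def generate_random_system(n_x: int, n_y: int, n_z: int, n_u: int,
                           nonlinearity: str = "none", seed: int = 0,
                           snr_y: float = 6.0, snr_z: float = 40.0,
                           input_pole: float = 0.9,
                           input_share: float = 0.93,
                           sigma_nu: float = None,
                           cz_a: float = 1.0, cz_b: float = 0.04,
                           spectral_radius: float = None,
                           n_z_latent_dims: int = None,
                           cy_dim_gains=None,
                           ideal_cc_band: tuple = (0.84, 0.93),
                           behavior_specific: bool = False,
                           bs_private_input: bool = True,
                           n3: int = 2, bs_gain: float = 1.0) -> TrueSimModel:
    """Draw a random stable input-driven system.

    The intrinsic transition matrix is a random matrix rescaled to a spectral
    radius drawn uniformly in [0.5, 0.95]; the input matrix is scaled so that
    the input process accounts for a fraction ``input_share`` of the
    stationary latent variance; neural read-out rows are scaled to unit
    signal variance with additive noise at ``snr_y``; behavior projections
    are scaled to standard deviation ``sigma_nu`` before the nonlinearity,
    with additive noise at ``snr_z``.  ``n_z_latent_dims`` restricts the
    behavior read-out to the first so-many latent coordinates (used to
    construct systems with a known behaviorally relevant subspace), and
    ``cy_dim_gains`` weights each latent coordinate's contribution to the
    neural read-out (before row normalisation), so behavior-irrelevant
    latents can be made to dominate neural variance.

    For the sinusoidal read-out, the system's difficulty is kept in a fixed
    regime: the ideal (Kalman-oracle) behavior decoding CC is computed in
    closed form and, if it falls outside ``ideal_cc_band``, the input share
    is adjusted by bisection to the nearest band edge.  This trims the tails
    of the across-system difficulty distribution so that batch averages are
    stable, while preserving spread inside the band; pass
    ``ideal_cc_band=None`` to disable.

    With ``behavior_specific=True`` a separate stable sub-system produces an
    input-driven behavior component that never enters the neural read-out;
    by default (``bs_private_input``) it is driven exclusively by the last
    input channel, which in turn is excluded from the neural latent drive,
    so the component is genuinely not encoded in y (requires n_u >= 2).
    """
    for name, v in (("n_x", n_x), ("n_y", n_y), ("n_z", n_z), ("n_u", n_u)):
        if v < 1:
            raise ValueError(f"{name} must be >= 1")
    if nonlinearity not in NONLINEARITIES:
        raise ValueError(f"unknown nonlinearity {nonlinearity!r}")
    if nonlinearity == "spiral_manifold" and n_z < 2:
        raise ValueError("spiral manifold requires n_z >= 2")
    rng = np.random.default_rng(seed)

    rho = spectral_radius if spectral_radius is not None else rng.uniform(0.5, 0.95)
    A = _stable_matrix(rng, n_x, rho)
    Q = np.eye(n_x)

    bs_private = behavior_specific and bs_private_input
    if bs_private and n_u < 2:
        raise ValueError("a private behavior-specific input channel requires n_u >= 2")
    K_raw = rng.standard_normal((n_x, n_u))
    if bs_private:
        K_raw[:, -1] = 0.0
    input_encoder = None
    if nonlinearity == "trig_input_encoder":
        S = rng.standard_normal((n_u, n_u))
        S *= 1.5 / np.sqrt(np.mean(np.sum(S ** 2, axis=1)))
        input_encoder = {"S": S}

    # Scale the input matrix so the input drives `input_share` of latent variance.
    cov_noise = solve_discrete_lyapunov(A, Q)
    drive_var = (1.0 if nonlinearity != "trig_input_encoder"
                 else float(np.mean(0.5 * (1 - np.exp(-2 * 2.25)))))  # Var[sin], arg std 1.5
    tmp = TrueSimModel(A_fw=A, K_fw=K_raw, Cy=np.zeros((1, n_x)), Q=0.0 * Q,
                       R=np.eye(1), eps_std=np.zeros(1), input_pole=input_pole,
                       input_std=np.full(n_u, np.sqrt(drive_var)),
                       nonlinearity="none", cz_params={"Hz": np.zeros((1, n_x))})
    cov_input = state_covariance(tmp)
    scale = np.sqrt(input_share / (1 - input_share)
                    * np.trace(cov_noise) / max(np.trace(cov_input), 1e-12))
    K_fw = K_raw * scale

    model = TrueSimModel(
        A_fw=A, K_fw=K_fw, Cy=np.zeros((n_y, n_x)), Q=Q, R=np.eye(n_y),
        eps_std=np.ones(n_z), input_pole=input_pole, input_std=np.ones(n_u),
        nonlinearity=nonlinearity, cz_params={"Hz": np.zeros((n_z, n_x))},
        input_encoder=input_encoder, seed=seed)

    # Stationary latent covariance (analytic; empirical for the sine encoder).
    if nonlinearity == "trig_input_encoder":
        probe = simulate(model, T=4000, seed=int(rng.integers(2 ** 31)),
                         _skip_obs=True)
        Sx = np.cov(probe.latents.T)
    else:
        Sx = state_covariance(model)

    Cy_raw = rng.standard_normal((n_y, n_x))
    if cy_dim_gains is not None:
        Cy_raw = Cy_raw * np.asarray(cy_dim_gains, float)[None, :]
    sig = np.einsum("ij,jk,ik->i", Cy_raw, Sx, Cy_raw)
    model.Cy = Cy_raw / np.sqrt(sig)[:, None]
    model.R = np.eye(n_y) / snr_y

    d_beh = n_z_latent_dims if n_z_latent_dims is not None else n_x
    if sigma_nu is None:
        sigma_nu = {"sinusoidal_cz": 2.0, "spiral_manifold": 1.0,
                    "trig_manifold": 1.5}.get(nonlinearity, 1.0)
    n_proj = max(n_z, 2) if nonlinearity == "spiral_manifold" else n_z
    Hz_raw = np.zeros((n_proj, n_x))
    Hz_raw[:, :d_beh] = rng.standard_normal((n_proj, d_beh))
    sig = np.einsum("ij,jk,ik->i", Hz_raw, Sx, Hz_raw)
    Hz = Hz_raw * (sigma_nu / np.sqrt(sig))[:, None]
    cz = {"Hz": Hz}
    if nonlinearity == "sinusoidal_cz":
        cz.update(a=cz_a, b=cz_b)
    elif nonlinearity == "spiral_manifold":
        cz.update(r0=1.0, r1=0.5, th1=1.5)
    elif nonlinearity == "trig_manifold":
        cz.update(amp_s=1.0, amp_c=1.0, Hz2_mix=rng.uniform(0.5, 1.5, size=n_proj))
    model.cz_params = cz

    # Behavior noise scaled to the signal variance of each channel
    # (exact Gaussian moments for the sinusoidal read-out, probe otherwise).
    if nonlinearity == "sinusoidal_cz":
        z_sig = np.full(n_z, _sinusoid_var(cz_a, cz_b, sigma_nu ** 2))
    else:
        probe_x = rng.multivariate_normal(np.zeros(n_x), Sx, size=4000)
        z_sig = model.C_z_map(probe_x).var(axis=0)
    model.eps_std = np.sqrt(z_sig / snr_z)

    if nonlinearity == "sinusoidal_cz" and ideal_cc_band is not None:
        def _rebuild(share):
            k_scale = np.sqrt(share / (1 - share)
                              * np.trace(cov_noise) / max(np.trace(cov_input), 1e-12))
            model.K_fw = K_raw * k_scale
            S = state_covariance(model)
            sig_y = np.einsum("ij,jk,ik->i", Cy_raw, S, Cy_raw)
            model.Cy = Cy_raw / np.sqrt(sig_y)[:, None]
            sig_z = np.einsum("ij,jk,ik->i", Hz_raw, S, Hz_raw)
            model.cz_params["Hz"] = Hz_raw * (sigma_nu / np.sqrt(sig_z))[:, None]
            return analytic_ideal_behavior_cc(model)

        cc0 = analytic_ideal_behavior_cc(model)
        lo_cc, hi_cc = ideal_cc_band
        target = lo_cc if cc0 < lo_cc else (hi_cc if cc0 > hi_cc else None)
        if target is not None:
            lo_s, hi_s = 0.2, 0.995
            for _ in range(40):
                mid = 0.5 * (lo_s + hi_s)
                if _rebuild(mid) < target:
                    lo_s = mid
                else:
                    hi_s = mid
            _rebuild(0.5 * (lo_s + hi_s))

    if behavior_specific:
        A3 = _stable_matrix(rng, n3, 0.8)
        K3 = rng.standard_normal((n3, n_u))
        if bs_private:
            K3[:, :-1] = 0.0
        C3 = rng.standard_normal((n_z, n3))
        # Scale the added component to bs_gain * the encoded-behavior std.
        tmp3 = TrueSimModel(A_fw=A3, K_fw=K3, Cy=np.zeros((1, n3)), Q=0.0 * np.eye(n3),
                            R=np.eye(1), eps_std=np.zeros(1), input_pole=input_pole,
                            input_std=np.ones(n_u), nonlinearity="none",
                            cz_params={"Hz": np.zeros((1, n3))})
        S3 = state_covariance(tmp3)
        c_var = np.einsum("ij,jk,ik->i", C3, S3, C3)
        C3 *= (bs_gain * np.sqrt(z_sig / np.maximum(c_var, 1e-12)))[:, None]
        model.behavior_specific = {"A3": A3, "K3": K3, "C3": C3, "gain": bs_gain}

    return model


def _generate_input(model: TrueSimModel, T: int, rng: np.random.Generator):
    """AR(1) input process with the model's pole and stationary std."""
    pole, std = model.input_pole, model.input_std
    innov = rng.standard_normal((T, model.n_u)) * (std * np.sqrt(1 - pole ** 2))
    u = np.zeros((T, model.n_u))
    u[0] = rng.standard_normal(model.n_u) * std
    for k in range(1, T):
        u[k] = pole * u[k - 1] + innov[k]
    return u


def simulate(model: TrueSimModel, T: int, seed: int = 0,
             _skip_obs: bool = False) -> TimeSeriesDataset:
    """Roll the generative model forward and return an aligned dataset.

    A burn-in prefix of ``max(100, 10 * n_x)`` samples is discarded so the
    returned series are approximately stationary.  Identical (model, T,
    seed) gives a bit-identical dataset.
    """
    if T < 2 * model.n_x:
        raise ValueError(f"T={T} too short; need at least {2 * model.n_x}")
    rng = np.random.default_rng(seed)
    burn = max(100, 10 * model.n_x)
    total = T + burn

    def _sample_noise(cov, n_rows):
        if np.allclose(cov, 0.0):
            return np.zeros((n_rows, cov.shape[0]))
        L = np.linalg.cholesky(cov + 1e-12 * np.eye(cov.shape[0]))
        return rng.standard_normal((n_rows, cov.shape[0])) @ L.T

    u = _generate_input(model, total, rng)
    u_enc = model.encode_input(u)
    w = _sample_noise(model.Q, total)

    x = np.zeros((total, model.n_x))
    for k in range(total - 1):
        x[k + 1] = model.A_fw @ x[k] + model.K_fw @ u_enc[k] + w[k]
        if np.max(np.abs(x[k + 1])) > _DIVERGENCE_LIMIT:
            raise FloatingPointError(f"state divergence at time step {k + 1}")

    x, u = x[burn:], u[burn:]
    if _skip_obs:
        return TimeSeriesDataset(y=np.zeros((T, 1)), z=np.zeros((T, 1)),
                                 u=u, seed=seed, latents=x)
    v = _sample_noise(model.R, T)
    eps = rng.standard_normal((T, model.n_z)) * model.eps_std
    y = model.C_y_map(x) + v
    z = model.C_z_map(x) + eps
    return TimeSeriesDataset(y=y, z=z, u=u, seed=seed, latents=x)


def add_behavior_specific(dataset: TimeSeriesDataset, model: TrueSimModel,
                          seed: int = 0) -> TimeSeriesDataset:
    """Add an input-driven behavior component not encoded in neural activity.

    A separate latent sub-system driven by the same measured input (but by
    none of the neural latent states) adds to z; its ground-truth trace is
    retained in ``extras['behavior_specific_trace']`` for testing.
    """
    if model.behavior_specific is None:
        raise ValueError("model.behavior_specific is not configured")
    bs = model.behavior_specific
    rng = np.random.default_rng(seed)
    T = dataset.T
    n3 = bs["A3"].shape[0]
    x3 = np.zeros((T, n3))
    for k in range(T - 1):
        x3[k + 1] = bs["A3"] @ x3[k] + bs["K3"] @ dataset.u[k]
    trace = x3 @ bs["C3"].T
    _ = rng  # reserved for stochastic sub-systems; current sub-system is noise-free
    if bs["gain"] == 0.0:
        trace = np.zeros_like(trace)
    return TimeSeriesDataset(
        y=dataset.y, z=dataset.z + trace, u=dataset.u, dt=dataset.dt,
        seed=dataset.seed, latents=dataset.latents,
        extras={**dataset.extras, "behavior_specific_trace": trace,
                "z_base": dataset.z.copy(), "x3": x3})


def _kalman_gain(model: TrueSimModel):
    A, C, Q, R = model.A_fw, model.Cy, model.Q, model.R
    P = solve_discrete_are(A.T, C.T, Q, R)
    return A @ P @ C.T @ np.linalg.inv(C @ P @ C.T + R)


def ideal_prediction_oracle(model: TrueSimModel, dataset: TimeSeriesDataset,
                            horizon: int = 1):
    """Ideal m-step predictions from the true generating model.

    Runs the steady-state Kalman filter of the linear core (predictor form),
    rolls the state ``horizon - 1`` steps with the true generative recursion
    and applies the true observation maps.  Returns (z_hat, y_hat) aligned
    with the dataset; entries before ``horizon`` use shorter histories.
    """
    if horizon < 1:
        raise ValueError("horizon must be >= 1")
    Kg = _kalman_gain(model)
    A, C = model.A_fw, model.Cy
    u_enc = model.encode_input(dataset.u)
    T = dataset.T
    xh = np.zeros((T, model.n_x))
    x = np.zeros(model.n_x)
    for k in range(T - 1):
        x = A @ x + model.K_fw @ u_enc[k] + Kg @ (dataset.y[k] - C @ x)
        xh[k + 1] = x
    P = xh
    for _ in range(horizon - 1):
        nxt = P[:-1] @ A.T + u_enc[:-1] @ model.K_fw.T
        P = np.vstack([P[:1], nxt])
    return model.C_z_map(P), model.C_y_map(P)
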