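"""Model structure: per-section predictor/generative recursions.

A model section holds six transformations:

* ``A``/``K`` — the *predictor-form* recursion, updating the inferred latent
  state as each new observation arrives::

      x_{k+1|k} = A(x_{k|k-1}) + K(o_k)

  where ``o_k`` concatenates the section's observed input signals at time k
  (section 1: ``[y_k, u_k]``; section 2: ``[y_k, u_k, x^{(1)}_{k|k-1}]``;
  section 3: ``[u_k]``).

* ``Afw``/``Kfw`` — the *generative-form* recursion, propagating a state
  forward under the intrinsic dynamics using only future inputs::

      x_{k+m|k} = Afw(x_{k+m-1|k}) + Kfw(u_{k+m-1})

* ``Cy``/``Cz`` — read-outs to neural activity and behavior.

Each map is linear (affine) or a small MLP per its :class:`TransformSpec`.
Predictions of held-out behavior and neural data use only past neural
activity and inputs — behavior itself is never an inference-time input.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .nn import MLP

__all__ = [
    "TransformSpec", "ModelSection", "BRAIDModel", "SignalScaler",
    "predictor_step", "forecast_rollout", "linearize_Afw",
]

MAP_NAMES = ("A", "Afw", "K", "Kfw", "Cy", "Cz")


@dataclass
class TransformSpec:
    """Configuration of one of the six transformations of a section."""

    name: str
    mode: str = "linear"          # "linear" | "nonlinear"
    hidden_layers: int = 1
    hidden_units: int = 32
    activation: str = "relu"

    def __post_init__(self):
        if self.name not in MAP_NAMES:
            raise ValueError(f"unknown transform name {self.name!r}")
        if self.mode not in ("linear", "nonlinear"):
            raise ValueError(f"mode must be 'linear' or 'nonlinear', got {self.mode!r}")

    def build(self, d_in: int, d_out: int, rng: np.random.Generator,
              out_scale: float = 1.0) -> MLP:
        if self.mode == "linear":
            return MLP(d_in, d_out, rng, hidden_layers=0, out_scale=out_scale)
        return MLP(d_in, d_out, rng, hidden_layers=self.hidden_layers,
                   hidden_units=self.hidden_units, activation=self.activation,
                   out_scale=out_scale)

    def to_dict(self):
        return {"name": self.name, "mode": self.mode,
                "hidden_layers": self.hidden_layers,
                "hidden_units": self.hidden_units,
                "activation": self.activation}

    @classmethod
    def from_dict(cls, d):
        return cls(**d)


def _check_finite(name, arr):
    if not np.all(np.isfinite(arr)):
        raise ValueError(f"non-finite values in {name}")


class ModelSection:
    """One latent-state section with its six transformations.

    ``input_signals`` declares which observed signals the predictor encoder
    ``K`` consumes, as a tuple of names from {"y", "u", "x1"}.  Section 3
    reads "u" only — its dynamics are behavior-specific and input-driven,
    and never see neural activity.
    """

    def __init__(self, section_id: int, state_dim: int, n_y: int, n_z: int,
                 n_u: int, input_signals: tuple, specs: dict,
                 rng: np.random.Generator, x1_dim: int = 0):
        if state_dim < 1:
            raise ValueError("state_dim must be >= 1")
        self.section_id = section_id
        self.state_dim = state_dim
        self.n_y, self.n_z, self.n_u = n_y, n_z, n_u
        self.input_signals = tuple(input_signals)
        if section_id == 3 and "y" in self.input_signals:
            raise ValueError("section 3 must not read neural activity")
        self.x1_dim = x1_dim
        self.specs = {name: specs.get(name, TransformSpec(name)) for name in MAP_NAMES}

        d_obs = self.encoder_input_dim()
        n = state_dim
        # Recursion maps start with damped output so the initial filter is stable.
        self.maps = {
            "A": self.specs["A"].build(n, n, rng, out_scale=0.3),
            "Afw": self.specs["Afw"].build(n, n, rng, out_scale=0.3),
            "K": self.specs["K"].build(d_obs, n, rng),
            "Kfw": self.specs["Kfw"].build(n_u, n, rng) if n_u > 0 else None,
            "Cy": self.specs["Cy"].build(n, n_y, rng),
            "Cz": self.specs["Cz"].build(n, n_z, rng),
        }

    def encoder_input_dim(self) -> int:
        dims = {"y": self.n_y, "u": self.n_u, "x1": self.x1_dim}
        return sum(dims[s] for s in self.input_signals)

    def gather_inputs(self, y=None, u=None, x1=None):
        """Concatenate the declared observed signals along the last axis."""
        parts = []
        for s in self.input_signals:
            arr = {"y": y, "u": u, "x1": x1}[s]
            if arr is None:
                raise ValueError(f"section {self.section_id} requires signal {s!r}")
            parts.append(arr)
        return np.concatenate(parts, axis=-1)

    # -- forward computations -------------------------------------------------
    def filter(self, obs: np.ndarray) -> np.ndarray:
        """Run the predictor recursion over a sequence.

        Parameters
        ----------
        obs : (T, d_obs) array of the section's concatenated inputs.

        Returns
        -------
        states : (T, state_dim) array with ``states[k] = x_{k|k-1}``, the
            state available for predicting the observation at time k;
            ``states[0]`` is the zero initial state.
        """
        _check_finite("filter inputs", obs)
        T = obs.shape[0]
        states = np.zeros((T, self.state_dim))
        x = np.zeros(self.state_dim)
        A, K = self.maps["A"], self.maps["K"]
        for k in range(T - 1):
            x = A.forward(x) + K.forward(obs[k])
            states[k + 1] = x
        return states

    def rollout_states(self, states: np.ndarray, u, horizon: int):
        """m-step-ahead states aligned with the target time index.

        Given 1-step states (``states[k] = x_{k|k-1}``), returns an array
        ``P`` with ``P[k] = x_{k|k-m}`` for ``k >= m`` (earlier rows are the
        best available shorter-horizon states, flagged by the returned
        validity index).  The generative recursion consumes future inputs
        ``u`` but never future neural data.
        """
        if horizon < 1:
            raise ValueError("horizon must be >= 1")
        P = states
        Afw, Kfw = self.maps["Afw"], self.maps["Kfw"]
        for _ in range(horizon - 1):
            nxt = Afw.forward(P[:-1])
            if Kfw is not None and u is not None:
                nxt = nxt + Kfw.forward(u[:-1])
            P = np.vstack([P[:1], nxt])
        return P

    def decode(self, states, which: str):
        return self.maps[which].forward(states)


def predictor_step(section: ModelSection, state: np.ndarray,
                   observed: np.ndarray) -> np.ndarray:
    """One predictor-form update: ``A(state) + K(observed)``."""
    state = np.asarray(state, dtype=float)
    observed = np.asarray(observed, dtype=float)
    if state.shape[-1] != section.state_dim:
        raise ValueError(f"state has {state.shape[-1]} entries, expected {section.state_dim}")
    if observed.shape[-1] != section.encoder_input_dim():
        raise ValueError(f"observed has {observed.shape[-1]} entries, "
                         f"expected {section.encoder_input_dim()}")
    return section.maps["A"].forward(state) + section.maps["K"].forward(observed)


def forecast_rollout(section: ModelSection, state_1step: np.ndarray,
                     future_u, m: int) -> np.ndarray:
    """Propagate a 1-step predicted state to ``m`` steps ahead.

    ``m = 1`` returns ``state_1step`` unchanged; otherwise applies the
    generative recursion ``x <- Afw(x) + Kfw(u)`` for ``m - 1`` steps,
    consuming the ``m - 1`` rows of ``future_u``.
    """
    if m < 1:
        raise ValueError("m must be >= 1")
    x = np.asarray(state_1step, dtype=float)
    if m == 1:
        return x
    Kfw = section.maps["Kfw"]
    if Kfw is not None:
        future_u = np.asarray(future_u, dtype=float)
        if future_u.ndim == 1:
            future_u = future_u[None, :]
        if future_u.shape[0] < m - 1:
            raise ValueError(f"need {m - 1} future input rows, got {future_u.shape[0]}")
    for j in range(m - 1):
        x = section.maps["Afw"].forward(x)
        if Kfw is not None:
            x = x + Kfw.forward(future_u[j])
    return x


def linearize_Afw(section: ModelSection):
    """Matrix and eigenvalues of the intrinsic-dynamics map.

    For a linear ``Afw`` this is its matrix; for a nonlinear one, the
    Jacobian at the origin of the (normalised) state space.  Eigenvalues are
    sorted by modulus descending, ties broken by angle.
    """
    J = section.maps["Afw"].jacobian(np.zeros(section.state_dim))
    eigs = np.linalg.eigvals(J)
    order = np.lexsort((np.angle(eigs), -np.abs(eigs)))
    return J, eigs[order]


@dataclass
class SignalScaler:
    """Per-channel affine normaliser fitted on training data."""

    mean: np.ndarray
    std: np.ndarray

    @classmethod
    def fit(cls, x: np.ndarray) -> "SignalScaler":
        mean = x.mean(axis=0)
        std = x.std(axis=0)
        std = np.where(std < 1e-12, 1.0, std)
        return cls(mean=mean, std=std)

    def transform(self, x):
        return (x - self.mean) / self.std

    def inverse(self, x):
        return x * self.std + self.mean


@dataclass
class BRAIDModel:
    """Fitted multi-section model.

    ``sections`` maps section id (1, 2, 3) to a :class:`ModelSection`.
    Neural-dynamics state dimension is ``n1 + n2``; the section-3 state is
    additional and behavior-only.  All internal computation happens in
    z-scored signal space; predictions are returned in original units.
    """

    sections: dict
    scalers: dict
    preprocessor: object = None
    variant: str = "braid"
    meta: dict = field(default_factory=dict)

    @property
    def n1(self):
        return self.sections[1].state_dim if 1 in self.sections else 0

    @property
    def n2(self):
        return self.sections[2].state_dim if 2 in self.sections else 0

    @property
    def n3(self):
        return self.sections[3].state_dim if 3 in self.sections else 0

    def _scaled(self, y, u):
        ys = self.scalers["y"].transform(y) if y is not None else None
        us = self.scalers["u"].transform(u) if (u is not None and "u" in self.scalers) else u
        if self.variant == "no_input_ablation":
            us = None
        return ys, us

    def filter_sequence(self, y: np.ndarray, u=None) -> dict:
        """Per-section 1-step-ahead state sequences ``x_{k|k-1}``.

        Causal: the state at index k depends only on observations up to
        k - 1.  Returns a dict keyed by section id.
        """
        ys, us = self._scaled(y, u)
        states = {}
        for sid in sorted(self.sections):
            sec = self.sections[sid]
            obs = sec.gather_inputs(y=ys, u=us, x1=states.get(1))
            states[sid] = sec.filter(obs)
        return states

    def _horizon_states(self, states, u, horizon):
        ys_unused, us = None, u
        if u is not None and "u" in self.scalers:
            us = self.scalers["u"].transform(u)
        if self.variant == "no_input_ablation":
            us = None
        return {sid: self.sections[sid].rollout_states(states[sid], us, horizon)
                for sid in states}

    def predict_observations(self, states: dict, u=None, horizon: int = 1):
        """Decode behavior and neural predictions from per-section states.

        ``z`` contributions are summed over all present sections; ``y``
        contributions over sections 1 and 2 (section 3 is behavior-only).
        Returns (z_hat, y_hat) in original units, with rows before
        ``horizon`` carrying shorter-horizon estimates.
        """
        if horizon < 1:
            raise ValueError("horizon must be >= 1")
        P = self._horizon_states(states, u, horizon)
        T = next(iter(P.values())).shape[0]
        zhat = np.zeros((T, self.scalers["z"].mean.shape[0]))
        yhat = np.zeros((T, self.scalers["y"].mean.shape[0]))
        for sid, sec in self.sections.items():
            zhat += sec.decode(P[sid], "Cz")
            if sid != 3:
                yhat += sec.decode(P[sid], "Cy")
        return self.scalers["z"].inverse(zhat), self.scalers["y"].inverse(yhat)

    def predict(self, y: np.ndarray, u=None, horizon: int = 1):
        """End-to-end held-out prediction: filter then decode at ``horizon``."""
        states = self.filter_sequence(y, u)
        return self.predict_observations(states, u=u, horizon=horizon)

    def intrinsic_eigenvalues(self, section_id: int = 1):
        _, eigs = linearize_Afw(self.sections[section_id])
        return eigs
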