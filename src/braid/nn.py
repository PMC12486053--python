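"""Minimal feed-forward building blocks with explicit reverse-mode gradients.

The maps used by the model family here are tiny (state dimensions of a few,
at most a few dozen hidden units), so each transformation is implemented as
an affine map or a small multi-layer perceptron with hand-written
forward/backward passes over numpy arrays.  All maps accept inputs of shape
``(..., d_in)`` and return ``(..., d_out)``; gradients of parameters are
accumulated into ``.grads`` so one backward sweep over a batch of sequence
segments produces the total gradient.
"""

from __future__ import annotations

import numpy as np

__all__ = ["Affine", "MLP", "Adam", "ACTIVATIONS"]


def _relu(x):
    return np.maximum(x, 0.0)


def _relu_grad(x, _y):
    return (x > 0.0).astype(x.dtype)


def _tanh(x):
    return np.tanh(x)


def _tanh_grad(_x, y):
    return 1.0 - y * y


ACTIVATIONS = {
    "relu": (_relu, _relu_grad),
    "tanh": (_tanh, _tanh_grad),
}


class Affine:
    """y = x @ W + b with Glorot-uniform initialisation."""

    def __init__(self, d_in: int, d_out: int, rng: np.random.Generator,
                 scale: float = 1.0):
        limit = scale * np.sqrt(6.0 / (d_in + d_out))
        self.W = rng.uniform(-limit, limit, size=(d_in, d_out))
        self.b = np.zeros(d_out)
        self.grads = {"W": np.zeros_like(self.W), "b": np.zeros_like(self.b)}
        self.d_in, self.d_out = d_in, d_out

    # -- parameter plumbing -------------------------------------------------
    @property
    def params(self):
        return {"W": self.W, "b": self.b}

    def zero_grad(self):
        self.grads["W"][:] = 0.0
        self.grads["b"][:] = 0.0

    # -- computation --------------------------------------------------------
    def forward(self, x):
        return x @ self.W + self.b

    def forward_cache(self, x):
        return x @ self.W + self.b, x

    def backward(self, cache, gy):
        x = cache
        xf = x.reshape(-1, self.d_in)
        gf = gy.reshape(-1, self.d_out)
        self.grads["W"] += xf.T @ gf
        self.grads["b"] += gf.sum(axis=0)
        return gy @ self.W.T

    def jacobian(self, _x):
        """Jacobian dy/dx (constant for an affine map)."""
        return self.W.T.copy()


class MLP:
    """MLP with ``hidden_layers`` hidden layers and a linear read-out.

    ``hidden_layers == 0`` degenerates to a plain affine map (kept as an
    MLP instance so specs with mode switching share one code path).
    """

    def __init__(self, d_in: int, d_out: int, rng: np.random.Generator,
                 hidden_layers: int = 1, hidden_units: int = 32,
                 activation: str = "relu", out_scale: float = 1.0):
        if activation not in ACTIVATIONS:
            raise ValueError(f"unknown activation {activation!r}")
        self.act_name = activation
        self.act, self.act_grad = ACTIVATIONS[activation]
        dims = [d_in] + [hidden_units] * hidden_layers + [d_out]
        self.layers = []
        for i in range(len(dims) - 1):
            scale = out_scale if i == len(dims) - 2 else 1.0
            self.layers.append(Affine(dims[i], dims[i + 1], rng, scale=scale))
        self.hidden_layers = hidden_layers
        self.d_in, self.d_out = d_in, d_out

    @property
    def params(self):
        out = {}
        for i, layer in enumerate(self.layers):
            for k, v in layer.params.items():
                out[f"l{i}.{k}"] = v
        return out

    @property
    def grads(self):
        out = {}
        for i, layer in enumerate(self.layers):
            for k, v in layer.grads.items():
                out[f"l{i}.{k}"] = v
        return out

    def zero_grad(self):
        for layer in self.layers:
            layer.zero_grad()

    def forward(self, x):
        h = x
        for i, layer in enumerate(self.layers):
            h = layer.forward(h)
            if i < len(self.layers) - 1:
                h = self.act(h)
        return h

    def forward_cache(self, x):
        caches = []
        h = x
        for i, layer in enumerate(self.layers):
            pre, c = layer.forward_cache(h)
            if i < len(self.layers) - 1:
                h = self.act(pre)
                caches.append((c, pre, h))
            else:
                h = pre
                caches.append((c, None, None))
        return h, caches

    def backward(self, caches, gy):
        g = gy
        for i in range(len(self.layers) - 1, -1, -1):
            c, pre, post = caches[i]
            if i < len(self.layers) - 1:
                g = g * self.act_grad(pre, post)
            g = self.layers[i].backward(c, g)
        return g

    def jacobian(self, x):
        """Jacobian dy/dx evaluated at a single point ``x`` (shape (d_in,))."""
        J = np.eye(self.d_in)
        h = np.asarray(x, dtype=float)
        for i, layer in enumerate(self.layers):
            pre = layer.forward(h)
            J = layer.W.T @ J
            if i < len(self.layers) - 1:
                post = self.act(pre)
                J = self.act_grad(pre, post)[:, None] * J
                h = post
            else:
                h = pre
        return J


class Adam:
    """Adam over the parameters of a collection of maps."""

    def __init__(self, maps, lr: float = 1e-3, beta1: float = 0.9,
                 beta2: float = 0.999, eps: float = 1e-8):
        self.maps = [m for m in maps if m is not None]
        self.lr, self.b1, self.b2, self.eps = lr, beta1, beta2, eps
        self.t = 0
        self.m = [{k: np.zeros_like(v) for k, v in mp.params.items()}
                  for mp in self.maps]
        self.v = [{k: np.zeros_like(v) for k, v in mp.params.items()}
                  for mp in self.maps]

    def zero_grad(self):
        for mp in self.maps:
            mp.zero_grad()

    def step(self):
        self.t += 1
        bc1 = 1.0 - self.b1 ** self.t
        bc2 = 1.0 - self.b2 ** self.t
        for mp, m, v in zip(self.maps, self.m, self.v):
            params, grads = mp.params, mp.grads
            for k in params:
                g = grads[k]
                m[k] = self.b1 * m[k] + (1 - self.b1) * g
                v[k] = self.b2 * v[k] + (1 - self.b2) * g * g
                params[k] -= self.lr * (m[k] / bc1) / (np.sqrt(v[k] / bc2) + self.eps)

    def state_snapshot(self):
        """Deep copy of current parameter values (for early-stopping restore)."""
        return [{k: v.copy() for k, v in mp.params.items()} for mp in self.maps]

    def restore(self, snapshot):
        for mp, snap in zip(self.maps, snapshot):
            for k, v in mp.params.items():
                v[:] = snap[k]
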