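"""Conditional invertible network (affine coupling flow) and LSTM summary net.

The flow ``f(theta; h)`` maps parameters to a standard-normal latent space,
conditioned on a fixed-size summary vector ``h`` produced by a recurrent
encoder from the (possibly variable-length) encoded data.  Each coupling
layer splits its input ``u = (u1, u2)`` and applies

    v1 = u1 * exp(s1(u2, h)) + t1(u2, h)
    v2 = u2 * exp(s2(v1, h)) + t2(v1, h)

with fully connected internal networks s1, t1, s2, t2 (ELU activations).
The map is bijective with an algebraic inverse, and its Jacobian
log-determinant is simply ``sum(s1) + sum(s2)``.  A fixed random permutation
between layers mixes dimensions.  Scale outputs are smoothly clamped to
(-alpha, alpha) before exponentiation to keep training stable.

Two execution paths exist: a differentiable one on the autodiff tape
(training) and a plain-numpy one (inverse direction / inference).  The
bijectivity tests exercise one against the other.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .autodiff import Tensor, concat, gather_cols
from .errors import ConfigurationError

__all__ = ["ArchConfig", "MLP", "CouplingLayer", "ConditionalFlow", "LSTMSummary", "init_networks"]


@dataclass(frozen=True)
class ArchConfig:
    """Architecture hyperparameters for flow and summary networks."""

    n_coupling_layers: int = 5
    st_hidden: tuple = (64, 64)  # hidden widths of the internal s/t networks
    lstm_hidden: int = 8  # summary size H (power of two close to data dim)
    clamp_alpha: float = 1.9  # soft bound on coupling log-scales


def _elu_np(x):
    return np.where(x > 0, x, np.expm1(x))


class MLP:
    """Fully connected net, ELU hidden activations, linear output.

    The output layer can be zero-initialized so that a fresh flow is the
    identity map (s = t = 0).
    """

    def __init__(self, d_in, hidden, d_out, rng, zero_init_last=True, name="mlp"):
        self.name = name
        self.weights: list[Tensor] = []
        self.biases: list[Tensor] = []
        dims = [d_in, *hidden, d_out]
        for i, (a, b) in enumerate(zip(dims[:-1], dims[1:])):
            last = i == len(dims) - 2
            if last and zero_init_last:
                w = np.zeros((a, b))
            else:
                w = rng.normal(0.0, np.sqrt(2.0 / a), size=(a, b))
            self.weights.append(Tensor(w, requires_grad=True))
            self.biases.append(Tensor(np.zeros(b), requires_grad=True))

    def forward(self, x: Tensor) -> Tensor:
        for i, (w, b) in enumerate(zip(self.weights, self.biases)):
            x = x @ w + b
            if i < len(self.weights) - 1:
                x = x.elu()
        return x

    def forward_np(self, x: np.ndarray) -> np.ndarray:
        for i, (w, b) in enumerate(zip(self.weights, self.biases)):
            x = x @ w.v + b.v
            if i < len(self.weights) - 1:
                x = _elu_np(x)
        return x

    def params(self) -> dict[str, Tensor]:
        out = {}
        for i, (w, b) in enumerate(zip(self.weights, self.biases)):
            out[f"{self.name}/W{i}"] = w
            out[f"{self.name}/b{i}"] = b
        return out


def _clamp_np(s, alpha):
    return (2.0 * alpha / np.pi) * np.arctan(s / alpha)


class CouplingLayer:
    """One conditional affine coupling block."""

    def __init__(self, n_theta, cond_dim, rng, hidden=(64, 64), clamp_alpha=1.9, name="cpl"):
        if n_theta < 2:
            raise ConfigurationError("coupling layers need at least 2 dimensions")
        self.d1 = int(np.ceil(n_theta / 2))
        self.d2 = n_theta - self.d1
        self.alpha = clamp_alpha
        self.s1 = MLP(self.d2 + cond_dim, hidden, self.d1, rng, name=f"{name}/s1")
        self.t1 = MLP(self.d2 + cond_dim, hidden, self.d1, rng, name=f"{name}/t1")
        self.s2 = MLP(self.d1 + cond_dim, hidden, self.d2, rng, name=f"{name}/s2")
        self.t2 = MLP(self.d1 + cond_dim, hidden, self.d2, rng, name=f"{name}/t2")

    def forward(self, u: Tensor, h: Tensor) -> tuple[Tensor, Tensor]:
        """Returns (v, per-sample logdet)."""
        u1, u2 = u.slice_cols(0, self.d1), u.slice_cols(self.d1, self.d1 + self.d2)
        in1 = concat([u2, h])
        s1 = self.s1.forward(in1).soft_clamp(self.alpha)
        v1 = u1 * s1.exp() + self.t1.forward(in1)
        in2 = concat([v1, h])
        s2 = self.s2.forward(in2).soft_clamp(self.alpha)
        v2 = u2 * s2.exp() + self.t2.forward(in2)
        return concat([v1, v2]), s1.sum(axis=1) + s2.sum(axis=1)

    def forward_np(self, u: np.ndarray, h: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        u1, u2 = u[:, : self.d1], u[:, self.d1 :]
        in1 = np.concatenate([u2, h], axis=1)
        s1 = _clamp_np(self.s1.forward_np(in1), self.alpha)
        v1 = u1 * np.exp(s1) + self.t1.forward_np(in1)
        in2 = np.concatenate([v1, h], axis=1)
        s2 = _clamp_np(self.s2.forward_np(in2), self.alpha)
        v2 = u2 * np.exp(s2) + self.t2.forward_np(in2)
        return np.concatenate([v1, v2], axis=1), s1.sum(axis=1) + s2.sum(axis=1)

    def inverse_np(self, v: np.ndarray, h: np.ndarray) -> np.ndarray:
        v1, v2 = v[:, : self.d1], v[:, self.d1 :]
        in2 = np.concatenate([v1, h], axis=1)
        s2 = _clamp_np(self.s2.forward_np(in2), self.alpha)
        u2 = (v2 - self.t2.forward_np(in2)) * np.exp(-s2)
        in1 = np.concatenate([u2, h], axis=1)
        s1 = _clamp_np(self.s1.forward_np(in1), self.alpha)
        u1 = (v1 - self.t1.forward_np(in1)) * np.exp(-s1)
        return np.concatenate([u1, u2], axis=1)

    def params(self) -> dict[str, Tensor]:
        out = {}
        for net in (self.s1, self.t1, self.s2, self.t2):
            out.update(net.params())
        return out


class ConditionalFlow:
    """Stack of coupling layers with fixed inter-layer permutations."""

    def __init__(self, n_theta, cond_dim, rng, arch: ArchConfig = ArchConfig()):
        self.n_theta = n_theta
        self.cond_dim = cond_dim
        self.arch = arch
        self.layers = [
            CouplingLayer(n_theta, cond_dim, rng, arch.st_hidden, arch.clamp_alpha, name=f"cpl{k}")
            for k in range(arch.n_coupling_layers)
        ]
        # fixed random permutation applied after every layer but the last
        self.perms = [rng.permutation(n_theta) for _ in range(arch.n_coupling_layers - 1)]

    def forward(self, theta: Tensor, h: Tensor) -> tuple[Tensor, Tensor]:
        """z = f(theta; h) with the total Jacobian log-determinant."""
        u, logdet = theta, None
        for k, layer in enumerate(self.layers):
            u, ld = layer.forward(u, h)
            logdet = ld if logdet is None else logdet + ld
            if k < len(self.perms):
                u = gather_cols(u, self.perms[k])
        return u, logdet

    def forward_np(self, theta: np.ndarray, h: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        u, logdet = np.atleast_2d(theta), 0.0
        h = np.atleast_2d(h)
        for k, layer in enumerate(self.layers):
            u, ld = layer.forward_np(u, h)
            logdet = logdet + ld
            if k < len(self.perms):
                u = u[:, self.perms[k]]
        return u, logdet

    def inverse_np(self, z: np.ndarray, h: np.ndarray) -> np.ndarray:
        """theta = f^{-1}(z; h), the exact algebraic inverse."""
        u = np.atleast_2d(z)
        h = np.atleast_2d(h)
        for k in range(len(self.layers) - 1, -1, -1):
            if k < len(self.perms):
                inv = np.argsort(self.perms[k])
                u = u[:, inv]
            u = self.layers[k].inverse_np(u, h)
        return u

    def log_density_np(self, theta: np.ndarray, h: np.ndarray) -> np.ndarray:
        """log pi(theta | h) via the change of variables to N(0, I)."""
        z, logdet = self.forward_np(theta, h)
        return -0.5 * np.sum(z**2, axis=1) - 0.5 * self.n_theta * np.log(2 * np.pi) + logdet

    def params(self) -> dict[str, Tensor]:
        out = {}
        for layer in self.layers:
            out.update(layer.params())
        return out


class LSTMSummary:
    """Recurrent encoder mapping an (M, T, D) sequence batch to (M, H).

    The final hidden state is the summary.  An empty sequence (all entries
    missing under the time-label encoding) summarizes to the zero vector.
    """

    def __init__(self, d_in, hidden, rng):
        self.d_in = d_in
        self.hidden = hidden
        s = 1.0 / np.sqrt(hidden)
        self.wx = Tensor(rng.uniform(-s, s, size=(d_in, 4 * hidden)), requires_grad=True)
        self.wh = Tensor(rng.uniform(-s, s, size=(hidden, 4 * hidden)), requires_grad=True)
        b = np.zeros(4 * hidden)
        b[hidden : 2 * hidden] = 1.0  # forget-gate bias
        self.b = Tensor(b, requires_grad=True)

    def _cell(self, gates, c_prev):
        hi = self.hidden
        i = gates.slice_cols(0, hi).sigmoid()
        f = gates.slice_cols(hi, 2 * hi).sigmoid()
        g = gates.slice_cols(2 * hi, 3 * hi).tanh()
        o = gates.slice_cols(3 * hi, 4 * hi).sigmoid()
        c = f * c_prev + i * g
        return o * c.tanh(), c

    def forward(self, x: np.ndarray) -> Tensor:
        x = np.asarray(x, dtype=float)
        if x.ndim != 3 or x.shape[2] != self.d_in:
            raise ConfigurationError(f"expected (M, T, {self.d_in}) input, got {x.shape}")
        m, t_len, _ = x.shape
        h = Tensor(np.zeros((m, self.hidden)))
        c = Tensor(np.zeros((m, self.hidden)))
        for t in range(t_len):
            gates = Tensor(x[:, t, :]) @ self.wx + h @ self.wh + self.b
            h, c = self._cell(gates, c)
        return h

    def forward_np(self, x: np.ndarray) -> np.ndarray:
        x = np.asarray(x, dtype=float)
        if x.ndim == 2:
            x = x[None, :, :]
        m, t_len, _ = x.shape
        hi = self.hidden
        h = np.zeros((m, hi))
        c = np.zeros((m, hi))
        for t in range(t_len):
            gates = x[:, t, :] @ self.wx.v + h @ self.wh.v + self.b.v
            i = 1.0 / (1.0 + np.exp(-gates[:, :hi]))
            f = 1.0 / (1.0 + np.exp(-gates[:, hi : 2 * hi]))
            g = np.tanh(gates[:, 2 * hi : 3 * hi])
            o = 1.0 / (1.0 + np.exp(-gates[:, 3 * hi :]))
            c = f * c + i * g
            h = o * np.tanh(c)
        return h

    def params(self) -> dict[str, Tensor]:
        return {"lstm/Wx": self.wx, "lstm/Wh": self.wh, "lstm/b": self.b}


def init_networks(
    n_theta: int, input_width: int, arch: ArchConfig = ArchConfig(), rng: np.random.Generator | None = None
) -> tuple[ConditionalFlow, LSTMSummary]:
    """Seeded construction of a matched (flow, summary) pair.

    ``input_width`` is the row width of the chosen data encoding; the summary
    size ``arch.lstm_hidden`` is the flow's conditioning dimension.  Final
    s/t layers start at zero, so the fresh flow is the identity (up to its
    permutations) with zero log-determinant.
    """
    if n_theta < 2:
        raise ConfigurationError("n_theta must be >= 2")
    if rng is None:
        rng = np.random.default_rng()
    flow = ConditionalFlow(n_theta, arch.lstm_hidden, rng, arch)
    summary = LSTMSummary(input_width, arch.lstm_hidden, rng)
    return flow, summary
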