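"""Fully connected coordinate network (x, y, t) -> (u, v, p).

Each hidden layer applies a weight matrix W, a bias b and a per-neuron
trainable gain g ("gamma vector"), followed by the activation:

    z_{k+1} = sigma( g_k * (z_k @ W_k + b_k) )

with a plain affine output layer.  The gain can be disabled
(``use_gamma=False``), in which case layers are ordinary affine maps.

Besides plain evaluation, :func:`forward_with_derivatives` propagates the
first derivatives with respect to the three inputs and the pure second
derivatives with respect to x and y through the layers as extra channels.
Every channel is built from taped :class:`~pivpressure.autodiff.Tensor`
operations, so reverse-mode differentiation of a loss that involves e.g.
``u_xx`` still reaches the parameters — exact derivatives, no finite
differencing anywhere.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .autodiff import Tensor, sigmoid, tanh

__all__ = ["NetworkConfig", "Network", "forward_values", "forward_with_derivatives"]


@dataclass
class NetworkConfig:
    """Architecture and initialization of the coordinate network.

    Defaults follow the full-scale setup (12 hidden layers of 120 sigmoid
    neurons); desk-scale presets shrink these for CPU runs.
    """

    n_hidden_layers: int = 12
    neurons_per_layer: int = 120
    activation: str = "sigmoid"  # "sigmoid" | "tanh"
    parameter_init_seed: int = 0
    use_gamma: bool = True
    # affine input normalization (x - center) / halfwidth, per input; fitted
    # from the training domain so sigmoid units start in their active range
    input_center: tuple = (0.0, 0.0, 0.0)
    input_halfwidth: tuple = (1.0, 1.0, 1.0)
    # optional random Fourier input embedding: the normalized inputs are
    # augmented with sin/cos(2 pi B x) pairs, B ~ N(0, scale^2), drawn once
    # from the init seed.  Lets a small network represent spatially localized
    # flow features (plain coordinate MLPs are biased toward low frequencies).
    fourier_features: int = 0
    fourier_scale: float = 2.0

    def __post_init__(self):
        if self.n_hidden_layers < 1 or self.neurons_per_layer < 1:
            raise ValueError("network needs at least one layer and one neuron")
        if self.activation not in ("sigmoid", "tanh"):
            raise ValueError(f"unknown activation {self.activation!r}")
        # tolerate list-valued input from serialized configs
        self.input_center = tuple(float(c) for c in self.input_center)
        self.input_halfwidth = tuple(float(h) for h in self.input_halfwidth)


_ACT = {"sigmoid": sigmoid, "tanh": tanh}


class Network:
    """Parameter container + forward passes. Pure function of (params, inputs)."""

    N_IN = 3   # x, y, t
    N_OUT = 3  # u, v, p

    def __init__(self, config: NetworkConfig):
        self.config = config
        rng = np.random.default_rng(config.parameter_init_seed)
        if config.fourier_features > 0:
            # fixed (non-trainable) embedding frequencies
            self.fourier_B = rng.normal(0.0, config.fourier_scale,
                                        (self.N_IN, config.fourier_features))
            n_in = self.N_IN + 2 * config.fourier_features
        else:
            self.fourier_B = None
            n_in = self.N_IN
        sizes = (
            [n_in]
            + [config.neurons_per_layer] * config.n_hidden_layers
            + [self.N_OUT]
        )
        self.params: list[Tensor] = []
        self._layers = []
        for k in range(len(sizes) - 1):
            fan_in, fan_out = sizes[k], sizes[k + 1]
            # Glorot-uniform weights; zero bias; unit gains
            limit = np.sqrt(6.0 / (fan_in + fan_out))
            W = Tensor(rng.uniform(-limit, limit, (fan_in, fan_out)), requires_grad=True)
            b = Tensor(np.zeros(fan_out), requires_grad=True)
            hidden = k < len(sizes) - 2
            if config.use_gamma and hidden:
                g = Tensor(np.ones(fan_out), requires_grad=True)
            else:
                g = None
            self._layers.append((W, b, g, hidden))
            self.params.extend(p for p in (W, b, g) if p is not None)

    # ----------------------------------------------------------- state access
    def get_state(self) -> list[np.ndarray]:
        return [p.value.copy() for p in self.params]

    def set_state(self, state: list[np.ndarray]) -> None:
        if len(state) != len(self.params):
            raise ValueError("state does not match network architecture")
        for p, v in zip(self.params, state):
            if p.value.shape != np.asarray(v).shape:
                raise ValueError("state does not match network architecture")
            p.value = np.asarray(v, dtype=np.float64).copy()

    def zero_grad(self) -> None:
        for p in self.params:
            p.grad = None


def _normalize(X: np.ndarray, cfg: NetworkConfig):
    c = np.asarray(cfg.input_center, dtype=np.float64)
    h = np.asarray(cfg.input_halfwidth, dtype=np.float64)
    return (X - c) / h, 1.0 / h


def _embed(Xn: np.ndarray, B: np.ndarray | None):
    """Fourier input embedding and its input-derivative seeds.

    Returns (features, first_derivs, second_derivs) where first/second are
    lists over the 3 raw inputs of arrays d(features)/d(x_i), d2/dx_i2 —
    all plain numpy (the embedding carries no trainable parameters).
    """
    n = Xn.shape[0]
    if B is None:
        feats = Xn
        firsts = [np.tile(e, (n, 1)) for e in np.eye(3)]
        seconds = [np.zeros((n, 3)), np.zeros((n, 3))]
        return feats, firsts, seconds
    phase = 2.0 * np.pi * (Xn @ B)          # (n, m)
    s, c = np.sin(phase), np.cos(phase)
    feats = np.concatenate([Xn, s, c], axis=1)
    firsts, seconds = [], []
    for i in range(3):
        w = 2.0 * np.pi * B[i]               # (m,)
        e = np.zeros((n, 3)); e[:, i] = 1.0
        firsts.append(np.concatenate([e, c * w, -s * w], axis=1))
        if i < 2:
            seconds.append(np.concatenate(
                [np.zeros((n, 3)), -s * w**2, -c * w**2], axis=1))
    return feats, firsts, seconds


def forward_values(net: Network, X: np.ndarray) -> Tensor:
    """Evaluate the network on points ``X`` of shape (N, 3); returns (N, 3)."""
    Xn, _ = _normalize(np.asarray(X, dtype=np.float64), net.config)
    feats, _, _ = _embed(Xn, net.fourier_B)
    act = _ACT[net.config.activation]
    z = Tensor(feats)
    for W, b, g, hidden in net._layers:
        a = z @ W + b
        if g is not None:
            a = a * g
        z = act(a) if hidden else a
    return z


def forward_with_derivatives(net: Network, X: np.ndarray) -> dict:
    """Evaluate values plus d/dx, d/dy, d/dt and d2/dx2, d2/dy2 channels.

    Returns a dict of (N, 3) Tensors keyed by
    ``val, dx, dy, dt, dxx, dyy`` — columns are (u, v, p).
    """
    Xn, inv_h = _normalize(np.asarray(X, dtype=np.float64), net.config)
    act_name = net.config.activation

    # channels seeded with the embedding derivatives (chain rule through the
    # affine input normalization)
    feats, d1, d2 = _embed(Xn, net.fourier_B)
    val = Tensor(feats)
    firsts = [Tensor(d1[i] * inv_h[i]) for i in range(3)]
    seconds = [Tensor(d2[i] * inv_h[i] ** 2) for i in range(2)]

    for W, b, g, hidden in net._layers:
        a = val @ W + b
        fa = [f @ W for f in firsts]
        sa = [s @ W for s in seconds]
        if g is not None:
            a = a * g
            fa = [f * g for f in fa]
            sa = [s * g for s in sa]
        if hidden:
            if act_name == "sigmoid":
                s1 = sigmoid(a)
                d1 = s1 * (1.0 - s1)            # sigma'
                d2 = d1 * (1.0 - 2.0 * s1)      # sigma''
                val = s1
            else:
                t1 = tanh(a)
                d1 = 1.0 - t1 * t1
                d2 = -2.0 * t1 * d1
                val = t1
            new_firsts = [d1 * f for f in fa]
            new_seconds = [d2 * fa[i].square() + d1 * sa[i] for i in range(2)]
            firsts, seconds = new_firsts, new_seconds
        else:
            val, firsts, seconds = a, fa, sa

    return {
        "val": val,
        "dx": firsts[0],
        "dy": firsts[1],
        "dt": firsts[2],
        "dxx": seconds[0],
        "dyy": seconds[1],
    }
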