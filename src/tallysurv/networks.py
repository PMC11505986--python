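"""Multilayer perceptron and Adam optimizer used by all four survival models.

Architecture follows the hyperparameter space of the study design:
`n_layers` hidden layers of `n_nodes` units each, ReLU activations and
dropout after every hidden layer, and a linear output head whose width
depends on the model family (1 for relative-risk scores, K or K+1 for the
discrete-time families).  `n_layers=0` degenerates to a linear model, which
is the special case used for parameter-recovery checks.
"""

from __future__ import annotations

import numpy as np

from ._autodiff import Tensor, as_tensor

__all__ = ["MLP", "Adam"]


class MLP:
    def __init__(
        self,
        in_dim: int,
        out_dim: int,
        n_layers: int = 2,
        n_nodes: int = 32,
        dropout: float = 0.0,
        rng: np.random.Generator | None = None,
    ):
        if rng is None:
            rng = np.random.default_rng()
        self.in_dim = in_dim
        self.out_dim = out_dim
        self.n_layers = n_layers
        self.n_nodes = n_nodes
        self.dropout = float(dropout)
        self.params: list[Tensor] = []
        dims = [in_dim] + [n_nodes] * n_layers + [out_dim]
        self.weights: list[Tensor] = []
        self.biases: list[Tensor] = []
        for d_in, d_out in zip(dims[:-1], dims[1:]):
            # He initialization, appropriate for ReLU hidden units
            w = Tensor(rng.normal(0.0, np.sqrt(2.0 / d_in), size=(d_in, d_out)),
                       requires_grad=True)
            b = Tensor(np.zeros(d_out), requires_grad=True)
            self.weights.append(w)
            self.biases.append(b)
            self.params.extend([w, b])

    def forward(self, x, *, training: bool = False,
                rng: np.random.Generator | None = None) -> Tensor:
        """Forward pass; dropout masks are drawn from `rng` only in training."""
        h = as_tensor(x)
        n_hidden = len(self.weights) - 1
        for i in range(n_hidden):
            h = (h @ self.weights[i] + self.biases[i]).relu()
            if training and self.dropout > 0.0:
                keep = 1.0 - self.dropout
                mask = (rng.random(h.shape) < keep) / keep  # inverted dropout
                h = h * mask
        return h @ self.weights[-1] + self.biases[-1]

    def predict(self, x: np.ndarray) -> np.ndarray:
        return self.forward(x, training=False).data

    # -- flat parameter (de)serialization --------------------------------

    def get_state(self) -> list[np.ndarray]:
        return [p.data.copy() for p in self.params]

    def set_state(self, state: list[np.ndarray]) -> None:
        for p, s in zip(self.params, state):
            p.data = np.asarray(s, dtype=np.float64).copy()


class Adam:
    """Adaptive moment estimation with the standard bias correction."""

    def __init__(self, params: list[Tensor], lr: float = 1e-3,
                 betas: tuple[float, float] = (0.9, 0.999), eps: float = 1e-8):
        self.params = params
        self.lr = lr
        self.b1, self.b2 = betas
        self.eps = eps
        self.t = 0
        self.m = [np.zeros_like(p.data) for p in params]
        self.v = [np.zeros_like(p.data) for p in params]

    def zero_grad(self) -> None:
        for p in self.params:
            p.grad = None

    def step(self) -> None:
        self.t += 1
        for i, p in enumerate(self.params):
            if p.grad is None:
                continue
            g = p.grad
            self.m[i] = self.b1 * self.m[i] + (1 - self.b1) * g
            self.v[i] = self.b2 * self.v[i] + (1 - self.b2) * g * g
            m_hat = self.m[i] / (1 - self.b1**self.t)
            v_hat = self.v[i] / (1 - self.b2**self.t)
            p.data -= self.lr * m_hat / (np.sqrt(v_hat) + self.eps)
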