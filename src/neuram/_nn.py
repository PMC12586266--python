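"""Small dense networks and an Adam optimizer on top of `_autodiff`.

Networks are plain lists of `(W, b)` numpy pairs; `mlp_apply` builds the
autodiff graph.  Hidden activations are tanh (smooth — the sensitivity
indices differentiate the trained networks), the output layer is linear
unless `squash=True`, in which case it is tanh: a decoder with a squashed
output layer maps into (-1, 1)^d by construction, which keeps reconstructed
points inside the (normalized) input box.
"""

from __future__ import annotations

import numpy as np

from ._autodiff import Var, as_var

Params = list[tuple[np.ndarray, np.ndarray]]


def init_mlp(sizes: list[int], rng: np.random.Generator) -> Params:
    """Glorot-uniform initialization for a dense network with layer `sizes`."""
    params: Params = []
    for n_in, n_out in zip(sizes[:-1], sizes[1:]):
        lim = np.sqrt(6.0 / (n_in + n_out))
        W = rng.uniform(-lim, lim, size=(n_in, n_out))
        b = np.zeros(n_out)
        params.append((W, b))
    return params


def mlp_apply(params, x, squash: bool = False):
    """Forward pass; `x` is (N, d_in) array or Var, returns (N, d_out) Var."""
    h = as_var(x)
    last = len(params) - 1
    for i, (W, b) in enumerate(params):
        h = h @ as_var(W) + as_var(b)
        if i < last or squash:
            h = h.tanh()
    return h


def params_to_vars(params: Params) -> list[Var]:
    return [as_var(a) for Wb in params for a in Wb]


def vars_to_params(vars_: list[Var]) -> Params:
    vals = [v.value for v in vars_]
    return [(vals[i], vals[i + 1]) for i in range(0, len(vals), 2)]


class Adam:
    """Adaptive-moment gradient descent over a flat list of arrays."""

    def __init__(self, n_arrays: int, lr: float = 1e-3,
                 beta1: float = 0.9, beta2: float = 0.999, eps: float = 1e-8):
        self.lr, self.beta1, self.beta2, self.eps = lr, beta1, beta2, eps
        self.m = [None] * n_arrays
        self.v = [None] * n_arrays
        self.t = 0

    def step(self, values: list[np.ndarray], grads: list[np.ndarray]) -> None:
        self.t += 1
        b1, b2 = self.beta1, self.beta2
        for i, (x, g) in enumerate(zip(values, grads)):
            if self.m[i] is None:
                self.m[i] = np.zeros_like(x)
                self.v[i] = np.zeros_like(x)
            self.m[i] = b1 * self.m[i] + (1 - b1) * g
            self.v[i] = b2 * self.v[i] + (1 - b2) * g * g
            mhat = self.m[i] / (1 - b1**self.t)
            vhat = self.v[i] / (1 - b2**self.t)
            x -= self.lr * mhat / (np.sqrt(vhat) + self.eps)
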