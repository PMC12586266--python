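"""The NeurAM container: encoder/decoder/latent-surrogate triple.

A NeurAM is a one-dimensional active manifold in input space together with a
scalar surrogate on the latent coordinate.  The triple satisfies (after
training) Q(x) ~= S(E(x)) and Q(x) ~= Q(D(E(x))): the decoder parameterizes
the manifold, the encoder projects onto it, and the surrogate emulates the
model along it.  Components expose value and first-derivative evaluations —
closed-form for analytic triples, reverse-mode autodiff for trained networks
— which is all the downstream sensitivity and multifidelity machinery needs.

Trained triples operate in normalized coordinates ([-1,1]^d); the attached
input distribution carries the (possibly log-scale) affine map from the raw
box, and the `*_raw` convenience methods apply it.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable

import numpy as np

from ._autodiff import Var, grad
from ._nn import Params, mlp_apply

__all__ = [
    "NeurAM",
    "AnalyticScalarField",
    "AnalyticCurve",
    "AnalyticScalar1D",
    "MLPScalarField",
    "MLPCurve",
    "MLPScalar1D",
    "latent_interval",
]


# ---------------------------------------------------------------------------
# component implementations
# ---------------------------------------------------------------------------

@dataclass
class AnalyticScalarField:
    """Closed-form scalar field R^d -> R with gradient."""

    fn: Callable[[np.ndarray], np.ndarray]
    grad_fn: Callable[[np.ndarray], np.ndarray]

    def __call__(self, X: np.ndarray) -> np.ndarray:
        return self.fn(np.atleast_2d(X))

    def grad(self, X: np.ndarray) -> np.ndarray:
        return self.grad_fn(np.atleast_2d(X))


@dataclass
class AnalyticCurve:
    """Closed-form curve R -> R^d with derivative."""

    fn: Callable[[np.ndarray], np.ndarray]
    jac_fn: Callable[[np.ndarray], np.ndarray]

    def __call__(self, t: np.ndarray) -> np.ndarray:
        return self.fn(np.atleast_1d(np.asarray(t, dtype=float)))

    def jac(self, t: np.ndarray) -> np.ndarray:
        return self.jac_fn(np.atleast_1d(np.asarray(t, dtype=float)))


@dataclass
class AnalyticScalar1D:
    """Closed-form function R -> R with derivative."""

    fn: Callable[[np.ndarray], np.ndarray]
    deriv_fn: Callable[[np.ndarray], np.ndarray]

    def __call__(self, t: np.ndarray) -> np.ndarray:
        return self.fn(np.atleast_1d(np.asarray(t, dtype=float)))

    def deriv(self, t: np.ndarray) -> np.ndarray:
        return self.deriv_fn(np.atleast_1d(np.asarray(t, dtype=float)))


class MLPScalarField:
    """Dense network R^d -> R; gradient via reverse-mode autodiff."""

    def __init__(self, params: Params):
        self.params = params

    def __call__(self, X: np.ndarray) -> np.ndarray:
        return mlp_apply(self.params, np.atleast_2d(X)).value[:, 0]

    def grad(self, X: np.ndarray) -> np.ndarray:
        xv = Var(np.atleast_2d(X))
        out = mlp_apply(self.params, xv).sum()
        return grad(out, [xv])[0]  # rows are independent samples


class MLPCurve:
    """Dense network R -> R^d with tanh-squashed output (stays in the box)."""

    def __init__(self, params: Params, squash: bool = True):
        self.params = params
        self.squash = squash

    def _t2col(self, t):
        return np.atleast_1d(np.asarray(t, dtype=float))[:, None]

    def __call__(self, t: np.ndarray) -> np.ndarray:
        return mlp_apply(self.params, self._t2col(t), squash=self.squash).value

    def jac(self, t: np.ndarray) -> np.ndarray:
        tv = Var(self._t2col(t))
        out = mlp_apply(self.params, tv, squash=self.squash)
        d = out.value.shape[1]
        cols = []
        for j in range(d):
            gj = grad(out[:, j].sum(), [tv])[0][:, 0]
            cols.append(gj)
        return np.stack(cols, axis=1)


class MLPScalar1D:
    """Dense network R -> R (the latent surrogate)."""

    def __init__(self, params: Params):
        self.params = params

    def _t2col(self, t):
        return np.atleast_1d(np.asarray(t, dtype=float))[:, None]

    def __call__(self, t: np.ndarray) -> np.ndarray:
        return mlp_apply(self.params, self._t2col(t)).value[:, 0]

    def deriv(self, t: np.ndarray) -> np.ndarray:
        tv = Var(self._t2col(t))
        out = mlp_apply(self.params, tv).sum()
        return grad(out, [tv])[0][:, 0]


# ---------------------------------------------------------------------------
# the trained/assembled triple
# ---------------------------------------------------------------------------

@dataclass
class NeurAM:
    """Encoder E, decoder D, latent surrogate S, and bookkeeping.

    `dist` holds the input normalization; `None` means the triple operates
    directly in raw coordinates (the analytic reference triple does).
    `latent_interval` is the empirical range of the encoder over the training
    sample — the parameter range of the manifold.
    """

    encoder: object
    decoder: object
    surrogate: object
    latent_interval: tuple[float, float]
    dist: object | None = None
    history: dict = field(default_factory=dict)
    seed: int | None = None
    meta: dict = field(default_factory=dict)

    # --- coordinate helpers ----------------------------------------------
    def to_net(self, X_raw: np.ndarray) -> np.ndarray:
        X_raw = np.atleast_2d(X_raw)
        return self.dist.normalize(X_raw) if self.dist is not None else X_raw

    def from_net(self, Z: np.ndarray) -> np.ndarray:
        return self.dist.denormalize(Z) if self.dist is not None else Z

    # --- main maps (raw coordinates) -------------------------------------
    def encode(self, X_raw: np.ndarray) -> np.ndarray:
        return self.encoder(self.to_net(X_raw))

    def project(self, X_raw: np.ndarray) -> np.ndarray:
        """D(E(x)): projection of x onto the manifold, in raw coordinates."""
        return self.from_net(self.decoder(self.encode(X_raw)))

    def surrogate_at(self, X_raw: np.ndarray) -> np.ndarray:
        """Q_S(x) = S(E(x))."""
        return self.surrogate(self.encode(X_raw))

    def manifold_point(self, t: np.ndarray) -> np.ndarray:
        """D(t) in raw coordinates."""
        return self.from_net(self.decoder(np.atleast_1d(t)))

    def reduce(self, x_raw: np.ndarray) -> tuple[float, np.ndarray, float]:
        """(t, x_proj, y_surr) for a single point."""
        x = np.atleast_2d(np.asarray(x_raw, dtype=float))
        t = self.encode(x)
        return float(t[0]), self.from_net(self.decoder(t))[0], float(self.surrogate(t)[0])


def latent_interval(neuram: NeurAM, samples_raw: np.ndarray) -> tuple[float, float]:
    """Empirical latent range [min E, max E] over a sample of inputs."""
    samples_raw = np.atleast_2d(samples_raw)
    if samples_raw.shape[0] == 0:
        raise ValueError("samples must be nonempty")
    t = neuram.encode(samples_raw)
    return float(np.min(t)), float(np.max(t))
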