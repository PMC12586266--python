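"""Benchmark model suite, input distributions, and dataset generation.

The registry holds scalar-output test functions Q: R^d -> R on box domains:
the parabolic pair on the unit square, three polynomial/exponential 2-D
models on [-1,1]^2, an exponential high/low-fidelity pair used for
multifidelity experiments, and the two closed-form outputs of the Hartmann
magnetohydrodynamics problem (laminar conducting flow between plates under a
transverse magnetic field) with log-uniform inputs.

Also provides the closed-form encoder/decoder/surrogate triple that globally
minimizes the training loss for the parabolic model — the package's exact
reference object.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np

from .core import AnalyticCurve, AnalyticScalar1D, AnalyticScalarField, NeurAM

__all__ = [
    "ModelSpec",
    "InputDistribution",
    "Dataset",
    "MODEL_NAMES",
    "get_model",
    "evaluate_model",
    "sample_inputs",
    "normalize_inputs",
    "denormalize_inputs",
    "make_dataset",
    "analytic_parabolic_neuram",
]


@dataclass(frozen=True)
class ModelSpec:
    """A named scalar-output function on a box domain."""

    name: str
    dim: int
    fn: Callable[[np.ndarray], np.ndarray]  # (N, d) -> (N,)
    lo: np.ndarray
    hi: np.ndarray

    def __post_init__(self):
        object.__setattr__(self, "lo", np.asarray(self.lo, dtype=float))
        object.__setattr__(self, "hi", np.asarray(self.hi, dtype=float))
        if self.lo.shape != (self.dim,) or self.hi.shape != (self.dim,):
            raise ValueError("domain bounds must have length dim")
        if not np.all(self.lo < self.hi):
            raise ValueError("domain requires lo < hi in every coordinate")

    def evaluate(self, x: np.ndarray) -> np.ndarray:
        """Evaluate at one point (d,) or a batch (N, d); checks the box."""
        x = np.atleast_2d(np.asarray(x, dtype=float))
        if x.shape[1] != self.dim:
            raise ValueError(f"expected {self.dim} coordinates, got {x.shape[1]}")
        tol = 1e-9 * np.maximum(1.0, np.abs(self.hi - self.lo))
        if np.any(x < self.lo - tol) or np.any(x > self.hi + tol):
            raise ValueError(f"point outside the domain box of '{self.name}'")
        return self.fn(x)


@dataclass(frozen=True)
class InputDistribution:
    """Independent uniform / log-uniform coordinates on a box."""

    kinds: tuple[str, ...]
    lo: np.ndarray
    hi: np.ndarray

    def __post_init__(self):
        object.__setattr__(self, "lo", np.asarray(self.lo, dtype=float))
        object.__setattr__(self, "hi", np.asarray(self.hi, dtype=float))
        for k, a in zip(self.kinds, self.lo):
            if k not in ("uniform", "loguniform"):
                raise ValueError(f"unknown distribution kind '{k}'")
            if k == "loguniform" and a <= 0:
                raise ValueError("log-uniform coordinates require lo > 0")
        if not np.all(self.lo < self.hi):
            raise ValueError("distribution requires lo < hi")

    @property
    def dim(self) -> int:
        return len(self.kinds)

    def sample(self, n: int, seed) -> np.ndarray:
        """n i.i.d. draws, (n, d). `seed` is an int or a Generator."""
        if n < 0:
            raise ValueError("n must be >= 0")
        rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
        u = rng.uniform(size=(n, self.dim))
        out = np.empty((n, self.dim))
        for i, k in enumerate(self.kinds):
            a, b = self.lo[i], self.hi[i]
            if k == "uniform":
                out[:, i] = a + (b - a) * u[:, i]
            else:
                la, lb = np.log(a), np.log(b)
                out[:, i] = np.exp(la + (lb - la) * u[:, i])
        return out

    def normalize(self, X: np.ndarray) -> np.ndarray:
        """Map the box onto [-1, 1]^d (affine; in log space for log-uniform)."""
        X = np.atleast_2d(np.asarray(X, dtype=float))
        out = np.empty_like(X)
        for i, k in enumerate(self.kinds):
            a, b = self.lo[i], self.hi[i]
            if k == "uniform":
                out[:, i] = 2.0 * (X[:, i] - a) / (b - a) - 1.0
            else:
                la, lb = np.log(a), np.log(b)
                out[:, i] = 2.0 * (np.log(X[:, i]) - la) / (lb - la) - 1.0
        return out

    def denormalize(self, Z: np.ndarray) -> np.ndarray:
        """Exact inverse of :meth:`normalize`."""
        Z = np.atleast_2d(np.asarray(Z, dtype=float))
        out = np.empty_like(Z)
        for i, k in enumerate(self.kinds):
            a, b = self.lo[i], self.hi[i]
            if k == "uniform":
                out[:, i] = a + (Z[:, i] + 1.0) * (b - a) / 2.0
            else:
                la, lb = np.log(a), np.log(b)
                out[:, i] = np.exp(la + (Z[:, i] + 1.0) * (lb - la) / 2.0)
        return out


@dataclass
class Dataset:
    """Paired inputs/outputs {(x_n, Q(x_n))} with the generating seed."""

    inputs: np.ndarray
    outputs: np.ndarray
    normalized: bool = False
    seed: int | None = None
    dist: InputDistribution | None = None

    def __post_init__(self):
        self.inputs = np.atleast_2d(np.asarray(self.inputs, dtype=float))
        self.outputs = np.asarray(self.outputs, dtype=float).ravel()
        if len(self.outputs) != self.inputs.shape[0]:
            raise ValueError("inputs and outputs must have the same length")

    def __len__(self) -> int:
        return self.inputs.shape[0]


# ---------------------------------------------------------------------------
# model registry
# ---------------------------------------------------------------------------

def _hartmann_u(x: np.ndarray) -> np.ndarray:
    # average flow velocity; l = 1, magnetic constant mu0 = 1
    mu, rho, dpdx, eta, B0 = x.T
    z = B0 / np.sqrt(eta * mu)
    return -dpdx * eta / B0**2 * (1.0 - z / np.tanh(z))


def _hartmann_b(x: np.ndarray) -> np.ndarray:
    # induced magnetic field
    mu, rho, dpdx, eta, B0 = x.T
    z = B0 / np.sqrt(eta * mu)
    return dpdx / (2.0 * B0) * (1.0 - (2.0 / z) * np.tanh(z / 2.0))


_HARTMANN_LO = [0.05, 1.0, 0.5, 0.5, 0.1]
_HARTMANN_HI = [0.2, 5.0, 3.0, 3.0, 1.0]

_REGISTRY: dict[str, tuple[Callable, list, list, tuple[str, ...]]] = {
    "parabolic": (lambda x: x[:, 0] ** 2 + x[:, 1], [0, 0], [1, 1], ("uniform",) * 2),
    "sine_parabolic": (
        lambda x: np.sin(x[:, 0] ** 2 + x[:, 1]), [0, 0], [1, 1], ("uniform",) * 2),
    "q1": (lambda x: np.exp(x[:, 1] - x[:, 0] ** 2), [-1, -1], [1, 1], ("uniform",) * 2),
    "q2": (lambda x: x[:, 0] ** 2 + x[:, 1] ** 2, [-1, -1], [1, 1], ("uniform",) * 2),
    "q3": (
        lambda x: x[:, 0] ** 3 + x[:, 1] ** 3 + 0.2 * x[:, 0] + 0.6 * x[:, 1],
        [-1, -1], [1, 1], ("uniform",) * 2),
    "hf_exp": (
        lambda x: np.exp(0.7 * x[:, 0] + 0.3 * x[:, 1]) + 0.15 * np.sin(2 * np.pi * x[:, 0]),
        [-1, -1], [1, 1], ("uniform",) * 2),
    "lf_exp": (
        lambda x: np.exp(0.01 * x[:, 0] + 0.99 * x[:, 1]) + 0.15 * np.sin(3 * np.pi * x[:, 1]),
        [-1, -1], [1, 1], ("uniform",) * 2),
    "hartmann_u": (_hartmann_u, _HARTMANN_LO, _HARTMANN_HI, ("loguniform",) * 5),
    "hartmann_b": (_hartmann_b, _HARTMANN_LO, _HARTMANN_HI, ("loguniform",) * 5),
}

MODEL_NAMES = tuple(_REGISTRY)


def get_model(name: str) -> tuple[ModelSpec, InputDistribution]:
    """Return the named model and its default input distribution."""
    try:
        fn, lo, hi, kinds = _REGISTRY[name]
    except KeyError:
        raise KeyError(f"unknown model '{name}'; known: {', '.join(MODEL_NAMES)}") from None
    spec = ModelSpec(name=name, dim=len(lo), fn=fn, lo=lo, hi=hi)
    dist = InputDistribution(kinds=kinds, lo=lo, hi=hi)
    return spec, dist


def evaluate_model(spec: ModelSpec, x: np.ndarray) -> np.ndarray | float:
    """Evaluate `spec` at `x`; scalar for a single point, array for a batch."""
    x = np.asarray(x, dtype=float)
    y = spec.evaluate(x)
    return float(y[0]) if x.ndim == 1 else y


def sample_inputs(dist: InputDistribution, n: int, seed) -> np.ndarray:
    """i.i.d. draws from `dist`, reproducible per seed."""
    return dist.sample(n, seed)


def normalize_inputs(dist: InputDistribution, X: np.ndarray) -> np.ndarray:
    """Map points of the box onto [-1, 1]^d (log-affine for log-uniform)."""
    return dist.normalize(X)


def denormalize_inputs(dist: InputDistribution, Z: np.ndarray) -> np.ndarray:
    """Exact inverse of :func:`normalize_inputs`."""
    return dist.denormalize(Z)


def make_dataset(spec: ModelSpec, dist: InputDistribution, n: int,
                 seed: int) -> Dataset:
    """Sample n inputs, evaluate the model, return the paired dataset."""
    if n < 1:
        raise ValueError("n must be >= 1")
    X = dist.sample(n, seed)
    y = spec.evaluate(X)
    return Dataset(inputs=X, outputs=y, normalized=False, seed=seed, dist=dist)


# ---------------------------------------------------------------------------
# closed-form reference minimizer for the parabolic model
# ---------------------------------------------------------------------------

def analytic_parabolic_neuram() -> NeurAM:
    """Exact zero-loss triple for Q(x) = x1^2 + x2 on U([0,1]^2).

    E*(x) = x1^2 + x2, D*(t) = [sqrt(t/2), t/2], S*(t) = t, with latent
    interval [0, 2].  The manifold is the parabola x2 = x1^2.  All components
    provide closed-form derivatives, so it serves as an exact oracle for the
    loss, the projection, and the sensitivity indices.
    """
    encoder = AnalyticScalarField(
        fn=lambda X: X[:, 0] ** 2 + X[:, 1],
        grad_fn=lambda X: np.stack([2.0 * X[:, 0], np.ones(len(X))], axis=1),
    )
    decoder = AnalyticCurve(
        fn=lambda t: np.stack([np.sqrt(t / 2.0), t / 2.0], axis=1),
        jac_fn=lambda t: np.stack(
            [np.where(t > 0, 1.0 / (2.0 * np.sqrt(2.0 * t)), np.inf),
             np.full_like(t, 0.5)], axis=1),
    )
    surrogate = AnalyticScalar1D(fn=lambda t: t.copy(),
                                 deriv_fn=lambda t: np.ones_like(t))
    return NeurAM(encoder=encoder, decoder=decoder, surrogate=surrogate,
                  latent_interval=(0.0, 2.0), dist=None)
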