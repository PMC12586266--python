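"""Sensitivity indices along the active manifold, plus a Sobol' comparison.

The local (dynamic) index of input i at manifold coordinate t is the
normalized squared partial derivative of the latent surrogate Q_S = S o E,
evaluated at the manifold point D(t):

    theta_i(t) = |d Q_S / d x_i (D(t))|^2 / ||grad Q_S(D(t))||^2,
    d Q_S / d x_i (D(t)) = S'(E(D(t))) * dE/dx_i (D(t)).

By construction the theta_i(t) sum to one wherever the gradient is nonzero,
giving a ranking of inputs that varies along the manifold.  Global indices
Theta_i are the arc-length averages of theta_i over the manifold; they again
sum to one.  Indices are computed in the triple's own (normalized)
coordinates — ranking raw-unit derivatives would make the result depend on
the choice of units.

First-order Sobol' indices of the exact model are provided for comparison;
they measure variance contributions rather than derivatives, so agreement is
expected only when input interactions are weak.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .core import NeurAM
from .models import InputDistribution, ModelSpec

__all__ = [
    "SensitivityProfile",
    "local_indices",
    "global_indices",
    "sensitivity_profile",
    "sobol_first_order",
]


@dataclass
class SensitivityProfile:
    """Local indices on a latent grid and their arc-length averages."""

    t_grid: np.ndarray       # (n,)
    local: np.ndarray        # (n, d); rows are theta(t), NaN where degenerate
    global_idx: np.ndarray   # (d,)
    arc_weights: np.ndarray  # (n,) |D'(t)| on the grid


def _surrogate_input_grad(neuram: NeurAM, t: np.ndarray) -> np.ndarray:
    """grad Q_S at the manifold points D(t) via the chain rule, (n, d)."""
    x = neuram.decoder(t)
    te = neuram.encoder(x)
    sp = neuram.surrogate.deriv(te)
    return sp[:, None] * neuram.encoder.grad(x)


def local_indices(neuram: NeurAM, t) -> np.ndarray:
    """theta(t): normalized squared surrogate derivatives at D(t).

    Accepts a scalar or an array of latent values; returns (d,) or (n, d).
    Points with a vanishing surrogate gradient are degenerate — the ranking
    is undefined there — and come back as NaN rows.
    """
    t_arr = np.atleast_1d(np.asarray(t, dtype=float))
    g = _surrogate_input_grad(neuram, t_arr)
    g2 = g**2
    norm2 = g2.sum(axis=1)
    theta = np.full_like(g2, np.nan)
    ok = norm2 > 0
    theta[ok] = g2[ok] / norm2[ok, None]
    return theta[0] if np.isscalar(t) or np.ndim(t) == 0 else theta


def global_indices(neuram: NeurAM, n_grid: int = 1024) -> np.ndarray:
    """Theta: arc-length average of the local indices over the manifold.

    Discretizes Theta_i = (int theta_i |D'| dt) / (int |D'| dt) on a uniform
    latent grid, using the chord length ||D(t_{k+1}) - D(t_k)|| as the
    arc-length element of each cell and the trapezoidal average of theta on
    its endpoints.  The polyline form is robust to parameterizations whose
    speed |D'| blows up at an endpoint while the manifold itself stays
    rectifiable (the closed-form parabolic triple is such a case).
    """
    if n_grid < 2:
        raise ValueError("n_grid must be >= 2")
    t0, t1 = neuram.latent_interval
    if not t1 > t0:
        raise ValueError("latent interval is degenerate")
    t = np.linspace(t0, t1, n_grid)
    theta = local_indices(neuram, t)
    P = neuram.decoder(t)
    chord = np.linalg.norm(np.diff(P, axis=0), axis=1)

    valid = ~np.isnan(theta[:, 0])
    if not np.any(valid):
        raise RuntimeError("all grid points are degenerate; indices undefined")
    if not np.all(valid):
        warnings.warn(f"{np.count_nonzero(~valid)} degenerate grid points "
                      "dropped from the arc-length average")
    seg_ok = valid[:-1] & valid[1:]
    if not np.any(seg_ok):
        raise RuntimeError("no non-degenerate segments on the latent grid")
    theta_bar = 0.5 * (theta[:-1][seg_ok] + theta[1:][seg_ok])
    w = chord[seg_ok]
    return (theta_bar * w[:, None]).sum(axis=0) / w.sum()


def sensitivity_profile(neuram: NeurAM, n_grid: int = 1024) -> SensitivityProfile:
    """Local indices on a uniform latent grid plus the global averages."""
    t0, t1 = neuram.latent_interval
    t = np.linspace(t0, t1, n_grid)
    with np.errstate(divide="ignore", invalid="ignore"):
        arc = np.linalg.norm(neuram.decoder.jac(t), axis=1)
    return SensitivityProfile(
        t_grid=t,
        local=local_indices(neuram, t),
        global_idx=global_indices(neuram, n_grid),
        arc_weights=arc,
    )


def sobol_first_order(spec: ModelSpec, dist: InputDistribution, n: int = 1024,
                      seed: int = 0) -> np.ndarray:
    """First-order Sobol' indices by the pick-freeze Monte Carlo estimator.

    Uses two independent n-sample matrices A, B with common random numbers
    and the estimator S_i = mean(f(B) * (f(A_B^i) - f(A))) / Var(f), where
    A_B^i is A with column i replaced from B.
    """
    if n < 64:
        raise ValueError("n must be >= 64 for a usable pick-freeze estimate")
    rng = np.random.default_rng(seed)
    A = dist.sample(n, rng)
    B = dist.sample(n, rng)
    fA = spec.evaluate(A)
    fB = spec.evaluate(B)
    V = np.var(np.concatenate([fA, fB]), ddof=1)
    S = np.empty(spec.dim)
    for i in range(spec.dim):
        ABi = A.copy()
        ABi[:, i] = B[:, i]
        S[i] = np.mean(fB * (spec.evaluate(ABi) - fA)) / V
    return S
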