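"""Joint training of the encoder/decoder/surrogate triple.

The three networks are trained simultaneously by full-batch Adam on the
three-term loss

    L = mean (Q - S(E(D(E(x)))))^2        surrogate accuracy on the manifold
      + mean (Q - S(E(x)))^2              surrogate accuracy off the manifold
      + mean ||D(E(x)) - D(E(D(E(x))))||^2   autoencoder behaviour *on* the
                                             manifold (projection idempotency)

evaluated on the training sample.  Note the triple is not asked to
reconstruct inputs — only model values — so D(E(x)) != x in general; the
third term only pins down points already on the manifold.

Inputs are normalized to [-1,1]^d before training; the decoder's tanh output
layer keeps reconstructed points inside that box by construction.  Outputs
are z-scored for optimizer conditioning and the affine map is folded back
into the surrogate's linear output layer, so the returned surrogate is in
raw output units.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from ._autodiff import grad
from ._nn import Adam, init_mlp, mlp_apply
from .core import MLPCurve, MLPScalar1D, MLPScalarField, NeurAM
from .models import Dataset, ModelSpec

__all__ = [
    "NetworkArchitecture",
    "TrainingConfig",
    "TrainingError",
    "loss_components",
    "train_neuram",
    "evaluation_errors",
]


@dataclass(frozen=True)
class NetworkArchitecture:
    """Layer layout shared by encoder, decoder, and surrogate."""

    hidden_layers: int = 2
    neurons_per_layer: int = 8
    activation: str = "tanh"

    def __post_init__(self):
        if not 1 <= self.hidden_layers <= 4:
            raise ValueError("hidden_layers must be in [1, 4]")
        if not 1 <= self.neurons_per_layer <= 16:
            raise ValueError("neurons_per_layer must be in [1, 16]")
        if self.activation != "tanh":
            raise ValueError("only the smooth 'tanh' activation is supported")

    def sizes(self, d_in: int, d_out: int) -> list[int]:
        return [d_in] + [self.neurons_per_layer] * self.hidden_layers + [d_out]


@dataclass(frozen=True)
class TrainingConfig:
    epochs: int = 10000
    learning_rate: float = 1e-3
    validation_fraction: float = 0.2
    seed: int = 0
    restarts: int = 3

    def __post_init__(self):
        if not 0.0 < self.validation_fraction < 1.0:
            raise ValueError("validation_fraction must be in (0, 1)")
        if self.epochs < 1 or self.restarts < 1:
            raise ValueError("epochs and restarts must be >= 1")


class TrainingError(RuntimeError):
    """Raised when the loss becomes non-finite; carries the epoch index."""

    def __init__(self, epoch: int, restart: int):
        self.epoch = epoch
        self.restart = restart
        super().__init__(f"non-finite loss at epoch {epoch} (restart {restart})")


def loss_components(neuram: NeurAM, batch: Dataset) -> tuple[float, float, float]:
    """The three loss terms of an assembled triple on a batch (raw inputs)."""
    if len(batch) == 0:
        raise ValueError("batch must be nonempty")
    X = neuram.to_net(batch.inputs)
    y = batch.outputs
    t = neuram.encoder(X)
    xp = neuram.decoder(t)
    t2 = neuram.encoder(xp)
    L1 = float(np.mean((y - neuram.surrogate(t2)) ** 2))
    L2 = float(np.mean((y - neuram.surrogate(t)) ** 2))
    L3 = float(np.mean(np.sum((xp - neuram.decoder(t2)) ** 2, axis=1)))
    return L1, L2, L3


def _forward_losses(pe, pd, ps, X, y):
    """Autodiff graph of the three loss terms; returns Var triple."""
    t = mlp_apply(pe, X)
    xp = mlp_apply(pd, t, squash=True)
    t2 = mlp_apply(pe, xp)
    y1 = mlp_apply(ps, t2)[:, 0]
    y2 = mlp_apply(ps, t)[:, 0]
    L1 = (y1 - y).square().mean()
    L2 = (y2 - y).square().mean()
    L3 = (xp - mlp_apply(pd, t2, squash=True)).square().sum(axis=1).mean()
    return L1, L2, L3


def _eval_total_loss(pe, pd, ps, X, y) -> float:
    L1, L2, L3 = _forward_losses(pe, pd, ps, X, y)
    return float(L1.value + L2.value + L3.value)


def train_neuram(data: Dataset, arch: NetworkArchitecture = NetworkArchitecture(),
                 config: TrainingConfig = TrainingConfig()) -> NeurAM:
    """Train a NeurAM on a dataset; returns the best-of-restarts triple.

    The dataset carries its input distribution (used to normalize inputs to
    [-1,1]^d) unless its inputs are already normalized.  The validation split
    is drawn once per config seed and shared across restarts; the parameters
    returned are the snapshot with the lowest validation loss over all epochs
    of the best restart.
    """
    if len(data) < 2:
        raise ValueError("training requires at least 2 samples")
    if data.normalized:
        X = data.inputs
        dist = None
    elif data.dist is not None:
        X = data.dist.normalize(data.inputs)
        dist = data.dist
    else:
        raise ValueError("dataset must be normalized or carry its input distribution")
    y_raw = data.outputs
    d = X.shape[1]

    # z-score outputs for conditioning; folded back into S afterwards
    ym = float(np.mean(y_raw))
    ys = float(np.std(y_raw))
    if ys == 0.0:
        ys = 1.0
    y = (y_raw - ym) / ys

    ss = np.random.SeedSequence(config.seed)
    split_rng = np.random.default_rng(ss.spawn(1)[0])
    n = len(y)
    n_val = max(1, int(round(config.validation_fraction * n))) if n > 2 else 0
    perm = split_rng.permutation(n)
    val_idx, tr_idx = perm[:n_val], perm[n_val:]
    if len(tr_idx) == 0:
        tr_idx, val_idx = perm, perm
    Xtr, ytr = X[tr_idx], y[tr_idx]
    Xva, yva = (X[val_idx], y[val_idx]) if n_val else (Xtr, ytr)

    best = None  # (val_loss, params, history)
    for r, child in enumerate(ss.spawn(config.restarts + 1)[1:]):
        rng = np.random.default_rng(child)
        pe = init_mlp(arch.sizes(d, 1), rng)
        pd = init_mlp(arch.sizes(1, d), rng)
        ps = init_mlp(arch.sizes(1, 1), rng)
        flat = [a for net in (pe, pd, ps) for Wb in net for a in Wb]
        opt = Adam(len(flat), lr=config.learning_rate)
        hist = np.empty((config.epochs, 4))
        best_val, best_params = np.inf, None
        for epoch in range(config.epochs):
            grads, losses = _param_grads(pe, pd, ps, Xtr, ytr)
            if not np.isfinite(losses[0]):
                raise TrainingError(epoch, r)
            opt.step(flat, grads)
            val = _eval_total_loss(pe, pd, ps, Xva, yva)
            hist[epoch] = losses
            if val < best_val:
                best_val = val
                best_params = ([(W.copy(), b.copy()) for W, b in net]
                               for net in (pe, pd, ps))
                best_params = list(best_params)
        if best is None or best_val < best[0]:
            best = (best_val, best_params, hist, r)

    val_loss, (pe, pd, ps), hist, r_best = best
    # fold the output z-score back into the surrogate's linear output layer
    W, b = ps[-1]
    ps[-1] = (W * ys, b * ys + ym)

    encoder = MLPScalarField(pe)
    t_all = encoder(X)
    neuram = NeurAM(
        encoder=encoder,
        decoder=MLPCurve(pd, squash=True),
        surrogate=MLPScalar1D(ps),
        latent_interval=(float(t_all.min()), float(t_all.max())),
        dist=dist,
        history={"loss": hist[:, 0], "loss_terms": hist[:, 1:],
                 "best_val_loss": val_loss, "best_restart": r_best},
        seed=config.seed,
        meta={"arch": arch, "config": config, "n_train": len(tr_idx),
              "n_val": len(val_idx)},
    )
    return neuram


def _param_grads(pe, pd, ps, X, y):
    """Gradients of the total loss w.r.t. all parameters, plus loss values."""
    from ._autodiff import as_var

    ve = [[as_var(W), as_var(b)] for W, b in pe]
    vd = [[as_var(W), as_var(b)] for W, b in pd]
    vs = [[as_var(W), as_var(b)] for W, b in ps]
    L1, L2, L3 = _forward_losses(ve, vd, vs, X, y)
    total = L1 + L2 + L3
    leaves = [v for net in (ve, vd, vs) for Wb in net for v in Wb]
    g = grad(total, leaves)
    values = (float(total.value), float(L1.value), float(L2.value), float(L3.value))
    return g, values


def evaluation_errors(spec: ModelSpec, neuram: NeurAM,
                      testset: Dataset) -> dict:
    """MAE/MSE of the reduction error e1 and surrogate error e2.

    e1(x) = Q(x) - Q(D(E(x))) isolates the cost of collapsing to the
    manifold (the model is re-evaluated at the projected point);
    e2(x) = Q(x) - S(E(x)) is the total surrogate error.
    """
    if len(testset) == 0:
        raise ValueError("testset must be nonempty")
    X = testset.inputs
    y = testset.outputs
    Xp = neuram.project(X)
    # squashed decoder keeps points inside the open box; clip guards the
    # boundary against floating round-off only
    Xp = np.clip(Xp, spec.lo, spec.hi)
    e1 = y - spec.evaluate(Xp)
    e2 = y - neuram.surrogate_at(X)
    return {
        "e1": {"mae": float(np.mean(np.abs(e1))), "mse": float(np.mean(e1**2))},
        "e2": {"mae": float(np.mean(np.abs(e2))), "mse": float(np.mean(e2**2))},
    }
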