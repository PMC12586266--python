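"""CDF-coupled shared space and multifidelity Monte Carlo estimation.

The multifidelity Monte Carlo (MFMC) estimator of q = E[Q_HF(X)] combines
N_HF high-fidelity evaluations with N_LF >= N_HF cheaper low-fidelity ones
as a control variate:

    q_hat = mean_{N_HF} Q_HF - beta * (mean_{N_HF} Q_LF - mean_{N_LF} Q_LF),

with beta = Cov(Q_HF, Q_LF)/Var(Q_LF) and the budget split B = N_HF + w N_LF
allocated optimally from the Pearson correlation rho.  Its variance,
(Var Q_HF / B)(sqrt(1-rho^2) + sqrt(w rho^2))^2, improves on plain Monte
Carlo only when rho^2 > w/(1+w), so raising the correlation is what matters.

The shared-space construction does exactly that: each fidelity's latent
coordinate is pushed through its empirical CDF onto U([0,1]), and the
low-fidelity model is reparameterized by pulling the high-fidelity latent
position back through the low-fidelity quantile function,

    Q~_LF(x) = Q_LF( D_LF( F_LF^{-1}( F_HF( E_HF(x) ) ) ) ).

Q~_LF has the same distribution as Q_LF (so the estimator's cost model and
unbiasedness are untouched) but is coupled comonotonically to the
high-fidelity latent variable; under an exact (zero-loss) reduction its
correlation with Q_HF provably never falls below the original one, and the
quantile coupling of the two output distributions gives the ideal ceiling.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, replace

import numpy as np

from .core import NeurAM
from .models import Dataset, InputDistribution, ModelSpec
from .train import NetworkArchitecture, TrainingConfig, train_neuram

__all__ = [
    "EmpiricalCDF",
    "AllocationPlan",
    "MFEstimate",
    "MFStudyResult",
    "build_empirical_cdf",
    "cdf_generalized_inverse",
    "pearson_correlation",
    "optimal_allocation",
    "control_variate_beta",
    "mfmc_estimate",
    "estimator_variance",
    "ideal_correlation",
    "shared_space_lowfi",
    "make_reparameterized_lowfi",
    "idealized_reparameterized",
    "neuram_mf_study",
]


class EmpiricalCDF:
    """Step-function CDF of a sample, with its generalized inverse.

    F(t) = (# values <= t)/N; the generalized inverse F^{-1}(u) =
    inf{t : F(t) >= u} always returns one of the sample atoms, with u = 0
    clamped to the sample minimum.
    """

    def __init__(self, values: np.ndarray):
        values = np.asarray(values, dtype=float).ravel()
        if values.size < 2:
            raise ValueError("an empirical CDF requires at least 2 values")
        if not np.all(np.isfinite(values)):
            raise ValueError("CDF values must be finite")
        self.sorted_values = np.sort(values)
        self.size = values.size

    def __call__(self, t) -> np.ndarray | float:
        f = np.searchsorted(self.sorted_values, np.asarray(t, dtype=float),
                            side="right") / self.size
        return float(f) if np.ndim(t) == 0 else f

    def inverse(self, u) -> np.ndarray | float:
        u_arr = np.asarray(u, dtype=float)
        if np.any(u_arr < 0) or np.any(u_arr > 1):
            raise ValueError("u must lie in [0, 1]")
        # smallest j with (j+1)/N >= u; the tiny slack absorbs float error in
        # u*N when u is itself an atom probability k/N
        idx = np.clip(np.ceil(u_arr * self.size - 1e-9).astype(int) - 1, 0,
                      self.size - 1)
        v = self.sorted_values[idx]
        return float(v) if np.ndim(u) == 0 else v


def build_empirical_cdf(latent_values: np.ndarray) -> EmpiricalCDF:
    return EmpiricalCDF(latent_values)


def cdf_generalized_inverse(cdf: EmpiricalCDF, u):
    return cdf.inverse(u)


def pearson_correlation(a: np.ndarray, b: np.ndarray) -> float:
    a = np.asarray(a, dtype=float).ravel()
    b = np.asarray(b, dtype=float).ravel()
    if a.size != b.size or a.size < 2:
        raise ValueError("arrays must have equal length >= 2")
    sa, sb = a.std(), b.std()
    if sa == 0 or sb == 0:
        raise ValueError("correlation undefined for zero-variance input")
    return float(np.mean((a - a.mean()) * (b - b.mean())) / (sa * sb))


@dataclass
class AllocationPlan:
    """Optimal budget split for the MFMC estimator."""

    w: float
    B: float
    rho: float
    gamma: float
    N_HF: int
    N_LF: int
    beta: float | None = None
    sign_flip: bool = False


def optimal_allocation(w: float, B: float, rho: float,
                       beta: float | None = None) -> AllocationPlan:
    """Solve the MFMC allocation problem for cost ratio w and budget B.

    gamma = sqrt(rho^2 / (w (1 - rho^2))) low-fidelity samples are taken per
    high-fidelity sample; counts are floored.  If rho^2 <= w/(1+w) the
    multifidelity estimator cannot beat plain Monte Carlo — a warning is
    issued but the plan is still returned.
    """
    if not 0 < w < 1:
        raise ValueError("cost ratio w must be in (0, 1)")
    if B <= 0:
        raise ValueError("budget B must be positive")
    r2 = rho * rho
    if r2 >= 1.0:
        raise ValueError("perfect correlation (rho^2 = 1): allocation degenerate")
    if rho == 0.0:
        return AllocationPlan(w=w, B=B, rho=rho, gamma=0.0,
                              N_HF=max(1, int(np.floor(B))), N_LF=0,
                              beta=beta, sign_flip=False)
    if r2 <= w / (1 + w):
        warnings.warn("rho^2 <= w/(1+w): the multifidelity estimator cannot "
                      "improve on single-fidelity Monte Carlo")
    gamma = float(np.sqrt(r2 / (w * (1.0 - r2))))
    N_HF = max(1, int(np.floor(B / (1.0 + w * gamma))))
    N_LF = max(1, int(np.floor(gamma * N_HF)))
    return AllocationPlan(w=w, B=B, rho=float(rho), gamma=gamma, N_HF=N_HF,
                          N_LF=N_LF, beta=beta, sign_flip=bool(rho < 0))


def control_variate_beta(yHF_pilot: np.ndarray, yLF_pilot: np.ndarray) -> float:
    """Optimal control-variate coefficient Cov(HF, LF)/Var(LF) from a pilot."""
    yHF = np.asarray(yHF_pilot, dtype=float).ravel()
    yLF = np.asarray(yLF_pilot, dtype=float).ravel()
    if yHF.size != yLF.size or yHF.size < 2:
        raise ValueError("pilot arrays must be paired with length >= 2")
    v = np.var(yLF, ddof=1)
    if v == 0:
        raise ValueError("low-fidelity pilot has zero variance")
    c = np.cov(yHF, yLF, ddof=1)[0, 1]
    return float(c / v)


@dataclass
class MFEstimate:
    q_hat: float
    variance_formula: float
    rho_used: float
    n_pilot: int | None
    seed: int | None


def _as_fn(model):
    return model.evaluate if isinstance(model, ModelSpec) else model


def mfmc_estimate(hf_model, lowfi_fn, plan: AllocationPlan,
                  dist: InputDistribution, seed, n_pilot: int | None = None
                  ) -> MFEstimate:
    """One realization of the MFMC estimator under an allocation plan.

    Draws the N_LF inputs from `dist`; the N_HF high-fidelity evaluations use
    the *first* N_HF of them (coupled streams, as the control-variate form
    requires).  `plan.beta` must already be estimated (from the pilot); with
    beta = 0 the estimator reduces to the plain high-fidelity mean.
    """
    if plan.beta is None:
        raise ValueError("plan.beta must be set (estimate it from a pilot)")
    if plan.N_HF < 1:
        raise ValueError("plan must allocate at least one HF sample")
    if 0 < plan.N_LF < plan.N_HF:
        raise ValueError("plan requires N_LF >= N_HF")
    hf = _as_fn(hf_model)
    n = max(plan.N_HF, plan.N_LF)
    X = dist.sample(n, seed)
    yHF = hf(X[: plan.N_HF])
    q = float(np.mean(yHF))
    if plan.N_LF > 0 and plan.beta != 0.0:
        yLF = np.asarray(lowfi_fn(X))
        q -= plan.beta * (float(np.mean(yLF[: plan.N_HF])) - float(np.mean(yLF)))
    var_hf = float(np.var(yHF, ddof=1)) if plan.N_HF > 1 else 0.0
    return MFEstimate(
        q_hat=q,
        variance_formula=estimator_variance(var_hf, plan.rho, plan.w, plan.B),
        rho_used=plan.rho,
        n_pilot=n_pilot,
        seed=seed if isinstance(seed, int) else None,
    )


def estimator_variance(varHF: float, rho: float, w: float, B: float) -> float:
    """Predicted MFMC variance (Var Q_HF / B)(sqrt(1-rho^2)+sqrt(w rho^2))^2."""
    if varHF < 0 or B <= 0:
        raise ValueError("varHF must be >= 0 and B > 0")
    r2 = rho * rho
    return varHF / B * (np.sqrt(1.0 - r2) + np.sqrt(w * r2)) ** 2


def ideal_correlation(yHF: np.ndarray, yLF: np.ndarray, n_u: int = 10000) -> float:
    """Correlation of the quantile (comonotone) coupling of the two outputs.

    Pairs the empirical quantile functions on a common uniform grid — the
    maximal correlation attainable by any reparameterization that preserves
    the low-fidelity output distribution, hence the ceiling for the
    shared-space construction.
    """
    if n_u < 100:
        raise ValueError("n_u must be >= 100")
    u = (np.arange(n_u) + 0.5) / n_u
    qh = EmpiricalCDF(yHF).inverse(u)
    ql = EmpiricalCDF(yLF).inverse(u)
    return pearson_correlation(qh, ql)


def shared_space_lowfi(neuram_HF: NeurAM, neuram_LF: NeurAM,
                       cdf_HF: EmpiricalCDF, cdf_LF: EmpiricalCDF,
                       lf_model, x: np.ndarray, sign_flip: bool = False,
                       flip_u: bool = False):
    """Reparameterized low-fidelity value(s) Q~_LF at input(s) x.

    Routes x through the high-fidelity encoder, the shared uniform space, and
    the low-fidelity quantile/decoder chain.  With `sign_flip` the coupling
    was built from -Q_LF (negative pilot correlation) and the sign is applied
    to the model output.  `flip_u` reverses the shared coordinate (u -> 1-u):
    a trained latent axis has an arbitrary orientation (E and -E parameterize
    the same manifold), and the bridge must pair like-oriented quantiles.
    """
    lf = _as_fn(lf_model)
    x2 = np.atleast_2d(np.asarray(x, dtype=float))
    t_hf = neuram_HF.encode(x2)
    u = cdf_HF(t_hf)
    if flip_u:
        u = 1.0 - u
    s = cdf_LF.inverse(u)
    z = neuram_LF.manifold_point(np.atleast_1d(s))
    y = np.asarray(lf(z), dtype=float)
    if sign_flip:
        y = -y
    return float(y[0]) if np.asarray(x).ndim == 1 else y


def make_reparameterized_lowfi(neuram_HF, neuram_LF, cdf_HF, cdf_LF, lf_model,
                               sign_flip: bool = False, flip_u: bool = False):
    """Callable Q~_LF(X) for batched use in estimators."""

    def qtilde(X):
        return shared_space_lowfi(neuram_HF, neuram_LF, cdf_HF, cdf_LF,
                                  lf_model, np.atleast_2d(X),
                                  sign_flip=sign_flip, flip_u=flip_u)

    return qtilde


def idealized_reparameterized(cdf_HF: EmpiricalCDF, cdf_LF: EmpiricalCDF,
                              hf_fn):
    """Q~_LF under the exact zero-loss reduction: F_LF^{-1}(F_HF(Q_HF(x))).

    This is the construction with encoders equal to the models themselves,
    used for the theoretical correlation-improvement guarantee.
    """
    hf = _as_fn(hf_fn)

    def qtilde(X):
        return cdf_LF.inverse(cdf_HF(np.asarray(hf(np.atleast_2d(X)))))

    return qtilde


# ---------------------------------------------------------------------------
# end-to-end study
# ---------------------------------------------------------------------------

@dataclass
class MFStudyResult:
    rho_original: float
    rho_neuram: float
    rho_ideal: float
    plan_standard: AllocationPlan
    plan_neuram: AllocationPlan
    q_standard: np.ndarray
    q_neuram: np.ndarray
    q_mc: np.ndarray
    neuram_HF: NeurAM
    neuram_LF: NeurAM


def neuram_mf_study(hf_model, lf_model, dist: InputDistribution, *,
                    budget: float = 1000.0, w: float = 0.01,
                    n_pilot: int = 1000, repetitions: int = 100, seed: int = 0,
                    arch: NetworkArchitecture = NetworkArchitecture(),
                    config: TrainingConfig | None = None) -> MFStudyResult:
    """Full pipeline: pilot, two NeurAMs, shared space, repeated estimates.

    A single pilot sample of size `n_pilot` is used to train both triples,
    freeze the two latent CDFs, and estimate all correlations and
    control-variate coefficients; pilot cost is not charged against the
    budget.  A negative pilot correlation flips the sign of the low-fidelity
    model before the coupling is built.  Each repetition then draws fresh
    estimation samples for the plain Monte Carlo, standard MFMC, and
    shared-space MFMC estimators.
    """
    hf = _as_fn(hf_model)
    lf = _as_fn(lf_model)
    ss = np.random.SeedSequence(seed)
    s_pilot, s_hf, s_lf, s_reps = ss.spawn(4)

    X_pilot = dist.sample(n_pilot, np.random.default_rng(s_pilot))
    yHF = np.asarray(hf(X_pilot))
    yLF = np.asarray(lf(X_pilot))
    rho0 = pearson_correlation(yHF, yLF)
    sign_flip = rho0 < 0
    lf_eff = (lambda X: -np.asarray(lf(X))) if sign_flip else lf
    yLF_eff = -yLF if sign_flip else yLF

    if config is None:
        config = TrainingConfig()
    nam_hf = train_neuram(
        Dataset(X_pilot, yHF, dist=dist), arch,
        replace(config, seed=int(s_hf.generate_state(1)[0] % 2**31)))
    nam_lf = train_neuram(
        Dataset(X_pilot, yLF_eff, dist=dist), arch,
        replace(config, seed=int(s_lf.generate_state(1)[0] % 2**31)))

    t_hf_pilot = nam_hf.encode(X_pilot)
    t_lf_pilot = nam_lf.encode(X_pilot)
    cdf_hf = EmpiricalCDF(t_hf_pilot)
    cdf_lf = EmpiricalCDF(t_lf_pilot)
    # align each latent axis with its own output before bridging: a trained
    # encoder is only defined up to orientation, and the quantile coupling
    # must pair the low ends of both *output* scales with each other
    orient_hf = pearson_correlation(t_hf_pilot, yHF)
    orient_lf = pearson_correlation(t_lf_pilot, yLF_eff)
    flip_u = (orient_hf < 0) != (orient_lf < 0)
    # with a negative pilot correlation the coupling is built from -Q_LF and
    # that negated model is simply used as *the* low-fidelity model from here
    qtilde = make_reparameterized_lowfi(nam_hf, nam_lf, cdf_hf, cdf_lf, lf_eff,
                                        flip_u=flip_u)
    y_tilde = qtilde(X_pilot)

    rho_neuram = pearson_correlation(yHF, y_tilde)
    rho_ideal = ideal_correlation(yHF, yLF_eff)

    plan_std = optimal_allocation(w, budget, rho0,
                                  beta=control_variate_beta(yHF, yLF))
    plan_neu = optimal_allocation(w, budget, rho_neuram,
                                  beta=control_variate_beta(yHF, y_tilde))
    plan_neu.sign_flip = sign_flip

    reps = s_reps.spawn(repetitions)
    q_std = np.empty(repetitions)
    q_neu = np.empty(repetitions)
    q_mc = np.empty(repetitions)
    n_mc = max(1, int(np.floor(budget)))
    for i, s in enumerate(reps):
        r1, r2, r3 = s.spawn(3)
        q_std[i] = mfmc_estimate(hf, lf, plan_std, dist,
                                 np.random.default_rng(r1)).q_hat
        q_neu[i] = mfmc_estimate(hf, qtilde, plan_neu, dist,
                                 np.random.default_rng(r2)).q_hat
        q_mc[i] = float(np.mean(hf(dist.sample(n_mc, np.random.default_rng(r3)))))

    return MFStudyResult(
        rho_original=rho0, rho_neuram=rho_neuram, rho_ideal=rho_ideal,
        plan_standard=plan_std, plan_neuram=plan_neu,
        q_standard=q_std, q_neuram=q_neu, q_mc=q_mc,
        neuram_HF=nam_hf, neuram_LF=nam_lf,
    )
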