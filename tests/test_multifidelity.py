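"""Empirical CDFs, allocation, control variates, shared-space coupling."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

import neuram as na
from neuram.multifidelity import idealized_reparameterized

EXACT_Q = 25 / 21 * (np.exp(-1) - np.exp(-2 / 5) - np.exp(2 / 5) + np.e)


# --------------------------------------------------------------------------
# empirical CDF and generalized inverse
# --------------------------------------------------------------------------

def test_cdf_counting():
    F = na.EmpiricalCDF([1.0, 2.0, 3.0])
    assert F(2.0) == pytest.approx(2 / 3)
    assert F(3.0) == 1.0
    assert F(0.5) == 0.0


def test_cdf_requires_two_values():
    with pytest.raises(ValueError, match="at least 2"):
        na.EmpiricalCDF([1.0])


def test_cdf_monotone_on_random_grid():
    rng = np.random.default_rng(2)
    F = na.EmpiricalCDF(rng.normal(size=200))
    g = np.sort(rng.uniform(-4, 4, size=500))
    v = F(g)
    assert np.all(np.diff(v) >= 0)


def test_generalized_inverse_examples():
    F = na.EmpiricalCDF([1.0, 2.0, 3.0])
    assert na.cdf_generalized_inverse(F, 0.5) == 2.0
    assert na.cdf_generalized_inverse(F, 1.0) == 3.0
    assert na.cdf_generalized_inverse(F, 0.0) == 1.0
    with pytest.raises(ValueError, match=r"\[0, 1\]"):
        na.cdf_generalized_inverse(F, 1.5)


@settings(derandomize=True, max_examples=60, deadline=None)
@given(st.lists(st.floats(-1e6, 1e6), min_size=2, max_size=40, unique=True))
def test_inverse_roundtrip_on_atoms(values):
    F = na.EmpiricalCDF(values)
    for v in values:
        assert F.inverse(F(v)) == v


# --------------------------------------------------------------------------
# correlation, allocation, beta, variance formula
# --------------------------------------------------------------------------

def test_pearson_basic():
    a = np.random.default_rng(0).normal(size=100)
    assert na.pearson_correlation(a, a) == pytest.approx(1.0)
    assert na.pearson_correlation(a, -a) == pytest.approx(-1.0)
    with pytest.raises(ValueError, match="zero-variance"):
        na.pearson_correlation(a, np.zeros(100))


def test_pearson_exponential_pair_against_bruteforce():
    hf, dist = na.get_model("hf_exp")
    lf, _ = na.get_model("lf_exp")
    X = dist.sample(100_000, seed=6)
    r = na.pearson_correlation(hf.evaluate(X), lf.evaluate(X))
    # independent larger-n Monte Carlo oracle
    Xo = dist.sample(400_000, seed=7)
    ro = np.corrcoef(hf.evaluate(Xo), lf.evaluate(Xo))[0, 1]
    se = (1 - ro**2) / np.sqrt(100_000)
    assert r == pytest.approx(ro, abs=3 * se)
    assert 0 < r < 1


def test_allocation_zero_rho():
    plan = na.optimal_allocation(w=0.01, B=500, rho=0.0)
    assert plan.gamma == 0.0 and plan.N_HF == 500 and plan.N_LF == 0


def test_allocation_formula():
    plan = na.optimal_allocation(w=0.01, B=1000, rho=0.9)
    assert plan.gamma == pytest.approx(np.sqrt(0.81 / (0.01 * 0.19)), rel=1e-12)
    assert plan.N_HF + plan.w * plan.N_LF <= plan.B + 1e-9
    assert plan.N_LF >= plan.N_HF


def test_allocation_warns_when_mf_cannot_win():
    with pytest.warns(UserWarning, match="cannot"):
        plan = na.optimal_allocation(w=0.5, B=100, rho=0.3)
    assert plan.N_HF >= 1


def test_allocation_sign_flip_recorded():
    assert na.optimal_allocation(w=0.01, B=100, rho=-0.8).sign_flip
    with pytest.raises(ValueError, match="perfect correlation"):
        na.optimal_allocation(w=0.01, B=100, rho=1.0)


def test_control_variate_beta_cases():
    rng = np.random.default_rng(3)
    y = rng.normal(size=2000)
    assert na.control_variate_beta(y, y) == pytest.approx(1.0)
    assert na.control_variate_beta(y, 2 * y) == pytest.approx(0.5)
    z = rng.normal(size=2000)
    assert abs(na.control_variate_beta(y, z)) < 0.1
    with pytest.raises(ValueError, match="zero variance"):
        na.control_variate_beta(y, np.ones(2000))


def test_estimator_variance_limits():
    assert na.estimator_variance(2.0, 0.0, 0.01, 100) == pytest.approx(0.02)
    assert na.estimator_variance(2.0, 0.8, 0.0, 100) == pytest.approx(
        2.0 * (1 - 0.64) / 100)


# --------------------------------------------------------------------------
# MFMC estimator algebra and statistics
# --------------------------------------------------------------------------

def test_mfmc_beta_zero_is_plain_mc():
    hf, dist = na.get_model("hf_exp")
    plan = na.AllocationPlan(w=0.01, B=100, rho=0.0, gamma=0.0, N_HF=100,
                             N_LF=0, beta=0.0)
    est = na.mfmc_estimate(hf, hf.evaluate, plan, dist, seed=5)
    X = dist.sample(100, seed=5)
    assert est.q_hat == pytest.approx(float(hf.evaluate(X).mean()))


def test_mfmc_identical_models_beta_one():
    hf, dist = na.get_model("hf_exp")
    plan = na.AllocationPlan(w=0.01, B=100, rho=0.99, gamma=10.0, N_HF=50,
                             N_LF=500, beta=1.0)
    est = na.mfmc_estimate(hf, hf.evaluate, plan, dist, seed=8)
    X = dist.sample(500, seed=8)
    assert est.q_hat == pytest.approx(float(hf.evaluate(X).mean()))


def test_mfmc_mean_matches_analytic_q():
    """Repetition mean of the standard estimator hits the closed-form mean."""
    hf, dist = na.get_model("hf_exp")
    lf, _ = na.get_model("lf_exp")
    Xp = dist.sample(1000, seed=100)
    yh, yl = hf.evaluate(Xp), lf.evaluate(Xp)
    plan = na.optimal_allocation(0.01, 1000, na.pearson_correlation(yh, yl),
                                 beta=na.control_variate_beta(yh, yl))
    qs = np.array([na.mfmc_estimate(hf, lf.evaluate, plan, dist, seed=s).q_hat
                   for s in range(200)])
    se = qs.std(ddof=1) / np.sqrt(len(qs))
    assert qs.mean() == pytest.approx(EXACT_Q, abs=3 * se)

    # predicted variance within 30% of the empirical repetition variance
    var_hf = float(np.var(yh, ddof=1))
    pred = na.estimator_variance(var_hf, plan.rho, plan.w, plan.B)
    emp = qs.var(ddof=1)
    assert pred == pytest.approx(emp, rel=0.3)


# --------------------------------------------------------------------------
# shared space
# --------------------------------------------------------------------------

def test_ideal_correlation_comonotone():
    rng = np.random.default_rng(9)
    y = rng.normal(size=5000)
    assert na.ideal_correlation(y, y, 2000) == pytest.approx(1.0, abs=1e-6)
    # affine increasing transform: quantile coupling is exact, correlation 1
    assert na.ideal_correlation(y, 2.5 * y + 1, 5000) == pytest.approx(
        1.0, abs=1e-6)
    # nonlinear increasing transform: the pairs are already comonotone, so
    # the ideal correlation coincides with the plain one (and cannot be 1)
    g = np.expm1(0.5 * y)
    assert na.ideal_correlation(y, g, 5000) == pytest.approx(
        na.pearson_correlation(y, g), abs=0.01)


def test_ideal_correlation_against_sort_and_pair():
    hf, dist = na.get_model("hf_exp")
    lf, _ = na.get_model("lf_exp")
    X = dist.sample(100_000, seed=11)
    yh, yl = hf.evaluate(X), lf.evaluate(X)
    r = na.ideal_correlation(yh, yl, n_u=10_000)
    oracle = np.corrcoef(np.sort(yh), np.sort(yl))[0, 1]
    assert r == pytest.approx(oracle, abs=0.01)


def test_idealized_reparameterization_collapses_for_identical_models():
    hf, dist = na.get_model("hf_exp")
    X = dist.sample(500, seed=14)
    y = hf.evaluate(X)
    F = na.EmpiricalCDF(y)
    qt = idealized_reparameterized(F, F, hf.evaluate)
    assert np.allclose(qt(X), y)


def test_idealized_correlation_never_decreases():
    """Correlation-improvement guarantee of the exact-reduction coupling,
    on the exponential pair and on monotone-distortion synthetic pairs."""
    hf, dist = na.get_model("hf_exp")
    lf, _ = na.get_model("lf_exp")
    X = dist.sample(10_000, seed=15)
    pairs = [(hf.evaluate(X), lf.evaluate(X))]
    rng = np.random.default_rng(16)
    base = hf.evaluate(X)
    for k in range(5):
        a, b = rng.uniform(0.2, 2.0, size=2)
        noise = rng.normal(scale=0.1 * (k + 1) / 5, size=base.size)
        pairs.append((base, a * base**3 + b * base + noise))
    for yh, yl in pairs:
        rho0 = na.pearson_correlation(yh, yl)
        qt = idealized_reparameterized(na.EmpiricalCDF(yh),
                                       na.EmpiricalCDF(yl), lambda _: yh)
        yt = qt(np.zeros((yh.size, 2)))
        rho_new = na.pearson_correlation(yh, yt)
        assert rho_new >= rho0 - 0.01


def test_distribution_preservation():
    """The reparameterized low-fidelity outputs keep the original output
    distribution (mean and variance within Monte Carlo error)."""
    hf, dist = na.get_model("hf_exp")
    lf, _ = na.get_model("lf_exp")
    Xp = dist.sample(4000, seed=18)
    F_hf = na.EmpiricalCDF(hf.evaluate(Xp))
    F_lf = na.EmpiricalCDF(lf.evaluate(Xp))
    qt = idealized_reparameterized(F_hf, F_lf, hf.evaluate)
    X = dist.sample(10_000, seed=19)
    yt = qt(X)
    yl = lf.evaluate(X)
    n = yl.size
    se_mean = yl.std() / np.sqrt(n)
    assert yt.mean() == pytest.approx(yl.mean(), abs=3 * se_mean)
    se_var = np.var(yl) * np.sqrt(2 / n) * 3  # ~3 SE for the variance
    assert np.var(yt) == pytest.approx(np.var(yl), abs=3 * se_var)


def test_shared_space_identical_fidelities(analytic_triple, parabolic_batch):
    """With equal models, NeurAMs, and CDFs the bridge reduces to the plain
    manifold projection value Q(D(E(x)))."""
    spec, _ = na.get_model("parabolic")
    t = analytic_triple.encode(parabolic_batch.inputs)
    F = na.EmpiricalCDF(t)
    y = na.shared_space_lowfi(analytic_triple, analytic_triple, F, F,
                              spec, parabolic_batch.inputs)
    y_direct = spec.evaluate(analytic_triple.project(parabolic_batch.inputs))
    assert np.allclose(y, y_direct)
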