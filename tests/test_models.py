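"""Benchmark model registry, samplers, normalization, datasets."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy import stats

import neuram as na


@pytest.mark.parametrize("name,x,expected", [
    ("parabolic", [1.0, 1.0], 2.0),
    ("sine_parabolic", [0.0, 0.0], 0.0),
    ("q2", [0.5, -0.5], 0.5),
    ("q3", [1.0, 1.0], 2.8),
    ("hf_exp", [0.0, 0.0], 1.0),
])
def test_model_values(name, x, expected):
    spec, _ = na.get_model(name)
    assert na.evaluate_model(spec, np.array(x)) == pytest.approx(expected)


def test_hartmann_u_matches_high_precision_closed_form():
    """Independent oracle: evaluate the coth formula with sympy mpmath."""
    import sympy as sp

    mu, eta, dpdx, B0 = sp.Rational(1, 10), 1, 1, sp.Rational(1, 2)
    z = B0 / sp.sqrt(eta * mu)
    expected = float((-dpdx * eta / B0**2 * (1 - z * sp.coth(z))).evalf(30))
    spec, _ = na.get_model("hartmann_u")
    got = na.evaluate_model(spec, np.array([0.1, 2.0, 1.0, 1.0, 0.5]))
    assert got == pytest.approx(expected, rel=1e-12)
    # the density (second coordinate) is inert
    got2 = na.evaluate_model(spec, np.array([0.1, 4.7, 1.0, 1.0, 0.5]))
    assert got2 == got


def test_hartmann_b_matches_high_precision_closed_form():
    import sympy as sp

    mu, eta, dpdx, B0 = sp.Rational(1, 5), 3, 2, 1
    z = B0 / sp.sqrt(eta * mu)
    expected = float((dpdx / (2 * B0) * (1 - (2 / z) * sp.tanh(z / 2))).evalf(30))
    spec, _ = na.get_model("hartmann_b")
    got = na.evaluate_model(spec, np.array([0.2, 1.0, 2.0, 3.0, 1.0]))
    assert got == pytest.approx(expected, rel=1e-12)


def test_evaluate_outside_box_raises():
    spec, _ = na.get_model("parabolic")
    with pytest.raises(ValueError, match="outside"):
        na.evaluate_model(spec, np.array([1.5, 0.5]))


def test_unknown_model_raises():
    with pytest.raises(KeyError, match="unknown model"):
        na.get_model("nope")


def test_sample_containment_and_empty():
    _, dist = na.get_model("parabolic")
    X = na.sample_inputs(dist, 100, seed=4)
    assert X.shape == (100, 2)
    assert np.all(X >= 0) and np.all(X <= 1)
    assert na.sample_inputs(dist, 0, seed=4).shape == (0, 2)


def test_loguniform_sampler_ks():
    """log of log-uniform draws is uniform (KS below the 1% critical value)."""
    dist = na.InputDistribution(kinds=("loguniform",), lo=[0.05], hi=[0.2])
    X = na.sample_inputs(dist, 10_000, seed=8)[:, 0]
    u = (np.log(X) - np.log(0.05)) / (np.log(0.2) - np.log(0.05))
    ks = stats.kstest(u, "uniform").statistic
    assert ks < 1.63 / np.sqrt(10_000)  # 1% critical value


def test_loguniform_requires_positive_lower_bound():
    with pytest.raises(ValueError, match="lo > 0"):
        na.InputDistribution(kinds=("loguniform",), lo=[0.0], hi=[1.0])


def test_normalization_midpoints():
    _, dist = na.get_model("parabolic")
    assert dist.normalize([[0.5, 0.5]])[0, 0] == pytest.approx(0.0)
    dlog = na.InputDistribution(kinds=("loguniform",), lo=[0.05], hi=[0.2])
    assert dlog.normalize([[0.1]])[0, 0] == pytest.approx(0.0)  # geometric mean


@settings(derandomize=True, max_examples=50, deadline=None)
@given(st.lists(st.floats(0.01, 0.99), min_size=2, max_size=5),
       st.booleans())
def test_normalization_roundtrip(fracs, log):
    d = len(fracs)
    lo = np.full(d, 0.05)
    hi = np.full(d, 2.0)
    kinds = ("loguniform",) * d if log else ("uniform",) * d
    dist = na.InputDistribution(kinds=kinds, lo=lo, hi=hi)
    x = (lo + np.array(fracs) * (hi - lo))[None, :]
    back = dist.denormalize(dist.normalize(x))
    assert np.allclose(back, x, rtol=1e-12, atol=1e-12)
    z = dist.normalize(x)
    assert np.all(z >= -1) and np.all(z <= 1)


def test_sampler_moments_converge():
    """Empirical mean at n=1e5 is within 4 standard errors of the analytic
    mean, for both uniform and log-uniform coordinates."""
    dist = na.InputDistribution(kinds=("uniform", "loguniform"),
                                lo=[0.0, 0.05], hi=[2.0, 0.2])
    X = na.sample_inputs(dist, 100_000, seed=12)
    # uniform on [0,2]: mean 1, var 1/3
    se0 = np.sqrt(1 / 3 / 100_000)
    assert abs(X[:, 0].mean() - 1.0) < 4 * se0
    # log-uniform on [a,b]: mean (b-a)/log(b/a)
    a, b = 0.05, 0.2
    m = (b - a) / np.log(b / a)
    se1 = X[:, 1].std() / np.sqrt(100_000)
    assert abs(X[:, 1].mean() - m) < 4 * se1


def test_make_dataset_determinism_and_consistency():
    spec, dist = na.get_model("parabolic")
    d1 = na.make_dataset(spec, dist, 5, seed=3)
    d2 = na.make_dataset(spec, dist, 5, seed=3)
    assert np.array_equal(d1.inputs, d2.inputs)
    assert np.array_equal(d1.outputs, d2.outputs)
    assert np.allclose(d1.outputs, spec.evaluate(d1.inputs))


def test_model_evaluation_is_pure():
    spec, dist = na.get_model("hartmann_b")
    x = na.sample_inputs(dist, 3, seed=0)
    assert np.array_equal(spec.evaluate(x), spec.evaluate(x))
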