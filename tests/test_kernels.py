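"""Kernel families, correlation matrices and Gaussian kernel expectations."""

import json

import numpy as np
import pytest
import scipy.integrate
from hypothesis import given, settings, strategies as st
from scipy.stats import norm

from dgpimpute.kernels import (KernelSpec, correlation_matrix, cross_correlation,
                               expectation_I, expectation_J, kernel_eval)

FAMILIES = ["squared_exponential", "matern_2_5"]


def _k(family, x, w, gamma):
    h = np.abs(x - w)
    if family == "squared_exponential":
        return np.exp(-h ** 2 / gamma ** 2)
    s = np.sqrt(5.0) * h / gamma
    return (1 + s + s * s / 3) * np.exp(-s)


def quad_oracle_I(family, gamma, mu, var, w):
    """Independent adaptive-quadrature evaluation of E[k(W, w)], W ~ N(mu, var)."""
    sd = np.sqrt(var)
    val, _ = scipy.integrate.quad(
        lambda x: norm.pdf(x, mu, sd) * _k(family, x, w, gamma),
        mu - 12 * sd, mu + 12 * sd,
        points=[w] if mu - 12 * sd < w < mu + 12 * sd else None,
        limit=200, epsabs=1e-12, epsrel=1e-12)
    return val


def quad_oracle_J(family, gamma, mu, var, wi, wj):
    sd = np.sqrt(var)
    pts = [w for w in (wi, wj) if mu - 12 * sd < w < mu + 12 * sd]
    val, _ = scipy.integrate.quad(
        lambda x: (norm.pdf(x, mu, sd) * _k(family, x, wi, gamma)
                   * _k(family, x, wj, gamma)),
        mu - 12 * sd, mu + 12 * sd, points=pts or None,
        limit=200, epsabs=1e-12, epsrel=1e-12)
    return val


@pytest.mark.parametrize("family", FAMILIES)
def test_kernel_is_correlation(family):
    spec = KernelSpec(family, [1.3, 0.7])
    a = np.array([0.2, -1.0])
    assert kernel_eval(spec, a, a) == 1.0
    b = np.array([1.5, 0.3])
    v = kernel_eval(spec, a, b)
    assert 0 < v < 1
    assert v == pytest.approx(kernel_eval(spec, b, a))
    # stationary decay
    assert kernel_eval(spec, a, a + np.array([60.0, 0.0])) < 1e-8


def test_kernel_product_over_dimensions():
    # 2-D value equals the product of independent 1-D evaluations
    spec2 = KernelSpec("squared_exponential", [1.5, 0.6])
    a, b = np.array([0.3, 1.1]), np.array([-0.4, 0.8])
    k1 = np.exp(-((a[0] - b[0]) ** 2) / 1.5 ** 2)
    k2 = np.exp(-((a[1] - b[1]) ** 2) / 0.6 ** 2)
    assert kernel_eval(spec2, a, b) == pytest.approx(k1 * k2, abs=1e-15)


def test_kernel_dimension_mismatch():
    spec = KernelSpec("squared_exponential", [1.0, 1.0])
    with pytest.raises(ValueError):
        kernel_eval(spec, [0.0], [0.0, 1.0])


def test_correlation_matrix_small_cases():
    spec = KernelSpec("squared_exponential", [2.0], nugget=0.1)
    assert correlation_matrix(spec, [[0.5]]) == pytest.approx(
        np.array([[1.1]]))
    # identical points, zero nugget: rank-1 all-ones
    spec0 = KernelSpec("squared_exponential", [2.0], nugget=0.0)
    R = correlation_matrix(spec0, [[1.0], [1.0], [1.0]])
    assert R == pytest.approx(np.ones((3, 3)))
    # elementwise oracle on distinct points
    X = np.array([[0.0], [1.0], [3.0]])
    R = correlation_matrix(spec, X)
    for i in range(3):
        for j in range(3):
            expect = kernel_eval(spec, X[i], X[j]) + (0.1 if i == j else 0.0)
            assert R[i, j] == pytest.approx(expect, abs=1e-15)


@settings(max_examples=30, deadline=None, derandomize=True)
@given(st.integers(0, 10_000), st.sampled_from(FAMILIES))
def test_correlation_matrix_is_spd(seed, family):
    rng = np.random.default_rng(seed)
    n, d = rng.integers(2, 12), rng.integers(1, 4)
    X = rng.normal(size=(n, d)) * 3
    spec = KernelSpec(family, rng.uniform(0.3, 3.0, size=d), nugget=1e-8)
    R = correlation_matrix(spec, X)
    assert np.allclose(R, R.T)
    assert np.allclose(np.diag(R), 1 + 1e-8)
    np.linalg.cholesky(R)  # succeeds iff PD


@pytest.mark.parametrize("family", FAMILIES)
def test_expectation_var_zero_collapses_to_kernel(family):
    spec = KernelSpec(family, [1.1])
    mu, w, wj = 0.4, 1.3, -0.5
    assert expectation_I(spec, mu, 0.0, w) == pytest.approx(
        kernel_eval(spec, [mu], [w]), abs=1e-15)
    assert expectation_J(spec, mu, 0.0, w, wj) == pytest.approx(
        kernel_eval(spec, [mu], [w]) * kernel_eval(spec, [mu], [wj]), abs=1e-15)
    assert expectation_J(spec, mu, 0.0, w, w) == pytest.approx(
        kernel_eval(spec, [mu], [w]) ** 2, abs=1e-15)


def test_expectation_I_limits_and_monotonicity():
    spec = KernelSpec("squared_exponential", [1.0])
    vals = [expectation_I(spec, 0.3, v, 1.0) for v in [0.0, 0.5, 2.0, 10.0]]
    assert all(a > b for a, b in zip(vals, vals[1:]))  # non-increasing in var
    assert expectation_I(spec, 0.3, 1e8, 1.0) < 1e-3   # mass escapes
    with pytest.raises(ValueError):
        expectation_I(spec, 0.0, -0.1, 1.0)
    with pytest.raises(ValueError):
        expectation_J(spec, 0.0, -0.1, 1.0, 2.0)


@settings(max_examples=80, deadline=None, derandomize=True)
@given(st.integers(0, 10_000), st.sampled_from(FAMILIES))
def test_expectations_match_quadrature_oracle(seed, family):
    rng = np.random.default_rng(seed)
    gamma = rng.uniform(0.3, 3.0)
    mu, var = rng.normal(0, 2), rng.uniform(0, 3)
    wi, wj = rng.normal(0, 2, size=2)
    spec = KernelSpec(family, [gamma])
    assert expectation_I(spec, mu, var, wi) == pytest.approx(
        quad_oracle_I(family, gamma, mu, var, wi), abs=1e-8)
    J = expectation_J(spec, mu, var, wi, wj)
    assert J == pytest.approx(quad_oracle_J(family, gamma, mu, var, wi, wj),
                              abs=1e-8)
    # symmetry and the Cauchy-Schwarz bound J(w, w) >= I(w)^2
    assert J == pytest.approx(expectation_J(spec, mu, var, wj, wi), abs=1e-12)
    assert expectation_J(spec, mu, var, wi, wi) >= \
        expectation_I(spec, mu, var, wi) ** 2 - 1e-12


def test_cross_correlation_matches_elementwise():
    spec = KernelSpec("matern_2_5", [1.2, 2.0])
    rng = np.random.default_rng(5)
    A, B = rng.normal(size=(4, 2)), rng.normal(size=(3, 2))
    C = cross_correlation(spec, A, B)
    for i in range(4):
        for j in range(3):
            assert C[i, j] == pytest.approx(kernel_eval(spec, A[i], B[j]),
                                            abs=1e-14)


def test_kernelspec_validation_and_json_roundtrip():
    with pytest.raises(ValueError):
        KernelSpec("squared_exponential", [-1.0])
    with pytest.raises(ValueError):
        KernelSpec("squared_exponential", [1.0], scale=0.0)
    with pytest.raises(ValueError):
        KernelSpec("squared_exponential", [1.0], nugget=-0.1)
    with pytest.raises(ValueError):
        KernelSpec("periodic", [1.0])
    spec = KernelSpec("matern_2_5", [1.0, 2.5], scale=0.7, nugget=1e-4)
    back = KernelSpec.from_json(spec.to_json())
    assert back.family == spec.family
    assert np.array_equal(back.lengthscales, spec.lengthscales)
    assert (back.scale, back.nugget) == (spec.scale, spec.nugget)
    assert set(json.loads(spec.to_json())) == {
        "family", "lengthscales", "scale", "nugget"}
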