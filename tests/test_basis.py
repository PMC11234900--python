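"""B-spline systems: evaluation, inner products, penalties, smoothing."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy.integrate import quad

from cropfda import (
    BasisSystem,
    constant_basis,
    eval_basis,
    gram_matrix,
    penalty_matrix,
    select_rho_gcv,
    smooth_to_functional,
)
from cropfda.basis import DomainError, SingularFitError


@given(st.floats(0.0, 60.0))
@settings(max_examples=50, deadline=None)
def test_partition_of_unity(u):
    b = BasisSystem((0.0, 60.0), n_basis=10)
    row = eval_basis(b, np.array([u]))[0]
    assert abs(row.sum() - 1.0) < 1e-10


@given(st.floats(0.5, 59.5))
@settings(max_examples=50, deadline=None)
def test_derivative_rows_sum_to_zero(u):
    b = BasisSystem((0.0, 60.0), n_basis=10)
    row = eval_basis(b, np.array([u]), deriv=1)[0]
    assert abs(row.sum()) < 1e-9


def test_constant_basis_is_one_everywhere():
    b = constant_basis((0.0, 300.0))
    pts = np.array([0.0, 7.3, 299.999, 300.0])
    assert np.allclose(eval_basis(b, pts), 1.0)
    assert np.allclose(eval_basis(b, pts, deriv=1), 0.0)


def test_out_of_domain_point_raises():
    b = BasisSystem((0.0, 60.0), n_basis=6)
    with pytest.raises(DomainError):
        eval_basis(b, np.array([61.0]))


def test_gram_constant_basis_unit_interval():
    b = constant_basis((0.0, 1.0))
    assert np.allclose(gram_matrix(b), [[1.0]])


def test_gram_matches_adaptive_quadrature():
    """Gauss–Legendre Gram entries agree with scipy adaptive integration."""
    b = BasisSystem((0.0, 10.0), n_basis=6)
    G = gram_matrix(b)
    pts = list(b.breakpoints)
    for m in range(b.n_basis):
        for k in range(m, b.n_basis):
            f = lambda u: (
                eval_basis(b, np.array([u]))[0, m]
                * eval_basis(b, np.array([u]))[0, k]
            )
            val, _ = quad(f, 0.0, 10.0, points=pts, limit=200)
            assert abs(G[m, k] - val) < 1e-8


def test_gram_transpose_symmetry():
    a = BasisSystem((0.0, 10.0), n_basis=7)
    b = BasisSystem((0.0, 10.0), n_basis=5)
    assert np.allclose(gram_matrix(a, b), gram_matrix(b, a).T)


def test_gram_domain_mismatch_raises():
    a = BasisSystem((0.0, 10.0), n_basis=5)
    b = BasisSystem((0.0, 20.0), n_basis=5)
    with pytest.raises(DomainError):
        gram_matrix(a, b)


def _coefs_reproducing(basis, func):
    """Least-squares coefficients reproducing an in-space function exactly."""
    u = np.linspace(*basis.domain, 200)
    Phi = eval_basis(basis, u)
    return np.linalg.lstsq(Phi, func(u), rcond=None)[0]


def test_penalty_null_space_constants_and_lines():
    b = BasisSystem((0.0, 60.0), n_basis=8)
    P = penalty_matrix(b)
    c1 = _coefs_reproducing(b, lambda u: np.ones_like(u))
    cu = _coefs_reproducing(b, lambda u: u)
    assert abs(c1 @ P @ c1) < 1e-8
    assert abs(cu @ P @ cu) < 1e-8


def test_penalty_quadratic_energy():
    """f(u)=u² on [0,1] has second-derivative energy ∫2² du = 4."""
    b = BasisSystem((0.0, 1.0), n_basis=8)
    c = _coefs_reproducing(b, lambda u: u**2)
    P = penalty_matrix(b)
    assert abs(c @ P @ c - 4.0) < 1e-6


def test_penalty_requires_enough_smoothness():
    with pytest.raises(ValueError):
        penalty_matrix(BasisSystem((0.0, 1.0), n_basis=2, order=2))


def test_smoothing_preserves_constants():
    b = BasisSystem((0.0, 60.0), n_basis=8)
    s = np.linspace(0.25, 59.75, 120)
    for rho in (0.0, 1.0, 1e6):
        fd = smooth_to_functional(s, np.full(120, 3.5), b, rho=rho)
        assert np.allclose(fd(s), 3.5, atol=1e-6)


def test_smoothing_large_rho_is_best_line():
    b = BasisSystem((0.0, 10.0), n_basis=8)
    s = np.linspace(0.0, 10.0, 200)
    v = np.sin(s)
    fd = smooth_to_functional(s, v, b, rho=1e12)
    coef = np.polyfit(s, v, 1)
    assert np.allclose(fd(s), np.polyval(coef, s), atol=1e-4)


def test_smoothing_matches_ridge_oracle():
    """Penalized smoothing equals an independently assembled ridge solve."""
    rng = np.random.default_rng(3)
    b = BasisSystem((0.0, 60.0), n_basis=10)
    s = np.linspace(0.02, 59.98, 500)
    v = np.sin(s / 8) + rng.normal(0, 0.3, s.size)
    rho = 2.5
    fd = smooth_to_functional(s, v, b, rho=rho)
    Phi = eval_basis(b, s)
    P = penalty_matrix(b)
    oracle = np.linalg.solve(Phi.T @ Phi + rho * P, Phi.T @ v)
    assert np.allclose(fd.coefficients, oracle, rtol=1e-8, atol=1e-10)


def test_smoothing_is_linear_in_data():
    rng = np.random.default_rng(4)
    b = BasisSystem((0.0, 60.0), n_basis=8)
    s = np.linspace(0.1, 59.9, 240)
    w1, w2 = rng.normal(size=240), rng.normal(size=240)
    c12 = smooth_to_functional(s, w1 + w2, b, rho=1.0).coefficients
    c1 = smooth_to_functional(s, w1, b, rho=1.0).coefficients
    c2 = smooth_to_functional(s, w2, b, rho=1.0).coefficients
    assert np.allclose(c12, c1 + c2, atol=1e-10)


def test_smoothing_skips_missing_cells():
    b = BasisSystem((0.0, 60.0), n_basis=6)
    s = np.linspace(0.1, 59.9, 100)
    v = np.full(100, 2.0)
    v[10:20] = np.nan
    fd = smooth_to_functional(s, v, b, rho=0.5)
    assert np.allclose(fd(s), 2.0, atol=1e-8)


def test_smoothing_insufficient_data_raises():
    b = BasisSystem((0.0, 60.0), n_basis=6)
    s = np.linspace(0.0, 60.0, 4)
    with pytest.raises(SingularFitError):
        smooth_to_functional(s, np.ones(4), b, rho=0.0)


def test_rho_gcv_prefers_smooth_fit_for_noise():
    rng = np.random.default_rng(5)
    b = BasisSystem((0.0, 60.0), n_basis=10)
    s = np.linspace(0.02, 59.98, 400)
    pure_noise = rng.normal(0, 1, s.size)
    rho_noise = select_rho_gcv(s, pure_noise, b)
    smooth_signal = np.sin(s / 20)
    rho_signal = select_rho_gcv(s, smooth_signal, b)
    assert rho_noise >= rho_signal
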