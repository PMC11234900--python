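"""The penalized tensor-product estimator and its baseline special case."""

import numpy as np
import pytest

from cropfda import (
    BasisSystem,
    FunctionalDatum,
    FunctionalSample,
    VCFRMSpec,
    assemble_penalty,
    build_design,
    constant_basis,
    eval_basis,
    fit,
    gram_matrix,
    objective,
    predict,
    resolve_spec,
    seasonal_intercept,
    surface_grid,
)
from cropfda.model import ExtrapolationError
from tests.conftest import random_functional_samples


def test_design_constant_bases_integrates_constant():
    """J=1, constant bases, x ≡ c on [0, L]: the single design entry is c·L."""
    L = 40.0
    sb = constant_basis((0.0, L))
    tb = constant_basis((0.0, 300.0))
    spec = VCFRMSpec(J=1, s_basis=sb, t_basis=tb)
    smp = FunctionalSample(1, 150.0, [FunctionalDatum(0, np.array([2.5]), sb)], 1.0)
    Z, y = build_design([smp], spec)
    assert Z.shape == (1, 1)
    assert np.isclose(Z[0, 0], 2.5 * L)


def test_design_matches_trapezoid_quadrature(small_bases, rng):
    """Z·vec(B) equals direct quadrature of ∫x(s)β(s,t_i)ds."""
    sb, tb = small_bases
    spec = VCFRMSpec(J=2, s_basis=sb, t_basis=tb)
    samples = random_functional_samples(rng, sb, tb, n=8)
    Z, _ = build_design(samples, spec)
    b = rng.normal(0, 1, spec.n_params)
    sg = np.linspace(*sb.domain, 24001)
    Phi = eval_basis(sb, sg)
    for i, smp in enumerate(samples):
        want = 0.0
        Psi_t = eval_basis(tb, np.array([smp.t]))[0]
        for j in range(2):
            B = b[j * 30 : (j + 1) * 30].reshape(6, 5)
            x = Phi @ smp.x[j].coefficients
            beta = Phi @ B @ Psi_t
            want += np.trapezoid(x * beta, sg)
        got = Z[i] @ b
        assert abs(got - want) < 1e-6 * max(1.0, abs(want))


def test_frm_design_dimensions(small_bases, fsamples):
    sb, tb = small_bases
    spec = VCFRMSpec(J=2, s_basis=sb, t_basis=tb, model_kind="constant-in-t")
    Z, _ = build_design(fsamples, spec)
    assert Z.shape == (len(fsamples), 2 * sb.n_basis)


def test_penalty_zero_lambdas_is_zero(small_bases):
    sb, tb = small_bases
    spec = VCFRMSpec(J=2, s_basis=sb, t_basis=tb, lambda_s=0.0, lambda_t=0.0)
    assert not assemble_penalty(spec).any()


def _surface_coefs(sb, tb, func):
    sg = np.linspace(*sb.domain, 120)
    tg = np.linspace(*tb.domain, 120)
    Phi, Psi = eval_basis(sb, sg), eval_basis(tb, tg)
    T = func(sg[:, None], tg[None, :])
    B = np.linalg.lstsq(Phi, np.linalg.lstsq(Psi, T.T, rcond=None)[0].T, rcond=None)[0]
    return B


def test_penalty_annihilates_bilinear_surfaces(small_bases):
    sb, tb = small_bases
    spec = VCFRMSpec(J=1, s_basis=sb, t_basis=tb, lambda_s=1.0, lambda_t=1.0)
    Lam = assemble_penalty(spec)
    B = _surface_coefs(sb, tb, lambda s, t: 1.0 + 0.2 * s - 0.05 * t + 0.01 * s * t)
    v = B.ravel()
    assert abs(v @ Lam @ v) < 1e-8 * (1 + v @ v)


def test_penalty_matches_2d_quadrature_oracle(small_bases):
    """Penalty quadratic form equals ∫∫ λ_s β_ss² + λ_t β_tt² by 2-D quadrature."""
    sb, tb = small_bases
    ls, lt = 2.0, 3.0
    spec = VCFRMSpec(J=1, s_basis=sb, t_basis=tb, lambda_s=ls, lambda_t=lt)
    Lam = assemble_penalty(spec)
    B = _surface_coefs(sb, tb, lambda s, t: 0.01 * s**2 * (1 + t / 300.0) + 0.002 * t**2)
    v = B.ravel()
    got = v @ Lam @ v
    sg = np.linspace(*sb.domain, 601)
    tg = np.linspace(*tb.domain, 601)
    d2s = eval_basis(sb, sg, deriv=2) @ B @ eval_basis(tb, tg).T
    d2t = eval_basis(sb, sg) @ B @ eval_basis(tb, tg, deriv=2).T
    want = ls * np.trapezoid(np.trapezoid(d2s**2, tg, axis=1), sg) + lt * np.trapezoid(
        np.trapezoid(d2t**2, tg, axis=1), sg
    )
    assert abs(got - want) < 1e-4 * max(1.0, want)


def test_fit_interpolates_square_system(small_bases, rng):
    """λ=0 with n equal to the parameter count reproduces y exactly."""
    sb, tb = small_bases
    spec = VCFRMSpec(J=1, s_basis=sb, t_basis=tb, lambda_s=0.0, lambda_t=0.0)
    samples = random_functional_samples(rng, sb, tb, n=sb.n_basis * tb.n_basis, J=1)
    f = fit(samples, spec)
    assert f.rss < 1e-8 * max(1.0, sum(s.y**2 for s in samples))


def test_fit_minimizes_objective(small_bases, fsamples, rng):
    """The solution beats 100 random perturbations on the explicit objective."""
    sb, tb = small_bases
    spec = VCFRMSpec(J=2, s_basis=sb, t_basis=tb, lambda_s=1.0, lambda_t=5.0)
    f = fit(fsamples, spec)
    base = objective(fsamples, spec, f.coef)
    for _ in range(100):
        pert = f.coef + rng.normal(0, 0.05, f.coef.size)
        assert objective(fsamples, spec, pert) >= base - 1e-9 * abs(base)


def test_fit_deterministic(small_bases, fsamples):
    sb, tb = small_bases
    spec = VCFRMSpec(J=2, s_basis=sb, t_basis=tb, lambda_s=1.0, lambda_t=1.0)
    a, b = fit(fsamples, spec), fit(fsamples, spec)
    assert np.array_equal(a.coef, b.coef)
    assert a.edf == b.edf and a.rss == b.rss


def test_predict_training_set_reproduces_fitted_values(small_bases, fsamples):
    sb, tb = small_bases
    spec = VCFRMSpec(J=2, s_basis=sb, t_basis=tb, lambda_s=0.5, lambda_t=0.5)
    f = fit(fsamples, spec)
    Z, _ = build_design(fsamples, spec)
    assert np.allclose(predict(f, fsamples), Z @ f.coef)


def test_predict_zero_surfaces_returns_mean(small_bases, fsamples):
    from cropfda import CenteringInfo

    sb, tb = small_bases
    spec = VCFRMSpec(J=2, s_basis=sb, t_basis=tb, lambda_s=1.0, lambda_t=1.0)
    f = fit(fsamples, spec, centering=CenteringInfo(42.0, []))
    f.coef = np.zeros_like(f.coef)
    assert np.allclose(predict(f, fsamples), 42.0)


def test_predict_rejects_extrapolation(small_bases, fsamples):
    sb, tb = small_bases
    spec = VCFRMSpec(J=2, s_basis=sb, t_basis=tb, lambda_s=1.0, lambda_t=1.0)
    f = fit(fsamples, spec)
    bad = [
        FunctionalSample(99, tb.domain[1] + 50.0, fsamples[0].x, 0.0)
    ]
    with pytest.raises(ExtrapolationError):
        predict(f, bad)


def test_surface_grid_frm_columns_identical(small_bases, fsamples):
    sb, tb = small_bases
    spec = VCFRMSpec(J=2, s_basis=sb, t_basis=tb, lambda_s=1.0, model_kind="constant-in-t")
    f = fit(fsamples, spec)
    M = surface_grid(f, 0, np.linspace(0, 60, 13), np.linspace(0, 300, 7))
    assert np.allclose(M, M[:, [0]])


def test_surface_grid_matches_pointwise_products(small_bases, fsamples):
    sb, tb = small_bases
    spec = VCFRMSpec(J=2, s_basis=sb, t_basis=tb, lambda_s=1.0, lambda_t=1.0)
    f = fit(fsamples, spec)
    s_grid, t_grid = np.linspace(5, 55, 9), np.linspace(10, 290, 8)
    M = surface_grid(f, 1, s_grid, t_grid)
    B = f.surfaces[1].B
    for a, s in enumerate(s_grid):
        for b, t in enumerate(t_grid):
            want = eval_basis(sb, [s])[0] @ B @ eval_basis(tb, [t])[0]
            assert abs(M[a, b] - want) < 1e-12


def test_rss_and_edf_monotone_in_lambda(small_bases, fsamples):
    sb, tb = small_bases
    rss_prev, edf_prev = -np.inf, np.inf
    for lam in [1e-3, 1e-1, 10.0, 1e3, 1e5, 1e7]:
        spec = VCFRMSpec(J=2, s_basis=sb, t_basis=tb, lambda_s=lam, lambda_t=lam)
        f = fit(fsamples, spec)
        assert f.rss >= rss_prev - 1e-9
        assert f.edf <= edf_prev + 1e-9
        rss_prev, edf_prev = f.rss, f.edf


def test_frm_objective_dominates_vcfrm(small_bases, fsamples):
    """The t-constant model lives inside the varying model's search space."""
    sb, tb = small_bases
    lam = 2.0
    vc = VCFRMSpec(J=2, s_basis=sb, t_basis=tb, lambda_s=lam, lambda_t=0.0)
    fr = VCFRMSpec(J=2, s_basis=sb, t_basis=tb, lambda_s=lam, model_kind="constant-in-t")
    f_vc, f_fr = fit(fsamples, vc), fit(fsamples, fr)
    obj_vc = objective(fsamples, vc, f_vc.coef)
    obj_fr = objective(fsamples, fr, f_fr.coef)
    assert obj_vc <= obj_fr + 1e-9 * abs(obj_fr)


def test_scaling_equivariance(small_bases, fsamples):
    """Scaling predictor j by a (and its λ by a²) scales β̂_j by 1/a."""
    from dataclasses import replace

    sb, tb = small_bases
    a = 3.0
    spec = VCFRMSpec(J=2, s_basis=sb, t_basis=tb, lambda_s=[2.0, 2.0], lambda_t=[1.0, 1.0])
    f = fit(fsamples, spec)
    scaled = [
        replace(
            s,
            x=[FunctionalDatum(0, s.x[0].coefficients * a, sb), s.x[1]],
        )
        for s in fsamples
    ]
    spec2 = VCFRMSpec(
        J=2, s_basis=sb, t_basis=tb,
        lambda_s=[2.0 * a**2, 2.0], lambda_t=[1.0 * a**2, 1.0],
    )
    f2 = fit(scaled, spec2)
    assert np.allclose(f2.surfaces[0].B, f.surfaces[0].B / a, rtol=1e-6, atol=1e-10)
    assert np.allclose(f2.surfaces[1].B, f.surfaces[1].B, rtol=1e-6, atol=1e-10)
    assert np.allclose(predict(f2, scaled), predict(f, fsamples), rtol=1e-8)


def test_recovery_on_noiseless_synthetic(small_bases, rng):
    """Generous basis, tiny λ, no noise: predictions within 1% of truth."""
    sb, tb = small_bases
    samples = random_functional_samples(rng, sb, tb, n=60, noise=0.0)
    spec = VCFRMSpec(J=2, s_basis=sb, t_basis=tb, lambda_s=1e-8, lambda_t=1e-8)
    f = fit(samples, spec)
    pred = predict(f, samples)
    truth = np.array([s.y for s in samples])
    scale = np.std(truth)
    assert np.max(np.abs(pred - truth)) < 0.01 * scale


def test_intercept_absent_evaluates_to_zero(small_bases, fsamples):
    sb, tb = small_bases
    spec = VCFRMSpec(J=2, s_basis=sb, t_basis=tb, lambda_s=1.0, lambda_t=1.0)
    f = fit(fsamples, spec)
    assert not seasonal_intercept(f, np.linspace(0, 300, 5)).any()


def test_resolve_spec_infinite_lambda_t_is_frm(small_bases):
    sb, tb = small_bases
    vc = VCFRMSpec(J=2, s_basis=sb, t_basis=tb, intercept=True)
    frm = resolve_spec(vc, 3.0, np.inf)
    assert frm.model_kind == "constant-in-t"
    assert frm.t_basis.n_basis == 1
    assert not frm.intercept
    finite = resolve_spec(vc, 3.0, 10.0)
    assert finite.model_kind == "varying" and finite.intercept
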