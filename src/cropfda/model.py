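"""The varying-coefficient functional regression model (VCFRM).

For harvest i with day-of-season t_i, centered moving-average yield y_i and J
centered functional predictors x_ij(s) on the lag axis s ∈ [0, L],

    y_i = Σ_{j=1}^{J} ∫_0^L x_ij(s) β_j(s, t_i) ds + ε_i,      ε_i ~ (0, σ²),

where each coefficient surface is expanded in a tensor product of B-spline
bases, β_j(s,t) = φ(s)ᵀ B_j ψ(t).  Writing x_ij(s) = Σ_m c_ijm φ_m(s), the
model integral becomes the bilinear form (G_s c_ij)ᵀ B_j ψ(t_i) with G_s the
s-basis Gram matrix, so the model is linear in vec(B) and is estimated by
penalized least squares,

    min_B  ‖y − Z vec(B)‖² + Σ_j [ λ_s ∫∫ (∂²β_j/∂s²)² + λ_t ∫∫ (∂²β_j/∂t²)² ],

whose penalty is block-Kronecker: λ_s (P_s ⊗ G_t) + λ_t (G_s ⊗ P_t) per
predictor.  The classical functional regression model (FRM), with β_j
constant in t, is the special case of a one-function constant t-basis; it
serves as the seasonal-invariance baseline.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.linalg

from .basis import (
    BasisSystem,
    DomainError,
    FunctionalDatum,
    SingularFitError,
    constant_basis,
    eval_basis,
    gram_matrix,
    penalty_matrix,
    smooth_to_functional,
    select_rho_gcv,
)
from .preprocess import AlignedSample, CenteringInfo


class ExtrapolationError(DomainError):
    """A prediction time lies outside the fitted t-basis domain."""


def _as_lambda_vector(lam, J: int) -> np.ndarray:
    arr = np.atleast_1d(np.asarray(lam, dtype=float))
    if arr.size == 1:
        arr = np.repeat(arr, J)
    if arr.size != J:
        raise ValueError(f"need 1 or {J} smoothness weights, got {arr.size}")
    if np.any(arr < 0):
        raise ValueError("smoothness weights must be >= 0")
    return arr


@dataclass
class VCFRMSpec:
    """Model specification: bases, smoothness weights, and model kind.

    ``lambda_s``/``lambda_t`` may be scalars (shared across predictors, the
    default) or length-J sequences.  ``model_kind='constant-in-t'`` replaces
    the t-basis with the one-function constant basis, which realizes the FRM
    baseline; its t-penalty is identically zero.

    ``intercept=True`` adds a smooth seasonal intercept α(t), expanded in the
    t-basis and left essentially unpenalized (a tiny ridge for numerical
    definiteness).  Centering removes only the *global* means; the term
    Σ_j ∫ x̄_j(s) β_j(s,t) ds that centering subtracts from the predictors
    still varies with t whenever the surfaces do, so without α(t) that
    nuisance is forced into the estimated surfaces.  For the t-constant
    model the analogous term is a constant and centering alone suffices.
    """

    J: int
    s_basis: BasisSystem
    t_basis: BasisSystem
    lambda_s: float | np.ndarray = 0.0
    lambda_t: float | np.ndarray = 0.0
    model_kind: str = "varying"
    intercept: bool = False

    def __post_init__(self) -> None:
        if self.model_kind not in ("varying", "constant-in-t"):
            raise ValueError(f"unknown model_kind {self.model_kind!r}")
        if self.model_kind == "constant-in-t":
            self.t_basis = constant_basis(self.t_basis.domain)
        _as_lambda_vector(self.lambda_s, self.J)
        _as_lambda_vector(self.lambda_t, self.J)

    @property
    def n_params(self) -> int:
        return self.J * self.s_basis.n_basis * self.t_basis.n_basis

    @property
    def _n_total(self) -> int:
        return self.n_params + (self.t_basis.n_basis if self.intercept else 0)

    def with_lambdas(self, lambda_s, lambda_t) -> "VCFRMSpec":
        return VCFRMSpec(
            J=self.J, s_basis=self.s_basis, t_basis=self.t_basis,
            lambda_s=lambda_s, lambda_t=lambda_t, model_kind=self.model_kind,
            intercept=self.intercept,
        )


def resolve_spec(template: "VCFRMSpec", lambda_s, lambda_t) -> "VCFRMSpec":
    """Spec at a smoothness pair, treating λ_t = ∞ as the t-constant limit.

    An infinite λ_t collapses the varying-coefficient model onto its FRM
    special case: constant-in-t surfaces and no seasonal intercept (the
    intercept exists to absorb the t-varying part of the centering nuisance,
    which is constant when the surfaces are).  This makes the FRM a regular
    rung of the smoothing ladder, so criterion-based selection can discard
    seasonal variation entirely when the data do not support it.
    """
    if np.isscalar(lambda_t) and np.isinf(lambda_t):
        return VCFRMSpec(
            J=template.J, s_basis=template.s_basis, t_basis=template.t_basis,
            lambda_s=lambda_s, lambda_t=0.0, model_kind="constant-in-t",
            intercept=False,
        )
    return template.with_lambdas(lambda_s, lambda_t)


@dataclass
class FunctionalSample:
    """One centered observation in basis-coefficient form."""

    index: int
    t: float
    x: list[FunctionalDatum]
    y: float


def functionalize(
    samples: list[AlignedSample],
    s_basis: BasisSystem,
    rho: float | str = "gcv",
) -> list[FunctionalSample]:
    """Smooth each hourly lag window into a functional datum.

    ``rho`` is either a fixed smoothing weight or ``"gcv"`` (the default), in
    which case each window's weight is chosen by generalized cross-validation.
    """
    out = []
    for s in samples:
        fds = []
        for j, w in enumerate(s.windows):
            r = select_rho_gcv(s.s_grid, w, s_basis) if rho == "gcv" else rho
            fds.append(
                smooth_to_functional(s.s_grid, w, s_basis, rho=r, predictor_index=j)
            )
        out.append(FunctionalSample(index=s.index, t=s.t, x=fds, y=s.y))
    return out


@dataclass
class CoefficientSurface:
    """β_j(s,t) = φ(s)ᵀ B_j ψ(t) on the domain rectangle."""

    predictor_index: int
    B: np.ndarray
    s_basis: BasisSystem
    t_basis: BasisSystem

    def __call__(self, s, t) -> np.ndarray:
        """Evaluate on the grid s × t; returns a (len(s), len(t)) matrix."""
        Phi = eval_basis(self.s_basis, np.atleast_1d(s))
        Psi = eval_basis(self.t_basis, np.atleast_1d(t))
        return Phi @ self.B @ Psi.T


@dataclass
class VCFRMFit:
    """A fitted model: surfaces, complexity and goodness-of-fit summaries."""

    spec: VCFRMSpec
    surfaces: list[CoefficientSurface]
    coef: np.ndarray
    edf: float
    rss: float
    n: int
    centering: CenteringInfo | None = None

    @property
    def gcv(self) -> float:
        from .selection import criterion_value

        return criterion_value(self, "gcv")


def build_design(
    samples: list[FunctionalSample], spec: VCFRMSpec
) -> tuple[np.ndarray, np.ndarray]:
    """Design matrix Z (n × J·Ks·Kt) and response vector for centered samples.

    Row i, block j is (G_s c_ij)ᵀ ⊗ ψ(t_i)ᵀ, so Z · vec(B) (row-major vec)
    reproduces Σ_j ∫ x_ij(s) β_j(s, t_i) ds exactly for any surface in the
    tensor-product space.
    """
    if not samples:
        raise ValueError("no samples")
    s_basis, t_basis = spec.s_basis, spec.t_basis
    for smp in samples:
        if len(smp.x) != spec.J:
            raise ValueError(
                f"sample {smp.index} has {len(smp.x)} predictors, spec J={spec.J}"
            )
        for fd in smp.x:
            if fd.basis != s_basis:
                raise ValueError(
                    "sample functional data use a different s-basis than the spec"
                )
    Gs = gram_matrix(s_basis)
    t_vals = np.array([smp.t for smp in samples])
    lo, hi = t_basis.domain
    if t_vals.min() < lo - 1e-9 or t_vals.max() > hi + 1e-9:
        raise ExtrapolationError(
            f"sample season times outside t-basis domain [{lo}, {hi}]"
        )
    Psi = eval_basis(t_basis, t_vals)  # n × Kt
    n, Ks, Kt = len(samples), s_basis.n_basis, t_basis.n_basis
    Z = np.empty((n, spec.J * Ks * Kt))
    for j in range(spec.J):
        C = np.stack([smp.x[j].coefficients for smp in samples])  # n × Ks
        A = C @ Gs  # n × Ks
        # row-wise Kronecker: a ⊗ ψ
        Z[:, j * Ks * Kt : (j + 1) * Ks * Kt] = (
            A[:, :, None] * Psi[:, None, :]
        ).reshape(n, Ks * Kt)
    y = np.array([smp.y for smp in samples])
    return Z, y


_INTERCEPT_RIDGE = 1e-6


def _full_design(
    samples: list[FunctionalSample], spec: VCFRMSpec
) -> tuple[np.ndarray, np.ndarray]:
    """Design including the seasonal-intercept columns when the spec has one."""
    Z, y = build_design(samples, spec)
    if spec.intercept:
        t_vals = np.array([smp.t for smp in samples])
        Z = np.hstack([Z, eval_basis(spec.t_basis, t_vals)])
    return Z, y


def _full_penalty(spec: VCFRMSpec) -> np.ndarray:
    Lam = assemble_penalty(spec)
    if spec.intercept:
        Kt = spec.t_basis.n_basis
        full = np.zeros((spec._n_total,) * 2)
        full[: spec.n_params, : spec.n_params] = Lam
        full[spec.n_params :, spec.n_params :] = _INTERCEPT_RIDGE * np.eye(Kt)
        return full
    return Lam


def assemble_penalty(spec: VCFRMSpec) -> np.ndarray:
    """Block-diagonal roughness penalty Λ over the J predictor blocks.

    Each block is λ_s (P_s ⊗ G_t) + λ_t (G_s ⊗ P_t): the quadratic form
    vec(B_j)ᵀ · block · vec(B_j) equals
    λ_s ∫∫ (∂²β_j/∂s²)² ds dt + λ_t ∫∫ (∂²β_j/∂t²)² ds dt.
    For the constant t-basis (FRM) P_t is identically zero — a degree-0
    spline has no curvature in t.
    """
    lam_s = _as_lambda_vector(spec.lambda_s, spec.J)
    lam_t = _as_lambda_vector(spec.lambda_t, spec.J)
    Ps = penalty_matrix(spec.s_basis)
    Gs = gram_matrix(spec.s_basis)
    Gt = gram_matrix(spec.t_basis)
    if spec.t_basis.order > 2:
        Pt = penalty_matrix(spec.t_basis)
    else:
        Pt = np.zeros((spec.t_basis.n_basis,) * 2)
    blocks = [
        lam_s[j] * np.kron(Ps, Gt) + lam_t[j] * np.kron(Gs, Pt)
        for j in range(spec.J)
    ]
    return scipy.linalg.block_diag(*blocks)


def _solve_penalized(
    ZtZ: np.ndarray, Zty: np.ndarray, Lam: np.ndarray
) -> tuple[np.ndarray, float]:
    """Solve (ZᵀZ + Λ) b = Zᵀy by Cholesky; returns (b, edf)."""
    A = ZtZ + Lam
    try:
        cho = scipy.linalg.cho_factor(A)
    except scipy.linalg.LinAlgError as exc:
        w = scipy.linalg.eigvalsh(A)
        raise SingularFitError(
            f"penalized system is not positive definite "
            f"(smallest eigenvalue {w.min():.3e}); increase λ or reduce basis size"
        ) from exc
    b = scipy.linalg.cho_solve(cho, Zty)
    edf = float(np.trace(scipy.linalg.cho_solve(cho, ZtZ)))
    return b, edf


def _unpack_surfaces(coef: np.ndarray, spec: VCFRMSpec) -> list[CoefficientSurface]:
    Ks, Kt = spec.s_basis.n_basis, spec.t_basis.n_basis
    return [
        CoefficientSurface(
            predictor_index=j,
            B=coef[j * Ks * Kt : (j + 1) * Ks * Kt].reshape(Ks, Kt),
            s_basis=spec.s_basis,
            t_basis=spec.t_basis,
        )
        for j in range(spec.J)
    ]


def fit(
    samples: list[FunctionalSample],
    spec: VCFRMSpec,
    centering: CenteringInfo | None = None,
) -> VCFRMFit:
    """Penalized least-squares estimate of the coefficient surfaces.

    vec(B̂) = (ZᵀZ + Λ)⁻¹ Zᵀ y.  Also records the residual sum of squares and
    the effective degrees of freedom trace(Z (ZᵀZ+Λ)⁻¹ Zᵀ) — the complexity
    measure of this linear smoother.  Deterministic given its inputs.
    """
    if len(samples) < 2:
        raise ValueError("need at least 2 samples")
    Z, y = _full_design(samples, spec)
    Lam = _full_penalty(spec)
    coef, edf = _solve_penalized(Z.T @ Z, Z.T @ y, Lam)
    resid = y - Z @ coef
    return VCFRMFit(
        spec=spec,
        surfaces=_unpack_surfaces(coef, spec),
        coef=coef,
        edf=edf,
        rss=float(resid @ resid),
        n=len(samples),
        centering=centering,
    )


def objective(
    samples: list[FunctionalSample], spec: VCFRMSpec, coef: np.ndarray
) -> float:
    """Value of the penalized least-squares objective at a coefficient vector."""
    Z, y = _full_design(samples, spec)
    Lam = _full_penalty(spec)
    r = y - Z @ coef
    return float(r @ r + coef @ Lam @ coef)


def predict(fit: VCFRMFit, new_samples: list[FunctionalSample]) -> np.ndarray:
    """Predicted yields in original units for already-centered samples.

    ŷ_i = α̂(t_i) + Σ_j ∫ x_ij(s) β̂_j(s, t_i) ds + stored training y-mean
    (the intercept term only when the spec includes one).  Season times
    outside the fitted t-basis domain raise — no silent extrapolation.
    """
    Z, _ = _full_design(new_samples, fit.spec)
    yhat = Z @ fit.coef
    if fit.centering is not None:
        yhat = yhat + fit.centering.y_mean
    return yhat


def seasonal_intercept(fit: VCFRMFit, t_grid: np.ndarray) -> np.ndarray:
    """Evaluate the fitted seasonal intercept α̂(t); zero when absent."""
    t_grid = np.atleast_1d(t_grid)
    if not fit.spec.intercept:
        return np.zeros(t_grid.shape)
    a = fit.coef[fit.spec.n_params :]
    return eval_basis(fit.spec.t_basis, t_grid) @ a


def surface_grid(
    fit: VCFRMFit, j: int, s_grid: np.ndarray, t_grid: np.ndarray
) -> np.ndarray:
    """β̂_j on a rectangular grid (rows: s, columns: t) for contour rendering."""
    return fit.surfaces[j](np.asarray(s_grid), np.asarray(t_grid))


def surface_grid_table(
    fit: VCFRMFit, s_grid: np.ndarray, t_grid: np.ndarray
) -> pd.DataFrame:
    """Long-format (s, t, j, value) table of all estimated surfaces."""
    rows = []
    for j in range(fit.spec.J):
        M = surface_grid(fit, j, s_grid, t_grid)
        for a, s in enumerate(s_grid):
            for b, t in enumerate(t_grid):
                rows.append((float(s), float(t), j, float(M[a, b])))
    return pd.DataFrame(rows, columns=["s", "t", "j", "value"])
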