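"""B-spline basis systems on the lag (s) and season (t) axes.

Functional data analysis represents each observed curve as a finite linear
combination of known basis functions.  This module provides the basis systems
used everywhere downstream: evaluation (with derivatives), Gram matrices of
pairwise inner products, second-derivative roughness-penalty matrices, and the
penalized least-squares smoother that turns an hourly lag window into a
:class:`FunctionalDatum`.

Inner products are computed by fixed-order Gauss–Legendre quadrature applied
per inter-knot interval.  Because products of B-splines (and of their
derivatives) are piecewise polynomials, this quadrature is exact up to
round-off — no adaptive integration is needed.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from functools import lru_cache

import numpy as np
from numpy.polynomial.legendre import leggauss
from scipy.interpolate import BSpline


class DomainError(ValueError):
    """An evaluation point or grid lies outside a basis domain."""


class SingularFitError(np.linalg.LinAlgError):
    """A least-squares system is rank deficient; a positive penalty may help."""


@dataclass(frozen=True)
class BasisSystem:
    """A univariate B-spline basis on a closed interval.

    Parameters
    ----------
    domain
        ``(lo, hi)`` endpoints, in days.
    n_basis
        Number of basis functions.  Must satisfy ``n_basis >= order``.
    order
        Spline order (degree + 1); the default 4 gives cubic splines.

    Interior knots are equally spaced.  The boundary knots are repeated
    ``order`` times (a clamped knot vector), so the basis satisfies the
    partition of unity on the whole domain.
    """

    domain: tuple[float, float]
    n_basis: int = 10
    order: int = 4

    def __post_init__(self) -> None:
        lo, hi = self.domain
        if not hi > lo:
            raise ValueError(f"degenerate domain {self.domain}")
        if self.order < 1:
            raise ValueError("spline order must be >= 1")
        if self.n_basis < self.order:
            raise ValueError(
                f"n_basis={self.n_basis} must be >= order={self.order}"
            )

    @property
    def degree(self) -> int:
        return self.order - 1

    @property
    def interior_knots(self) -> np.ndarray:
        lo, hi = self.domain
        n_int = self.n_basis - self.order
        return np.linspace(lo, hi, n_int + 2)[1:-1]

    @property
    def knots(self) -> np.ndarray:
        """Full clamped knot vector of length ``n_basis + order``."""
        lo, hi = self.domain
        return np.concatenate(
            [np.full(self.order, lo), self.interior_knots, np.full(self.order, hi)]
        )

    @property
    def breakpoints(self) -> np.ndarray:
        lo, hi = self.domain
        return np.concatenate([[lo], self.interior_knots, [hi]])


def constant_basis(domain: tuple[float, float]) -> BasisSystem:
    """The one-function basis φ(u) ≡ 1 — used for coefficients constant in t."""
    return BasisSystem(domain=domain, n_basis=1, order=1)


@dataclass
class FunctionalDatum:
    """One lagged environmental curve x_ij(s) = Σ_m c_m φ_m(s)."""

    predictor_index: int
    coefficients: np.ndarray
    basis: BasisSystem

    def __post_init__(self) -> None:
        self.coefficients = np.asarray(self.coefficients, dtype=float)
        if self.coefficients.shape != (self.basis.n_basis,):
            raise ValueError(
                f"coefficient length {self.coefficients.shape} does not match "
                f"basis size {self.basis.n_basis}"
            )
        if not np.all(np.isfinite(self.coefficients)):
            raise ValueError("non-finite basis coefficients")

    def __call__(self, s: np.ndarray) -> np.ndarray:
        return eval_basis(self.basis, np.atleast_1d(s)) @ self.coefficients


def eval_basis(
    basis: BasisSystem, points: np.ndarray, deriv: int = 0
) -> np.ndarray:
    """Evaluate all basis functions (or a derivative) at ``points``.

    Returns a dense ``(len(points), n_basis)`` matrix with entry (p, k) equal
    to d^deriv φ_k / du^deriv at points[p].
    """
    pts = np.asarray(points, dtype=float)
    lo, hi = basis.domain
    eps = 1e-9 * (hi - lo)
    if pts.size and (pts.min() < lo - eps or pts.max() > hi + eps):
        raise DomainError(
            f"evaluation points outside domain [{lo}, {hi}]: "
            f"range [{pts.min()}, {pts.max()}]"
        )
    pts = np.clip(pts, lo, hi)
    if deriv < 0:
        raise ValueError("derivative order must be >= 0")
    if basis.n_basis == 1 and basis.order == 1:
        # degree-0 single basis: constant one; all derivatives vanish
        col = np.ones_like(pts) if deriv == 0 else np.zeros_like(pts)
        return col[:, None]
    if deriv >= basis.order:
        return np.zeros((pts.size, basis.n_basis))
    spl = BSpline(basis.knots, np.eye(basis.n_basis), basis.degree)
    if deriv:
        spl = spl.derivative(deriv)
    out = spl(pts)
    # clamped evaluation at the right endpoint is the left limit
    return np.asarray(out, dtype=float)


def _quad_nodes(
    breakpoints: np.ndarray, npts: int
) -> tuple[np.ndarray, np.ndarray]:
    """Gauss–Legendre nodes/weights on each breakpoint interval, concatenated."""
    gx, gw = leggauss(npts)
    a = breakpoints[:-1][:, None]
    b = breakpoints[1:][:, None]
    nodes = 0.5 * (b - a) * (gx[None, :] + 1.0) + a
    weights = 0.5 * (b - a) * gw[None, :]
    return nodes.ravel(), weights.ravel()


@lru_cache(maxsize=256)
def _gram_cached(
    a: BasisSystem, b: BasisSystem, deriv_a: int, deriv_b: int
) -> np.ndarray:
    bp = np.unique(np.concatenate([a.breakpoints, b.breakpoints]))
    deg = max(a.degree - deriv_a, 0) + max(b.degree - deriv_b, 0)
    nodes, weights = _quad_nodes(bp, deg // 2 + 1)
    Fa = eval_basis(a, nodes, deriv_a)
    Fb = eval_basis(b, nodes, deriv_b)
    G = (Fa * weights[:, None]).T @ Fb
    if a == b and deriv_a == deriv_b:
        G = 0.5 * (G + G.T)
    return G


def gram_matrix(
    a: BasisSystem,
    b: BasisSystem | None = None,
    deriv_a: int = 0,
    deriv_b: int = 0,
) -> np.ndarray:
    """Matrix of inner products ∫ φ_m^(deriv_a) ψ_k^(deriv_b) du.

    ``a`` and ``b`` must share a domain.  The quadrature order is chosen so the
    piecewise-polynomial integrand is integrated exactly.
    """
    if b is None:
        b = a
    if a.domain != b.domain:
        raise DomainError(f"domain mismatch: {a.domain} vs {b.domain}")
    return _gram_cached(a, b, deriv_a, deriv_b)


def penalty_matrix(basis: BasisSystem, deriv_order: int = 2) -> np.ndarray:
    """Roughness penalty ∫ φ_m'' φ_k'' du (or another derivative order).

    The quadratic form c'Pc equals the integrated squared ``deriv_order``-th
    derivative of the spline with coefficients c; its null space is the
    polynomials of degree < deriv_order.
    """
    if deriv_order >= basis.order:
        raise ValueError(
            f"penalty derivative order {deriv_order} must be < spline order "
            f"{basis.order}"
        )
    return gram_matrix(basis, basis, deriv_a=deriv_order, deriv_b=deriv_order)


_design_store: dict = {}
_smoother_store: dict = {}


def _design_cache(basis: BasisSystem, s: np.ndarray) -> np.ndarray:
    key = (basis, s.tobytes())
    M = _design_store.get(key)
    if M is None:
        M = eval_basis(basis, s)
        if len(_design_store) > 64:
            _design_store.clear()
        _design_store[key] = M
    return M


def _smoother_cache(
    basis: BasisSystem, s: np.ndarray, mask: np.ndarray, rho: float
) -> np.ndarray:
    """The linear smoother S with c = S v[mask]; data independent, so cached."""
    key = (basis, s.tobytes(), mask.tobytes(), float(rho))
    S = _smoother_store.get(key)
    if S is None:
        Phi = _design_cache(basis, s)[mask]
        A = Phi.T @ Phi
        if rho:
            A = A + rho * penalty_matrix(basis)
        cond = np.linalg.cond(A)
        if not np.isfinite(cond) or (rho == 0 and cond > 1e12):
            raise SingularFitError(
                f"near-singular smoothing design (cond={cond:.2e}); use rho > 0"
            )
        S = np.linalg.solve(A, Phi.T)
        if len(_smoother_store) > 512:
            _smoother_store.clear()
        _smoother_store[key] = S
    return S


def smooth_to_functional(
    s: np.ndarray,
    values: np.ndarray,
    basis: BasisSystem,
    rho: float = 0.0,
    predictor_index: int = 0,
) -> FunctionalDatum:
    """Penalized least-squares smoothing of a sampled lag window.

    Minimizes Σ_cells (v − Σ_m c_m φ_m(s))² + rho·c'Pc over the coefficient
    vector c, skipping missing (NaN) cells.  With ``rho=0`` and exactly
    ``n_basis`` distinct support points the fit interpolates.
    """
    if rho < 0:
        raise ValueError("smoothing weight rho must be >= 0")
    s = np.asarray(s, dtype=float)
    v = np.asarray(values, dtype=float)
    mask = np.isfinite(v)
    n_obs = int(mask.sum())
    min_needed = basis.n_basis if rho == 0 else 2
    if n_obs < min_needed:
        raise SingularFitError(
            f"only {n_obs} non-missing cells; need >= {min_needed} "
            f"(rho={rho})"
        )
    try:
        S = _smoother_cache(basis, s, mask, rho)
    except np.linalg.LinAlgError as exc:
        raise SingularFitError(
            "singular smoothing system at rho=0; use rho > 0"
        ) from exc
    c = S @ v[mask]
    return FunctionalDatum(predictor_index, c, basis)


def select_rho_gcv(
    s: np.ndarray,
    values: np.ndarray,
    basis: BasisSystem,
    rho_grid: np.ndarray | None = None,
) -> float:
    """Pick the smoothing weight for one window by generalized cross-validation.

    GCV(rho) = n·RSS/(n − edf)² for the linear smoother defined by rho; ties
    broken toward the larger (smoother) rho.
    """
    if rho_grid is None:
        rho_grid = np.logspace(-4, 4, 9)
    s = np.asarray(s, dtype=float)
    v = np.asarray(values, dtype=float)
    mask = np.isfinite(v)
    Phi = _design_cache(basis, s)[mask]
    y = v[mask]
    n = y.size
    PtP = Phi.T @ Phi
    Pty = Phi.T @ y
    P = penalty_matrix(basis)
    best = (np.inf, 0.0)
    for rho in sorted(np.asarray(rho_grid, dtype=float), reverse=True):
        A = PtP + rho * P
        try:
            c = np.linalg.solve(A, Pty)
            edf = np.trace(np.linalg.solve(A, PtP))
        except np.linalg.LinAlgError:
            continue
        resid = y - Phi @ c
        rss = float(resid @ resid)
        if edf >= n:
            continue
        gcv = n * rss / (n - edf) ** 2
        if gcv < best[0]:
            best = (gcv, float(rho))
    if not np.isfinite(best[0]):
        raise SingularFitError("GCV failed at every rho on the grid")
    return best[1]
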