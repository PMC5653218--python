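"""Functional principal component analysis of DVH curves.

The curves live on a uniform dose grid, so all functional inner
products are left-Riemann quadratures ⟨f, g⟩ = Δd Σ_k f(d_k) g(d_k).
FPCA eigenfunctions ξ_k(d) diagonalize the covariance operator
Σ(d1, d2) = Cov[V(d1), V(d2)] under that inner product; per-patient
scores are c_ik = ⟨V_i − μ, ξ_k⟩.  The decomposition is computed from
the singular value decomposition of the centered curve matrix (the
dense eigendecomposition of the discretized operator is kept as an
independent test oracle).

Component signs are mathematically arbitrary; a deterministic
convention is applied: each component is flipped so its inner product
with the centered dose ramp (d − d̄) is non-negative (ties broken toward
a positive last element), making fitted coefficients reproducible.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence, Union

import numpy as np

from .dvh import Cohort, DoseGrid, DVHCurve

__all__ = [
    "FunctionalBasis",
    "as_curve_matrix",
    "mean_function",
    "covariance_operator",
    "fpca_decompose",
    "reconstruct",
    "variance_explained",
]

ORTHO_TOL = 1e-8


def as_curve_matrix(curves: Union[Cohort, Sequence[DVHCurve], np.ndarray], grid: Optional[DoseGrid] = None):
    """Normalize curve input to ``(matrix, grid)``.

    Accepts a Cohort, a sequence of DVHCurve on one grid, or a raw
    ``n x m`` array (with ``grid`` given explicitly).
    """
    if isinstance(curves, Cohort):
        return curves.volumes, curves.grid
    if isinstance(curves, np.ndarray):
        if grid is None:
            raise ValueError("grid must be provided with a raw curve matrix")
        if curves.ndim != 2 or curves.shape[1] != grid.size:
            raise ValueError("curve matrix must be n x grid.size")
        return np.asarray(curves, dtype=float), grid
    curves = list(curves)
    if not curves:
        raise ValueError("at least one curve is required")
    g = curves[0].grid
    for c in curves[1:]:
        if c.grid != g:
            raise ValueError("all curves must share one grid")
    return np.stack([c.volume for c in curves]), g


@dataclass
class FunctionalBasis:
    """Ordered component functions with their scores and variance summary.

    components[k] is ξ_k(d) on the grid, orthonormal under the
    quadrature inner product.  For kind="fpca", ``eigenvalues`` are the
    score variances λ_k (divisor n); for kind="fpls" they are the
    squared covariances of the component scores with the (centered)
    response.  ``total_variance`` is the full quadrature-integrated
    pointwise variance Δd Σ_d Var V(d), so variance fractions can be
    reported even when only the leading components are kept.
    """

    grid: DoseGrid
    kind: str  # "fpca" | "fpls"
    components: np.ndarray  # k x m
    eigenvalues: np.ndarray  # k
    mean_function: np.ndarray  # m
    scores: np.ndarray  # n x k
    total_variance: float

    @property
    def n_components(self) -> int:
        return self.components.shape[0]

    def inner(self, f: np.ndarray, g: np.ndarray) -> float:
        return float(self.grid.step * np.dot(f, g))

    def project_scores(self, X: np.ndarray) -> np.ndarray:
        """Quadrature scores of (possibly new) curves against this basis."""
        return self.grid.step * (X - self.mean_function) @ self.components.T


def apply_sign_convention(components: np.ndarray, grid: DoseGrid) -> np.ndarray:
    """Flip each component so ⟨ξ, d − d̄⟩ ≥ 0 (ties: positive last value)."""
    ramp = grid.points - grid.points.mean()
    flipped = components.copy()
    for k in range(flipped.shape[0]):
        s = grid.step * np.dot(flipped[k], ramp)
        if s < -1e-12 or (abs(s) <= 1e-12 and flipped[k, -1] < 0):
            flipped[k] = -flipped[k]
    return flipped


def mean_function(curves, grid: Optional[DoseGrid] = None) -> np.ndarray:
    """Pointwise mean curve μ(d)."""
    X, _ = as_curve_matrix(curves, grid)
    if X.shape[0] < 1:
        raise ValueError("at least one curve is required")
    return X.mean(axis=0)


def covariance_operator(curves, grid: Optional[DoseGrid] = None) -> np.ndarray:
    """Discretized covariance operator Σ(d1, d2), divisor n (expectation form)."""
    X, _ = as_curve_matrix(curves, grid)
    if X.shape[0] < 2:
        raise ValueError("at least two curves are required")
    Xc = X - X.mean(axis=0)
    return Xc.T @ Xc / X.shape[0]


def fpca_decompose(curves, k_max: Optional[int] = None, grid: Optional[DoseGrid] = None) -> FunctionalBasis:
    """Top-``k_max`` FPCA eigenpairs of the quadrature-weighted covariance.

    Computed via SVD of the centered curve matrix: with X_c = U S Vᵀ,
    the discretized operator Δd·Σ has eigenvalues λ = Δd s²/n and
    Euclidean-orthonormal eigenvectors given by the rows of Vᵀ; dividing
    by √Δd makes them orthonormal under the quadrature inner product.
    """
    X, g = as_curve_matrix(curves, grid)
    n, m = X.shape
    if n < 2:
        raise ValueError("at least two curves are required")
    limit = min(n - 1, m)
    if k_max is None:
        k_max = limit
    if not (1 <= k_max <= limit):
        raise ValueError(f"k_max must be in [1, {limit}] for n={n}, grid size {m}")

    mu = X.mean(axis=0)
    Xc = X - mu
    _, s, vt = np.linalg.svd(Xc, full_matrices=False)
    lam = g.step * s**2 / n
    comps = apply_sign_convention(vt[:k_max] / np.sqrt(g.step), g)
    scores = g.step * Xc @ comps.T
    total_var = float(g.step * Xc.var(axis=0).sum())
    return FunctionalBasis(
        grid=g,
        kind="fpca",
        components=comps,
        eigenvalues=lam[:k_max],
        mean_function=mu,
        scores=scores,
        total_variance=total_var,
    )


def reconstruct(basis: FunctionalBasis, k_n: int) -> np.ndarray:
    """Truncated Karhunen-Loève reconstruction μ + Σ_{k≤k_n} c_k ξ_k."""
    if not (0 <= k_n <= basis.n_components):
        raise ValueError("k_n exceeds available components")
    out = np.tile(basis.mean_function, (basis.scores.shape[0], 1))
    if k_n > 0:
        out = out + basis.scores[:, :k_n] @ basis.components[:k_n]
    return out


def variance_explained(basis: FunctionalBasis, k: Optional[int] = None) -> np.ndarray:
    """Percent of total curve variance carried by each leading component.

    Computed from the training-score variances (divisor n), which for
    FPCA equal the eigenvalues λ_k; the denominator is the full
    quadrature-integrated curve variance, so the fractions over all
    components sum to 100%.
    """
    if k is None:
        k = basis.n_components
    if k > basis.n_components:
        raise ValueError("k exceeds available components")
    var_k = basis.scores[:, :k].var(axis=0)
    return 100.0 * var_k / basis.total_variance
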