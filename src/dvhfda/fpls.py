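"""Functional partial least squares for binary toxicity outcomes.

FPLS is the supervised analogue of FPCA: instead of maximizing the
variance of curve projections, the first component maximizes the squared
covariance between the projected DVH curves and the (centered) outcome,
and subsequent components repeat the construction on curve data deflated
by the fitted rank-1 approximation, under the constraint that all
components stay mutually orthogonal.

This is NIPALS-style PLS1 on quadrature-weighted centered curve vectors:
for a single response the weight vector w ∝ Cov(V(d), y) attains the
maximal squared covariance among unit-norm directions, which is the
defining property tested here.  Explicit Gram-Schmidt re-orthogonalization
against earlier components guards against numerical drift; the algorithm
itself contains no randomness, so identical inputs give identical
components bit for bit.
"""

from __future__ import annotations

from typing import Optional

import numpy as np

from .dvh import DoseGrid
from .fpca import FunctionalBasis, apply_sign_convention, as_curve_matrix

__all__ = ["fpls_decompose", "fpls_scores"]


def _second_difference_matrix(m: int, step: float) -> np.ndarray:
    """Second-derivative operator (central interior, one-sided ends)."""
    D = np.zeros((m, m))
    for i in range(1, m - 1):
        D[i, i - 1 : i + 2] = (1.0, -2.0, 1.0)
    D[0, :3] = (1.0, -2.0, 1.0)
    D[-1, -3:] = (1.0, -2.0, 1.0)
    return D / step**2


def fpls_decompose(
    curves,
    y,
    k_max: int,
    grid: Optional[DoseGrid] = None,
    penalized_extraction: bool = False,
    r: float = 0.0,
) -> FunctionalBasis:
    """Extract ``k_max`` FPLS components of curves against a binary response.

    The response is centered before extraction, so the component shapes
    are invariant to affine recoding of y.  With
    ``penalized_extraction=True``, each weight function is normalized
    under the roughness-penalized inner product
    ⟨w, (I + r P̃) w⟩ = 1 with P̃ the squared-second-derivative operator,
    a sensitivity-analysis alternative to penalizing only in the
    regression step (the default).
    """
    X, g = as_curve_matrix(curves, grid)
    n, m = X.shape
    y = np.asarray(y, dtype=float)
    if y.shape != (n,):
        raise ValueError("y must have one entry per curve")
    if len(np.unique(y)) < 2:
        raise ValueError("both outcome classes must be present")
    limit = min(n - 1, m)
    if not (1 <= k_max <= limit):
        raise ValueError(f"k_max must be in [1, {limit}] for n={n}, grid size {m}")

    mu = X.mean(axis=0)
    Xc = X - mu
    yc = y - y.mean()
    step = g.step

    if penalized_extraction:
        D = _second_difference_matrix(m, step)
        pen = np.eye(m) + r * (D.T @ D) * step

    comps = []
    Xd = Xc.copy()
    for _ in range(k_max):
        w = Xd.T @ yc / n  # ∝ Cov(V(d), y) on the deflated data
        # re-orthogonalize against accepted components (quadrature metric)
        for xi in comps:
            w = w - (step * np.dot(w, xi)) * xi
        norm2 = step * float(w @ (pen @ w)) if penalized_extraction else step * float(w @ w)
        if norm2 < 1e-24:
            raise ValueError("k_max exceeds the covariance rank of the data")
        w = w / np.sqrt(norm2)
        comps.append(w)
        # deflate curves by the fitted rank-1 approximation
        t = step * Xd @ w
        denom = float(t @ t)
        if denom < 1e-24:
            raise ValueError("k_max exceeds the covariance rank of the data")
        p = Xd.T @ t / denom
        Xd = Xd - np.outer(t, p)

    components = apply_sign_convention(np.stack(comps), g)
    scores = step * Xc @ components.T  # against the *original* centered curves
    cov_y = scores.T @ yc / n
    total_var = float(step * Xc.var(axis=0).sum())
    return FunctionalBasis(
        grid=g,
        kind="fpls",
        components=components,
        eigenvalues=cov_y**2,
        mean_function=mu,
        scores=scores,
        total_variance=total_var,
    )


def fpls_scores(curves, basis: FunctionalBasis, grid: Optional[DoseGrid] = None) -> np.ndarray:
    """Quadrature scores of curves against a fitted basis.

    Centering uses the *training* mean stored in the basis, which is
    what external validation requires.
    """
    X, g = as_curve_matrix(curves, grid)
    if g != basis.grid:
        raise ValueError("curves are not on the basis grid")
    return basis.project_scores(X)
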