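"""Quadrature rules on reference simplices.

Conical-product (collapsed Gauss--Jacobi) rules on the unit interval,
triangle and tetrahedron.  Exact for polynomials up to the requested
degree, with positive weights; point counts grow like ``((d+1)/2)^dim``
which is perfectly adequate for the low orders used here.
"""

from __future__ import annotations

import functools

import numpy as np
from scipy.special import roots_jacobi

__all__ = ["simplex_quadrature"]


def _gauss_jacobi_01(n: int, alpha: int) -> tuple[np.ndarray, np.ndarray]:
    """Gauss-Jacobi rule with weight (1-x)^alpha, shifted to [0, 1]."""
    x, w = roots_jacobi(n, alpha, 0.0)
    # map from [-1,1] with weight (1-x)^alpha to [0,1] with weight (1-t)^alpha
    t = 0.5 * (x + 1.0)
    w = w * 0.5 ** (alpha + 1)
    return t, w


@functools.lru_cache(maxsize=None)
def simplex_quadrature(dim: int, degree: int) -> tuple[np.ndarray, np.ndarray]:
    """Return ``(points, weights)`` integrating degree-``degree`` polynomials
    exactly over the unit simplex of dimension ``dim`` (0, 1, 2 or 3).

    Weights sum to the simplex measure (1, 1/2, 1/6).
    """
    if dim == 0:
        return np.zeros((1, 0)), np.ones(1)
    n = max(1, (degree + 2) // 2)
    if dim == 1:
        t, w = _gauss_jacobi_01(n, 0)
        return t[:, None].copy(), w.copy()
    if dim == 2:
        # collapsed coordinates: x = a(1-b), y = b
        a, wa = _gauss_jacobi_01(n, 0)
        b, wb = _gauss_jacobi_01(n, 1)
        A, B = np.meshgrid(a, b, indexing="ij")
        pts = np.column_stack([(A * (1.0 - B)).ravel(), B.ravel()])
        wts = np.outer(wa, wb).ravel()
        return pts, wts
    if dim == 3:
        a, wa = _gauss_jacobi_01(n, 0)
        b, wb = _gauss_jacobi_01(n, 1)
        c, wc = _gauss_jacobi_01(n, 2)
        A, B, C = np.meshgrid(a, b, c, indexing="ij")
        x = A * (1.0 - B) * (1.0 - C)
        y = B * (1.0 - C)
        z = C
        pts = np.column_stack([x.ravel(), y.ravel(), z.ravel()])
        wts = (wa[:, None, None] * wb[None, :, None] * wc[None, None, :]).ravel()
        return pts, wts
    raise ValueError(f"unsupported simplex dimension {dim}")
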