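"""Finite-difference operators on the uniform structured grid.

Zero-flux (Neumann) boundaries are closed with mirror ghost nodes, the
standard second-order treatment for node-centered grids.  The trapezoid
quadrature weights returned by :func:`quadrature_weights` are the left
null-vector of the Neumann Laplacian, which is what makes the discrete
Cahn-Hilliard mass exactly conserved.
"""

from __future__ import annotations

from functools import lru_cache

import numpy as np
import scipy.sparse as sp

__all__ = ["neumann_laplacian", "quadrature_weights", "gradient", "grad_norm"]


def _laplacian_1d(n: int, h: float) -> sp.csr_matrix:
    if n == 1:
        return sp.csr_matrix((1, 1))
    main = np.full(n, -2.0)
    off = np.ones(n - 1)
    L = sp.diags([off, main, off], [-1, 0, 1], format="lil")
    # mirror ghost: u[-1] = u[1], u[n] = u[n-2]
    L[0, 1] = 2.0
    L[n - 1, n - 2] = 2.0
    return (L / h**2).tocsr()


@lru_cache(maxsize=32)
def neumann_laplacian(shape: tuple[int, ...], h: float) -> sp.csr_matrix:
    """Sparse Laplacian with zero-flux boundaries on an ``shape`` grid
    (row-major / C-order flattening)."""
    ops = [_laplacian_1d(n, h) for n in shape]
    eyes = [sp.identity(n, format="csr") for n in shape]
    L = sp.csr_matrix((int(np.prod(shape)),) * 2)
    for axis, op in enumerate(ops):
        factors = [eyes[i] if i != axis else op for i in range(len(shape))]
        term = factors[0]
        for f in factors[1:]:
            term = sp.kron(term, f, format="csr")
        L = L + term
    return L.tocsr()


@lru_cache(maxsize=32)
def quadrature_weights(shape: tuple[int, ...], h: float) -> np.ndarray:
    """Trapezoid weights w with w @ L = 0 for the Neumann Laplacian.

    Returned flattened (C-order); multiply the weighted sum by nothing
    extra — the h^dim volume factor is already included.
    """
    parts = []
    for n in shape:
        wi = np.ones(n)
        if n > 1:
            wi[0] = wi[-1] = 0.5
        parts.append(wi)
    w = parts[0]
    for p in parts[1:]:
        w = np.multiply.outer(w, p)
    return (w * h ** len(shape)).ravel()


def gradient(f: np.ndarray, h: float) -> list[np.ndarray]:
    """Nodal gradient: central differences inside, one-sided at the
    boundary (``numpy.gradient`` convention)."""
    if f.ndim == 1:
        return [np.gradient(f, h)]
    return list(np.gradient(f, h))


def grad_norm(f: np.ndarray, h: float) -> np.ndarray:
    """Euclidean norm of the nodal gradient."""
    g = gradient(f, h)
    return np.sqrt(sum(gi**2 for gi in g))
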