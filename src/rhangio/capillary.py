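"""Capillary phase field: split Cahn-Hilliard dynamics with
AF-dependent endothelial proliferation.

The fourth-order equation

    dc/dt = M lap(mu) + B_p(af) * c * H(c),    mu = -c + c^3 - eps lap(c)

is advanced by backward Euler on the coupled (c, mu) system, solved with
Newton's method; both fields carry zero-flux boundaries.  With the
default alpha_p = 0 the proliferation source vanishes identically and
all vessel growth enters through the tip-cell imprint.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import scipy.sparse as sp
import scipy.sparse.linalg as spla

from .af_solver import AFField, heaviside
from .geometry import SimDomain
from .operators import gradient, neumann_laplacian, quadrature_weights
from .units import ParameterSet

__all__ = [
    "CapillaryState",
    "B_p",
    "step_capillaries",
    "ginzburg_landau_energy",
    "vessel_mass",
    "CapillaryStepError",
]


class CapillaryStepError(RuntimeError):
    """Newton failed to converge; caller may retry with a smaller dt."""

    def __init__(self, message: str, residual: float):
        super().__init__(message)
        self.residual = residual


@dataclass
class CapillaryState:
    """Phase field c (~+1 vessel, ~-1 tissue) and auxiliary potential mu."""

    c: np.ndarray
    mu: np.ndarray

    @classmethod
    def from_field(cls, c: np.ndarray, p: ParameterSet, domain: SimDomain) -> "CapillaryState":
        """Initialize mu consistently from c: mu = -c + c^3 - eps lap(c)."""
        L = neumann_laplacian(domain.shape, domain.h)
        mu = -c + c**3 - p.eps * (L @ c.ravel()).reshape(c.shape)
        return cls(c=c.astype(float).copy(), mu=mu)

    def copy(self) -> "CapillaryState":
        return CapillaryState(c=self.c.copy(), mu=self.mu.copy())

    def overshoot_nodes(self, tol: float = 0.1) -> int:
        """Diagnostic: number of nodes with |c| > 1 + tol."""
        return int(np.count_nonzero(np.abs(self.c) > 1.0 + tol))


def B_p(af: np.ndarray | float, alpha: float, af_p: float) -> np.ndarray | float:
    """Piecewise-linear proliferation rate: 0 below af = 0, linear slope
    ``alpha`` up to ``af_p``, saturated at ``alpha * af_p`` above."""
    return alpha * np.clip(af, 0.0, af_p)


def step_capillaries(
    state: CapillaryState,
    af: AFField | None,
    dt: float,
    p: ParameterSet,
    domain: SimDomain,
    *,
    newton_tol: float = 1e-8,
    max_newton: int = 30,
) -> CapillaryState:
    """One backward-Euler step of the coupled (c, mu) system.

    Residual (flattened, N nodes each):

        F1 = c - c_old - dt * (M L mu + B_p(af) c H(c))
        F2 = mu + c - c^3 + eps L c

    Returns a new state; raises :class:`CapillaryStepError` on Newton
    failure so the caller can halve dt.
    """
    if dt <= 0:
        raise ValueError("dt must be positive")
    shape = domain.shape
    L = neumann_laplacian(shape, domain.h)
    n = L.shape[0]
    I = sp.identity(n, format="csr")
    c_old = state.c.ravel()

    src_rate = 0.0
    if af is not None and p.alpha_p != 0.0:
        src_rate = np.asarray(B_p(af.af, p.alpha_p, p.af_p)).ravel()

    c = state.c.ravel().copy()
    mu = state.mu.ravel().copy()
    resid = np.inf
    for _ in range(max_newton):
        Hc = heaviside(c)
        source = src_rate * c * Hc if np.ndim(src_rate) else src_rate * c * Hc
        F1 = c - c_old - dt * (p.M * (L @ mu) + source)
        F2 = mu + c - c**3 + p.eps * (L @ c)
        resid = max(np.abs(F1).max(), np.abs(F2).max())
        if resid < newton_tol:
            break
        # H treated as piecewise constant within the Newton iteration
        dF1_dc = I - dt * sp.diags(np.broadcast_to(src_rate * Hc, (n,)).copy())
        dF1_dmu = -dt * p.M * L
        dF2_dc = sp.diags(1.0 - 3.0 * c**2) + p.eps * L
        J = sp.bmat([[dF1_dc, dF1_dmu], [dF2_dc, I]], format="csc")
        delta = spla.spsolve(J, np.concatenate([F1, F2]))
        c -= delta[:n]
        mu -= delta[n:]
    else:
        raise CapillaryStepError(
            f"Newton did not converge (residual {resid:.3e})", residual=resid
        )
    return CapillaryState(c=c.reshape(shape), mu=mu.reshape(shape))


def ginzburg_landau_energy(state: CapillaryState, p: ParameterSet, domain: SimDomain) -> float:
    """Discrete free energy: integral of 1/4 (c^2-1)^2 + eps/2 |grad c|^2.

    Quadrature is matched to the stepper's discrete operators (trapezoid
    node weights, gradients on cell edges), which makes the backward
    Euler flow dissipate exactly this functional."""
    c = state.c
    w = quadrature_weights(domain.shape, domain.h).reshape(domain.shape)
    well = float(np.sum(w * 0.25 * (c**2 - 1.0) ** 2))
    grad = 0.0
    for axis in range(c.ndim):
        g = np.diff(c, axis=axis) / domain.h
        # edge weight: mean of the two node weights
        lo = [slice(None)] * c.ndim
        hi = [slice(None)] * c.ndim
        lo[axis] = slice(None, -1)
        hi[axis] = slice(1, None)
        we = 0.5 * (w[tuple(lo)] + w[tuple(hi)])
        grad += float(np.sum(we * g**2))
    return well + 0.5 * p.eps * grad


def vessel_mass(state: CapillaryState, domain: SimDomain) -> float:
    """Conserved discrete mass of c (trapezoid quadrature, the left
    null-vector of the Neumann Laplacian)."""
    w = quadrature_weights(domain.shape, domain.h)
    return float(w @ state.c.ravel())


def vessel_volume_fraction(state: CapillaryState, domain: SimDomain) -> float:
    """Fraction of nodes on the vessel side of the c = 0 isosurface."""
    return float(np.count_nonzero(state.c > 0.0)) / state.c.size
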