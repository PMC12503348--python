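"""Quasi-steady angiogenic-factor (AF) field.

The AF concentration solves, at every step, the linear elliptic balance

    D_af lap(af) + V_pT * phi * (1 - H(c)) - V_uc * af * H(c) - V_d * af = 0

with zero-flux boundaries.  ``H`` is the Heaviside function with
``H(0) = 0``: the diffuse interface's midpoint belongs to tissue, so AF
production is suppressed strictly inside vessels only.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import scipy.sparse as sp
import scipy.sparse.linalg as spla

from .geometry import SimDomain
from .operators import grad_norm, gradient, neumann_laplacian
from .units import ParameterSet

__all__ = ["AFField", "heaviside", "solve_af_steady", "af_gradient", "SingularAFSystem"]


class SingularAFSystem(RuntimeError):
    """The pure-Neumann AF system has no reaction term anywhere
    (V_d = 0 and no vessel nodes) and is singular."""


class AFSolveError(RuntimeError):
    """The linear AF solve did not reach the requested residual."""


def heaviside(c: np.ndarray | float) -> np.ndarray | float:
    """H(c) = 1 where c > 0 (intravascular), else 0. H(0) = 0."""
    if np.isscalar(c):
        return 1.0 if c > 0 else 0.0
    return (np.asarray(c) > 0).astype(float)


@dataclass
class AFField:
    """Solved AF concentration with a cached nodal gradient."""

    af: np.ndarray
    h: float
    _grad: list[np.ndarray] | None = field(default=None, repr=False)

    @property
    def grad(self) -> list[np.ndarray]:
        if self._grad is None:
            self._grad = gradient(self.af, self.h)
        return self._grad

    @property
    def grad_norm(self) -> np.ndarray:
        return np.sqrt(sum(g**2 for g in self.grad))

    def at(self, idx: tuple[int, ...]) -> float:
        return float(self.af[idx])

    def grad_at(self, idx: tuple[int, ...]) -> np.ndarray:
        return np.array([g[idx] for g in self.grad])


def solve_af_steady(
    phi: np.ndarray,
    c: np.ndarray,
    p: ParameterSet,
    domain: SimDomain,
    *,
    rtol: float = 1e-10,
) -> AFField:
    """Solve the quasi-steady AF balance on the grid.

    Returns the nodal field; raises :class:`SingularAFSystem` when the
    operator is not coercive (V_d = 0 and no uptake anywhere).
    """
    shape = domain.shape
    Hc = heaviside(c).ravel()
    if p.V_d == 0.0 and not Hc.any():
        raise SingularAFSystem(
            "V_d = 0 and no vessel nodes: pure-Neumann system is singular"
        )
    L = neumann_laplacian(shape, domain.h)
    A = p.D_af * L - sp.diags(p.V_uc * Hc + p.V_d)
    b = -p.V_pT * (phi.ravel() * (1.0 - Hc))
    af = spla.spsolve(A.tocsc(), b)
    resid = np.linalg.norm(A @ af - b)
    scale = max(np.linalg.norm(b), 1.0)
    if not np.all(np.isfinite(af)) or resid > max(rtol * scale, 1e-8):
        raise AFSolveError(f"AF solve residual {resid:.3e} above tolerance")
    return AFField(af=af.reshape(shape), h=domain.h)


def af_gradient(aff: AFField, domain: SimDomain) -> list[np.ndarray]:
    """Nodal gradient of the solved AF field (central differences in
    the interior, one-sided at boundaries)."""
    return gradient(aff.af, domain.h)
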