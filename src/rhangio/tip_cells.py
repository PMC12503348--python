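"""Discrete tip-cell agents: activation, Notch exclusion, deactivation,
chemotactic motion and the phase-field imprint with stalk-cell
proliferation.

Per-step ordering (driven by the simulation loop):
deactivate -> activate -> compute velocities -> imprint -> move, so the
imprint uses the velocity assigned in the same sweep.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np

from .af_solver import AFField
from .capillary import CapillaryState
from .geometry import SimDomain
from .units import ParameterSet

__all__ = [
    "TipCell",
    "activate_tips",
    "deactivate_tips",
    "tip_velocity",
    "imprint_tips",
    "move_tips",
    "S_p",
]

log = logging.getLogger(__name__)


@dataclass
class TipCell:
    """A migratory endothelial agent (positions in sau)."""

    position: np.ndarray
    velocity: np.ndarray
    active: bool = True
    born_at: float = 0.0

    def copy(self) -> "TipCell":
        return TipCell(
            position=self.position.copy(),
            velocity=self.velocity.copy(),
            active=self.active,
            born_at=self.born_at,
        )


def S_p(af: np.ndarray | float, p: ParameterSet) -> np.ndarray | float:
    """Stalk-cell proliferation rate: same piecewise-linear shape as the
    endothelial term but with the stalk-cell rate alpha_pSC."""
    return p.alpha_pSC * np.clip(af, 0.0, p.af_p)


def _eligible_nodes(
    c: np.ndarray, aff: AFField, p: ParameterSet
) -> np.ndarray:
    """Boolean mask of nodes satisfying all activation predicates."""
    return (
        (c >= 1.0 - p.c_tol)
        & (aff.af >= p.T_c)
        & (aff.grad_norm >= p.G_m)
    )


def any_activation_possible(c: np.ndarray, aff: AFField, p: ParameterSet) -> bool:
    """True if at least one node satisfies the activation predicates
    (ignores Notch exclusion — used by activation-time bisection and the
    minimal-size estimator)."""
    return bool(_eligible_nodes(c, aff, p).any())


def activate_tips(
    c: np.ndarray,
    aff: AFField,
    tips: list[TipCell],
    p: ParameterSet,
    domain: SimDomain,
    *,
    t: float = 0.0,
    order: str = "lex",
    rng: np.random.Generator | None = None,
) -> list[TipCell]:
    """Place new tip cells at eligible nodes, honoring Notch exclusion.

    A node is eligible when c >= 1 - c_tol, af >= T_c and |grad af| >=
    G_m.  Candidates are visited in lexicographic node order (or a
    seeded random order with ``order='random'``) and accepted greedily
    whenever no active tip — existing or newly placed — lies within
    delta4.  Returns a new list; the input tips are carried over.
    """
    mask = _eligible_nodes(c, aff, p)
    new_tips = [tc for tc in tips]
    if not mask.any():
        return new_tips
    idx = np.argwhere(mask)
    if order == "random":
        if rng is None:
            rng = np.random.default_rng(0)
        idx = idx[rng.permutation(len(idx))]
    elif order != "lex":
        raise ValueError(f"unknown traversal order {order!r}")

    active_pos = [tc.position for tc in new_tips if tc.active]
    origin = np.asarray(domain.origin)
    d4sq = p.delta4**2
    for node in idx:
        pos = origin + domain.h * node.astype(float)
        ok = True
        for q in active_pos:
            if float(np.sum((pos - q) ** 2)) < d4sq:
                ok = False
                break
        if not ok:
            continue
        tc = TipCell(
            position=pos,
            velocity=np.zeros(domain.dim),
            active=True,
            born_at=t,
        )
        new_tips.append(tc)
        active_pos.append(pos)
        log.debug("TC activated at %s (t=%.3f)", pos, t)
    return new_tips


def deactivate_tips(
    tips: list[TipCell], aff: AFField, p: ParameterSet, domain: SimDomain
) -> list[TipCell]:
    """Deactivate tips whose local af or |grad af| fell below threshold."""
    out = []
    for tc in tips:
        tc = tc.copy()
        if tc.active:
            idx = domain.nearest_node(tc.position)
            af_loc = aff.at(idx)
            g_loc = float(np.linalg.norm(aff.grad_at(idx)))
            if af_loc < p.T_c or g_loc < p.G_m:
                tc.active = False
                log.debug("TC deactivated at %s", tc.position)
        out.append(tc)
    return out


def tip_velocity(grad_af: np.ndarray, p: ParameterSet) -> np.ndarray:
    """Chemotactic velocity: v = chi * grad(af), with the speed capped
    at chi * G_M for gradients steeper than G_M.

    Calling this with |grad af| < G_m is a caller-ordering bug (the tip
    should have been deactivated first).
    """
    g = float(np.linalg.norm(grad_af))
    if g < p.G_m:
        raise ValueError(
            f"tip_velocity called with G={g:.6g} < G_m={p.G_m:.6g}; "
            "deactivation must run before motion"
        )
    if g >= p.G_M:
        return p.chi * np.asarray(grad_af) * (p.G_M / g)
    return p.chi * np.asarray(grad_af)


def assign_velocities(
    tips: list[TipCell], aff: AFField, p: ParameterSet, domain: SimDomain
) -> list[TipCell]:
    """Compute this step's velocity for every active tip."""
    out = []
    for tc in tips:
        tc = tc.copy()
        if tc.active:
            idx = domain.nearest_node(tc.position)
            tc.velocity = tip_velocity(aff.grad_at(idx), p)
        out.append(tc)
    return out


def imprint_tips(
    state: CapillaryState,
    tips: list[TipCell],
    aff: AFField,
    p: ParameterSet,
    domain: SimDomain,
) -> CapillaryState:
    """Overwrite c with the tip-cell value at every node within R_c of
    an active tip:

        c_c = S_p(af) * pi * R_c^2 / |v|

    evaluated with the tip's local af and this step's speed (floored at
    v_min to guard the division)."""
    if not any(tc.active for tc in tips):
        return state
    new = state.copy()
    shape = domain.shape
    origin = np.asarray(domain.origin)
    h = domain.h
    r_nodes = int(math.ceil(p.R_c / h))
    axes = domain.axes()
    for tc in tips:
        if not tc.active:
            continue
        idx = domain.nearest_node(tc.position)
        af_loc = aff.at(idx)
        speed = float(np.linalg.norm(tc.velocity))
        if speed < p.v_min:
            log.debug("TC speed %.3e floored to v_min", speed)
            speed = p.v_min
        c_c = float(S_p(af_loc, p)) * math.pi * p.R_c**2 / speed
        # local window around the tip
        sl = []
        for d in range(domain.dim):
            i0 = max(idx[d] - r_nodes - 1, 0)
            i1 = min(idx[d] + r_nodes + 2, shape[d])
            sl.append(slice(i0, i1))
        grids = np.meshgrid(
            *[axes[d][sl[d]] for d in range(domain.dim)], indexing="ij"
        )
        dist2 = sum(
            (grids[d] - tc.position[d]) ** 2 for d in range(domain.dim)
        )
        inside = dist2 <= p.R_c**2
        new.c[tuple(sl)][inside] = c_c
    return new


def move_tips(
    tips: list[TipCell], dt: float, domain: SimDomain
) -> list[TipCell]:
    """Advance active tips by v * dt, clamped to the domain box."""
    out = []
    for tc in tips:
        tc = tc.copy()
        if tc.active:
            target = tc.position + tc.velocity * dt
            clamped = domain.clamp(target)
            if not np.array_equal(target, clamped):
                log.debug("TC clamped at boundary: %s -> %s", target, clamped)
            tc.position = clamped
        out.append(tc)
    return out


def n_active(tips: list[TipCell]) -> int:
    return sum(1 for tc in tips if tc.active)
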