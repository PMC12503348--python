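"""Simulation orchestration: the coupled time loop with adaptive
stepping, activation-time bisection and the minimal-tumor-size
estimator.

Per step: update the tumor ellipsoid at the current time, refresh the
quasi-steady AF field, run the agent sweep (deactivate -> activate ->
velocities -> imprint), choose dt (dt_min whenever active tips exist,
otherwise the adaptive rule checked by activation-time bisection), move
the tips and advance the capillary field, then append the history row.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Callable

import numpy as np

from . import tip_cells as tcs
from .af_solver import AFField, solve_af_steady
from .capillary import (
    CapillaryState,
    CapillaryStepError,
    ginzburg_landau_energy,
    step_capillaries,
    vessel_volume_fraction,
)
from .geometry import SimDomain, TumorEllipsoid, tumor_field
from .operators import gradient
from .units import ParameterSet

__all__ = [
    "SimState",
    "MinimalSizeResult",
    "adaptive_dt",
    "step",
    "run",
    "bisect_activation_time",
    "estimate_minimal_size",
]

log = logging.getLogger(__name__)

HISTORY_COLUMNS = (
    "step",
    "t_tau",
    "dt",
    "n_active_tips",
    "af_mean",
    "af_max",
    "af_min",
    "tumor_volume",
    "vessel_volume_fraction",
    "energy",
)


@dataclass
class SimState:
    """The full coupled state of a run."""

    domain: SimDomain
    tumor: TumorEllipsoid
    capillaries: CapillaryState
    tips: list = field(default_factory=list)
    af: AFField | None = None
    t: float = 0.0
    step_index: int = 0
    seed: int = 0
    history: list[dict] = field(default_factory=list)
    events: list[dict] = field(default_factory=list)

    def copy(self) -> "SimState":
        return SimState(
            domain=self.domain,
            tumor=self.tumor,
            capillaries=self.capillaries.copy(),
            tips=[tc.copy() for tc in self.tips],
            af=self.af,
            t=self.t,
            step_index=self.step_index,
            seed=self.seed,
            history=list(self.history),
            events=list(self.events),
        )

    @property
    def n_active_tips(self) -> int:
        return tcs.n_active(self.tips)


def adaptive_dt(mu: np.ndarray, p: ParameterSet, domain: SimDomain, *, norm: str = "l2") -> float:
    """Adaptive time step dt = max(dt_min, dt_max / (1 + alpha |E'|^2))
    with E' = -||grad mu||^2.

    The gradient norm is the domain L2 norm by default (``norm='linf'``
    for the pointwise maximum)."""
    g = gradient(mu, domain.h)
    grad2 = sum(gi**2 for gi in g)
    if norm == "l2":
        norm2 = float(np.sum(grad2)) * domain.h**domain.dim
    elif norm == "linf":
        norm2 = float(np.max(grad2))
    else:
        raise ValueError(f"unknown norm {norm!r}")
    e_prime = -norm2
    return max(p.dt_min, p.dt_max / (1.0 + p.alpha_dt * e_prime**2))


def _solve_af(state: SimState, p: ParameterSet, t: float | None = None) -> AFField:
    phi = tumor_field(state.domain, state.t if t is None else t, state.tumor)
    return solve_af_steady(phi, state.capillaries.c, p, state.domain)


def bisect_activation_time(
    state: SimState,
    dt_candidate: float,
    p: ParameterSet,
    *,
    activation_at: Callable[[float], bool] | None = None,
) -> float:
    """Smallest dt in [dt_min, dt_candidate] (to within dt_min) at which
    a tip-cell activation would occur, or dt_candidate if none.

    The trial at dt advances the tumor clock and takes one capillary
    step of size dt, re-solves the AF field, and applies the activation
    predicates (Notch exclusion is irrelevant to existence).  A custom
    ``activation_at`` predicate may be supplied (synthetic ramps, tests).
    """
    if dt_candidate <= p.dt_min:
        return dt_candidate

    def default_activation_at(dt: float) -> bool:
        try:
            trial = step_capillaries(state.capillaries, state.af, dt, p, state.domain)
        except CapillaryStepError:
            return True  # force the short step; the main loop will retry
        phi = tumor_field(state.domain, state.t + dt, state.tumor)
        aff = solve_af_steady(phi, trial.c, p, state.domain)
        return tcs.any_activation_possible(trial.c, aff, p)

    if activation_at is None:
        activation_at = default_activation_at

    if not activation_at(dt_candidate):
        return dt_candidate
    if activation_at(p.dt_min):
        return p.dt_min
    lo, hi = p.dt_min, dt_candidate
    while hi - lo > p.dt_min:
        mid = 0.5 * (lo + hi)
        if activation_at(mid):
            hi = mid
        else:
            lo = mid
    return hi


def step(state: SimState, p: ParameterSet, *, max_retries: int = 6) -> SimState:
    """Advance the simulation by one (possibly adaptive) time step."""
    state = state.copy()
    domain = state.domain

    aff = _solve_af(state, p)
    state.af = aff

    # agent sweep: deactivate -> activate -> velocities -> imprint
    tips = tcs.deactivate_tips(state.tips, aff, p, domain)
    n_before = tcs.n_active(tips)
    tips = tcs.activate_tips(
        state.capillaries.c, aff, tips, p, domain, t=state.t
    )
    n_new = tcs.n_active(tips) - n_before
    if n_new:
        state.events.append(
            {"t": state.t, "event": "activation", "count": n_new}
        )
    tips = tcs.assign_velocities(tips, aff, p, domain)
    imprinted = tcs.imprint_tips(state.capillaries, tips, aff, p, domain)

    if tcs.n_active(tips) > 0:
        dt = p.dt_min
    else:
        dt = adaptive_dt(state.capillaries.mu, p, domain)
        if dt > p.dt_min:
            dt = bisect_activation_time(state, dt, p)

    # capillary advance with halved-dt retry on Newton failure
    new_cap = None
    for attempt in range(max_retries):
        try:
            new_cap = step_capillaries(imprinted, aff, dt, p, domain)
            break
        except CapillaryStepError as err:
            if dt <= p.dt_min or attempt == max_retries - 1:
                raise
            dt = max(p.dt_min, dt / 2.0)
            log.warning("capillary step failed (%s); retrying with dt=%.3g", err, dt)
    assert new_cap is not None

    tips = tcs.move_tips(tips, dt, domain)

    state.capillaries = new_cap
    state.tips = tips
    state.t += dt
    state.step_index += 1
    state.history.append(
        {
            "step": state.step_index,
            "t_tau": state.t,
            "dt": dt,
            "n_active_tips": tcs.n_active(tips),
            "af_mean": float(aff.af.mean()),
            "af_max": float(aff.af.max()),
            "af_min": float(aff.af.min()),
            "tumor_volume": state.tumor.volume(state.t, dim=domain.dim),
            "vessel_volume_fraction": vessel_volume_fraction(new_cap, domain),
            "energy": ginzburg_landau_energy(new_cap, p, domain),
        }
    )
    log.info(
        "step %d: t=%.2f tau, dt=%.2f, %d active TCs",
        state.step_index, state.t, dt, tcs.n_active(tips),
    )
    return state


def run(
    state: SimState,
    p: ParameterSet,
    *,
    t_end: float | None = None,
    n_steps: int | None = None,
    callback: Callable[[SimState], None] | None = None,
) -> SimState:
    """Advance until ``t_end`` (tau) or for ``n_steps`` steps."""
    if (t_end is None) == (n_steps is None):
        raise ValueError("give exactly one of t_end / n_steps")
    while True:
        if t_end is not None and state.t >= t_end - 1e-12:
            break
        if n_steps is not None and state.step_index >= n_steps:
            break
        state = step(state, p)
        if callback is not None:
            callback(state)
    return state


@dataclass(frozen=True)
class MinimalSizeResult:
    """Outcome of the minimal angiogenic tumor size search."""

    capable: bool
    min_volume_fraction: float | None
    min_diameter_fraction: float | None
    iterations: int
    bracket_width: float

    def __post_init__(self) -> None:
        if self.capable and not (0.0 < self.min_volume_fraction <= 1.0):
            raise ValueError("min_volume_fraction must lie in (0, 1]")
        if self.capable and self.bracket_width >= 0.05 + 1e-12:
            raise ValueError("stopping bracket must be below 5% of max volume")


def estimate_minimal_size(
    activation_test: Callable[[float], bool],
    *,
    rel_tol: float = 0.05,
) -> MinimalSizeResult:
    """Bisect the tumor volume fraction for the smallest activating size.

    ``activation_test(fraction)`` performs the deterministic one-step
    activation check at the given fraction of the maximal volume.  The
    search first tests the full volume (fraction 1); if negative the
    condition is flagged incapable.  Otherwise the bracket (0, 1] is
    bisected until its width falls below ``rel_tol`` of the maximal
    volume, and the upper (activating) end is reported.
    """
    iterations = 1
    if not activation_test(1.0):
        return MinimalSizeResult(
            capable=False,
            min_volume_fraction=None,
            min_diameter_fraction=None,
            iterations=iterations,
            bracket_width=1.0,
        )
    lo, hi = 0.0, 1.0
    while hi - lo > rel_tol:
        mid = 0.5 * (lo + hi)
        iterations += 1
        if activation_test(mid):
            hi = mid
        else:
            lo = mid
    return MinimalSizeResult(
        capable=True,
        min_volume_fraction=hi,
        min_diameter_fraction=hi ** (1.0 / 3.0),
        iterations=iterations,
        bracket_width=hi - lo,
    )


def scenario_activation_test(
    domain: SimDomain,
    tumor: TumorEllipsoid,
    c0: np.ndarray,
    p: ParameterSet,
) -> Callable[[float], bool]:
    """One-step activation predicate for a concrete scenario.

    The probe at volume fraction f rescales both tumor diameters by
    f^(1/3), solves the AF field on the initial capillary network, and
    checks whether any node satisfies the activation predicates (the
    model is deterministic, so one step suffices)."""
    from .geometry import TumorEllipsoid as _TE

    def test(fraction: float) -> bool:
        s = fraction ** (1.0 / 3.0)
        probe = _TE(
            center=tumor.center,
            d_p=tumor.d_p * s,
            d_a=tumor.d_a * s,
            tgr=tumor.tgr,
            tau_minutes=tumor.tau_minutes,
        )
        phi = tumor_field(domain, 0.0, probe)
        aff = solve_af_steady(phi, c0, p, domain)
        return tcs.any_activation_possible(c0, aff, p)

    return test
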