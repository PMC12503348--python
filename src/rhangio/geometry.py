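"""Simulation domain, structured grid and the prescribed tumor ellipsoid.

The reference discretization is a structured axis-aligned grid with
uniform spacing ``h``: node-centered fields, 0-based indexing, physical
coordinate = ``origin + index * h``.  Lateral axes (x, y) run parallel to
the retinal layers; z points toward the inner eye.  All lengths are in
simulation units (sau) unless stated otherwise.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np

from .units import MINUTES_PER_YEAR

__all__ = [
    "SimDomain",
    "TumorEllipsoid",
    "make_domain",
    "semiaxes_at",
    "tumor_indicator",
    "GridSpacingWarning",
]


class GridSpacingWarning(UserWarning):
    """Grid spacing exceeds the tip-cell radius (agent imprints may be
    under-resolved)."""


@dataclass(frozen=True)
class SimDomain:
    """Axis-aligned box domain with a uniform structured grid."""

    dim: int
    extent: tuple[float, ...]  # side length per axis, sau
    h: float  # grid spacing, sau
    origin: tuple[float, ...] = None  # type: ignore[assignment]

    def __post_init__(self) -> None:
        if self.dim not in (1, 2, 3):
            raise ValueError("dim must be 1, 2 or 3")
        if len(self.extent) != self.dim:
            raise ValueError("extent length must match dim")
        if any(e <= 0 for e in self.extent):
            raise ValueError("extent must be strictly positive")
        if self.h <= 0:
            raise ValueError("h must be strictly positive")
        if self.origin is None:
            object.__setattr__(self, "origin", (0.0,) * self.dim)

    @property
    def shape(self) -> tuple[int, ...]:
        """Node count per axis (extent is an integer multiple of h)."""
        return tuple(int(round(e / self.h)) + 1 for e in self.extent)

    @property
    def n_nodes(self) -> int:
        return int(np.prod(self.shape))

    def axes(self) -> list[np.ndarray]:
        """Node coordinates along each axis."""
        return [
            o + self.h * np.arange(n)
            for o, n in zip(self.origin, self.shape)
        ]

    def meshgrid(self) -> list[np.ndarray]:
        """Full nodal coordinate arrays (``indexing='ij'``)."""
        return list(np.meshgrid(*self.axes(), indexing="ij"))

    def contains(self, x: np.ndarray) -> bool:
        x = np.asarray(x, dtype=float)
        lo = np.asarray(self.origin)
        hi = lo + np.asarray(self.extent)
        return bool(np.all(x >= lo) and np.all(x <= hi))

    def clamp(self, x: np.ndarray) -> np.ndarray:
        """Project a position onto the closed box."""
        lo = np.asarray(self.origin)
        hi = lo + np.asarray(self.extent)
        return np.clip(np.asarray(x, dtype=float), lo, hi)

    def nearest_node(self, x: np.ndarray) -> tuple[int, ...]:
        idx = np.rint((np.asarray(x, dtype=float) - np.asarray(self.origin)) / self.h)
        return tuple(
            int(np.clip(i, 0, n - 1)) for i, n in zip(idx, self.shape)
        )


def make_domain(
    lesion_bbox: tuple[float, ...],
    retinal_depth: float | None,
    h: float,
    dim: int = 3,
    *,
    R_c: float | None = None,
    strict: bool = False,
) -> SimDomain:
    """Build a domain twice the lesion bounding box laterally and (for
    3D) as deep as the retina axially.

    Extents are rounded up to an integer multiple of ``h``.  When ``R_c``
    is given and ``h > R_c`` a :class:`GridSpacingWarning` is emitted, or
    a ``ValueError`` raised with ``strict=True``.
    """
    if h <= 0:
        raise ValueError("h must be positive")
    if any(b <= 0 for b in lesion_bbox):
        raise ValueError("lesion bbox must be positive")
    if R_c is not None and h > R_c:
        msg = f"grid spacing h={h} exceeds tip-cell radius R_c={R_c}"
        if strict:
            raise ValueError(msg)
        warnings.warn(msg, GridSpacingWarning, stacklevel=2)

    def _round_up(v: float) -> float:
        n = math.ceil(v / h - 1e-9)
        return n * h

    if len(lesion_bbox) == 1 and dim > 1 and retinal_depth is None:
        # single lateral size: square footprint, no axial side
        lesion_bbox = tuple(lesion_bbox) * dim
    lateral = [_round_up(2.0 * b) for b in lesion_bbox]
    if dim == len(lesion_bbox):
        # caller passed a full-dimension bbox and no separate depth
        extent = tuple(lateral)
    elif dim == len(lesion_bbox) + 1:
        if retinal_depth is None or retinal_depth <= 0:
            raise ValueError("retinal_depth required for an axial side")
        extent = tuple(lateral + [_round_up(retinal_depth)])
    else:
        raise ValueError("bbox length incompatible with dim")
    return SimDomain(dim=dim, extent=extent, h=h)


@dataclass(frozen=True)
class TumorEllipsoid:
    """Prescribed tumor: an ellipsoid growing by a fixed volumetric
    factor per year, lateral semiaxes equal (``s_x = s_y``).

    ``d_p`` is the initial lateral diameter, ``d_a`` the initial axial
    diameter (both sau); ``tgr`` the yearly volumetric growth factor.
    ``tau_minutes`` fixes the simulation time unit so that times given in
    tau convert to years.
    """

    center: tuple[float, ...]
    d_p: float
    d_a: float
    tgr: float = 1.35
    tau_minutes: float = 26.0

    def __post_init__(self) -> None:
        if self.d_p <= 0 or self.d_a <= 0:
            raise ValueError("tumor diameters must be positive")
        if self.tgr <= 0:
            raise ValueError("tgr must be positive")

    @property
    def tgr_per_tau(self) -> float:
        """Volumetric growth factor over one tau."""
        return self.tgr ** (self.tau_minutes / MINUTES_PER_YEAR)

    def semiaxes(self, t: float) -> tuple[float, ...]:
        return semiaxes_at(t, self)

    def volume(self, t: float, dim: int = 3) -> float:
        """Analytic ellipsoid volume (3D) or lateral-section area (2D)."""
        s = semiaxes_at(t, self)
        if dim == 3:
            return 4.0 / 3.0 * math.pi * s[0] * s[1] * s[2]
        return math.pi * s[0] * s[1]


def semiaxes_at(t: float, tumor: TumorEllipsoid) -> tuple[float, float, float]:
    """Semiaxes at time ``t`` (tau): ``s(t) = s(0) * g^(t/3)`` with g the
    per-tau volumetric factor, so the volume grows exactly by the yearly
    factor over one year."""
    if t < 0:
        raise ValueError("t must be nonnegative")
    growth = tumor.tgr_per_tau ** (t / 3.0)
    return (
        tumor.d_p / 2.0 * growth,
        tumor.d_p / 2.0 * growth,
        tumor.d_a / 2.0 * growth,
    )


def tumor_indicator(
    x: np.ndarray | list[np.ndarray],
    t: float,
    tumor: TumorEllipsoid,
    dim: int | None = None,
) -> np.ndarray:
    """Indicator field of the tumor ellipsoid at time ``t``.

    ``x`` is either a single position (1D array of length dim) or a list
    of coordinate arrays (one per axis, e.g. from
    :meth:`SimDomain.meshgrid`); boundary points (sum exactly 1) count as
    inside.
    """
    s = semiaxes_at(t, tumor)
    if isinstance(x, np.ndarray) and x.ndim == 1:
        coords = [np.asarray(x[i], dtype=float) for i in range(len(x))]
    else:
        coords = [np.asarray(a, dtype=float) for a in x]
    ndim = dim if dim is not None else len(coords)
    q = 0.0
    for i in range(ndim):
        # in 2D the two coordinates are the lateral axes
        si = s[i] if ndim == 3 or i < 2 else s[2]
        q = q + (coords[i] - tumor.center[i]) ** 2 / si**2
    return (q <= 1.0).astype(float)


def tumor_field(domain: SimDomain, t: float, tumor: TumorEllipsoid) -> np.ndarray:
    """Nodal tumor indicator on the whole grid."""
    return tumor_indicator(domain.meshgrid(), t, tumor, dim=domain.dim)


def discrete_tumor_volume(domain: SimDomain, t: float, tumor: TumorEllipsoid) -> float:
    """Voxel-sum estimate of the tumor volume (nodes inside x h^dim)."""
    return float(tumor_field(domain, t, tumor).sum()) * domain.h**domain.dim


def default_tumor(
    domain: SimDomain,
    d_p: float,
    d_a: float | None = None,
    tgr: float = 1.35,
    tau_minutes: float = 26.0,
    center: tuple[float, ...] | None = None,
) -> TumorEllipsoid:
    """Tumor centered laterally and mid-depth axially (configurable)."""
    if center is None:
        center = tuple(
            o + e / 2.0 for o, e in zip(domain.origin, domain.extent)
        )
    if d_a is None:
        d_a = d_p
    return TumorEllipsoid(
        center=center, d_p=d_p, d_a=d_a, tgr=tgr, tau_minutes=tau_minutes
    )
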