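"""Simulation unit system and model parameters.

All computation inside the package happens in simulation units: ``sau``
(space), ``tau`` (time) and ``afau`` (angiogenic-factor concentration).
Physical units appear only at I/O boundaries, where quantities carry an
explicit unit string (e.g. ``"um^2*mL*min^-1*ng^-1"``) and are converted
through :func:`to_sim_units` / :func:`from_sim_units`.

Internally a unit string is reduced to a signature of powers of
(length, time, concentration); mass and volume tokens are accepted as long
as they combine into a pure concentration power (mass/volume).
"""

from __future__ import annotations

import dataclasses
import json
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

import yaml

__all__ = [
    "UnitSystem",
    "ParameterSet",
    "UnitSignatureError",
    "parse_unit",
    "to_sim_units",
    "from_sim_units",
    "default_parameters",
    "load_parameters",
    "MINUTES_PER_YEAR",
]

#: minutes in a (365-day) year, used for yearly growth-rate conversion
MINUTES_PER_YEAR = 365.0 * 24.0 * 60.0


class UnitSignatureError(ValueError):
    """Raised when a unit string cannot be reduced to powers of
    length, time and concentration."""


@dataclass(frozen=True)
class UnitSystem:
    """The three base simulation units.

    Attributes
    ----------
    sau : float
        Space unit in micrometres.
    tau : float
        Time unit in minutes.
    afau : float
        AF-concentration unit in pg/mL.
    """

    sau: float = 800.0
    tau: float = 26.0
    afau: float = 6000.0

    def __post_init__(self) -> None:
        for name in ("sau", "tau", "afau"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be strictly positive")


# scale of each token to the base physical units (um, min, pg, mL), with
# the dimension axis it lives on: L (length), T (time), Ms (mass), V (volume)
_TOKENS: dict[str, tuple[str, float]] = {
    # length -> um
    "um": ("L", 1.0),
    "μm": ("L", 1.0),
    "mm": ("L", 1e3),
    "cm": ("L", 1e4),
    "m": ("L", 1e6),
    # time -> min
    "s": ("T", 1.0 / 60.0),
    "sec": ("T", 1.0 / 60.0),
    "min": ("T", 1.0),
    "hr": ("T", 60.0),
    "h": ("T", 60.0),
    "day": ("T", 1440.0),
    "d": ("T", 1440.0),
    "y": ("T", MINUTES_PER_YEAR),
    "yr": ("T", MINUTES_PER_YEAR),
    "year": ("T", MINUTES_PER_YEAR),
    # mass -> pg
    "pg": ("Ms", 1.0),
    "ng": ("Ms", 1e3),
    "ug": ("Ms", 1e6),
    "mg": ("Ms", 1e9),
    "g": ("Ms", 1e12),
    # volume -> mL
    "mL": ("V", 1.0),
    "ml": ("V", 1.0),
    "L": ("V", 1e3),
    "uL": ("V", 1e-3),
    "ul": ("V", 1e-3),
}

# simulation-unit tokens map straight onto the sim signature
_SIM_TOKENS = {"sau": "L_sim", "tau": "T_sim", "afau": "C_sim"}

_TOKEN_RE = re.compile(r"^([A-Za-zμ]+)(?:\^?(-?\d+))?$")


def parse_unit(unit: str) -> dict[str, int]:
    """Parse a unit string into exponent counts per dimension axis.

    Supports products separated by ``*``, ``·`` or whitespace, a single
    level of ``/`` division, and integer exponents written ``^2`` /
    ``^-1`` (or a bare trailing integer, e.g. ``um2``).  ``"1"`` and
    ``""`` denote a dimensionless quantity.
    """
    axes: dict[str, int] = {}
    text = unit.replace("·", "*").strip()
    if text in ("", "1", "-"):
        return axes
    segments = text.split("/")
    for seg_i, segment in enumerate(segments):
        sign = 1 if seg_i == 0 else -1
        for raw in re.split(r"[\s*]+", segment.strip()):
            if not raw or raw == "1":
                continue
            m = _TOKEN_RE.match(raw)
            if m is None:
                # allow forms like "um2" (exponent glued to the name)
                m2 = re.match(r"^([A-Za-zμ]+?)(-?\d+)$", raw)
                if m2 is None:
                    raise UnitSignatureError(f"cannot parse unit token {raw!r}")
                name, exp_s = m2.group(1), m2.group(2)
            else:
                name, exp_s = m.group(1), m.group(2)
            exp = sign * (int(exp_s) if exp_s else 1)
            if name in _SIM_TOKENS:
                key = _SIM_TOKENS[name]
            elif name in _TOKENS:
                key = name
            else:
                raise UnitSignatureError(f"unknown unit token {name!r} in {unit!r}")
            axes[key] = axes.get(key, 0) + exp
    return {k: v for k, v in axes.items() if v != 0}


def _signature(unit: str, units: UnitSystem) -> tuple[float, int, int, int]:
    """Reduce a unit string to (scale-to-sim, L-power, T-power, C-power).

    ``value_phys * scale`` gives the value in simulation units.
    """
    axes = parse_unit(unit)
    scale = 1.0
    powers = {"L": 0, "T": 0, "Ms": 0, "V": 0}
    for key, exp in axes.items():
        if key in _SIM_TOKENS.values():
            powers_key = {"L_sim": "L", "T_sim": "T", "C_sim": "C"}[key]
            if powers_key == "C":
                # afau token: already in sim units on the conc axis
                powers["Ms"] += exp
                powers["V"] -= exp
                scale *= units.afau**exp
            elif powers_key == "L":
                powers["L"] += exp
                scale *= units.sau**exp
            else:
                powers["T"] += exp
                scale *= units.tau**exp
        else:
            axis, factor = _TOKENS[key]
            powers[axis] += exp
            scale *= factor**exp
    if powers["Ms"] != -powers["V"]:
        raise UnitSignatureError(
            f"unit {unit!r} does not reduce to length/time/concentration "
            f"(residual mass power {powers['Ms']}, volume power {powers['V']})"
        )
    conc_pow = powers["Ms"]  # mass/volume pairs = concentration power
    sim_scale = scale / (
        units.sau ** powers["L"] * units.tau ** powers["T"] * units.afau**conc_pow
    )
    return sim_scale, powers["L"], powers["T"], conc_pow


def to_sim_units(value: float, unit: str, units: UnitSystem | None = None) -> float:
    """Convert a physical quantity to a dimensionless simulation value."""
    units = units or UnitSystem()
    scale, *_ = _signature(unit, units)
    return value * scale


def from_sim_units(value: float, unit: str, units: UnitSystem | None = None) -> float:
    """Convert a simulation value back to the given physical unit."""
    units = units or UnitSystem()
    scale, *_ = _signature(unit, units)
    return value / scale


@dataclass
class ParameterSet:
    """All model parameters, expressed in simulation units.

    Field-by-field unit signatures are documented in
    :data:`PHYSICAL_DEFAULTS`; validity invariants are enforced at
    construction.
    """

    M: float  # capillary-field mobility, sau^2/tau
    eps: float  # interface-width parameter, sau^2
    alpha_p: float  # mature-endothelial proliferation rate, 1/(afau*tau)
    alpha_pSC: float  # stalk-cell proliferation rate, 1/(afau*tau)
    af_p: float  # AF level of maximal proliferation, afau
    G_m: float  # minimum AF gradient for TC migration, afau/sau
    G_M: float  # capping AF gradient, afau/sau
    chi: float  # chemotactic sensitivity, sau^2/(afau*tau)
    R_c: float  # tip-cell radius, sau
    T_c: float  # minimum AF concentration for TC activation, afau
    delta4: float  # minimum TC-TC distance (Notch), sau
    D_af: float  # AF diffusivity, sau^2/tau
    V_pT: float  # AF production rate, afau/tau
    V_uc: float  # AF uptake rate, 1/tau
    V_d: float  # AF degradation rate, 1/tau
    tgr: float = 1.35  # volumetric tumor growth factor per year
    dt_min: float = 1.0  # tau
    dt_max: float = 50.0  # tau
    alpha_dt: float = 100.0  # adaptive-step weight
    c_tol: float = 1e-3  # activation tolerance on c >= 1
    v_min: float = 1e-6  # imprint division floor, sau/tau

    def __post_init__(self) -> None:
        if not self.G_m < self.G_M:
            raise ValueError("G_m must be < G_M")
        for name in (
            "M", "eps", "alpha_p", "alpha_pSC", "D_af",
            "V_pT", "V_uc", "V_d", "chi",
        ):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be nonnegative")
        if self.dt_min > self.dt_max:
            raise ValueError("dt_min must be <= dt_max")
        if self.af_p <= 0:
            raise ValueError("af_p must be positive")
        if self.R_c <= 0:
            raise ValueError("R_c must be positive")
        if self.delta4 <= 0:
            raise ValueError("delta4 must be positive")

    def replace(self, **changes: float) -> "ParameterSet":
        return dataclasses.replace(self, **changes)

    def as_dict(self) -> dict[str, float]:
        return dataclasses.asdict(self)


#: physical default for each parameter: (value, unit string).  Ranged
#: parameters default to the headline-run values.
PHYSICAL_DEFAULTS: Mapping[str, tuple[float, str]] = {
    "M": (1e-9, "mm^2*s^-1"),
    "eps": (1.5625, "um^2"),
    "alpha_p": (0.0, "mL*hr^-1*pg^-1"),
    "alpha_pSC": (0.000538889, "mL*hr^-1*pg^-1"),
    "af_p": (1800.0, "pg*mL^-1"),
    "G_m": (14.0, "ng*mL^-1*mm^-1"),
    "G_M": (42.0, "ng*mL^-1*mm^-1"),
    "chi": (8.33333, "um^2*mL*min^-1*ng^-1"),
    "R_c": (10.0, "um"),
    "T_c": (3000.0, "pg*mL^-1"),
    "delta4": (40.0, "um"),
    "D_af": (4.24e-5, "mm^2*s^-1"),
    "V_pT": (47.3, "pg*mL^-1*s^-1"),
    "V_uc": (2.3e-4, "s^-1"),
    "V_d": (0.92, "hr^-1"),
}


def yearly_growth_per_tau(tgr_per_year: float, units: UnitSystem) -> float:
    """Volumetric growth factor per tau equivalent to ``tgr_per_year``."""
    return tgr_per_year ** (units.tau / MINUTES_PER_YEAR)


def default_parameters(units: UnitSystem | None = None) -> ParameterSet:
    """Build the default :class:`ParameterSet` in simulation units.

    Every value is recomputed from its physical default, so the printed
    nondimensional table is reproduced up to its own rounding.
    """
    units = units or UnitSystem()
    sim = {k: to_sim_units(v, u, units) for k, (v, u) in PHYSICAL_DEFAULTS.items()}
    return ParameterSet(tgr=1.35, **sim)


def load_parameters(path: str | Path, units: UnitSystem | None = None) -> ParameterSet:
    """Load a parameter file (YAML or JSON) with explicit unit strings.

    Each entry is either a bare number (taken as already in simulation
    units) or a mapping ``{value: ..., unit: "..."}`` converted on load.
    Unlisted parameters keep their defaults.
    """
    units = units or UnitSystem()
    path = Path(path)
    text = path.read_text()
    raw = json.loads(text) if path.suffix == ".json" else yaml.safe_load(text)
    base = default_parameters(units)
    changes: dict[str, float] = {}
    for key, entry in (raw or {}).items():
        if isinstance(entry, dict):
            changes[key] = to_sim_units(float(entry["value"]), entry.get("unit", "1"), units)
        else:
            changes[key] = float(entry)
    return base.replace(**changes)
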