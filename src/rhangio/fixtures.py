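"""Deterministic scenario factory.

Every test and demo consumes scenarios built here (or analytic fields),
so no external data is ever required.  Fixture tumors use the printed
lesion diameters of the three clinical-like cases (490 / 208 / 560 um)
with the default parameter table; quantitative patient-specific numbers
are out of scope by construction.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field as dc_field

import numpy as np

from .capillary import CapillaryState
from .driver import SimState
from .geometry import SimDomain, default_tumor, make_domain
from .units import ParameterSet, UnitSystem, default_parameters
from .vessel_init import PlexusSpec, VesselMask, reconstruct_field_2d, reconstruct_field_3d, synth_plexus

__all__ = ["Scenario", "make_scenario", "build_state", "SCENARIO_NAMES"]


@dataclass(frozen=True)
class Scenario:
    """A fully serializable, replayable simulation setup."""

    name: str
    seed: int
    dim: int
    bbox_um: tuple[float, ...]
    depth_um: float | None
    h_um: float
    tumor_d_p_um: float
    tumor_d_a_um: float
    vessel: str  # "plexus" or "none"
    plexus: PlexusSpec | None = None
    overrides: dict = dc_field(default_factory=dict)

    def as_dict(self) -> dict:
        d = {
            "name": self.name,
            "seed": self.seed,
            "dim": self.dim,
            "bbox_um": list(self.bbox_um),
            "depth_um": self.depth_um,
            "h_um": self.h_um,
            "tumor_d_p_um": self.tumor_d_p_um,
            "tumor_d_a_um": self.tumor_d_a_um,
            "vessel": self.vessel,
            "overrides": dict(self.overrides),
        }
        if self.plexus is not None:
            d["plexus"] = self.plexus.__dict__.copy()
        return d


def _plexus_for(
    bbox_um: tuple[float, ...], tumor_d_um: float, n: int = 5, gap_um: float = 20.0
) -> PlexusSpec:
    size = (2.0 * bbox_um[0], 2.0 * bbox_um[1])
    return PlexusSpec(
        n_vessels=n,
        width_range_um=(6.0, 18.0),
        avascular_radius_um=tumor_d_um / 2.0 + gap_um,
        image_size_um=size,
        pixel_size_um=2.0,
    )


def make_scenario(name: str, seed: int = 1) -> Scenario:
    """Look up a named scenario from the registry."""
    if name == "p0_like":
        # 490 um lesion, patient-like distances, 3D at coarse spacing
        bbox = (666.5, 666.5)
        return Scenario(
            name=name, seed=seed, dim=3, bbox_um=bbox, depth_um=1031.0,
            h_um=28.0, tumor_d_p_um=490.0, tumor_d_a_um=490.0,
            vessel="plexus", plexus=_plexus_for(bbox, 490.0),
        )
    if name == "p1_like":
        # 208 um lesion in a shallow domain
        bbox = (281.5, 281.5)
        return Scenario(
            name=name, seed=seed, dim=3, bbox_um=bbox, depth_um=155.0,
            h_um=14.0, tumor_d_p_um=208.0, tumor_d_a_um=100.0,
            vessel="plexus", plexus=_plexus_for(bbox, 208.0, n=3),
        )
    if name == "2d_sprouting":
        # 280 um tumor with vessels 10 um off the rim: activates at the
        # default (lowest) uptake while staying desk-scale (58x58 grid)
        bbox = (200.0, 200.0)
        return Scenario(
            name=name, seed=seed, dim=2, bbox_um=bbox, depth_um=None,
            h_um=7.0, tumor_d_p_um=280.0, tumor_d_a_um=280.0,
            vessel="plexus", plexus=_plexus_for(bbox, 280.0, n=4, gap_um=10.0),
        )
    if name == "2d_no_angio":
        base = make_scenario("2d_sprouting", seed)
        # production too low for any node to reach the activation
        # concentration threshold
        return dataclasses.replace(base, name=name, overrides={"V_pT": 0.002})
    if name == "uniform_af":
        # domain-filling tumor, no vessels: af has the closed form V_pT/V_d
        return Scenario(
            name=name, seed=seed, dim=2, bbox_um=(200.0, 200.0), depth_um=None,
            h_um=10.0, tumor_d_p_um=4000.0, tumor_d_a_um=4000.0,
            vessel="none",
        )
    if name == "sc_proliferation_bug":
        # regression demo: mature-endothelial rate set equal to the
        # stalk-cell rate reproduces the spurious whole-network
        # enlargement pathology
        base = make_scenario("2d_sprouting", seed)
        p = default_parameters()
        return dataclasses.replace(
            base, name=name, overrides={"alpha_p": p.alpha_pSC}
        )
    raise KeyError(f"unknown scenario {name!r}")


SCENARIO_NAMES = (
    "p0_like",
    "p1_like",
    "2d_sprouting",
    "2d_no_angio",
    "uniform_af",
    "sc_proliferation_bug",
)


def build_state(
    scenario: Scenario, units: UnitSystem | None = None
) -> tuple[SimState, ParameterSet]:
    """Realize a scenario: domain, parameters, initial capillary field
    and tumor, packaged as a ready-to-run :class:`SimState`."""
    units = units or UnitSystem()
    p = default_parameters(units).replace(**scenario.overrides)
    bbox_sau = tuple(b / units.sau for b in scenario.bbox_um)
    depth_sau = None if scenario.depth_um is None else scenario.depth_um / units.sau
    domain = make_domain(
        bbox_sau, depth_sau, scenario.h_um / units.sau, dim=scenario.dim
    )
    tumor = default_tumor(
        domain,
        d_p=scenario.tumor_d_p_um / units.sau,
        d_a=scenario.tumor_d_a_um / units.sau,
        tau_minutes=units.tau,
    )
    if scenario.vessel == "plexus":
        # size the raster to the realized (h-rounded) domain extent
        extent_um = tuple(e * units.sau for e in domain.extent[:2])
        plexus = dataclasses.replace(scenario.plexus, image_size_um=extent_um)
        mask = synth_plexus(plexus, scenario.seed)
        if scenario.dim == 2:
            c0 = reconstruct_field_2d(mask, domain, sau_um=units.sau)
        else:
            z0 = domain.origin[2] + domain.extent[2] / 2.0
            c0 = reconstruct_field_3d(mask, domain, z0, sau_um=units.sau)
    elif scenario.vessel == "none":
        c0 = np.full(domain.shape, -1.0)
    else:
        raise ValueError(f"unknown vessel spec {scenario.vessel!r}")
    cap = CapillaryState.from_field(c0, p, domain)
    state = SimState(domain=domain, tumor=tumor, capillaries=cap, seed=scenario.seed)
    return state, p
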