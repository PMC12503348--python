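"""Readers, writers and export conventions for run artifacts.

Fields go out as legacy ASCII VTK structured points (readable by
standard viewers) with full float64 round-trip precision; history tables
as CSV with both simulation-unit and physical-unit columns; run metadata
as JSON.  Display conventions (capillaries at the c = 0 isosurface, the
tumor at phi = 0.5) are recorded in the metadata of every field file
batch.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .driver import HISTORY_COLUMNS, SimState
from .geometry import SimDomain, tumor_field
from .units import UnitSystem

__all__ = [
    "write_vtk",
    "read_vtk",
    "write_fields",
    "export_history",
    "RunRecord",
]

log = logging.getLogger(__name__)

ISOSURFACE_CONVENTIONS = {"capillaries": "c=0", "tumor": "phi=0.5"}


def write_vtk(path: str | Path, domain: SimDomain, fields: dict[str, np.ndarray]) -> Path:
    """Write nodal scalar fields as a legacy ASCII VTK structured-points
    file.  Values are formatted with %.17g so float64 round-trips
    exactly."""
    path = Path(path)
    shape3 = tuple(domain.shape) + (1,) * (3 - domain.dim)
    origin3 = tuple(domain.origin) + (0.0,) * (3 - domain.dim)
    n = int(np.prod(shape3))
    lines = [
        "# vtk DataFile Version 3.0",
        "rhangio fields",
        "ASCII",
        "DATASET STRUCTURED_POINTS",
        f"DIMENSIONS {shape3[0]} {shape3[1]} {shape3[2]}",
        f"ORIGIN {origin3[0]:.17g} {origin3[1]:.17g} {origin3[2]:.17g}",
        f"SPACING {domain.h:.17g} {domain.h:.17g} {domain.h:.17g}",
        f"POINT_DATA {n}",
    ]
    for name, arr in fields.items():
        arr = np.asarray(arr, dtype=float)
        if arr.shape != domain.shape:
            raise ValueError(f"field {name!r} shape {arr.shape} != grid {domain.shape}")
        lines.append(f"SCALARS {name} double 1")
        lines.append("LOOKUP_TABLE default")
        # VTK structured points iterate x fastest: Fortran order of (x,y,z)
        flat = arr.reshape(shape3).ravel(order="F")
        lines.extend(f"{v:.17g}" for v in flat)
    try:
        path.write_text("\n".join(lines) + "\n")
    except OSError as err:
        raise OSError(f"cannot write field file {path}: {err}") from err
    return path


def read_vtk(path: str | Path) -> tuple[SimDomain, dict[str, np.ndarray]]:
    """Read a field file written by :func:`write_vtk`."""
    tokens = Path(path).read_text().splitlines()
    dims = spacing = origin = None
    fields: dict[str, np.ndarray] = {}
    i = 0
    while i < len(tokens):
        line = tokens[i]
        if line.startswith("DIMENSIONS"):
            dims = tuple(int(x) for x in line.split()[1:])
        elif line.startswith("SPACING"):
            spacing = float(line.split()[1])
        elif line.startswith("ORIGIN"):
            origin = tuple(float(x) for x in line.split()[1:])
        elif line.startswith("SCALARS"):
            name = line.split()[1]
            n = int(np.prod(dims))
            vals = np.array([float(v) for v in tokens[i + 2 : i + 2 + n]])
            fields[name] = vals
            i += 1 + n
        i += 1
    dim = sum(1 for d in dims if d > 1) or 1
    shape = dims[:dim]
    domain = SimDomain(
        dim=dim,
        extent=tuple((s - 1) * spacing for s in shape),
        h=spacing,
        origin=origin[:dim],
    )
    out = {
        k: v.reshape(dims, order="F").reshape(shape) for k, v in fields.items()
    }
    return domain, out


def write_fields(
    state: SimState,
    path: str | Path,
    *,
    units: UnitSystem | None = None,
    fmt: str = "vtk",
) -> Path:
    """Write the current c, mu, af and phi fields plus a JSON metadata
    sidecar recording the display conventions and unit system."""
    if fmt != "vtk":
        raise ValueError(f"unsupported format {fmt!r}")
    units = units or UnitSystem()
    path = Path(path)
    phi = tumor_field(state.domain, state.t, state.tumor)
    fields = {"c": state.capillaries.c, "mu": state.capillaries.mu, "phi": phi}
    if state.af is not None:
        fields["af"] = state.af.af
    write_vtk(path, state.domain, fields)
    meta = {
        "t_tau": state.t,
        "step": state.step_index,
        "isosurfaces": ISOSURFACE_CONVENTIONS,
        "units": {"sau_um": units.sau, "tau_min": units.tau, "afau_pg_per_mL": units.afau},
    }
    path.with_suffix(path.suffix + ".json").write_text(json.dumps(meta, indent=1))
    return path


def export_history(
    state: SimState, path: str | Path, *, units: UnitSystem | None = None
) -> pd.DataFrame:
    """Write the per-step history as CSV.

    Simulation-unit columns are accompanied by physical-unit companions
    (t_days, tumor volume in mm^3)."""
    units = units or UnitSystem()
    path = Path(path)
    df = pd.DataFrame(state.history, columns=list(HISTORY_COLUMNS))
    minutes_per_day = 1440.0
    df.insert(2, "t_days", df["t_tau"] * units.tau / minutes_per_day)
    df["tumor_volume_mm3"] = df["tumor_volume"] * (units.sau / 1000.0) ** state.domain.dim
    df.to_csv(path, index=False)
    return df


@dataclass
class RunRecord:
    """Reproducibility record of a run: config, seed, history, and the
    snapshot index (step -> file)."""

    config: dict
    seed: int
    history_path: str
    snapshots: dict[int, str] = field(default_factory=dict)

    def parameter_hash(self) -> str:
        payload = json.dumps(self.config, sort_keys=True).encode()
        return hashlib.sha256(payload).hexdigest()[:16]

    def save(self, path: str | Path) -> Path:
        path = Path(path)
        payload = {
            "config": self.config,
            "seed": self.seed,
            "history": self.history_path,
            "snapshots": {str(k): v for k, v in self.snapshots.items()},
            "parameter_hash": self.parameter_hash(),
        }
        path.write_text(json.dumps(payload, indent=1, sort_keys=True))
        return path

    @classmethod
    def load(cls, path: str | Path) -> "RunRecord":
        raw = json.loads(Path(path).read_text())
        rec = cls(
            config=raw["config"],
            seed=raw["seed"],
            history_path=raw["history"],
            snapshots={int(k): v for k, v in raw["snapshots"].items()},
        )
        missing = [f for f in rec.snapshots.values() if not Path(f).exists()]
        if missing:
            raise FileNotFoundError(f"missing snapshot files: {missing}")
        return rec
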