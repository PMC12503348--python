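"""Initial capillary field construction.

Two routes produce c(x, 0):

* a synthetic planar plexus generator (:func:`synth_plexus`) emulating a
  network of vessels of varying widths around an avascular disk, and
* reconstruction from a binary 2D segmentation raster, either directly
  in-plane (:func:`reconstruct_field_2d`) or lifted to 3D as a union of
  balls of the local vessel radius centered on the medial-axis skeleton
  placed at a chosen depth (:func:`reconstruct_field_3d`).

The reconstructed field is sharp (+1 inside vessels, -1 outside); the
first Cahn-Hilliard step relaxes it into a diffuse interface.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
from PIL import Image
from scipy import ndimage
from skimage.morphology import medial_axis

from .geometry import SimDomain

__all__ = [
    "VesselMask",
    "reconstruct_field_2d",
    "reconstruct_field_3d",
    "local_radius",
    "synth_plexus",
    "PlexusSpec",
]


@dataclass
class VesselMask:
    """Binary 2D raster of vessel pixels with physical pixel size.

    ``pixels[i, j]`` follows (row, col) = (x-index, y-index) of the grid
    convention used across the package; ``pixel_size`` is in micrometres.
    """

    pixels: np.ndarray
    pixel_size: float
    provenance: str = "unknown"

    def __post_init__(self) -> None:
        if self.pixel_size <= 0:
            raise ValueError("pixel_size must be positive")
        self.pixels = (np.asarray(self.pixels) > 0).astype(np.uint8)
        if self.pixels.ndim != 2:
            raise ValueError("mask must be 2D")

    @property
    def extent_um(self) -> tuple[float, float]:
        return (
            self.pixels.shape[0] * self.pixel_size,
            self.pixels.shape[1] * self.pixel_size,
        )

    def save(self, path: str | Path) -> None:
        """Write the mask as PNG/TIFF plus a JSON sidecar with pixel size."""
        path = Path(path)
        Image.fromarray(self.pixels * np.uint8(255)).save(path)
        sidecar = path.with_suffix(path.suffix + ".json")
        sidecar.write_text(
            json.dumps(
                {"pixel_size_um": self.pixel_size, "provenance": self.provenance}
            )
        )

    @classmethod
    def load(cls, path: str | Path, pixel_size: float | None = None) -> "VesselMask":
        path = Path(path)
        arr = np.asarray(Image.open(path).convert("L"))
        provenance = str(path)
        if pixel_size is None:
            sidecar = path.with_suffix(path.suffix + ".json")
            if not sidecar.exists():
                raise FileNotFoundError(
                    f"no pixel size given and sidecar {sidecar} missing"
                )
            meta = json.loads(sidecar.read_text())
            pixel_size = float(meta["pixel_size_um"])
            provenance = meta.get("provenance", provenance)
        return cls(pixels=arr, pixel_size=pixel_size, provenance=provenance)


def _node_to_pixel(coord: np.ndarray, pixel_size: float, n_pix: int) -> np.ndarray:
    """Map node coordinates (same length unit as pixel_size) to pixel
    indices by nearest pixel center; ties break toward the lower index."""
    i = np.ceil(coord / pixel_size).astype(int) - 1
    return np.clip(i, 0, n_pix - 1)


def reconstruct_field_2d(
    mask: VesselMask, domain: SimDomain, *, sau_um: float = 800.0, rtol: float = 1e-6
) -> np.ndarray:
    """Sample the mask onto a 2D grid: +1 at nodes inside a vessel
    pixel, -1 elsewhere.

    The mask must cover the domain extent after the pixel -> sau scaling
    (``sau_um`` micrometres per space unit)."""
    if domain.dim != 2:
        raise ValueError("reconstruct_field_2d needs a 2D domain")
    ext_um = np.asarray(domain.extent) * sau_um
    mask_ext = np.asarray(mask.extent_um)
    if np.any(ext_um > mask_ext * (1.0 + rtol) + 1e-9):
        raise ValueError(
            f"mask extent {tuple(mask_ext)} um does not cover domain "
            f"extent {tuple(ext_um)} um"
        )
    axes_um = [a * sau_um for a in domain.axes()]
    ix = _node_to_pixel(axes_um[0], mask.pixel_size, mask.pixels.shape[0])
    iy = _node_to_pixel(axes_um[1], mask.pixel_size, mask.pixels.shape[1])
    inside = mask.pixels[np.ix_(ix, iy)] > 0
    return np.where(inside, 1.0, -1.0)


def local_radius(mask: VesselMask) -> np.ndarray:
    """Per-pixel local vessel radius in micrometres: the exact Euclidean
    distance transform of the vessel region, restricted to the
    medial-axis skeleton (zero off-skeleton)."""
    pixels = mask.pixels > 0
    if not pixels.any():
        return np.zeros(pixels.shape, dtype=float)
    skel = medial_axis(pixels)
    dist = ndimage.distance_transform_edt(pixels)
    return np.where(skel, dist, 0.0) * mask.pixel_size


def reconstruct_field_3d(
    mask: VesselMask,
    domain: SimDomain,
    z0: float,
    *,
    sau_um: float = 800.0,
) -> np.ndarray:
    """Lift a 2D mask to a 3D field: the vessel body is the union of
    balls of the local radius centered on skeleton points placed on the
    z = z0 plane (z0 in sau).  Returns +1/-1 nodal values."""
    if domain.dim != 3:
        raise ValueError("reconstruct_field_3d needs a 3D domain")
    if not (domain.origin[2] <= z0 <= domain.origin[2] + domain.extent[2]):
        raise ValueError(f"z0={z0} outside the axial extent")
    radius_um = local_radius(mask)
    c = np.full(domain.shape, -1.0)
    pts = np.argwhere(radius_um > 0)
    if len(pts) == 0:
        return c
    axes = domain.axes()
    h = domain.h
    shape = domain.shape
    # skeleton pixel centers in sau
    centers = (pts.astype(float) + 0.5) * (mask.pixel_size / sau_um)
    radii = radius_um[pts[:, 0], pts[:, 1]] / sau_um
    for (cx, cy), r in zip(centers, radii):
        n_r = [int(np.ceil(r / h)) + 1] * 3
        i0 = domain.nearest_node(np.array([cx, cy, z0]))
        sl = [
            slice(max(i0[d] - n_r[d], 0), min(i0[d] + n_r[d] + 1, shape[d]))
            for d in range(3)
        ]
        gx, gy, gz = np.meshgrid(
            axes[0][sl[0]], axes[1][sl[1]], axes[2][sl[2]], indexing="ij"
        )
        dist2 = (gx - cx) ** 2 + (gy - cy) ** 2 + (gz - z0) ** 2
        region = c[tuple(sl)]
        region[dist2 <= r**2] = 1.0
    return c


@dataclass(frozen=True)
class PlexusSpec:
    """Specification for the synthetic planar plexus generator."""

    n_vessels: int = 6
    width_range_um: tuple[float, float] = (5.0, 20.0)
    avascular_center_um: tuple[float, float] | None = None  # default: image center
    avascular_radius_um: float = 100.0
    image_size_um: tuple[float, float] = (800.0, 800.0)
    pixel_size_um: float = 2.0
    wiggle: float = 0.15  # sinusoidal perturbation amplitude, fraction of size

    def __post_init__(self) -> None:
        if self.width_range_um[0] <= 0 or self.width_range_um[1] < self.width_range_um[0]:
            raise ValueError("invalid width range")


def synth_plexus(spec: PlexusSpec, seed: int, *, max_retries: int = 200) -> VesselMask:
    """Deterministic synthetic plexus: smooth vessel paths of varying
    widths that never enter the avascular disk.

    Paths are straight chords with a gentle sinusoidal wiggle, drawn at a
    perpendicular offset from the disk center large enough that the whole
    stroke (centerline offset minus wiggle minus half-width) clears the
    disk by construction.  Identical seeds yield bitwise-identical masks.
    """
    rng = np.random.default_rng(seed)
    nx = int(round(spec.image_size_um[0] / spec.pixel_size_um))
    ny = int(round(spec.image_size_um[1] / spec.pixel_size_um))
    cx, cy = spec.avascular_center_um or (
        spec.image_size_um[0] / 2.0,
        spec.image_size_um[1] / 2.0,
    )
    half_diag = float(np.hypot(*spec.image_size_um)) / 2.0
    mask = np.zeros((nx, ny), dtype=np.uint8)
    wiggle_amp = spec.wiggle * min(spec.image_size_um)

    drawn = 0
    for _ in range(max_retries):
        if drawn >= spec.n_vessels:
            break
        width = rng.uniform(*spec.width_range_um)
        theta = rng.uniform(0.0, np.pi)
        clearance = spec.avascular_radius_um + width / 2.0 + wiggle_amp + spec.pixel_size_um
        if clearance >= half_diag:
            continue  # this vessel cannot fit outside the disk
        side = rng.choice([-1.0, 1.0])
        offset = side * rng.uniform(clearance, half_diag)
        # chord direction and its normal
        d = np.array([np.cos(theta), np.sin(theta)])
        nvec = np.array([-np.sin(theta), np.cos(theta)])
        base = np.array([cx, cy]) + offset * nvec
        phase = rng.uniform(0.0, 2.0 * np.pi)
        freq = rng.uniform(0.5, 2.0) * np.pi / half_diag
        s = np.linspace(-1.5 * half_diag, 1.5 * half_diag, 600)
        # wiggle pushes the path away from the disk only
        lateral = side * wiggle_amp * (0.5 + 0.5 * np.sin(freq * s + phase))
        path = base[None, :] + s[:, None] * d[None, :] + lateral[:, None] * nvec[None, :]
        _stamp_path(mask, path, width / 2.0, spec.pixel_size_um)
        drawn += 1
    if drawn < spec.n_vessels:
        raise RuntimeError(
            f"could only place {drawn}/{spec.n_vessels} vessels outside the "
            "avascular disk"
        )
    # enforce the avascular constraint exactly (paths are built to clear
    # the disk; this guards rasterization corner cases)
    ii, jj = np.meshgrid(
        (np.arange(nx) + 0.5) * spec.pixel_size_um,
        (np.arange(ny) + 0.5) * spec.pixel_size_um,
        indexing="ij",
    )
    disk = (ii - cx) ** 2 + (jj - cy) ** 2 <= spec.avascular_radius_um**2
    mask[disk] = 0
    return VesselMask(pixels=mask, pixel_size=spec.pixel_size_um, provenance=f"synth(seed={seed})")


def _stamp_path(mask: np.ndarray, path_um: np.ndarray, radius_um: float, ps: float) -> None:
    """Rasterize a polyline with circular brush of the given radius."""
    nx, ny = mask.shape
    r_pix = radius_um / ps
    n_r = int(np.ceil(r_pix)) + 1
    for px, py in path_um:
        i = px / ps - 0.5
        j = py / ps - 0.5
        i0, j0 = int(round(i)), int(round(j))
        if i0 < -n_r or j0 < -n_r or i0 >= nx + n_r or j0 >= ny + n_r:
            continue
        ilo, ihi = max(i0 - n_r, 0), min(i0 + n_r + 1, nx)
        jlo, jhi = max(j0 - n_r, 0), min(j0 + n_r + 1, ny)
        if ilo >= ihi or jlo >= jhi:
            continue
        gi, gj = np.meshgrid(np.arange(ilo, ihi), np.arange(jlo, jhi), indexing="ij")
        inside = (gi - i) ** 2 + (gj - j) ** 2 <= r_pix**2
        mask[ilo:ihi, jlo:jhi][inside] = 1
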