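"""Pore, cargo and tether geometry.

The nuclear pore channel is modelled as a cylinder of diameter
``D_pore`` and height ``h_pore``; its axis is the z axis with
z ∈ [0, h_pore] and the origin on the axis at the bottom face.  The side
wall and the cargo sphere are hard (absorbing, Dirichlet) surfaces; the
two open ends are reflecting (Neumann).  FG-Nup anchor points sit 1 nm
radially inward from the wall to keep them clear of the discretized
Dirichlet surface.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .grids import (AxisymmetricGrid, CylinderWall, GeometryError, Grid3D,
                    SphereObstacle)

TETHER_INSET_NM = 1.0  # radial relocation of anchors away from the wall


@dataclass(frozen=True)
class PoreGeometry:
    """Cylindrical channel: diameter and height in nm."""

    diameter: float = 40.0
    height: float = 40.0

    def __post_init__(self):
        if self.diameter <= 0 or self.height <= 0:
            raise GeometryError("pore diameter and height must be positive")

    @property
    def radius(self) -> float:
        return self.diameter / 2.0

    @property
    def center(self) -> np.ndarray:
        """Geometric center of the channel (on the axis, mid-height)."""
        return np.array([0.0, 0.0, self.height / 2.0])


@dataclass(frozen=True)
class CargoSpec:
    """Spherical cargo: diameter, center position and orientation.

    ``orientation`` = (θ, φ) rotates the body-frame binding-spot layout
    (rotation R_z(φ) · R_y(θ)); it is irrelevant for inert cargoes.
    ``spots`` is a :class:`~npcfield.binding.BindingSpotSet` or ``None``
    for an inert cargo.
    """

    diameter: float
    center: tuple[float, float, float] = (0.0, 0.0, 20.0)
    orientation: tuple[float, float] = (0.0, 0.0)
    spots: object | None = None

    def __post_init__(self):
        if self.diameter <= 0:
            raise GeometryError("cargo diameter must be positive")

    @property
    def radius(self) -> float:
        return self.diameter / 2.0

    def on_axis(self) -> bool:
        return abs(self.center[0]) < 1e-12 and abs(self.center[1]) < 1e-12

    def rotation_matrix(self) -> np.ndarray:
        th, ph = self.orientation
        cy, sy = np.cos(th), np.sin(th)
        cz, sz = np.cos(ph), np.sin(ph)
        ry = np.array([[cy, 0, sy], [0, 1, 0], [-sy, 0, cy]])
        rz = np.array([[cz, -sz, 0], [sz, cz, 0], [0, 0, 1]])
        return rz @ ry

    def validate_inside(self, pore: PoreGeometry) -> None:
        cx, cy, cz = self.center
        if np.hypot(cx, cy) + self.radius >= pore.radius:
            raise GeometryError(
                f"cargo (d={self.diameter}) touches or crosses the pore wall")
        if cz - self.radius < -1e-9 or cz + self.radius > pore.height + 1e-9:
            raise GeometryError("cargo extends beyond the open pore ends")


@dataclass(frozen=True)
class TetherSet:
    """Anchor positions of the n FG-Nups (nm, world frame)."""

    positions: np.ndarray

    def __post_init__(self):
        pos = np.atleast_2d(np.asarray(self.positions, dtype=float))
        if pos.shape[1] != 3:
            raise ValueError("tether positions must be (n, 3)")
        object.__setattr__(self, "positions", pos)

    @property
    def n(self) -> int:
        return self.positions.shape[0]


@dataclass(frozen=True)
class DiscretizationParams:
    """Spatial resolution. ``cell_volume_nm3`` mimics a tetrahedral mesh
    budget: the nominal node spacing is the edge of a regular tetrahedron
    of that volume (0.1 nm³ → 0.947 nm ≈ the Kuhn length).  The
    axisymmetric path uses half that spacing since the 2-D problem is
    cheap.  ``strict`` upgrades the coarse-resolution warning to an error."""

    spacing_nm: float | None = None
    cell_volume_nm3: float = 0.1
    axisym_refine: int = 2
    strict: bool = False

    @property
    def spacing(self) -> float:
        if self.spacing_nm is not None:
            return float(self.spacing_nm)
        return tetrahedron_edge(self.cell_volume_nm3)

    @property
    def axisym_spacing(self) -> float:
        return self.spacing / self.axisym_refine


def tetrahedron_edge(volume: float) -> float:
    """Edge length of a regular tetrahedron of the given volume.

    V = a³ / (6√2), so a = (6√2 V)^(1/3); 0.1 nm³ gives ≈ 0.94 nm.
    """
    return float((6.0 * np.sqrt(2.0) * volume) ** (1.0 / 3.0))


def build_domain(pore: PoreGeometry, cargo: CargoSpec | None,
                 params: DiscretizationParams | None = None,
                 method: str = "grid3d", kuhn_length: float = 0.86):
    """Discretize the fluid region (cylinder minus cargo sphere).

    ``method`` is ``"grid3d"`` (full Cartesian grid) or ``"axisym"``
    ((r, z) reduction; requires an on-axis or absent cargo).  Boundary
    tags: Dirichlet on the side wall and the cargo surface, Neumann on
    the two open ends.
    """
    params = params or DiscretizationParams()
    if cargo is not None:
        cargo.validate_inside(pore)
    if method == "axisym":
        h = params.axisym_spacing
        if h > kuhn_length:
            _resolution_complaint(h, kuhn_length, params.strict)
        sphere = None
        if cargo is not None:
            if not cargo.on_axis():
                raise GeometryError("axisymmetric path requires an on-axis cargo")
            sphere = (cargo.center[2], cargo.radius)
        return AxisymmetricGrid(pore.radius, pore.height, h, sphere=sphere)
    if method == "grid3d":
        h = params.spacing
        if h > kuhn_length:
            _resolution_complaint(h, kuhn_length, params.strict)
        surfaces = [CylinderWall(pore.radius)]
        if cargo is not None:
            surfaces.append(SphereObstacle(tuple(cargo.center), cargo.radius))
        R = pore.radius
        return Grid3D(((-R, R), (-R, R), (0.0, pore.height)), h,
                      surfaces=surfaces)
    raise ValueError(f"unknown discretization method {method!r}")


def build_box(extents, spacing: float, face_bc: dict | None = None) -> Grid3D:
    """Plain Cartesian box (no wall, no cargo) — validation geometries."""
    return Grid3D(extents, spacing, face_bc=face_bc)


def _resolution_complaint(h, b, strict):
    msg = (f"node spacing {h:.3f} nm is coarser than the Kuhn length "
           f"{b:.3f} nm; the continuous-chain model is not resolved")
    if strict:
        raise GeometryError(msg)
    warnings.warn(msg)


# ---------------------------------------------------------------------------
# tether placement
# ---------------------------------------------------------------------------

def place_tethers(pore: PoreGeometry, n: int = 80, mode: str = "synthetic-rings",
                  source: str | Path | None = None, rings: int = 2) -> TetherSet:
    """Place the n FG-Nup anchors at radius D_pore/2 − 1 nm.

    ``synthetic-rings`` distributes them over ``rings`` equally spaced
    horizontal rings (z = h·(k+1)/(rings+1)) with equal angular spacing;
    consecutive rings are staggered by half a spacing.  The layout is a
    deterministic stand-in for a reconstructed anchor map; ``from-file``
    reads a CSV with columns ``x_nm,y_nm,z_nm`` and projects each row
    radially onto the anchor radius.
    """
    if n < 1:
        raise ValueError("need at least one tether")
    radius = pore.radius - TETHER_INSET_NM
    if radius <= 0:
        raise GeometryError("pore too narrow for inward-relocated tethers")
    if mode == "synthetic-rings":
        rings = min(rings, n)
        counts = [n // rings + (1 if k < n % rings else 0) for k in range(rings)]
        pos = []
        for k, m in enumerate(counts):
            z = pore.height * (k + 1) / (rings + 1) if rings > 1 else pore.height / 2
            ang = 2 * np.pi * (np.arange(m) + 0.5 * k) / m
            for a in ang:
                pos.append([radius * np.cos(a), radius * np.sin(a), z])
        return TetherSet(np.array(pos))
    if mode == "from-file":
        if source is None:
            raise IOError("from-file mode requires a source path")
        try:
            df = pd.read_csv(source)
            xyz = df[["x_nm", "y_nm", "z_nm"]].to_numpy(dtype=float)
        except (OSError, KeyError, ValueError) as exc:
            raise IOError(f"malformed or missing tether file {source}: {exc}")
        if ((xyz[:, 2] < 0) | (xyz[:, 2] > pore.height)).any():
            raise ValueError("tether z outside the pore height")
        rxy = np.hypot(xyz[:, 0], xyz[:, 1])
        if (rxy == 0).any():
            raise ValueError("on-axis tether cannot be projected to the wall")
        scale = radius / rxy
        out = xyz.copy()
        out[:, 0] *= scale
        out[:, 1] *= scale
        return TetherSet(out)
    raise ValueError(f"unknown tether mode {mode!r}")


def tethers_to_csv(tethers: TetherSet, path) -> None:
    pd.DataFrame(tethers.positions, columns=["x_nm", "y_nm", "z_nm"]).to_csv(
        path, index=False)


# ---------------------------------------------------------------------------
# cargo orientation grid
# ---------------------------------------------------------------------------

def orientation_grid() -> list[tuple[float, float]]:
    """The 220 (θ, φ) body rotations used for orientation averaging:
    θ = pπ/5 (p = 0..19), φ = mπ/10 (m = 0..10)."""
    return [(p * np.pi / 5.0, m * np.pi / 10.0)
            for p in range(20) for m in range(11)]
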