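"""Regular-grid finite-volume discretizations of the pore domain.

Two discretizations share one contract: a vertex-centred finite-volume
grid with volume weights ``w``, a symmetric stiffness matrix ``K``
(discrete ``-∇²`` scaled by cell volumes), and linear interpolation of
nodal fields.  Curved Dirichlet surfaces (cylinder wall, cargo sphere)
are embedded with a Shortley-Weller correction: a fluid node whose
neighbour lies inside a solid region couples to a zero boundary value at
the actual surface-intersection fraction ``θ`` of the link, which keeps
the boundary error well below first order in the grid spacing.

``Grid3D`` is a Cartesian box (optionally carved by a cylinder wall and
a sphere); ``AxisymmetricGrid`` is the (r, z) reduction used for
centred, orientation-independent cargoes where the full solution is
rotationally symmetric.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import scipy.sparse as sp
from scipy.interpolate import RegularGridInterpolator

_THETA_MIN = 0.05  # clamp for near-degenerate boundary intersections


# ---------------------------------------------------------------------------
# implicit solid surfaces (signed distance, positive in the fluid)
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class CylinderWall:
    """Hard cylindrical side wall of radius ``radius`` about the z axis."""

    radius: float

    def signed_distance(self, pts: np.ndarray) -> np.ndarray:
        return self.radius - np.hypot(pts[..., 0], pts[..., 1])


@dataclass(frozen=True)
class SphereObstacle:
    """Hard spherical cargo surface (fluid outside the sphere)."""

    center: tuple[float, float, float]
    radius: float

    def signed_distance(self, pts: np.ndarray) -> np.ndarray:
        d = pts - np.asarray(self.center)
        return np.linalg.norm(d, axis=-1) - self.radius


class GeometryError(ValueError):
    """Raised when a requested domain is geometrically inadmissible."""


def _cell_widths(coords: np.ndarray) -> np.ndarray:
    """Vertex-centred control-volume widths along one axis."""
    n = coords.size
    if n == 1:
        return np.array([1.0])
    w = np.empty(n)
    w[1:-1] = 0.5 * (coords[2:] - coords[:-2])
    w[0] = 0.5 * (coords[1] - coords[0])
    w[-1] = 0.5 * (coords[-1] - coords[-2])
    return w


class _GridBase:
    """State shared by the two discretizations after assembly."""

    #: per-fluid-node control volumes (nm³)
    weights: np.ndarray
    #: symmetric stiffness matrix; A = diag(w) + c K is the implicit operator
    stiffness: sp.csr_matrix
    #: world coordinates of fluid nodes, shape (n, 3)
    points: np.ndarray
    #: characteristic spacing (nm)
    spacing: float
    #: counts of link types for boundary bookkeeping
    link_counts: dict

    @property
    def n_nodes(self) -> int:
        return self.points.shape[0]

    @property
    def fluid_volume(self) -> float:
        return float(self.weights.sum())

    def integrate(self, values: np.ndarray) -> float:
        return float(self.weights @ values)

    # subclasses implement: contains, interpolate, nearest_fluid_node


# ---------------------------------------------------------------------------
# full 3-D Cartesian grid
# ---------------------------------------------------------------------------

class Grid3D(_GridBase):
    """Cartesian box grid with optional embedded cylinder wall and sphere.

    Parameters
    ----------
    extents:
        ((x0, x1), (y0, y1), (z0, z1)) box bounds in nm.
    spacing:
        target node spacing in nm; actual spacing rounds the node count.
    face_bc:
        mapping face -> "neumann" | "dirichlet" for the six box faces
        ("x-", "x+", "y-", "y+", "z-", "z+").  Dirichlet faces pin the
        face node layer to zero.
    surfaces:
        implicit solid surfaces (Dirichlet zero) carving the box.
    """

    def __init__(self, extents, spacing: float, face_bc: dict | None = None,
                 surfaces: Sequence | None = None):
        face_bc = dict(face_bc or {})
        surfaces = list(surfaces or [])
        axes = []
        for (lo, hi) in extents:
            ncell = max(int(round((hi - lo) / spacing)), 1)
            axes.append(np.linspace(lo, hi, ncell + 1))
        self.axes = axes
        self.spacing = float(np.mean([a[1] - a[0] for a in axes]))
        self.surfaces = surfaces
        shape = tuple(a.size for a in axes)
        X, Y, Z = np.meshgrid(*axes, indexing="ij")
        pts = np.stack([X, Y, Z], axis=-1)

        # signed distance to the nearest solid constraint
        psi = np.full(shape, np.inf)
        for s in surfaces:
            psi = np.minimum(psi, s.signed_distance(pts))
        psi = np.minimum(psi, 1e9)  # finite so boundary fractions stay defined
        names = ["x-", "x+", "y-", "y+", "z-", "z+"]
        for ax in range(3):
            for side, name in ((0, names[2 * ax]), (-1, names[2 * ax + 1])):
                if face_bc.get(name, "neumann") == "dirichlet":
                    sl = [slice(None)] * 3
                    sl[ax] = side
                    psi[tuple(sl)] = np.minimum(psi[tuple(sl)], 0.0)
        fluid = psi > 0.0
        if not fluid.any():
            raise GeometryError("no fluid nodes: domain entirely solid")

        ids = np.full(shape, -1, dtype=np.int64)
        n = int(fluid.sum())
        ids[fluid] = np.arange(n)
        self._shape = shape
        self._fluid = fluid
        self._ids = ids
        self._psi = psi
        self.points = pts[fluid]

        widths = [_cell_widths(a) for a in axes]
        W = widths[0][:, None, None] * widths[1][None, :, None] * widths[2][None, None, :]
        self.weights = W[fluid]

        rows, cols, vals = [], [], []
        diag = np.zeros(n)
        counts = {"fluid": 0, "dirichlet": 0, "neumann": 0}
        for ax in range(3):
            h = axes[ax][1] - axes[ax][0] if axes[ax].size > 1 else 1.0
            slP = [slice(None)] * 3
            slQ = [slice(None)] * 3
            slP[ax] = slice(0, -1)
            slQ[ax] = slice(1, None)
            P, Q = ids[tuple(slP)], ids[tuple(slQ)]
            psiP, psiQ = psi[tuple(slP)], psi[tuple(slQ)]
            # face area: product of perpendicular cell widths
            perp = [w for k, w in enumerate(widths) if k != ax]
            other = [k for k in range(3) if k != ax]
            area = np.ones([s - (1 if k == ax else 0) for k, s in enumerate(shape)])
            area = area * perp[0].reshape([shape[other[0]] if k == other[0] else 1 for k in range(3)])
            area = area * perp[1].reshape([shape[other[1]] if k == other[1] else 1 for k in range(3)])
            both = (P >= 0) & (Q >= 0)
            pf, qf = P[both], Q[both]
            c = (area[both] / h)
            rows += [pf, qf]
            cols += [qf, pf]
            vals += [-c, -c]
            np.add.at(diag, pf, c)
            np.add.at(diag, qf, c)
            counts["fluid"] += 2 * int(both.sum())
            for fl, so in ((P, Q), (Q, P)):
                mask = (fl >= 0) & (so < 0)
                if not mask.any():
                    continue
                pP, pQ = (psiP, psiQ) if fl is P else (psiQ, psiP)
                theta = np.clip(pP[mask] / np.maximum(pP[mask] - pQ[mask], 1e-300),
                                _THETA_MIN, 1.0)
                np.add.at(diag, fl[mask], area[mask] / (h * theta))
                counts["dirichlet"] += int(mask.sum())
        # Neumann faces: everything not fluid-fluid or fluid-solid
        counts["neumann"] = 6 * n - counts["fluid"] - counts["dirichlet"]
        rows.append(np.arange(n))
        cols.append(np.arange(n))
        vals.append(diag)
        self.stiffness = sp.csr_matrix(
            (np.concatenate(vals), (np.concatenate(rows), np.concatenate(cols))),
            shape=(n, n))
        self.link_counts = counts

    # -- queries ------------------------------------------------------------

    def contains(self, point) -> bool:
        p = np.asarray(point, dtype=float)
        for a, x in zip(self.axes, p):
            if x < a[0] - 1e-12 or x > a[-1] + 1e-12:
                return False
        psi = min((s.signed_distance(p[None, :])[0] for s in self.surfaces),
                  default=np.inf)
        return bool(psi > 0.0)

    def full_array(self, values: np.ndarray, fill: float = 0.0) -> np.ndarray:
        out = np.full(self._shape, fill)
        out[self._fluid] = values
        return out

    def interpolate(self, values: np.ndarray, points: np.ndarray) -> np.ndarray:
        """Trilinear interpolation; solid nodes contribute their Dirichlet 0."""
        f = RegularGridInterpolator(self.axes, self.full_array(values),
                                    method="linear", bounds_error=True)
        return f(np.atleast_2d(points))

    def nearest_fluid_node(self, point) -> int:
        d = np.linalg.norm(self.points - np.asarray(point), axis=1)
        return int(np.argmin(d))


# ---------------------------------------------------------------------------
# axisymmetric (r, z) grid
# ---------------------------------------------------------------------------

class AxisymmetricGrid(_GridBase):
    """(r, z) finite-volume grid for rotationally symmetric problems.

    The cylinder wall at ``r = radius`` is a Dirichlet node line; the two
    z faces are zero-flux open ends (Neumann) unless overridden; an
    optional on-axis sphere (center z, radius) is embedded as a solid.
    Control volumes carry the 2π r measure so that ``integrate`` returns
    true 3-D volume integrals.
    """

    def __init__(self, radius: float, height: float, spacing: float,
                 sphere: tuple[float, float] | None = None,
                 z_bc: tuple[str, str] = ("neumann", "neumann")):
        nr = max(int(round(radius / spacing)), 2)
        nz = max(int(round(height / spacing)), 2)
        r = np.linspace(0.0, radius, nr + 1)
        z = np.linspace(0.0, height, nz + 1)
        dr, dz = r[1] - r[0], z[1] - z[0]
        self.radius, self.height = float(radius), float(height)
        self.r_axis, self.z_axis = r, z
        self.spacing = 0.5 * (dr + dz)
        self.sphere = sphere

        R, Z = np.meshgrid(r, z, indexing="ij")
        psi = radius - R  # wall: nodes at r=radius are exactly on it
        if sphere is not None:
            zc, a = sphere
            psi = np.minimum(psi, np.hypot(R, Z - zc) - a)
        for side, bc in ((0, z_bc[0]), (-1, z_bc[1])):
            if bc == "dirichlet":
                psi[:, side] = np.minimum(psi[:, side], 0.0)
        fluid = psi > 0.0
        if not fluid.any():
            raise GeometryError("no fluid nodes: domain entirely solid")
        shape = (nr + 1, nz + 1)
        ids = np.full(shape, -1, dtype=np.int64)
        n = int(fluid.sum())
        ids[fluid] = np.arange(n)
        self._shape, self._fluid, self._ids, self._psi = shape, fluid, ids, psi
        self._rz = np.stack([R[fluid], Z[fluid]], axis=1)
        self.points = np.stack(
            [R[fluid], np.zeros(n), Z[fluid]], axis=1)

        # annular control volumes; outermost fluid ring extends to the wall
        r_in = np.maximum(r - dr / 2, 0.0)
        r_out = np.minimum(r + dr / 2, radius)
        r_out[-2] = radius  # absorb the wall half-shell where q ≈ 0
        ring = np.pi * (r_out ** 2 - r_in ** 2)
        wz = _cell_widths(z)
        W = ring[:, None] * wz[None, :]
        self.weights = W[fluid]

        rows, cols, vals = [], [], []
        diag = np.zeros(n)
        counts = {"fluid": 0, "dirichlet": 0, "neumann": 0}
        # radial links (face at r_{i+1/2}, lateral area 2π r_face Δz)
        rf = r[:-1] + dr / 2
        for (axis, h) in ((0, dr), (1, dz)):
            if axis == 0:
                P, Q = ids[:-1, :], ids[1:, :]
                psiP, psiQ = psi[:-1, :], psi[1:, :]
                area = (2 * np.pi * rf)[:, None] * wz[None, :]
            else:
                P, Q = ids[:, :-1], ids[:, 1:]
                psiP, psiQ = psi[:, :-1], psi[:, 1:]
                area = ring[:, None] * np.ones((1, nz))
            both = (P >= 0) & (Q >= 0)
            c = area[both] / h
            rows += [P[both], Q[both]]
            cols += [Q[both], P[both]]
            vals += [-c, -c]
            np.add.at(diag, P[both], c)
            np.add.at(diag, Q[both], c)
            counts["fluid"] += 2 * int(both.sum())
            for fl, so, pF, pS in ((P, Q, psiP, psiQ), (Q, P, psiQ, psiP)):
                mask = (fl >= 0) & (so < 0)
                if not mask.any():
                    continue
                theta = np.clip(pF[mask] / np.maximum(pF[mask] - pS[mask], 1e-300),
                                _THETA_MIN, 1.0)
                np.add.at(diag, fl[mask], area[mask] / (h * theta))
                counts["dirichlet"] += int(mask.sum())
        counts["neumann"] = 4 * n - counts["fluid"] - counts["dirichlet"]
        rows.append(np.arange(n))
        cols.append(np.arange(n))
        vals.append(diag)
        self.stiffness = sp.csr_matrix(
            (np.concatenate(vals), (np.concatenate(rows), np.concatenate(cols))),
            shape=(n, n))
        self.link_counts = counts

    # -- queries ------------------------------------------------------------

    @staticmethod
    def _to_rz(points: np.ndarray) -> np.ndarray:
        p = np.atleast_2d(points)
        return np.stack([np.hypot(p[:, 0], p[:, 1]), p[:, 2]], axis=1)

    def contains(self, point) -> bool:
        rz = self._to_rz(np.asarray(point, float))[0]
        if rz[1] < -1e-12 or rz[1] > self.height + 1e-12:
            return False
        psi = self.radius - rz[0]
        if self.sphere is not None:
            zc, a = self.sphere
            psi = min(psi, np.hypot(rz[0], rz[1] - zc) - a)
        return bool(psi > 0.0)

    def full_array(self, values: np.ndarray, fill: float = 0.0) -> np.ndarray:
        out = np.full(self._shape, fill)
        out[self._fluid] = values
        return out

    def interpolate(self, values: np.ndarray, points: np.ndarray) -> np.ndarray:
        f = RegularGridInterpolator((self.r_axis, self.z_axis),
                                    self.full_array(values),
                                    method="linear", bounds_error=True)
        return f(self._to_rz(np.asarray(points, float)))

    def nearest_fluid_node(self, point) -> int:
        rz = self._to_rz(np.asarray(point, float))[0]
        d = np.linalg.norm(self._rz - rz, axis=1)
        return int(np.argmin(d))
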