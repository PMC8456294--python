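"""Binding spots on the cargo surface and the adsorption potential.

Nuclear transport receptors decorate a cargo with short-range attractive
patches for FG-Nups.  The cargo surface is discretized into ``N_all``
near-uniform vertices (Fibonacci lattice at a fixed surface density);
``N_bind`` of them are selected as binding spots either as a uniform
spherical cap ("all spots on one side") or by weighted sampling from a
Kent directional distribution, whose concentration κ controls how
clustered the spots are.  A chain segment within ``r_cutoff`` of any
spot feels a square-well energy −γ (in units of k_BT).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.spatial import cKDTree

#: vertices per nm² of cargo surface (≈ one per Kuhn length squared)
VERTEX_DENSITY = 1.0
#: reference binding area S* = full surface of a 20-nm cargo (nm²)
S_STAR = np.pi * 20.0 ** 2
#: body-frame cap pole; orientation (0, 0) points the cap toward z = 0
CAP_POLE = np.array([0.0, 0.0, -1.0])


@dataclass(frozen=True)
class KentParams:
    """Kent (Fisher-Bingham 5-parameter) distribution on the sphere.

    κ ≥ 0 is the concentration, β the ellipticity (0 here, reducing to
    the von Mises-Fisher form), ``mean_direction`` the density maximum.
    The major/minor axes are built orthonormal to the mean direction.
    """

    kappa: float
    beta: float = 0.0
    mean_direction: tuple[float, float, float] = (0.0, 0.0, -1.0)

    def __post_init__(self):
        if self.kappa < 0:
            raise ValueError("concentration κ must be non-negative")
        g1 = np.asarray(self.mean_direction, dtype=float)
        nrm = np.linalg.norm(g1)
        if nrm == 0:
            raise ValueError("mean direction must be non-zero")
        object.__setattr__(self, "mean_direction", tuple(g1 / nrm))

    def frame(self) -> np.ndarray:
        """Orthonormal frame (γ1, γ2, γ3), rows are the axes."""
        g1 = np.asarray(self.mean_direction)
        helper = np.array([1.0, 0.0, 0.0])
        if abs(g1 @ helper) > 0.9:
            helper = np.array([0.0, 1.0, 0.0])
        g2 = helper - (helper @ g1) * g1
        g2 /= np.linalg.norm(g2)
        g3 = np.cross(g1, g2)
        return np.stack([g1, g2, g3])


def kent_normalization(params: KentParams, n_quad: int = 400) -> float:
    """Normalization constant c(κ, β) with ∫ f dΩ = 1.

    For β = 0 the closed form is c = 4π sinh(κ)/κ (4π at κ = 0); for
    β ≠ 0 it is computed by Gauss-Legendre quadrature over the sphere.
    """
    k, b = params.kappa, params.beta
    if b == 0.0:
        if k == 0.0:
            return 4.0 * np.pi
        return float(4.0 * np.pi * np.sinh(k) / k)
    # quadrature in the distribution's own frame
    x, wx = np.polynomial.legendre.leggauss(n_quad)  # cosθ nodes
    phi = (np.arange(n_quad) + 0.5) * 2 * np.pi / n_quad
    ct = x[:, None]
    st = np.sqrt(1 - ct ** 2)
    expo = k * ct + b * (st ** 2) * np.cos(2 * phi[None, :])
    integ = (np.exp(expo) * wx[:, None]).sum() * (2 * np.pi / n_quad)
    return float(integ)


def kent_density(x, params: KentParams) -> np.ndarray | float:
    """Probability density (per steradian) of the Kent distribution at
    unit vector(s) ``x``."""
    x = np.asarray(x, dtype=float)
    single = x.ndim == 1
    pts = np.atleast_2d(x)
    if not np.allclose(np.linalg.norm(pts, axis=1), 1.0, atol=1e-8):
        raise ValueError("kent_density expects unit vectors")
    g1, g2, g3 = params.frame()
    expo = params.kappa * (pts @ g1)
    if params.beta != 0.0:
        expo = expo + params.beta * ((pts @ g2) ** 2 - (pts @ g3) ** 2)
    dens = np.exp(expo) / kent_normalization(params)
    return float(dens[0]) if single else dens


# ---------------------------------------------------------------------------
# surface discretization and spot selection
# ---------------------------------------------------------------------------

def discretize_sphere_surface(d_cargo: float,
                              vertex_density: float = VERTEX_DENSITY) -> np.ndarray:
    """Deterministic Fibonacci lattice of unit directions on the cargo
    sphere, with the vertex count conserving the surface density:
    N_all = round(σ_v π d²)."""
    if d_cargo <= 0:
        raise ValueError("cargo diameter must be positive")
    n = max(int(round(vertex_density * np.pi * d_cargo ** 2)), 1)
    k = np.arange(n)
    z = 1.0 - (2.0 * k + 1.0) / n
    phi = k * np.pi * (3.0 - np.sqrt(5.0))
    s = np.sqrt(np.maximum(1.0 - z ** 2, 0.0))
    return np.stack([s * np.cos(phi), s * np.sin(phi), z], axis=1)


@dataclass(frozen=True)
class BindingSpotSet:
    """Vertices (unit body-frame directions), the selected spot subset,
    and how the subset was drawn."""

    vertices: np.ndarray
    spot_indices: np.ndarray
    distribution: str = "uniform-cap"
    rng_seed: int | None = None
    metadata: dict = field(default_factory=dict)

    def __post_init__(self):
        v = np.atleast_2d(np.asarray(self.vertices, dtype=float))
        idx = np.asarray(self.spot_indices, dtype=np.int64)
        if idx.size and (idx.min() < 0 or idx.max() >= len(v)):
            raise ValueError("spot indices out of range")
        object.__setattr__(self, "vertices", v)
        object.__setattr__(self, "spot_indices", idx)

    @property
    def n_all(self) -> int:
        return self.vertices.shape[0]

    @property
    def n_bind(self) -> int:
        return self.spot_indices.size

    @property
    def spot_directions(self) -> np.ndarray:
        return self.vertices[self.spot_indices]


def uniform_cap_spots(vertices: np.ndarray, coverage_fraction: float) -> BindingSpotSet:
    """Select the spherical cap around the body-frame pole whose area
    fraction is ``coverage_fraction`` (cap area fraction (1−cos θ_c)/2)."""
    if not 0.0 <= coverage_fraction <= 1.0:
        raise ValueError("coverage fraction must lie in [0, 1]")
    vertices = np.atleast_2d(np.asarray(vertices, dtype=float))
    if coverage_fraction == 0.0:
        idx = np.empty(0, dtype=np.int64)
    else:
        cos_from_pole = vertices @ CAP_POLE
        idx = np.flatnonzero(cos_from_pole >= 1.0 - 2.0 * coverage_fraction - 1e-12)
    return BindingSpotSet(vertices, idx, distribution="uniform-cap",
                          metadata={"coverage_fraction": coverage_fraction})


def kent_spots(vertices: np.ndarray, n_bind: int, params: KentParams,
               seed: int) -> BindingSpotSet:
    """Sample ``n_bind`` distinct vertices with probability ∝ the Kent
    density at each vertex (reproducible for a fixed seed)."""
    vertices = np.atleast_2d(np.asarray(vertices, dtype=float))
    if n_bind > len(vertices):
        raise ValueError("cannot select more spots than vertices")
    w = kent_density(vertices, params)
    w = np.asarray(w) / np.sum(w)
    rng = np.random.default_rng(seed)
    idx = rng.choice(len(vertices), size=n_bind, replace=False, p=w)
    return BindingSpotSet(vertices, np.sort(idx),
                          distribution=f"kent(kappa={params.kappa},beta={params.beta})",
                          rng_seed=seed,
                          metadata={"kappa": params.kappa, "beta": params.beta})


def spots_for_area(vertices: np.ndarray, d_cargo: float, S_target: float,
                   layout, **kwargs) -> BindingSpotSet:
    """Spot set of fixed absolute binding area S on a cargo of diameter d.

    The requested coverage N_bind/N_all = S/(π d²) is clamped at 1 (with
    a warning) when the cargo is too small to carry that much area.
    ``layout`` is "uniform-cap" or a KentParams instance.
    """
    coverage = S_target / (np.pi * d_cargo ** 2)
    if coverage > 1.0:
        warnings.warn(f"requested binding area {S_target:.1f} nm² exceeds the "
                      f"cargo surface; clamping coverage to 1")
        coverage = 1.0
    if layout == "uniform-cap":
        return uniform_cap_spots(vertices, coverage)
    n_bind = int(round(coverage * len(np.atleast_2d(vertices))))
    return kent_spots(vertices, n_bind, layout, kwargs["seed"])


# ---------------------------------------------------------------------------
# adsorption potential
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class AdsorptionPotential:
    """Square-well attraction: V(r) = −γ when the distance from r to the
    closest binding spot is strictly below ``r_cutoff``, else 0."""

    gamma: float
    spot_positions: np.ndarray
    r_cutoff: float = 0.86

    def __post_init__(self):
        if self.gamma < 0:
            raise ValueError("interfacial energy γ must be non-negative")
        if self.r_cutoff <= 0:
            raise ValueError("cutoff radius must be positive")
        pos = np.atleast_2d(np.asarray(self.spot_positions, dtype=float))
        object.__setattr__(self, "spot_positions", pos)
        object.__setattr__(self, "_tree", cKDTree(pos) if len(pos) else None)

    @classmethod
    def from_cargo(cls, cargo, gamma: float, r_cutoff: float = 0.86):
        """World-frame spot coordinates from the cargo's body-frame spot
        directions, orientation and center."""
        spots = cargo.spots
        if spots is None or spots.n_bind == 0:
            return cls(gamma, np.empty((0, 3)), r_cutoff)
        R = cargo.rotation_matrix()
        world = (spots.spot_directions @ R.T) * cargo.radius + np.asarray(cargo.center)
        return cls(gamma, world, r_cutoff)

    def evaluate(self, points: np.ndarray) -> np.ndarray:
        pts = np.atleast_2d(np.asarray(points, dtype=float))
        if self._tree is None or self.gamma == 0.0:
            return np.zeros(len(pts))
        dist, _ = self._tree.query(pts)
        return np.where(dist < self.r_cutoff, -self.gamma, 0.0)


def potential_at(r, pot: AdsorptionPotential) -> float:
    """Adsorption energy (k_BT) at a single point."""
    return float(pot.evaluate(np.asarray(r, dtype=float))[0])


# ---------------------------------------------------------------------------
# geometric statistics
# ---------------------------------------------------------------------------

def binding_surface_area(spots: BindingSpotSet, d_cargo: float) -> tuple[float, float]:
    """Binding area S = (N_bind/N_all) π d² and its ratio to the
    reference S* (full surface of a 20-nm cargo)."""
    S = spots.n_bind / spots.n_all * np.pi * d_cargo ** 2
    return float(S), float(S / S_STAR)


def clustering_degree(spots: BindingSpotSet, cargo, tethers,
                      r_cluster: float = 8.6) -> float:
    """Clustering degree p_cluster of the spot layout.

    The binding spot closest (in world coordinates) to any FG-Nup anchor
    is the "nearest-to-wall" point; among all surface vertices within
    ``r_cluster`` (default 10 Kuhn lengths = 8.6 nm) of it, the returned
    fraction are binding spots.
    """
    if spots.n_bind == 0:
        raise ValueError("clustering degree undefined for an empty spot set")
    R = cargo.rotation_matrix()
    center = np.asarray(cargo.center)
    verts_w = (spots.vertices @ R.T) * cargo.radius + center
    spots_w = verts_w[spots.spot_indices]
    d = np.linalg.norm(spots_w[:, None, :] - tethers.positions[None, :, :], axis=2)
    nw = spots_w[np.unravel_index(np.argmin(d), d.shape)[0]]
    near_all = np.linalg.norm(verts_w - nw, axis=1) <= r_cluster
    near_bind = near_all[spots.spot_indices]
    return float(near_bind.sum() / near_all.sum())
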