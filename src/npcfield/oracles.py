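"""Independent references for the chain solver.

Two routes that never touch the PDE machinery: the closed-form
absorbing-half-space propagator, and a direct Monte-Carlo sampler of
discrete Gaussian chains that estimates partition-function ratios by
brute force.  The sampler draws per-coordinate Gaussian steps of
variance b²Δs/3 (matching the b²/6 contour diffusivity), kills chains
that enter a hard obstacle — with a Brownian-bridge crossing correction
so absorption between sampled points is not missed — and
Boltzmann-weights each surviving chain by the adsorption energy it
accumulates.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable, Sequence

import numpy as np
from scipy.special import erf


@dataclass(frozen=True)
class OracleResult:
    estimate: float
    stderr: float
    method: str

    def __post_init__(self):
        if self.stderr < 0:
            raise ValueError("standard error cannot be negative")


def halfspace_qtilde(z, s: float, b: float):
    """q̃(z, s) for a single absorbing plane at z = 0 in an otherwise
    unbounded domain: the image solution erf(z √(3/(2 b² s)))."""
    z = np.asarray(z, dtype=float)
    out = erf(z * np.sqrt(3.0 / (2.0 * b ** 2 * s)))
    return float(out) if out.ndim == 0 else out


# ---------------------------------------------------------------------------
# obstacles with signed distances (positive in the fluid)
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class PlaneWall:
    """Fluid on the side of ``point`` + t*``normal``, t > 0."""
    point: tuple[float, float, float]
    normal: tuple[float, float, float]

    def signed_distance(self, pts):
        n = np.asarray(self.normal, float)
        n = n / np.linalg.norm(n)
        return (pts - np.asarray(self.point, float)) @ n


@dataclass(frozen=True)
class CylinderBore:
    """Fluid inside radius R about the z axis."""
    radius: float

    def signed_distance(self, pts):
        return self.radius - np.hypot(pts[..., 0], pts[..., 1])


@dataclass(frozen=True)
class ReflectingSlab:
    """Zero-flux (reflecting) planes at z = z0 and z = z1: walker
    positions are folded back into the slab after every step, which is
    exact for Brownian increments by the reflection principle."""
    z0: float
    z1: float

    def fold(self, pts):
        L = self.z1 - self.z0
        z = np.mod(pts[..., 2] - self.z0, 2.0 * L)
        z = np.where(z > L, 2.0 * L - z, z)
        out = pts.copy()
        out[..., 2] = z + self.z0
        return out


@dataclass(frozen=True)
class HardSphere:
    """Fluid outside the sphere."""
    center: tuple[float, float, float]
    radius: float

    def signed_distance(self, pts):
        return np.linalg.norm(pts - np.asarray(self.center, float), axis=-1) - self.radius


def mc_propagator_weight(start, obstacles: Sequence, potential,
                         b: float, N: float, ds: float,
                         n_samples: int, rng: np.random.Generator) -> OracleResult:
    """Monte-Carlo estimate of q̃(start, N) for the given obstacles and
    adsorption potential (callable point -> k_BT energy, or None)."""
    n_steps = int(round(N / ds))
    step_var = b * b * ds / 3.0
    sd = np.sqrt(step_var)
    reflectors = [o for o in obstacles if isinstance(o, ReflectingSlab)]
    obstacles = [o for o in obstacles if not isinstance(o, ReflectingSlab)]
    pos = np.tile(np.asarray(start, float), (n_samples, 1))
    log_w = np.zeros(n_samples)
    alive = np.ones(n_samples, dtype=bool)
    phi_prev = [np.asarray(o.signed_distance(pos)) for o in obstacles]
    if any((p <= 0).any() for p in phi_prev):
        raise ValueError("chain start lies inside an obstacle")
    for _ in range(n_steps):
        stepv = rng.normal(scale=sd, size=(n_samples, 3))
        pos = pos + stepv
        for refl in reflectors:
            pos = refl.fold(pos)
        for i, o in enumerate(obstacles):
            phi = np.asarray(o.signed_distance(pos))
            dead = phi <= 0.0
            alive &= ~dead
            # bridge correction: crossing probability between samples
            with np.errstate(over="ignore"):
                p_cross = np.exp(-2.0 * np.clip(phi_prev[i], 0, None)
                                 * np.clip(phi, 0, None) / step_var)
            log_w = np.where(alive, log_w + np.log1p(-np.minimum(p_cross, 1 - 1e-15)),
                             log_w)
            phi_prev[i] = phi
        if potential is not None:
            log_w = np.where(alive, log_w - ds * potential(pos), log_w)
    w = np.where(alive, np.exp(log_w), 0.0)
    mean = float(w.mean())
    se = float(w.std(ddof=1) / np.sqrt(n_samples))
    if mean <= 0.0:
        raise RuntimeError("no surviving chains: estimate degenerate")
    return OracleResult(mean, se, "mc-chain")


def mc_chain_free_energy(tether_positions, obstacles_empty: Sequence,
                         obstacles_cargo: Sequence, b: float, N: float,
                         potential=None, ds: float = 0.05,
                         n_samples: int = 20000, seed: int = 0) -> OracleResult:
    """Brute-force ΔF = −Σ_i ln[q̃_cargo(r_i)/q̃_empty(r_i)] in k_BT.

    Chains are sampled independently per tether and per domain; the
    standard error combines the per-estimate delta-method errors.
    The adsorption potential (if any) acts only in the cargo domain.
    """
    rng = np.random.default_rng(seed)
    dF = 0.0
    var = 0.0
    for pos in np.atleast_2d(np.asarray(tether_positions, float)):
        qe = mc_propagator_weight(pos, obstacles_empty, None, b, N, ds,
                                  n_samples, rng)
        qc = mc_propagator_weight(pos, obstacles_cargo, potential, b, N, ds,
                                  n_samples, rng)
        dF += -(np.log(qc.estimate) - np.log(qe.estimate))
        var += (qc.stderr / qc.estimate) ** 2 + (qe.stderr / qe.estimate) ** 2
    return OracleResult(float(dF), float(np.sqrt(var)), "mc-chain")
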