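"""Free energies, densities, critical diameters and insertion forces.

All energies are in k_BT (β = 1), lengths in nm.  The free energy of
the chain ensemble is F = −ln Z with Z = Π_i q̃(r_i, N) evaluated at the
n tether positions; the physically meaningful output is the difference
ΔF = F_cargo − F_empty between matched discretizations, which cancels
the discretization bias of the absolute free energies.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import binding
from .geometry import (CargoSpec, DiscretizationParams, PoreGeometry,
                       TetherSet, build_domain, orientation_grid)
from .mde import ChainParameters, PropagatorField, SolverConfig, solve_qc, solve_qtilde

KBT_PER_NM_IN_PN = 4.114  # 1 k_BT/nm at T = 298 K


@dataclass
class FreeEnergyScan:
    """Rows of (cargo diameter, ΔF or orientation-averaged ΔF̄) plus the
    scan conditions."""

    table: pd.DataFrame
    metadata: dict = field(default_factory=dict)

    def __post_init__(self):
        d = self.table["d_cargo_nm"].to_numpy()
        if d.size > 1 and not np.all(np.diff(d) > 0):
            raise ValueError("cargo diameters must be strictly increasing")

    def to_csv(self, path) -> None:
        cols = self.table.copy()
        for key in ("gamma_kBT", "S_over_Sstar", "kappa", "seed"):
            if key not in cols:
                cols[key] = self.metadata.get(key, np.nan)
        cols.to_csv(path, index=False)


@dataclass
class DensityMap:
    """Mean segment density ρ(node) ≥ 0 (contour units per nm³)."""

    grid: object
    values: np.ndarray

    @property
    def total(self) -> float:
        """∫ρ dr; equals n·N up to contour-quadrature round-off."""
        return self.grid.integrate(self.values)


# ---------------------------------------------------------------------------
# partition function and free-energy differences
# ---------------------------------------------------------------------------

def log_partition(qtilde: PropagatorField, tethers: TetherSet) -> float:
    """ln Z = Σ_i ln q̃(r_i, N) with q̃ interpolated at the anchors."""
    vals = qtilde.at_points(tethers.positions)
    if np.any(vals <= 0.0):
        raise ValueError("q̃ ≤ 0 at a tether: anchor unreachable by the chain")
    return float(np.log(vals).sum())


def _pick_method(cargo: CargoSpec | None, gamma: float, method: str) -> str:
    if method != "auto":
        return method
    inert = cargo is None or gamma == 0.0 or cargo.spots is None \
        or cargo.spots.n_bind == 0
    if inert and (cargo is None or cargo.on_axis()):
        return "axisym"
    return "grid3d"


def pore_log_partition(pore: PoreGeometry, chain: ChainParameters,
                       tethers: TetherSet, cargo: CargoSpec | None = None,
                       gamma: float = 0.0, r_cutoff: float = 0.86,
                       cfg: SolverConfig | None = None,
                       disc: DiscretizationParams | None = None,
                       method: str = "auto") -> float:
    """ln Z of the pore with (or without) a cargo; V is the square-well
    adsorption field of the cargo's binding spots when γ > 0."""
    cfg = cfg or SolverConfig()
    method = _pick_method(cargo, gamma, method)
    grid = build_domain(pore, cargo, disc, method=method, kuhn_length=chain.b)
    pot = None
    if cargo is not None and gamma > 0.0 and cargo.spots is not None \
            and cargo.spots.n_bind > 0:
        if method == "axisym":
            raise ValueError("adsorption potential breaks axisymmetry; "
                             "use the 3-D grid")
        pot = binding.AdsorptionPotential.from_cargo(cargo, gamma, r_cutoff)
    qt = solve_qtilde(grid, chain, pot, cfg)
    return log_partition(qt, tethers)


def free_energy_difference(pore: PoreGeometry, chain: ChainParameters,
                           cargo: CargoSpec, tethers: TetherSet,
                           gamma: float = 0.0, r_cutoff: float = 0.86,
                           cfg: SolverConfig | None = None,
                           disc: DiscretizationParams | None = None,
                           method: str = "auto",
                           lnZ_empty: float | None = None) -> float:
    """ΔF = F_cargo − F_empty = −[ln Z_cargo − ln Z_empty] in k_BT.

    ``lnZ_empty`` may be passed to reuse an empty-pore solve; it must
    come from the same resolution and method family.
    """
    method = _pick_method(cargo, gamma, method)
    if lnZ_empty is None:
        empty_method = "axisym" if method == "axisym" else method
        lnZ_empty = pore_log_partition(pore, chain, tethers, None,
                                       cfg=cfg, disc=disc, method=empty_method)
    lnZ_cargo = pore_log_partition(pore, chain, tethers, cargo, gamma,
                                   r_cutoff, cfg, disc, method)
    return float(-(lnZ_cargo - lnZ_empty))


def orientation_averaged_dF(pore: PoreGeometry, chain: ChainParameters,
                            cargo: CargoSpec, tethers: TetherSet,
                            gamma: float, r_cutoff: float = 0.86,
                            cfg: SolverConfig | None = None,
                            disc: DiscretizationParams | None = None,
                            orientations=None,
                            average: str = "arithmetic",
                            lnZ_empty: float | None = None) -> float:
    """ΔF̄ = mean over cargo orientations of F_cargo, minus F_empty.

    The default orientation set is the full 220-point (θ, φ) grid; the
    mean is the arithmetic mean of free energies (a Boltzmann average of
    the partition functions is available via ``average="boltzmann"``).
    """
    if cargo.spots is None or cargo.spots.n_bind == 0:
        return free_energy_difference(pore, chain, cargo, tethers, 0.0,
                                      r_cutoff, cfg, disc,
                                      lnZ_empty=lnZ_empty)
    orientations = orientations if orientations is not None else orientation_grid()
    if lnZ_empty is None:
        lnZ_empty = pore_log_partition(pore, chain, tethers, None, cfg=cfg,
                                       disc=disc, method="grid3d")
    lnZs = []
    for (theta, phi) in orientations:
        oriented = CargoSpec(cargo.diameter, cargo.center, (theta, phi),
                             cargo.spots)
        lnZs.append(pore_log_partition(pore, chain, tethers, oriented, gamma,
                                       r_cutoff, cfg, disc, method="grid3d"))
    lnZs = np.asarray(lnZs)
    if average == "arithmetic":
        F_bar = float(np.mean(-lnZs))
    elif average == "boltzmann":
        F_bar = float(-(np.log(np.mean(np.exp(lnZs - lnZs.max()))) + lnZs.max()))
    else:
        raise ValueError(f"unknown averaging mode {average!r}")
    return F_bar - (-lnZ_empty)


# ---------------------------------------------------------------------------
# density
# ---------------------------------------------------------------------------

def mean_density(qtilde: PropagatorField, qc: PropagatorField,
                 chain: ChainParameters) -> DensityMap:
    """ρ(r) = ∫₀ᴺ ds q_c(r, s) q̃(r, N−s), trapezoidal in s.

    Requires both propagators stored at every contour step on the same
    grid; the symmetric contour grid makes N−s_k a stored step.
    """
    if qtilde.values is None or qc.values is None:
        raise ValueError("density needs store_all propagator fields")
    if qtilde.grid is not qc.grid or qtilde.s.shape != qc.s.shape:
        raise ValueError("propagators live on mismatched discretizations")
    integrand = qc.values * qtilde.values[::-1]
    rho = np.trapezoid(integrand, x=qc.s, axis=0)
    return DensityMap(qc.grid, np.maximum(rho, 0.0))


# ---------------------------------------------------------------------------
# derived quantities
# ---------------------------------------------------------------------------

def free_volume(pore: PoreGeometry, d_cargo: float = 0.0) -> float:
    """Fluid volume v = π D² h / 4 − π d³ / 6 (nm³)."""
    return float(np.pi * pore.diameter ** 2 * pore.height / 4.0
                 - np.pi * d_cargo ** 3 / 6.0)


def critical_diameter(scan: FreeEnergyScan | pd.DataFrame,
                      threshold: float = 1.0) -> float | None:
    """Diameter where ΔF first crosses the thermal energy, by linear
    interpolation between the bracketing grid points.

    Returns ``None`` when the scan never reaches the threshold.  If the
    curve crosses more than once (possible for strongly attractive
    cargoes), the final upward crossing is used — i.e. the largest
    diameter range with ΔF ≤ threshold — and a warning is issued.
    """
    table = scan.table if isinstance(scan, FreeEnergyScan) else scan
    d = table["d_cargo_nm"].to_numpy(dtype=float)
    f = table["dF_kBT"].to_numpy(dtype=float)
    if d.size < 2:
        raise ValueError("need at least two scan rows")
    up = np.flatnonzero((f[:-1] < threshold) & (f[1:] >= threshold))
    if f[0] >= threshold and up.size == 0:
        warnings.warn("ΔF already exceeds the threshold at the smallest "
                      "diameter; returning the grid start")
        return float(d[0])
    if up.size == 0:
        return None
    if up.size > 1 or f[0] >= threshold:
        warnings.warn("ΔF crosses the threshold more than once; using the "
                      "final upward crossing")
    k = up[-1]
    frac = (threshold - f[k]) / (f[k + 1] - f[k])
    return float(d[k] + frac * (d[k + 1] - d[k]))


def mean_insertion_force(pore: PoreGeometry, chain: ChainParameters,
                         d_cargo: float, tethers: TetherSet,
                         cfg: SolverConfig | None = None,
                         disc: DiscretizationParams | None = None,
                         z_path: np.ndarray | None = None,
                         z_step: float = 1.0,
                         lnZ_empty: float | None = None) -> pd.DataFrame:
    """Mean force −dΔF/dz along the axial insertion path, in pN.

    The cargo center moves on the axis from the pore mouth (sphere
    tangent to the open end) to the pore center; the slope of ΔF(z) is
    taken by central differences and converted at 298 K
    (1 k_BT/nm = 4.114 pN).
    """
    a = d_cargo / 2.0
    if z_path is None:
        z_path = np.arange(a, pore.height / 2.0 + 1e-9, z_step)
        if z_path[-1] < pore.height / 2.0 - 1e-9:
            z_path = np.append(z_path, pore.height / 2.0)
    z_path = np.asarray(z_path, dtype=float)
    if (z_path - a < -1e-9).any() or (z_path + a > pore.height + 1e-9).any():
        raise ValueError("cargo leaves the domain along the requested path")
    if lnZ_empty is None:
        lnZ_empty = pore_log_partition(pore, chain, tethers, None, cfg=cfg,
                                       disc=disc, method="axisym")
    dF = np.array([
        free_energy_difference(pore, chain,
                               CargoSpec(d_cargo, (0.0, 0.0, z)), tethers,
                               cfg=cfg, disc=disc, method="axisym",
                               lnZ_empty=lnZ_empty)
        for z in z_path])
    if z_path.size > 1:
        force = -np.gradient(dF, z_path) * KBT_PER_NM_IN_PN
    else:
        force = np.zeros_like(dF)
    return pd.DataFrame({"z_nm": z_path, "dF_kBT": dF, "force_pN": force})


def position_scan(pore: PoreGeometry, chain: ChainParameters,
                  cargo: CargoSpec, tethers: TetherSet,
                  cfg: SolverConfig | None = None,
                  disc: DiscretizationParams | None = None,
                  axial_offsets=(), lateral_offsets=()) -> pd.DataFrame:
    """ΔF for axial (along the pore axis) and lateral (radial) shifts of
    the cargo center away from the pore center."""
    rows = []
    base = np.asarray(pore.center)
    lnZ_empty_ax = pore_log_partition(pore, chain, tethers, None, cfg=cfg,
                                      disc=disc, method="axisym")
    lnZ_empty_3d = None
    for off in axial_offsets:
        c = base + np.array([0.0, 0.0, off])
        dF = free_energy_difference(pore, chain, CargoSpec(cargo.diameter, tuple(c)),
                                    tethers, cfg=cfg, disc=disc, method="axisym",
                                    lnZ_empty=lnZ_empty_ax)
        rows.append(("axial", float(off), dF))
    for off in lateral_offsets:
        c = base + np.array([off, 0.0, 0.0])
        if lnZ_empty_3d is None:
            lnZ_empty_3d = pore_log_partition(pore, chain, tethers, None,
                                              cfg=cfg, disc=disc, method="grid3d")
        dF = free_energy_difference(pore, chain, CargoSpec(cargo.diameter, tuple(c)),
                                    tethers, cfg=cfg, disc=disc, method="grid3d",
                                    lnZ_empty=lnZ_empty_3d)
        rows.append(("lateral", float(off), dF))
    return pd.DataFrame(rows, columns=["direction", "offset_nm", "dF_kBT"])
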