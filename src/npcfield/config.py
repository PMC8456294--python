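"""Run configuration and figure-style scan drivers.

A :class:`RunConfig` collects every geometry, chain, binding and
numerics parameter with the reference defaults (n = 80 chains,
b = 0.86 nm, l = 180 nm, D_pore = h_pore = 40 nm), round-trips through
YAML, and feeds the three drivers: the inert-cargo diameter scan, the
orientation-averaged attractive scan, and a self-validation suite.
All internal energies are k_BT; piconewtons appear only in outputs.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import binding, thermo
from .geometry import (CargoSpec, DiscretizationParams, PoreGeometry,
                       TetherSet, orientation_grid, place_tethers)
from .mde import ChainParameters, SolverConfig, error_ratio_control, solve_qc, solve_qtilde
from .thermo import FreeEnergyScan, critical_diameter

log = logging.getLogger("npcfield")

REFERENCE_DIAMETERS = tuple(range(2, 39, 2))  # nm, the standard scan grid


@dataclass
class RunConfig:
    # pore geometry
    pore_diameter_nm: float = 40.0
    pore_height_nm: float = 40.0
    # chain parameters
    chain_kuhn_nm: float = 0.86
    chain_contour_nm: float = 180.0
    chain_count: int = 80
    # cargo / binding
    cargo_diameter_nm: float = 20.0
    cargo_center: tuple = (0.0, 0.0, 20.0)
    gamma_kBT: float = 0.0
    r_cutoff_nm: float = 0.86
    coverage: float | None = None           # uniform-cap area fraction of S*
    kappa: float | None = None              # Kent concentration (clustered spots)
    # numerics
    ds: float = 0.4
    cell_volume_nm3: float = 0.1
    axisym_refine: int = 2
    # scan specifications
    diameters_nm: tuple = REFERENCE_DIAMETERS
    gammas_kBT: tuple = ()
    coverages: tuple = ()
    kappas: tuple = ()
    orientations: int | None = None         # None = full 220-point grid
    # bookkeeping
    seed: int = 0
    output_dir: str | None = None

    # -- derived objects ----------------------------------------------------

    def pore(self) -> PoreGeometry:
        return PoreGeometry(self.pore_diameter_nm, self.pore_height_nm)

    def chain(self) -> ChainParameters:
        return ChainParameters(self.chain_kuhn_nm, self.chain_contour_nm,
                               self.chain_count)

    def tethers(self) -> TetherSet:
        return place_tethers(self.pore(), self.chain_count)

    def solver(self) -> SolverConfig:
        return SolverConfig(ds=self.ds)

    def disc(self) -> DiscretizationParams:
        return DiscretizationParams(cell_volume_nm3=self.cell_volume_nm3,
                                    axisym_refine=self.axisym_refine)

    def orientation_set(self):
        full = orientation_grid()
        if self.orientations is None or self.orientations >= len(full):
            return full
        step = max(len(full) // self.orientations, 1)
        return full[::step][: self.orientations]

    # -- serialization ------------------------------------------------------

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        for k, v in d.items():
            if isinstance(v, tuple):
                d[k] = list(v)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        kwargs = {}
        for f in dataclasses.fields(cls):
            if f.name in d:
                v = d[f.name]
                kwargs[f.name] = tuple(v) if isinstance(v, list) else v
        return cls(**kwargs)

    def to_yaml(self, path) -> None:
        Path(path).write_text(yaml.safe_dump(self.to_dict(), sort_keys=True))

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        return cls.from_dict(yaml.safe_load(Path(path).read_text()))


# ---------------------------------------------------------------------------
# scan drivers
# ---------------------------------------------------------------------------

def run_inert_scan(config: RunConfig) -> tuple[FreeEnergyScan, dict]:
    """ΔF(d) for inert cargoes on the configured diameter grid, plus the
    critical-diameter report.  A failure at one diameter is logged and
    skipped instead of aborting the scan."""
    pore, chain, tethers = config.pore(), config.chain(), config.tethers()
    cfg, disc = config.solver(), config.disc()
    lnZ_empty = thermo.pore_log_partition(pore, chain, tethers, None,
                                          cfg=cfg, disc=disc, method="axisym")
    rows = []
    for d in config.diameters_nm:
        try:
            cargo = CargoSpec(float(d), (0.0, 0.0, pore.height / 2.0))
            dF = thermo.free_energy_difference(pore, chain, cargo, tethers,
                                               cfg=cfg, disc=disc,
                                               method="axisym",
                                               lnZ_empty=lnZ_empty)
            log.info("inert d=%g nm: dF = %.4f kBT", d, dF)
            rows.append((float(d), dF))
        except Exception as exc:  # per-diameter isolation
            log.error("inert scan failed at d=%g nm: %s", d, exc)
    table = pd.DataFrame(rows, columns=["d_cargo_nm", "dF_kBT"])
    table["dF_is_averaged"] = False
    scan = FreeEnergyScan(table, metadata={
        "gamma_kBT": 0.0, "S_over_Sstar": 0.0, "kappa": np.nan,
        "seed": config.seed, "D_pore_nm": pore.diameter,
        "b_nm": chain.b, "l_nm": chain.l, "n": chain.n})
    dstar = critical_diameter(scan) if len(rows) >= 2 else None
    report = {"critical_diameter_nm": dstar, "threshold_kBT": 1.0,
              "n_diameters": len(rows)}
    _maybe_write(config, scan, report, "inert_scan")
    return scan, report


def run_attractive_scan(config: RunConfig) -> tuple[list[FreeEnergyScan], dict]:
    """Orientation-averaged ΔF̄(d) scans for attractive cargoes.

    One scan per (γ, layout) combination, where the layout list is the
    configured uniform-cap coverages and/or Kent κ values at fixed
    binding area.  γ outside the 0.9-1.2 k_BT window is allowed with a
    warning."""
    pore, chain, tethers = config.pore(), config.chain(), config.tethers()
    cfg, disc = config.solver(), config.disc()
    gammas = config.gammas_kBT or (config.gamma_kBT,)
    layouts: list[tuple[str, float]] = [("uniform-cap", c) for c in
                                        (config.coverages or
                                         ((config.coverage,) if config.coverage
                                          is not None else ()))]
    layouts += [("kent", k) for k in
                (config.kappas or ((config.kappa,) if config.kappa is not None
                                   else ()))]
    if not layouts:
        raise ValueError("attractive scan needs coverages and/or kappas")
    orientations = config.orientation_set()
    lnZ_empty = thermo.pore_log_partition(pore, chain, tethers, None,
                                          cfg=cfg, disc=disc, method="grid3d")
    scans, reports = [], {}
    for gamma in gammas:
        if not 0.9 <= gamma <= 1.2 and gamma != 0.0:
            log.warning("interfacial energy γ=%.2f kBT outside the modelled "
                        "0.9-1.2 range", gamma)
        for kind, par in layouts:
            rows = []
            for d in config.diameters_nm:
                try:
                    cargo = _attractive_cargo(config, pore, float(d), kind, par)
                    dF = thermo.orientation_averaged_dF(
                        pore, chain, cargo, tethers, gamma,
                        config.r_cutoff_nm, cfg, disc,
                        orientations=orientations, lnZ_empty=lnZ_empty)
                    rows.append((float(d), dF))
                    log.info("γ=%.2f %s=%.2f d=%g: dF̄ = %.4f", gamma, kind,
                             par, d, dF)
                except Exception as exc:
                    log.error("attractive scan failed at d=%g: %s", d, exc)
            table = pd.DataFrame(rows, columns=["d_cargo_nm", "dF_kBT"])
            table["dF_is_averaged"] = True
            meta = {"gamma_kBT": gamma, "seed": config.seed,
                    "S_over_Sstar": par if kind == "uniform-cap" else 0.2,
                    "kappa": par if kind == "kent" else np.nan}
            scan = FreeEnergyScan(table, metadata=meta)
            scans.append(scan)
            key = f"gamma={gamma}_{kind}={par}"
            reports[key] = {"critical_diameter_nm":
                            critical_diameter(scan) if len(rows) >= 2 else None}
    _maybe_write(config, scans[-1], reports, "attractive_scan")
    return scans, reports


def _attractive_cargo(config: RunConfig, pore: PoreGeometry, d: float,
                      kind: str, par: float) -> CargoSpec:
    """Cargo with spots at fixed absolute binding area S = par·S* (the
    cap coverage / Kent selection is scaled per diameter)."""
    verts = binding.discretize_sphere_surface(d)
    S_target = par * binding.S_STAR if kind == "uniform-cap" else 0.2 * binding.S_STAR
    layout = "uniform-cap" if kind == "uniform-cap" else \
        binding.KentParams(kappa=par)
    spots = binding.spots_for_area(verts, d, S_target, layout,
                                   seed=config.seed)
    return CargoSpec(d, (0.0, 0.0, pore.height / 2.0), spots=spots)


def run_validation_suite(config: RunConfig) -> dict:
    """Machine-readable pass/fail report of the built-in checks: the
    half-space closed form, density normalization, the pure-Neumann null
    result, inert monotonicity and resolution convergence."""
    chain = config.chain()
    report: dict[str, dict] = {}

    err = error_ratio_control(b=chain.b, N=chain.N, spacing=config.disc().spacing,
                              ds=config.ds)
    report["halfspace_erf"] = {"max_rel_error": err, "pass": bool(err < 0.05)}

    # density normalization on a reduced pore
    pore = PoreGeometry(config.pore_diameter_nm / 2, config.pore_height_nm / 2)
    small_chain = ChainParameters(chain.b, chain.l / 4, 8)
    tethers = place_tethers(pore, small_chain.n)
    from .geometry import build_domain
    grid = build_domain(pore, None, config.disc(), method="axisym",
                        kuhn_length=chain.b)
    cfg = SolverConfig(ds=config.ds, store_all=True)
    qt = solve_qtilde(grid, small_chain, cfg=cfg)
    qc = solve_qc(grid, small_chain, tethers, qt, cfg=cfg)
    rho = thermo.mean_density(qt, qc, small_chain)
    expect = small_chain.n * small_chain.N
    rel = abs(rho.total - expect) / expect
    report["density_normalization"] = {"integral": rho.total,
                                       "expected": expect,
                                       "rel_error": rel,
                                       "pass": bool(rel < 0.01)}

    # pure-Neumann box: inserting nothing costs nothing
    from .geometry import build_box
    box = build_box(((0, 5), (0, 5), (0, 5)), 0.5)
    qt_box = solve_qtilde(box, small_chain, cfg=SolverConfig(ds=config.ds))
    report["pure_neumann_null"] = {
        "max_dev_from_1": float(np.max(np.abs(qt_box.final - 1.0))),
        "pass": bool(np.allclose(qt_box.final, 1.0, atol=1e-8))}

    # monotonicity on a short inert scan of the reduced pore
    lnZ_e = thermo.pore_log_partition(pore, small_chain, tethers, None,
                                      cfg=SolverConfig(ds=config.ds),
                                      disc=config.disc(), method="axisym")
    dFs = [thermo.free_energy_difference(
        pore, small_chain, CargoSpec(d, (0, 0, pore.height / 2)), tethers,
        cfg=SolverConfig(ds=config.ds), disc=config.disc(), method="axisym",
        lnZ_empty=lnZ_e) for d in (2.0, 6.0, 10.0)]
    report["inert_monotonic"] = {"dF": dFs,
                                 "pass": bool(np.all(np.diff(dFs) > 0))}

    # convergence: refined empty-pore free energy moves by < 0.5 kBT
    coarse = thermo.pore_log_partition(pore, small_chain, tethers, None,
                                       cfg=SolverConfig(ds=config.ds),
                                       disc=config.disc(), method="axisym")
    fine_disc = DiscretizationParams(
        cell_volume_nm3=config.cell_volume_nm3,
        axisym_refine=config.axisym_refine * 2)
    fine = thermo.pore_log_partition(pore, small_chain, tethers, None,
                                     cfg=SolverConfig(ds=config.ds / 2),
                                     disc=fine_disc, method="axisym")
    report["resolution_convergence"] = {
        "delta_F_empty": abs(coarse - fine),
        "pass": bool(abs(coarse - fine) < 0.5)}

    report["all_pass"] = all(v["pass"] for k, v in report.items()
                             if isinstance(v, dict))
    if config.output_dir:
        out = Path(config.output_dir)
        out.mkdir(parents=True, exist_ok=True)
        (out / "validation_report.json").write_text(
            json.dumps(report, indent=2, sort_keys=True))
    return report


def _maybe_write(config: RunConfig, scan: FreeEnergyScan, report: dict,
                 stem: str) -> None:
    if not config.output_dir:
        return
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    scan.to_csv(out / f"{stem}.csv")
    (out / f"{stem}_report.json").write_text(
        json.dumps(report, indent=2, sort_keys=True, default=float))
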