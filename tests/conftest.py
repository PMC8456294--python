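"""Shared fixtures: the expensive reference scans are computed once per
session; small-pore instances keep the 3-D and Monte-Carlo tests fast."""

from __future__ import annotations

import numpy as np
import pytest

import npcfield as nf
from npcfield.config import RunConfig, run_inert_scan


@pytest.fixture(scope="session")
def reference_scan():
    """Inert-cargo ΔF(d) scan at the reference parameters
    (n=80, b=0.86, l=180, D=h=40), diameters 2..38 step 2."""
    scan, report = run_inert_scan(RunConfig())
    return scan, report


@pytest.fixture(scope="session")
def dilated_scan():
    """Same protocol with the pore dilated to D = 60 nm."""
    scan, report = run_inert_scan(RunConfig(pore_diameter_nm=60.0))
    return scan, report


class SmallPore:
    """A D = h = 10 nm pore with 8 short chains: cheap enough for full
    3-D solves yet large enough to exercise every code path."""

    def __init__(self):
        self.pore = nf.PoreGeometry(10.0, 10.0)
        self.chain = nf.ChainParameters(b=0.86, l=21.5, n=8)
        self.tethers = nf.place_tethers(self.pore, 8, rings=1)
        self.disc = nf.DiscretizationParams(spacing_nm=0.43)
        self.cfg = nf.SolverConfig()
        self._lnZ = {}

    def lnZ_empty(self, method):
        if method not in self._lnZ:
            self._lnZ[method] = nf.pore_log_partition(
                self.pore, self.chain, self.tethers, None,
                cfg=self.cfg, disc=self.disc, method=method)
        return self._lnZ[method]

    def cargo(self, d=4.0, spots=None):
        return nf.CargoSpec(d, (0.0, 0.0, 5.0), spots=spots)


@pytest.fixture(scope="session")
def small_pore():
    return SmallPore()


@pytest.fixture(scope="session")
def small_verts():
    return nf.discretize_sphere_surface(4.0)


@pytest.fixture(scope="session")
def mc_vs_pde():
    """ΔF of a 4-nm inert cargo in a D = h = 10 nm pore, computed by
    direct chain sampling and by the propagator solver."""
    from npcfield.oracles import (CylinderBore, HardSphere, ReflectingSlab,
                                  mc_chain_free_energy)
    pore = nf.PoreGeometry(10.0, 10.0)
    b, N = 0.86, 25.0
    chain = nf.ChainParameters(b=b, l=N * b, n=4)
    teth = nf.place_tethers(pore, 4, rings=1)
    slab = ReflectingSlab(0.0, 10.0)
    mc = mc_chain_free_energy(
        teth.positions,
        [CylinderBore(5.0), slab],
        [CylinderBore(5.0), HardSphere((0, 0, 5.0), 2.0), slab],
        b, N, ds=0.0125, n_samples=8000, seed=11)
    pde = nf.free_energy_difference(
        pore, chain, nf.CargoSpec(4.0, (0, 0, 5.0)), teth,
        cfg=nf.SolverConfig(ds=0.1),
        disc=nf.DiscretizationParams(spacing_nm=0.15), method="axisym")
    return mc, pde
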