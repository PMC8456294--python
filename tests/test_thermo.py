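"""Free energies, density maps, critical diameters and position scans."""

import numpy as np
import pandas as pd
import pytest

import npcfield as nf


class TestLogPartition:
    def test_neumann_box_gives_zero(self):
        box = nf.build_box(((0, 5), (0, 5), (0, 5)), 0.5)
        chain = nf.ChainParameters(b=1.0, l=10.0, n=2)
        qt = nf.solve_qtilde(box, chain)
        teth = nf.TetherSet(np.array([[1, 1, 1.0], [3, 3, 3.0]]))
        assert nf.log_partition(qt, teth) == pytest.approx(0.0, abs=1e-9)

    def test_product_over_identical_tethers(self, small_pore):
        sp = small_pore
        grid = nf.build_domain(sp.pore, None, sp.disc, method="axisym")
        qt = nf.solve_qtilde(grid, sp.chain, cfg=sp.cfg)
        one = nf.TetherSet(sp.tethers.positions[:1])
        lnZ1 = nf.log_partition(qt, one)
        lnZ8 = nf.log_partition(qt, sp.tethers)
        assert lnZ8 == pytest.approx(8 * lnZ1, rel=1e-9)  # ring symmetry


class TestFreeEnergyDifference:
    def test_axisym_and_3d_paths_agree(self, small_pore):
        sp = small_pore
        cargo = sp.cargo(4.0)
        dF3 = nf.free_energy_difference(sp.pore, sp.chain, cargo, sp.tethers,
                                        cfg=sp.cfg, disc=sp.disc,
                                        method="grid3d",
                                        lnZ_empty=sp.lnZ_empty("grid3d"))
        dFa = nf.free_energy_difference(sp.pore, sp.chain, cargo, sp.tethers,
                                        cfg=sp.cfg, disc=sp.disc,
                                        method="axisym",
                                        lnZ_empty=sp.lnZ_empty("axisym"))
        assert dFa == pytest.approx(dF3, rel=0.05)

    def test_gamma_zero_with_spots_matches_inert(self, small_pore, small_verts):
        sp = small_pore
        spots = nf.uniform_cap_spots(small_verts, 0.5)
        dF0 = nf.free_energy_difference(sp.pore, sp.chain,
                                        sp.cargo(4.0, spots), sp.tethers,
                                        gamma=0.0, cfg=sp.cfg, disc=sp.disc,
                                        method="grid3d",
                                        lnZ_empty=sp.lnZ_empty("grid3d"))
        dFi = nf.free_energy_difference(sp.pore, sp.chain, sp.cargo(4.0),
                                        sp.tethers, cfg=sp.cfg, disc=sp.disc,
                                        method="grid3d",
                                        lnZ_empty=sp.lnZ_empty("grid3d"))
        assert dF0 == pytest.approx(dFi, abs=1e-9)

    def test_attraction_lowers_free_energy(self, small_pore, small_verts):
        sp = small_pore
        spots = nf.uniform_cap_spots(small_verts, 0.5)
        dFs = [nf.free_energy_difference(sp.pore, sp.chain,
                                         sp.cargo(4.0, spots), sp.tethers,
                                         gamma=g, cfg=sp.cfg, disc=sp.disc,
                                         method="grid3d",
                                         lnZ_empty=sp.lnZ_empty("grid3d"))
               for g in (0.9, 1.05, 1.2)]
        assert dFs[0] > dFs[1] > dFs[2]


class TestOrientationAverage:
    def test_empty_spot_set_reduces_to_plain_difference(self, small_pore,
                                                        small_verts):
        sp = small_pore
        empty = nf.BindingSpotSet(small_verts, np.empty(0, dtype=int))
        dF = nf.orientation_averaged_dF(sp.pore, sp.chain,
                                        sp.cargo(4.0, empty), sp.tethers,
                                        gamma=1.0, cfg=sp.cfg, disc=sp.disc,
                                        lnZ_empty=sp.lnZ_empty("axisym"))
        ref = nf.free_energy_difference(sp.pore, sp.chain, sp.cargo(4.0),
                                        sp.tethers, cfg=sp.cfg, disc=sp.disc,
                                        lnZ_empty=sp.lnZ_empty("axisym"))
        assert dF == pytest.approx(ref, abs=1e-12)

    def test_full_coverage_orientation_independent(self, small_pore,
                                                   small_verts):
        """A fully covered cargo is (up to the finite vertex lattice)
        rotationally symmetric: the average is the arithmetic mean of
        the per-orientation values, and those differ by only a few
        percent despite the lattice rotating with the cargo."""
        sp = small_pore
        dense = nf.discretize_sphere_surface(4.0, vertex_density=8.0)
        spots = nf.uniform_cap_spots(dense, 1.0)
        lnZe = sp.lnZ_empty("grid3d")
        ors = [(0.0, 0.0), (np.pi / 2, np.pi / 5)]
        singles = [nf.free_energy_difference(
            sp.pore, sp.chain,
            nf.CargoSpec(4.0, (0, 0, 5.0), o, spots), sp.tethers,
            gamma=1.0, cfg=sp.cfg, disc=sp.disc, method="grid3d",
            lnZ_empty=lnZe) for o in ors]
        avg = nf.orientation_averaged_dF(sp.pore, sp.chain,
                                         sp.cargo(4.0, spots), sp.tethers,
                                         gamma=1.0, cfg=sp.cfg, disc=sp.disc,
                                         orientations=ors, lnZ_empty=lnZe)
        assert avg == pytest.approx(np.mean(singles), rel=1e-9)
        assert singles[0] == pytest.approx(singles[1], rel=0.05)


class TestDensity:
    def test_normalization_and_wall_enrichment(self):
        pore = nf.PoreGeometry(20.0, 20.0)
        chain = nf.ChainParameters(b=0.86, l=45.0, n=8)
        teth = nf.place_tethers(pore, 8)
        grid = nf.build_domain(pore, nf.CargoSpec(6.0, (0, 0, 10.0)),
                               nf.DiscretizationParams(spacing_nm=0.43),
                               method="axisym")
        cfg = nf.SolverConfig(store_all=True)
        qt = nf.solve_qtilde(grid, chain, cfg=cfg)
        qc = nf.solve_qc(grid, chain, teth, qt, cfg=cfg)
        rho = nf.mean_density(qt, qc, chain)
        assert rho.values.min() >= 0.0
        assert rho.total == pytest.approx(chain.n * chain.N, rel=0.01)
        r = grid.points[:, 0]
        assert rho.values[(r > 7) & (r < 9)].mean() > \
            3 * rho.values[r < 2].mean()

    def test_unstored_fields_rejected(self, small_pore):
        sp = small_pore
        grid = nf.build_domain(sp.pore, None, sp.disc, method="axisym")
        qt = nf.solve_qtilde(grid, sp.chain, cfg=nf.SolverConfig())
        with pytest.raises(ValueError):
            nf.mean_density(qt, qt, sp.chain)  # no stored contour steps


class TestCriticalDiameter:
    def test_linear_interpolation(self):
        tab = pd.DataFrame({"d_cargo_nm": [4.0, 6.0], "dF_kBT": [0.8, 1.2]})
        assert nf.critical_diameter(tab) == pytest.approx(5.0)

    def test_no_crossing_returns_none(self):
        tab = pd.DataFrame({"d_cargo_nm": [4.0, 6.0, 8.0],
                            "dF_kBT": [0.1, 0.3, 0.9]})
        assert nf.critical_diameter(tab) is None

    def test_multiple_crossings_warns_and_uses_last(self):
        tab = pd.DataFrame({"d_cargo_nm": [2.0, 4.0, 6.0, 8.0],
                            "dF_kBT": [0.5, 1.5, 0.5, 1.5]})
        with pytest.warns(UserWarning, match="more than once"):
            d = nf.critical_diameter(tab)
        assert d == pytest.approx(7.0)

    def test_scan_rows_must_increase(self):
        with pytest.raises(ValueError):
            nf.FreeEnergyScan(pd.DataFrame({"d_cargo_nm": [4.0, 2.0],
                                            "dF_kBT": [0.1, 0.2]}))


class TestFreeVolumeAndForces:
    def test_free_volume_formula(self):
        pore = nf.PoreGeometry(40.0, 40.0)
        assert nf.free_volume(pore, 0.0) == pytest.approx(50265.48, abs=0.01)
        assert nf.free_volume(pore, 20.0) == pytest.approx(46076.69, abs=0.01)
        ds = np.arange(2.0, 40.0, 2.0)
        vs = [nf.free_volume(pore, d) for d in ds]
        assert np.all(np.diff(vs) < 0)

    def test_insertion_force_profile(self, small_pore):
        sp = small_pore
        prof = nf.mean_insertion_force(sp.pore, sp.chain, 3.0, sp.tethers,
                                       cfg=sp.cfg, disc=sp.disc, z_step=0.5,
                                       lnZ_empty=sp.lnZ_empty("axisym"))
        assert prof["z_nm"].iloc[0] == pytest.approx(1.5)  # tangent at mouth
        assert prof["z_nm"].iloc[-1] == pytest.approx(5.0)  # pore center
        # ΔF grows as the cargo is pushed in
        assert prof["dF_kBT"].iloc[-1] > prof["dF_kBT"].iloc[0]
        assert np.isfinite(prof["force_pN"]).all()

    def test_insertion_path_outside_domain_rejected(self, small_pore):
        sp = small_pore
        with pytest.raises(ValueError):
            nf.mean_insertion_force(sp.pore, sp.chain, 3.0, sp.tethers,
                                    cfg=sp.cfg, disc=sp.disc,
                                    z_path=np.array([0.5, 2.0]))


class TestPositionScan:
    def test_lateral_minimum_at_center_axial_variation_small(self, small_pore):
        sp = small_pore
        tab = nf.position_scan(sp.pore, sp.chain, sp.cargo(3.0), sp.tethers,
                               cfg=sp.cfg, disc=sp.disc,
                               axial_offsets=(-1.0, 0.0, 1.0),
                               lateral_offsets=(0.0, 1.0, 2.0))
        lat = tab[tab.direction == "lateral"].set_index("offset_nm").dF_kBT
        assert lat[0.0] < lat[1.0] < lat[2.0]
        ax = tab[tab.direction == "axial"].set_index("offset_nm").dF_kBT
        # moving along the axis changes ΔF less than moving into the brush
        assert abs(ax[1.0] - ax[0.0]) < lat[2.0] - lat[0.0]
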