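"""Binding-spot generation, the Kent distribution and the adsorption field."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy import integrate

import npcfield as nf
from npcfield.binding import S_STAR, spots_for_area


class TestSurfaceDiscretization:
    def test_vertex_count_conserves_density(self):
        v20 = nf.discretize_sphere_surface(20.0)
        assert len(v20) == round(np.pi * 400)  # 1257 at 1 vertex/nm²
        v40 = nf.discretize_sphere_surface(40.0)
        assert len(v40) == pytest.approx(4 * len(v20), abs=2)
        assert np.allclose(np.linalg.norm(v20, axis=1), 1.0)

    def test_vertices_distinct(self):
        v = nf.discretize_sphere_surface(4.0)
        gram = v @ v.T
        np.fill_diagonal(gram, -1.0)
        assert gram.max() < 1.0 - 1e-6  # strictly positive pairwise angles


class TestUniformCap:
    def test_degenerate_coverages(self):
        v = nf.discretize_sphere_surface(20.0)
        assert nf.uniform_cap_spots(v, 1.0).n_bind == len(v)
        assert nf.uniform_cap_spots(v, 0.0).n_bind == 0

    def test_hemisphere_boundary(self):
        v = nf.discretize_sphere_surface(20.0)
        s = nf.uniform_cap_spots(v, 0.5)
        # every selected vertex lies within π/2 of the cap pole
        from npcfield.binding import CAP_POLE
        cos = s.spot_directions @ CAP_POLE
        assert cos.min() >= -1e-9

    @settings(deadline=None, derandomize=True, max_examples=25)
    @given(st.floats(min_value=0.02, max_value=0.98))
    def test_selected_fraction_tracks_coverage(self, cov):
        v = nf.discretize_sphere_surface(20.0)
        s = nf.uniform_cap_spots(v, cov)
        n = len(v)
        assert abs(s.n_bind / n - cov) < 3.0 / np.sqrt(n) + 2.0 / n


class TestKent:
    def test_uniform_limit(self):
        assert nf.kent_density((0.0, 0.0, 1.0), nf.KentParams(0.0)) == \
            pytest.approx(1.0 / (4 * np.pi))

    def test_mean_direction_value_vmf(self):
        p = nf.KentParams(kappa=1.0)
        val = nf.kent_density(np.array(p.mean_direction), p)
        assert val == pytest.approx(np.e / (4 * np.pi * np.sinh(1.0)), rel=1e-10)

    @pytest.mark.parametrize("kappa,beta", [(0.0, 0.0), (1.0, 0.0),
                                            (5.0, 0.0), (3.0, 0.5)])
    def test_density_normalized_on_sphere(self, kappa, beta):
        params = nf.KentParams(kappa, beta)

        def f(th, ph):
            x = (np.sin(th) * np.cos(ph), np.sin(th) * np.sin(ph), np.cos(th))
            return nf.kent_density(x, params) * np.sin(th)

        val, _ = integrate.dblquad(f, 0, 2 * np.pi, 0, np.pi,
                                   epsabs=1e-9, epsrel=1e-9)
        assert val == pytest.approx(1.0, abs=1e-6)

    def test_negative_kappa_rejected(self):
        with pytest.raises(ValueError):
            nf.KentParams(-1.0)

    def test_sampling_concentration_limits(self, small_verts):
        # κ=0: selection statistically uniform → short resultant vector
        res0 = [np.linalg.norm(
            nf.kent_spots(small_verts, 10, nf.KentParams(0.0), s)
            .spot_directions.mean(axis=0)) for s in range(40)]
        # κ=50: spots hug the mean direction → long resultant
        res50 = [np.linalg.norm(
            nf.kent_spots(small_verts, 10, nf.KentParams(50.0), s)
            .spot_directions.mean(axis=0)) for s in range(40)]
        assert np.mean(res0) < 0.35 < 0.8 < np.mean(res50)

    def test_sampling_reproducible_and_bounded(self, small_verts):
        a = nf.kent_spots(small_verts, 10, nf.KentParams(2.0), seed=3)
        b = nf.kent_spots(small_verts, 10, nf.KentParams(2.0), seed=3)
        assert np.array_equal(a.spot_indices, b.spot_indices)
        with pytest.raises(ValueError):
            nf.kent_spots(small_verts, len(small_verts) + 1,
                          nf.KentParams(1.0), seed=0)


class TestPotential:
    def test_square_well_values(self):
        pot = nf.AdsorptionPotential(1.3, np.array([[0.0, 0.0, 0.0]]), 0.86)
        assert nf.potential_at((0, 0, 0), pot) == -1.3
        assert nf.potential_at((0, 0, 0.86), pot) == 0.0  # strict inequality
        assert nf.potential_at((5, 5, 5), pot) == 0.0

    def test_two_valued_everywhere(self):
        rng = np.random.default_rng(0)
        spots = rng.normal(size=(30, 3))
        pot = nf.AdsorptionPotential(0.9, spots, 0.86)
        vals = pot.evaluate(rng.normal(scale=2.0, size=(500, 3)))
        assert set(np.unique(vals)) <= {-0.9, 0.0}


class TestAreaAndClustering:
    def test_binding_area_formula(self):
        v = nf.discretize_sphere_surface(20.0)
        full = nf.uniform_cap_spots(v, 1.0)
        S, ratio = nf.binding_surface_area(full, 20.0)
        assert S == pytest.approx(np.pi * 400, rel=1e-12)
        assert ratio == pytest.approx(1.0)
        none = nf.uniform_cap_spots(v, 0.0)
        assert nf.binding_surface_area(none, 20.0)[0] == 0.0

    def test_area_ratio_fifth(self):
        v = nf.discretize_sphere_surface(20.0)
        s = spots_for_area(v, 20.0, 0.2 * S_STAR, "uniform-cap")
        S, ratio = nf.binding_surface_area(s, 20.0)
        assert S == pytest.approx(251.33, rel=0.02)
        assert ratio == pytest.approx(0.2, rel=0.02)

    def test_area_clamped_for_small_cargo(self):
        v = nf.discretize_sphere_surface(4.0)
        with pytest.warns(UserWarning, match="clamping"):
            s = spots_for_area(v, 4.0, S_STAR, "uniform-cap")
        assert s.n_bind == len(v)

    def test_clustering_degree_counts(self):
        """8 vertices near the wall-proximal point, 4 of them spots → 0.5."""
        near = []
        rng = np.random.default_rng(1)
        for _ in range(8):  # within ~10° of +x
            d = np.array([1.0, *rng.normal(scale=0.05, size=2)])
            near.append(d / np.linalg.norm(d))
        far = [np.array([-1.0, 0, 0]), np.array([0, 1.0, 0]),
               np.array([0, -1.0, 0]), np.array([0, 0, 1.0])]
        verts = np.array(near + far)
        spots = nf.BindingSpotSet(verts, np.arange(4))
        cargo = nf.CargoSpec(2.0, (0.0, 0.0, 5.0), spots=spots)
        tethers = nf.TetherSet(np.array([[4.0, 0.0, 5.0]]))
        p = nf.clustering_degree(spots, cargo, tethers, r_cluster=0.6)
        assert p == pytest.approx(0.5)

    def test_all_spots_gives_unity(self, small_verts):
        spots = nf.BindingSpotSet(small_verts, np.arange(len(small_verts)))
        cargo = nf.CargoSpec(4.0, (0, 0, 5.0), spots=spots)
        tethers = nf.TetherSet(np.array([[4.0, 0.0, 5.0]]))
        assert nf.clustering_degree(spots, cargo, tethers) == 1.0
        empty = nf.BindingSpotSet(small_verts, np.empty(0, dtype=int))
        with pytest.raises(ValueError):
            nf.clustering_degree(empty, cargo, tethers)

    def test_clustering_degree_increases_with_kappa(self, small_verts):
        """E[p_cluster] is non-decreasing in κ (50 seeds per κ)."""
        cargo_of = lambda s: nf.CargoSpec(4.0, (0, 0, 5.0), spots=s)
        teth = nf.TetherSet(np.array([[4.0, 0.0, 5.0]]))
        means = []
        for kappa in (0.5, 2.0, 8.0):
            vals = []
            for seed in range(50):
                s = nf.kent_spots(small_verts, 10, nf.KentParams(kappa), seed)
                vals.append(nf.clustering_degree(s, cargo_of(s), teth,
                                                 r_cluster=2.0))
            means.append(np.mean(vals))
            assert 0.0 < means[-1] <= 1.0
        assert means[0] < means[1] < means[2]
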