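"""Microsphere deposition: counting, placement, population, rasterization."""

import numpy as np
import pytest

import remicro as rm
from remicro.deposition import (
    _deposit_positions,
    default_cluster_budget,
    nearest_neighbor_distances,
    uniform_positions,
)
from conftest import small_geometry


class TestCounting:
    def test_target_count_default_geometry(self):
        cfg = rm.ModelConfig(variant="UNI", concentration_per_ml=5000.0)
        assert rm.target_count(cfg) == 53240
        cfg = rm.ModelConfig(variant="UNI", concentration_per_ml=60000.0)
        assert rm.target_count(cfg) == 638880

    def test_zero_concentration_rejected(self):
        with pytest.raises(ValueError):
            rm.ModelConfig(concentration_per_ml=0.0)


class TestLattice:
    def test_default_lattice_count(self):
        cfg = rm.ModelConfig(variant="MED")
        clusters = rm.place_clusters_lattice(cfg)
        assert len(clusters) == 46 ** 3 == 97336

    def test_spacing_equals_side_gives_single_cluster(self):
        cfg = small_geometry(100, variant="MED")
        clusters = rm.place_clusters_lattice(cfg, spacing_um=cfg.side_um)
        assert len(clusters) == 1

    def test_lattice_nearest_neighbor_is_spacing(self):
        cfg = small_geometry(100, variant="MED")
        clusters = rm.place_clusters_lattice(cfg, spacing_um=470.0)
        nn = nearest_neighbor_distances(clusters)
        assert np.allclose(nn, 470.0)

    def test_oversized_spacing_raises(self):
        cfg = small_geometry(50, variant="MED")
        with pytest.raises(ValueError):
            rm.place_clusters_lattice(cfg, spacing_um=cfg.side_um * 2)


@pytest.fixture(scope="module")
def layout():
    cfg = small_geometry(200, variant="REF", seed=9)
    rng = np.random.default_rng(9)
    return cfg, rm.place_clusters_stochastic(cfg, n_clusters=600, rng=rng)


class TestStochasticPlacement:
    def test_first_cluster_always_accepted(self):
        cfg = small_geometry(60, variant="REF")
        one = rm.place_clusters_stochastic(cfg, n_clusters=1,
                                           rng=np.random.default_rng(0))
        assert len(one) == 1

    def test_nearest_neighbor_floor(self, layout):
        _, clusters = layout
        nn = nearest_neighbor_distances(clusters)
        assert nn.min() >= 89.0

    def test_support_within_observed_range(self, layout):
        _, clusters = layout
        nn = nearest_neighbor_distances(clusters)
        assert nn.max() <= 3105.0

    def test_spheres_inside_volume(self, layout):
        cfg, clusters = layout
        for c in clusters:
            r = c.diameter / 2.0
            assert np.all(c.center - r >= -1e-9)
            assert np.all(c.center + r <= cfg.side_um + 1e-9)


class TestPopulate:
    def _lattice(self, n=97336):
        cfg = rm.ModelConfig(variant="MED")
        return rm.place_clusters_lattice(cfg)

    def test_fixed_median_population_count(self):
        clusters = self._lattice()
        populated = rm.populate_clusters(clusters, 5, target=53240,
                                         rng=np.random.default_rng(1))
        assert len(populated) == 10648  # ceil(53240 / 5)
        assert sum(c.population for c in populated) == 53240

    def test_truncation_hits_target_exactly(self):
        clusters = self._lattice()
        populated = rm.populate_clusters(clusters, 5, target=53242,
                                         rng=np.random.default_rng(1))
        assert sum(c.population for c in populated) == 53242
        assert min(c.population for c in populated) >= 1

    def test_capacity_error_names_variant(self):
        clusters = self._lattice()
        with pytest.raises(rm.CapacityError, match="MED"):
            rm.populate_clusters(clusters, 5, target=97336 * 5 + 1,
                                 rng=np.random.default_rng(1), variant="MED")


class TestMicrospheres:
    def test_positions_within_cluster_sphere(self):
        c = rm.Cluster(center=[500.0, 500.0, 500.0], diameter=300.0,
                       population=200)
        pos = rm.place_microspheres(c, rng=np.random.default_rng(2))
        assert pos.shape == (200, 3)
        r = np.linalg.norm(pos - c.center, axis=1)
        assert r.max() <= 150.0

    def test_single_sphere(self):
        c = rm.Cluster(center=[100.0, 100.0, 100.0], diameter=50.0,
                       population=1)
        assert rm.place_microspheres(c, rng=np.random.default_rng(0)).shape == (1, 3)

    def test_mean_radius_is_three_quarters(self):
        # uniform in a sphere: E[r] = (3/4) R
        c = rm.Cluster(center=[0.0, 0.0, 0.0], diameter=2.0, population=200000)
        pos = rm.place_microspheres(c, rng=np.random.default_rng(3))
        assert np.linalg.norm(pos, axis=1).mean() == pytest.approx(0.75, rel=0.01)

    def test_collision_avoidance_spreads_spheres(self):
        # plenty of voxels per cluster -> no multi-occupancy after redraws
        cfg = small_geometry(100)
        clusters = [rm.Cluster(center=[1500.0, 1500.0, 1500.0], diameter=900.0,
                               population=50)]
        pos = _deposit_positions(clusters, np.random.default_rng(0),
                                 cfg.voxel_pitch_um, cfg.dims)
        grid = rm.rasterize(pos, cfg)
        assert grid.counts.max() == 1


class TestRasterize:
    def test_voxel_conventions(self):
        cfg = small_geometry(100)
        p = cfg.voxel_pitch_um
        pos = np.array([[0.0, 0.0, 0.0], [p, 0.0, 0.0], [cfg.side_um] * 3])
        grid = rm.rasterize(pos, cfg)
        assert grid.counts[0, 0, 0] == 1
        assert grid.counts[1, 0, 0] == 1
        assert grid.counts[-1, -1, -1] == 1  # upper boundary clamps
        assert grid.total == 3

    def test_positions_outside_volume_rejected(self):
        cfg = small_geometry(50)
        with pytest.raises(ValueError):
            rm.rasterize(np.array([[-1.0, 0.0, 0.0]]), cfg)


class TestUniformModel:
    def test_exact_count_and_margins(self):
        cfg = small_geometry(100, variant="UNI", concentration_per_ml=20000.0)
        pos = uniform_positions(cfg)
        assert len(pos) == rm.target_count(cfg)
        assert pos.min() > 0 and pos.max() < cfg.side_um

    def test_build_succeeds_any_concentration_below_voxel_count(self):
        cfg = small_geometry(60, variant="UNI", concentration_per_ml=40000.0)
        res = rm.build_model(cfg)
        assert res.grid.total == rm.target_count(cfg)


class TestBuildModel:
    def test_exact_sphere_count_every_variant(self, ):
        for variant in ("REF", "MED", "UNI", "DIA", "DIST", "POP", "DIST_POP"):
            cfg = small_geometry(150, variant=variant,
                                 concentration_per_ml=8000.0, seed=5)
            res = rm.build_model(cfg)
            assert res.grid.total == rm.target_count(cfg), variant
            assert np.all(res.grid.counts >= 0)

    def test_median_model_capacity_ceiling(self):
        # fixed-population-5 lattice cannot reach 50,000 /mL
        with pytest.raises(rm.CapacityError):
            rm.build_model(rm.ModelConfig(variant="MED",
                                          concentration_per_ml=50000.0))

    def test_capacity_law_small_geometry(self):
        # max concentration = floor(L/470)^3 * 5 / volume for fixed pop 5
        cfg = small_geometry(150, variant="MED", concentration_per_ml=8000.0)
        cap = int(cfg.side_um // 470.0) ** 3 * 5 / cfg.volume_ml
        ok = rm.build_model(rm.ModelConfig(**{**cfg.__dict__,
                                              "concentration_per_ml": cap * 0.99}))
        assert ok.grid.total > 0
        with pytest.raises(rm.CapacityError):
            rm.build_model(rm.ModelConfig(**{**cfg.__dict__,
                                             "concentration_per_ml": cap * 1.01}))

    def test_reference_model_reaches_reference_capacity(self):
        cfg = small_geometry(150, variant="REF",
                             concentration_per_ml=60000.0, seed=2)
        res = rm.build_model(cfg)
        assert res.grid.total == rm.target_count(cfg)

    def test_determinism_same_seed_identical_grid(self):
        cfg = small_geometry(120, variant="REF", concentration_per_ml=10000.0,
                             seed=77)
        a = rm.build_model(cfg)
        b = rm.build_model(cfg)
        assert np.array_equal(a.grid.counts, b.grid.counts)
        assert np.array_equal(a.realized_nn_distances, b.realized_nn_distances)

    def test_layout_reuse_changes_population_only(self):
        cfg = small_geometry(120, variant="REF", concentration_per_ml=5000.0,
                             seed=8)
        first = rm.build_model(cfg)
        centers = np.array([c.center for c in first.clusters])
        for c in first.clusters:
            c.population = 0
        cfg2 = rm.ModelConfig(**{**cfg.__dict__, "concentration_per_ml": 10000.0})
        second = rm.build_model(cfg2, layout=first.clusters)
        assert second.grid.total == rm.target_count(cfg2)
        assert np.array_equal(centers,
                              np.array([c.center for c in second.clusters]))

    def test_cluster_budget_scales_with_reference_capacity(self):
        cfg = small_geometry(150)
        b1 = default_cluster_budget(cfg, mean_pop=5.0)
        b2 = default_cluster_budget(cfg, mean_pop=18.0)
        assert b1 > b2
        assert b1 <= int(cfg.side_um // 470.0) ** 3
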